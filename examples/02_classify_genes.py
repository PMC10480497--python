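"""Classify genes by expression specificity across disease-level profiles.

Aggregates cell lines into CLDs (per-disease mean profiles), assigns every
gene one of five specificity categories (enriched / group-enriched /
enhanced / low-specificity / not-detected) and one of five distribution
categories, and compares the result with the generator's planted truth.
"""

from collections import Counter

from cellrep import classify as cls
from cellrep import normalize as norm
from cellrep import synthetic as syn

cfg = syn.PanelConfig(seed=2, dispersion=0.0)   # noiseless: exact recovery
counts, tpm, ann, truth = syn.generate_panel(cfg)
ntpm = norm.tpm_to_ntpm(tpm)

clds = cls.aggregate_cld(ntpm, ann)
calls = cls.classify_matrix(clds)
dist = cls.distribution_matrix(ntpm)

spec_counts = Counter(c.category for c in calls.values())
dist_counts = Counter(d.category for d in dist.values())
agree = sum(1 for g, c in calls.items()
            if c.category == truth.gene_category[g])

print(f"{ntpm.n_samples} cell lines -> {clds.n_samples} CLDs")
print("specificity categories:", dict(spec_counts))
print("distribution categories:", dict(dist_counts))
print(f"agreement with planted truth: {agree}/{len(calls)} "
      f"({100 * agree / len(calls):.1f}%)")
print("at dispersion 0 the classifier recovers every planted category;")
print("the elevated union (enriched+group-enriched+enhanced) per disease")
print("is the disease's signature used downstream for GSEA ranking.")
elev = cls.elevated_set(calls, clds.sample_ids[0])
print(f"example: {clds.sample_ids[0]} has {len(elev)} elevated genes")
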