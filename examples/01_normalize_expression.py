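"""Normalize a TPM panel to nTPM (pTPM rescaling + TMM between-sample factors).

Generates a small synthetic panel, runs the normalization chain, and shows
the per-sample TMM scaling factors.  Factors near 1 mean the samples were
already on a comparable scale; the geometric mean of the factors is 1 by
construction, so nTPM values are comparable across samples.
"""

import numpy as np

from cellrep import normalize as norm
from cellrep import synthetic as syn

cfg = syn.PanelConfig(seed=1, n_diseases=4, lines_per_disease=3, n_genes=500,
                      enriched_per_disease=6, group_enriched_per_group=4,
                      enhanced_per_disease=4)
counts, tpm, ann, truth = syn.generate_panel(cfg)

ptpm = norm.to_ptpm(tpm, tpm.gene_ids)
ref = norm.select_tmm_reference(ptpm)
factors = norm.tmm_factors(ptpm, ref=ref)
ntpm = norm.apply_tmm(ptpm, factors)

print(f"panel: {tpm.n_genes} genes x {tpm.n_samples} cell lines")
print(f"TMM reference sample (median upper-quartile column): {ref}")
print("TMM factors (first 6):")
for sid, f in factors.head(6).items():
    print(f"  {sid}: {f:.4f}")
print(f"factor product: {np.prod(factors.to_numpy()):.6f}  (must be 1)")
print(f"nTPM matrix: {ntpm.n_genes} x {ntpm.n_samples}, unit {ntpm.unit!r}")
print("column sums differ from 1e6 exactly by each sample's TMM factor,")
print("which is what makes expression comparable across samples.")
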