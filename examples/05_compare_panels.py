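"""Panel comparison utilities: CLD-cohort correlation, clustering, overlap.

Shows the Spearman correlation matrix between disease-level cell-line
profiles and their matched pseudo-tumor cohorts (the diagonal should carry
the row maxima), complete-linkage clustering of CLDs on the 1 - rho
distance, and a hypergeometric overlap test between two gene sets.
"""

from cellrep import classify as cls
from cellrep import compare as cmp
from cellrep import normalize as norm
from cellrep import synthetic as syn

cfg = syn.PanelConfig(seed=5, n_diseases=5, lines_per_disease=4, n_genes=900,
                      enriched_per_disease=10, group_enriched_per_group=6,
                      enhanced_per_disease=6)
_, tpm, ann, truth = syn.generate_panel(cfg)
cohort_tpm, cohort_ann, truth = syn.generate_cohorts(cfg, truth,
                                                     samples_per_cohort=12)
ntpm = norm.tpm_to_ntpm(tpm)
cohort_ntpm = norm.tpm_to_ntpm(cohort_tpm)
clds = cls.aggregate_cld(ntpm, ann)
cohort_clds = cls.aggregate_cld(cohort_ntpm, cohort_ann, by="cohort")

rho, tests = cmp.cld_cohort_correlation(clds, cohort_clds,
                                        truth.disease_cohort)
print("CLD x cohort Spearman rho (matched pairs on the diagonal):")
print(rho.round(3).to_string())
print("\none-sided signed-rank test (unmatched < matched):")
print(tests[["matched_rho", "p_value"]].round(4).to_string())

Z, labels = cmp.hcluster_profiles(clds)
print("\ncomplete-linkage dendrogram (Newick, distance 1 - rho):")
print(cmp.linkage_to_newick(Z, labels))

a = truth.elevated_genes("D00")
b = truth.elevated_genes("D01")
universe = set(truth.gene_category)
res = cmp.hypergeom_overlap(a, b, universe, "D00_elevated", "D01_elevated")
print(f"\nelevated-set overlap D00 vs D01: {res.n_overlap} genes, "
      f"hypergeometric p = {res.p_value:.3g}")
print("(the shared genes are the planted group-enriched ones both diseases")
print("carry; the test asks if that overlap exceeds chance)")
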