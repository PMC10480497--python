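"""Shared fixtures: small matrices and a compact synthetic panel."""

import numpy as np
import pandas as pd
import pytest

from cellrep import classify as cls
from cellrep import normalize as norm
from cellrep import synthetic as syn
from cellrep.matrix import ExpressionMatrix, SampleAnnotation


def make_matrix(values, genes=None, samples=None, unit="nTPM"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            unit)


@pytest.fixture(scope="session")
def small_config():
    """A compact panel configuration used across recovery tests."""
    return syn.PanelConfig(seed=11, n_diseases=5, lines_per_disease=5,
                           n_genes=1200, enriched_per_disease=15,
                           group_enriched_per_group=8, enhanced_per_disease=8)


@pytest.fixture(scope="session")
def small_panel(small_config):
    """Panel + cohorts generated once per session (dispersion 0.1)."""
    counts, tpm, ann, truth = syn.generate_panel(small_config)
    cohort_tpm, cohort_ann, truth = syn.generate_cohorts(
        small_config, truth, samples_per_cohort=15)
    return {
        "config": small_config, "counts": counts, "tpm": tpm, "ann": ann,
        "truth": truth, "cohort_tpm": cohort_tpm, "cohort_ann": cohort_ann,
    }


@pytest.fixture(scope="session")
def small_panel_ntpm(small_panel):
    """Normalized panel + cohort matrices and disease-level profiles."""
    ntpm = norm.tpm_to_ntpm(small_panel["tpm"])
    cohort_ntpm = norm.tpm_to_ntpm(small_panel["cohort_tpm"])
    clds = cls.aggregate_cld(ntpm, small_panel["ann"])
    cohort_clds = cls.aggregate_cld(cohort_ntpm, small_panel["cohort_ann"],
                                    by="cohort")
    return {"ntpm": ntpm, "cohort_ntpm": cohort_ntpm, "clds": clds,
            "cohort_clds": cohort_clds, **small_panel}
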