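"""Synthetic cell-line panels, pseudo-tumor cohorts, and signature matrices.

Every generator plants known structure so downstream stages have a
recoverable ground truth:

* :func:`generate_panel` builds a multi-disease cell-line panel with planted
  **enriched** (one disease at ``fold_planted`` times baseline),
  **group-enriched** (a small disease group elevated together) and
  **enhanced** genes (one disease moderately elevated over the *mean* of the
  others while staying below the enriched threshold against the single
  highest other disease — forced by giving one other disease a moderately
  raised mean), plus housekeeping and background genes.  Counts are drawn
  from a negative binomial (gamma-Poisson; variance = mu + dispersion * mu^2,
  dispersion 0 degenerates to Poisson) and TPM is derived by per-sample
  scaling to one million.

* Each disease's first cell line is the designated **best line**: its
  expected profile equals the disease mean exactly.  Every other line gets a
  line-specific multiplicative jitter on background genes and a line-specific
  attenuation of its enriched/group-enriched folds, so both the correlation
  and the enrichment metric genuinely prefer the best line.

* :func:`generate_cohorts` emits one disease-matched pseudo-tumor cohort per
  disease, sharing the disease's planted elevated genes, with purity labels
  drawn inside a configurable range and stage labels of which one stage
  carries an extra planted fourfold-plus signature.

* :func:`generate_signature_matrix` builds a random weight matrix with
  planted per-sample activities and centered-log expression
  ``activities @ weights.T + Gaussian noise``.

All randomness flows from a single integer seed; per-matrix sub-streams are
derived deterministically, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleAnnotation


class ConfigurationError(ValueError):
    """Raised when a generator configuration is infeasible."""


@dataclass
class PanelConfig:
    """Conditions for a synthetic multi-disease cell-line panel.

    The defaults describe a desk-scale panel: 8 cancer types with 6 lines
    each, 2,000 protein-coding genes at a 20 nTPM typical baseline, planted
    folds of 8 (twice the classification threshold), and mild
    negative-binomial overdispersion.
    """

    n_diseases: int = 8
    lines_per_disease: int | Sequence[int] = 6
    n_genes: int = 2000
    frac_housekeeping: float = 0.10
    enriched_per_disease: int = 20
    group_enriched_per_group: int = 10
    group_size: int = 2
    enhanced_per_disease: int = 10
    fold_planted: float = 8.0
    baseline_expression: float = 20.0
    dispersion: float = 0.1
    library_size: float = 1.0e7
    seed: int = 0
    #: log2-scale sd of per-line multiplicative jitter on background genes
    #: (the designated best line of each disease gets none).
    line_jitter_sd: float = 0.4
    #: range of the per-line fold attenuation exponent applied to planted
    #: enriched / group-enriched genes of non-best lines.
    attenuation_range: tuple[float, float] = (0.05, 0.15)
    #: range of the per-line fraction of its elevated genes whose planted
    #: fold is dropped to baseline (the best line drops none).
    dropout_frac_range: tuple[float, float] = (0.05, 0.15)
    #: extra background jitter added to metastatic lines (log2 sd).
    metastatic_extra_jitter: float = 0.0
    #: fraction of non-planted, non-housekeeping genes that are detected.
    background_detected_frac: float = 0.65

    def lines_for(self) -> list[int]:
        if isinstance(self.lines_per_disease, int):
            return [self.lines_per_disease] * self.n_diseases
        lines = list(self.lines_per_disease)
        if len(lines) != self.n_diseases:
            raise ConfigurationError(
                "lines_per_disease list length must equal n_diseases")
        return lines

    def validate(self) -> None:
        if self.n_diseases < 2:
            raise ConfigurationError("need at least two diseases")
        if self.fold_planted <= 4.0:
            raise ConfigurationError(
                "fold_planted must strictly exceed the classification threshold 4")
        if not (0.0 <= self.frac_housekeeping <= 1.0):
            raise ConfigurationError("frac_housekeeping must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be nonnegative")
        if self.group_enriched_per_group > 0:
            if not (2 <= self.group_size <= 10):
                raise ConfigurationError("group_size must lie in [2, 10]")
            if self.group_size >= self.n_diseases:
                raise ConfigurationError(
                    "group_size must leave at least one disease outside the group")
        if self.enhanced_per_disease > 0 and self.n_diseases < 4:
            raise ConfigurationError(
                "enhanced genes require at least four diseases (the moderate "
                "elevation needs margin against every other category)")
        n_hk = round(self.frac_housekeeping * self.n_genes)
        planted = (self.n_diseases * self.enriched_per_disease
                   + self.n_diseases * self.group_enriched_per_group
                   + self.n_diseases * self.enhanced_per_disease)
        if n_hk + planted > self.n_genes:
            raise ConfigurationError(
                f"planted sets ({planted}) + housekeeping ({n_hk}) exceed "
                f"n_genes ({self.n_genes})")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic panel / cohort set."""

    gene_category: dict[str, str] = field(default_factory=dict)
    gene_groups: dict[str, list[str]] = field(default_factory=dict)
    disease_cohort: dict[str, str] = field(default_factory=dict)
    cohort_best_line: dict[str, str] = field(default_factory=dict)
    best_line: dict[str, str] = field(default_factory=dict)  # disease -> line
    line_attenuation: dict[str, float] = field(default_factory=dict)
    stage_signatures: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    activities: Optional[pd.DataFrame] = None

    def elevated_genes(self, disease: str) -> set[str]:
        """Planted elevated set of a disease: enriched + group-enriched +
        enhanced genes having the disease among their defining groups."""
        return {
            g for g, cat in self.gene_category.items()
            if cat in ("enriched", "group-enriched", "enhanced")
            and disease in self.gene_groups.get(g, [])
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_category": self.gene_category,
            "gene_groups": self.gene_groups,
            "disease_cohort": self.disease_cohort,
            "cohort_best_line": self.cohort_best_line,
            "best_line": self.best_line,
            "line_attenuation": self.line_attenuation,
            "stage_signatures": {c: {s: sorted(g) for s, g in d.items()}
                                 for c, d in self.stage_signatures.items()},
            "activities": (None if self.activities is None
                           else self.activities.to_dict(orient="split")),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        act = d.get("activities")
        return cls(
            gene_category=d["gene_category"],
            gene_groups=d["gene_groups"],
            disease_cohort=d["disease_cohort"],
            cohort_best_line=d["cohort_best_line"],
            best_line=d["best_line"],
            line_attenuation=d["line_attenuation"],
            stage_signatures={c: {s: list(g) for s, g in sd.items()}
                              for c, sd in d["stage_signatures"].items()},
            activities=(None if act is None else
                        pd.DataFrame(act["data"], index=act["index"],
                                     columns=act["columns"])),
        )


# ---------------------------------------------------------------------------


def _enhanced_levels(n_diseases: int) -> tuple[float, float]:
    """Target (a, b) multipliers for an enhanced gene.

    The elevated disease sits at ``a`` times baseline and one designated other
    disease at ``b = a / 3.5`` so that a/b < 4 (not enriched) while
    ``a >= 4.6 x`` the mean of the other diseases (comfortably enhanced) and
    the top-2 mean stays below 4 x the remaining maximum (not group-enriched).
    """
    D = n_diseases
    a = (4.6 * (D - 2) / (D - 1)) / (1.0 - 4.6 / (3.5 * (D - 1)))
    return a, a / 3.5


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial counts, var = mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.maximum(mu, 0.0)
    if dispersion <= 0:
        return rng.poisson(mu).astype(np.int64)
    shape = 1.0 / dispersion
    lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.shape) * mu / shape, 0.0)
    return rng.poisson(lam).astype(np.int64)


def _counts_to_tpm(counts: np.ndarray) -> np.ndarray:
    colsums = counts.sum(axis=0, keepdims=True).astype(float)
    colsums[colsums == 0] = 1.0
    return counts / colsums * 1.0e6


def _build_means(config: PanelConfig) -> tuple[np.ndarray, dict[str, str],
                                                dict[str, list[str]]]:
    """Deterministic disease mean profiles (genes x diseases) plus the planted
    category and defining-group maps.  Shared by panel and cohort generation
    so both sides agree on the planted structure."""
    D = config.n_diseases
    diseases = [f"D{i:02d}" for i in range(D)]
    base = config.baseline_expression
    n_hk = round(config.frac_housekeeping * config.n_genes)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    rng_means = np.random.default_rng([config.seed, 11])
    M = np.zeros((config.n_genes, D))
    category: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        idx = list(range(cursor, cursor + n))
        cursor += n
        return idx

    for d_i, disease in enumerate(diseases):
        for g in take(config.enriched_per_disease):
            M[g, :] = base
            M[g, d_i] = config.fold_planted * base
            category[gene_ids[g]] = "enriched"
            groups[gene_ids[g]] = [disease]
    if config.group_enriched_per_group > 0:
        for d_i in range(D):
            members = [(d_i + k) % D for k in range(config.group_size)]
            labels = sorted(diseases[m] for m in members)
            for g in take(config.group_enriched_per_group):
                M[g, :] = base
                M[g, members] = config.fold_planted * base
                category[gene_ids[g]] = "group-enriched"
                groups[gene_ids[g]] = labels
    if config.enhanced_per_disease > 0:
        a_lvl, b_lvl = _enhanced_levels(D)
        for d_i, disease in enumerate(diseases):
            partner = (d_i + 1) % D
            for g in take(config.enhanced_per_disease):
                M[g, :] = base
                M[g, d_i] = a_lvl * base
                M[g, partner] = b_lvl * base
                category[gene_ids[g]] = "enhanced"
                groups[gene_ids[g]] = [disease]
    # housekeeping genes carry most of the transcriptome mass (as the top
    # expressed genes do in real bulk RNA-seq), keeping the planted nTPM
    # scale close to the per-sample 1e6 pTPM budget
    for g in take(n_hk):
        level = float(np.exp(rng_means.uniform(np.log(50 * base),
                                               np.log(500 * base))))
        M[g, :] = level
        category[gene_ids[g]] = "low-specificity"
        groups[gene_ids[g]] = []
    remaining = list(range(cursor, config.n_genes))
    n_det = round(config.background_detected_frac * len(remaining))
    for j, g in enumerate(remaining):
        if j < n_det:
            level = float(np.exp(rng_means.uniform(np.log(5.0), np.log(10 * base))))
            cat = "low-specificity"
        else:
            level = float(rng_means.uniform(0.0, 0.2))
            cat = "not-detected"
        M[g, :] = level
        category[gene_ids[g]] = cat
        groups[gene_ids[g]] = []
    return M, category, groups


def generate_panel(config: PanelConfig
                   ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                              SampleAnnotation, GroundTruth]:
    """Generate a cell-line panel with planted specificity structure.

    Returns (counts, TPM, annotation, ground truth).
    """
    config.validate()
    D = config.n_diseases
    diseases = [f"D{i:02d}" for i in range(D)]
    lines_per = config.lines_for()
    base = config.baseline_expression
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    M, category, groups = _build_means(config)
    truth = GroundTruth(gene_category=category, gene_groups=groups)

    # jitter only detected background genes: sub-cutoff genes must stay
    # deterministically below the detection threshold
    background_mask = np.zeros(config.n_genes, dtype=bool)
    attenuated_mask = np.zeros(config.n_genes, dtype=bool)
    for g, gid in enumerate(gene_ids):
        cat = category[gid]
        if cat == "low-specificity":
            background_mask[g] = True
        elif cat in ("enriched", "group-enriched"):
            attenuated_mask[g] = True

    rng_lines = np.random.default_rng([config.seed, 12])
    rng_counts = np.random.default_rng([config.seed, 13])
    sample_ids: list[str] = []
    ann_rows: list[dict] = []
    cols: list[np.ndarray] = []
    sites = ["lymph_node", "liver", "lung"]
    for d_i, disease in enumerate(diseases):
        eligible = np.flatnonzero(attenuated_mask & (M[:, d_i] > base))
        # cap dropouts per gene so the disease mean keeps a safe margin above
        # the fourfold threshold even in the worst draw
        drop_cap = max((lines_per[d_i] - 1) // 2, 0)
        drop_counts = np.zeros(config.n_genes, dtype=int)
        for l_i in range(lines_per[d_i]):
            sid = f"{disease}_L{l_i:02d}"
            sample_ids.append(sid)
            is_best = l_i == 0
            is_met = l_i % 2 == 1
            mu = M[:, d_i].copy()
            if is_best:
                gamma = 0.0
            else:
                gamma = float(rng_lines.uniform(*config.attenuation_range))
                # fold attenuation toward baseline: v -> v * (v / base) ** -gamma
                v = mu[attenuated_mask]
                mu[attenuated_mask] = v * np.where(
                    v > base, (v / base) ** (-gamma), 1.0)
                # a small line-specific fraction of this line's elevated genes
                # loses the planted fold entirely (dropped back to baseline),
                # so enrichment rankings genuinely separate lines
                frac = float(rng_lines.uniform(*config.dropout_frac_range))
                n_drop = int(round(frac * eligible.size))
                droppable = eligible[drop_counts[eligible] < drop_cap]
                n_drop = min(n_drop, droppable.size)
                if n_drop:
                    drop = rng_lines.choice(droppable, size=n_drop, replace=False)
                    mu[drop] = base
                    drop_counts[drop] += 1
                sd = config.line_jitter_sd + (
                    config.metastatic_extra_jitter if is_met else 0.0)
                if sd > 0:
                    jitter = rng_lines.normal(0.0, sd, size=int(background_mask.sum()))
                    mu[background_mask] *= 2.0 ** jitter
            truth.line_attenuation[sid] = gamma
            if is_best:
                truth.best_line[disease] = sid
            lam = mu / mu.sum() * config.library_size
            cols.append(_nb_counts(rng_counts, lam, config.dispersion))
            ann_rows.append({
                "sample_id": sid, "disease": disease, "panel": "synthetic",
                "rrid": f"CVCL_S{d_i:02d}{l_i:02d}",
                "primary_or_metastasis": "metastasis" if is_met else "primary",
                "collection_site": sites[l_i % len(sites)] if is_met else "primary_site",
                "lineage": disease,
            })

    counts = np.column_stack(cols)
    counts_em = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), "counts")
    tpm_em = ExpressionMatrix(
        pd.DataFrame(_counts_to_tpm(counts), index=gene_ids, columns=sample_ids),
        "TPM")
    ann = SampleAnnotation(pd.DataFrame(ann_rows).set_index("sample_id"))
    return counts_em, tpm_em, ann, truth


def generate_cohorts(config: PanelConfig, truth: GroundTruth,
                     samples_per_cohort: int = 20,
                     purity_range: tuple[float, float] = (0.75, 1.0),
                     n_stages: int = 3,
                     stage_genes_per_cohort: int = 15,
                     stage_fold: float = 5.0,
                     ) -> tuple[ExpressionMatrix, SampleAnnotation, GroundTruth]:
    """Generate disease-matched pseudo-tumor cohorts.

    Cohort samples share the disease's planted mean profile (hence its
    elevated genes); one stage per cohort additionally carries a planted
    ``stage_fold`` signature on background genes.  Purity is drawn uniformly
    inside ``purity_range`` (annotation-only; it does not alter expression).
    Returns (TPM matrix, cohort annotation, updated truth).
    """
    config.validate()
    if samples_per_cohort < 2:
        raise ConfigurationError("samples_per_cohort must be at least 2")
    if not (0.0 <= purity_range[0] <= purity_range[1] <= 1.0):
        raise ConfigurationError("purity_range must be an interval inside [0, 1]")
    D = config.n_diseases
    diseases = [f"D{i:02d}" for i in range(D)]
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    M, category, _ = _build_means(config)

    rng = np.random.default_rng([config.seed, 21])
    background = [i for i, g in enumerate(gene_ids)
                  if category[g] == "low-specificity"]
    sample_ids, ann_rows, cols = [], [], []
    for d_i, disease in enumerate(diseases):
        cohort_id = f"cohort_{disease}"
        truth.disease_cohort[disease] = cohort_id
        if disease in truth.best_line:
            truth.cohort_best_line[cohort_id] = truth.best_line[disease]
        stage_genes = rng.choice(background, size=min(stage_genes_per_cohort,
                                                      len(background)),
                                 replace=False)
        stage_labels = [f"stage{k + 1}" for k in range(n_stages)]
        truth.stage_signatures[cohort_id] = {
            s: ([gene_ids[g] for g in sorted(stage_genes)] if s == stage_labels[0]
                else []) for s in stage_labels}
        for s_i in range(samples_per_cohort):
            sid = f"{cohort_id}_T{s_i:03d}"
            stage = stage_labels[s_i % n_stages]
            mu = M[:, d_i].copy()
            if stage == stage_labels[0]:
                mu[stage_genes] *= stage_fold
            lam = mu / mu.sum() * config.library_size
            cols.append(_nb_counts(rng, lam, config.dispersion))
            sample_ids.append(sid)
            ann_rows.append({
                "sample_id": sid, "disease": disease, "cohort": cohort_id,
                "purity": float(rng.uniform(*purity_range)), "stage": stage,
            })
    counts = np.column_stack(cols)
    tpm = ExpressionMatrix(
        pd.DataFrame(_counts_to_tpm(counts), index=gene_ids, columns=sample_ids),
        "TPM")
    ann = SampleAnnotation(pd.DataFrame(ann_rows).set_index("sample_id"))
    return tpm, ann, truth


def generate_signature_matrix(n_genes: int, n_signatures: int,
                              genes_per_signature: int, seed: int = 0,
                              n_samples: int = 50, noise_sd: float = 0.1,
                              ) -> tuple[pd.DataFrame, pd.DataFrame,
                                         ExpressionMatrix]:
    """Random signature weights with planted activities and noisy expression.

    Returns (weights genes x signatures, planted activities samples x
    signatures, centered-log expression genes x samples) where
    expression = weights @ activities.T + Gaussian(0, noise_sd), centered per
    gene.
    """
    if genes_per_signature > n_genes:
        raise ConfigurationError("genes_per_signature cannot exceed n_genes")
    if genes_per_signature < 3:
        raise ConfigurationError("signatures need at least 3 genes")
    rng = np.random.default_rng([seed, 31])
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sig_ids = [f"SIG{i:02d}" for i in range(n_signatures)]
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    W = np.zeros((n_genes, n_signatures))
    for j in range(n_signatures):
        members = rng.choice(n_genes, size=genes_per_signature, replace=False)
        W[members, j] = rng.normal(0.0, 1.0, size=genes_per_signature)
    A = rng.normal(0.0, 1.0, size=(n_samples, n_signatures))
    E = W @ A.T
    if noise_sd > 0:
        E = E + rng.normal(0.0, noise_sd, size=E.shape)
    E = E - E.mean(axis=1, keepdims=True)
    weights = pd.DataFrame(W, index=gene_ids, columns=sig_ids)
    activities = pd.DataFrame(A, index=sample_ids, columns=sig_ids)
    expr = ExpressionMatrix(pd.DataFrame(E, index=gene_ids, columns=sample_ids),
                            "centered-log")
    return weights, activities, expr
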