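"""Cell-line prioritization against disease-matched tumor cohorts.

Two complementary similarity metrics are computed per (cell line, cohort):

* **Correlation metric** — Spearman rho between the cell line's nTPM profile
  and the cohort's per-gene mean nTPM over the shared genes.

* **GSEA metric** — each cell line's genes are ranked by log2 fold change
  relative to the *disease baseline* (the unweighted mean over disease-level
  CLD mean profiles), and the cohort's elevated-gene signature is tested for
  enrichment at the top of that ranking by preranked GSEA.  A positive
  normalized enrichment score (NES) means the cohort's signature genes sit
  high in the cell line's ranking, i.e. the line over-expresses what the
  cohort over-expresses.

Cell lines are ranked on each metric separately (descending rho, descending
NES) and the two rank lists are combined by their average; the top
``top_k`` lines (plus exact ties with the k-th) are flagged as selected.

The preranked GSEA here uses the weighted Kolmogorov-Smirnov running sum with
hit increments proportional to ``|stat|^weight_exponent`` and a gene-label
permutation null: random same-size gene sets define the null ES distribution,
NES is the ES divided by the mean |null ES| of matching sign, and the p-value
is the one-sided null exceedance frequency with +1 smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import stage_signature
from .compare import bh_adjust
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class GseaParams:
    """Preranked-GSEA tuning parameters."""

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be nonnegative")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class PrioritizationRecord:
    cell_line_id: str
    cohort_id: str
    rho: float = float("nan")
    es: float = float("nan")
    nes: float = float("nan")
    p_value: float = float("nan")
    adj_p: float = float("nan")
    rank_corr: float = float("nan")
    rank_gsea: float = float("nan")
    combined_rank: float = float("nan")
    final_rank: int = 0
    selected: bool = False


def cohort_mean_profile(cohort: ExpressionMatrix) -> pd.Series:
    """Per-gene arithmetic mean over the cohort's samples."""
    if cohort.n_samples < 1:
        raise ValueError("cohort has no samples")
    return cohort.data.mean(axis=1)


def correlation_metric(lines: ExpressionMatrix, cohort_mean: pd.Series,
                       min_common_genes: int = 100) -> pd.Series:
    """Spearman rho of each cell line against the cohort mean profile."""
    genes = lines.gene_ids.intersection(cohort_mean.index)
    if len(genes) < min_common_genes:
        raise ValueError(
            f"only {len(genes)} shared genes; need at least {min_common_genes}")
    ref = cohort_mean.loc[genes].rank()
    sub = lines.data.loc[genes].rank(axis=0)
    refz = (ref - ref.mean()) / ref.std(ddof=0)
    subz = (sub - sub.mean()) / sub.std(ddof=0)
    rho = subz.T.to_numpy() @ refz.to_numpy() / len(genes)
    return pd.Series(rho, index=lines.sample_ids, dtype=float)


def disease_baseline(clds: ExpressionMatrix) -> pd.Series:
    """Unweighted mean over CLD mean profiles (not over individual lines)."""
    if clds.n_samples < 2:
        raise ValueError("disease baseline needs at least two CLD columns")
    return clds.data.mean(axis=1)


def ranked_fold_changes(line: pd.Series, baseline: pd.Series,
                        params: Optional[GseaParams] = None) -> pd.Series:
    """log2 fold change of each gene vs. the disease baseline, sorted
    descending, ties broken by gene ID for determinism."""
    params = params or GseaParams()
    genes = line.index.intersection(baseline.index)
    stat = np.log2((line.loc[genes] + params.pseudocount)
                   / (baseline.loc[genes] + params.pseudocount))
    order = np.lexsort((genes.astype(str), -stat.to_numpy()))
    return stat.iloc[order]


def _es_from_positions(abs_w: np.ndarray, positions: np.ndarray,
                       miss_step: float) -> float:
    """Enrichment score given sorted hit positions in a ranked list.

    ``abs_w`` holds |stat|^exponent for the hit positions (ranking order);
    the running sum climbs by the normalized hit weight at each hit and falls
    by ``miss_step`` per miss.  Returns the signed maximum deviation.
    """
    w = abs_w[positions]
    total = w.sum()
    if total <= 0:
        # degenerate all-zero statistics inside the set: uniform hit weights
        w = np.ones_like(w)
        total = w.sum()
    hit_cum = np.cumsum(w) / total
    j = np.arange(1, positions.size + 1)
    # running sum right after each hit, and right before each hit
    after = hit_cum - (positions + 1 - j) * miss_step
    before = np.concatenate(([0.0], hit_cum[:-1])) - (positions + 1 - j) * miss_step
    hi = after.max()
    lo = min(before.min(), after.min())
    return float(hi if hi >= -lo else lo)


def gsea_preranked(stats: pd.Series, gene_set: Iterable[str],
                   params: Optional[GseaParams] = None
                   ) -> tuple[float, float, float]:
    """Preranked GSEA of ``gene_set`` against a descending statistic vector.

    Returns (ES, NES, p_value).  ``stats`` must be sorted descending (as
    produced by :func:`ranked_fold_changes`).
    """
    params = params or GseaParams()
    genes = stats.index
    n = len(genes)
    in_set = genes.isin(set(gene_set))
    m = int(in_set.sum())
    if m == 0 or m == n:
        raise ValueError(f"gene set hits {m} of {n} ranked genes; "
                         "need a proper nonempty subset")
    abs_w = np.abs(stats.to_numpy(dtype=float)) ** params.weight_exponent
    miss_step = 1.0 / (n - m)
    positions = np.flatnonzero(in_set)
    es = _es_from_positions(abs_w, positions, miss_step)

    rng = np.random.default_rng(params.seed)
    null = np.empty(params.n_permutations)
    for i in range(params.n_permutations):
        perm = np.sort(rng.choice(n, size=m, replace=False))
        null[i] = _es_from_positions(abs_w, perm, miss_step)

    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        same_sign = null
    denom = np.mean(np.abs(same_sign))
    nes = es / denom if denom > 0 else 0.0
    n_exceed = int(np.sum(np.abs(same_sign) >= abs(es)))
    p = (n_exceed + 1) / (same_sign.size + 1)
    return es, float(nes), float(p)


def integrate_ranks(records: Sequence[PrioritizationRecord],
                    top_k: int = 5) -> list[PrioritizationRecord]:
    """Combine the correlation and GSEA rankings by average rank.

    rho and NES are each ranked descending with average ranks for ties; the
    combined score is the mean of the two ranks.  The final ordering is
    ascending combined rank, ties broken by higher rho then lexicographic
    cell-line ID.  Lines with final rank <= ``top_k``, plus any line tied on
    the combined score with the ``top_k``-th line, are flagged selected.
    """
    if not records:
        return []
    for r in records:
        if np.isnan(r.rho) or np.isnan(r.nes):
            raise ValueError(f"record {r.cell_line_id!r} is missing a metric")
    rho = pd.Series({r.cell_line_id: r.rho for r in records})
    nes = pd.Series({r.cell_line_id: r.nes for r in records})
    rank_corr = rho.rank(ascending=False, method="average")
    rank_gsea = nes.rank(ascending=False, method="average")
    combined = (rank_corr + rank_gsea) / 2.0
    order = sorted(records,
                   key=lambda r: (combined[r.cell_line_id], -r.rho, r.cell_line_id))
    for i, r in enumerate(order, start=1):
        r.rank_corr = float(rank_corr[r.cell_line_id])
        r.rank_gsea = float(rank_gsea[r.cell_line_id])
        r.combined_rank = float(combined[r.cell_line_id])
        r.final_rank = i
    if len(order) > top_k:
        cut = order[top_k - 1].combined_rank
        for r in order:
            r.selected = r.final_rank <= top_k or r.combined_rank == cut
    else:
        for r in order:
            r.selected = True
    return order


def prioritize_cohort(lines: ExpressionMatrix, cohort: ExpressionMatrix,
                      clds: ExpressionMatrix, cohort_signature: Iterable[str],
                      cohort_id: str = "cohort",
                      params: Optional[GseaParams] = None,
                      top_k: int = 5,
                      min_common_genes: int = 100) -> list[PrioritizationRecord]:
    """Full prioritization of ``lines`` against one cohort.

    ``cohort_signature`` is the cohort's elevated gene set (union of enriched,
    group-enriched and enhanced genes classified at the cohort level).
    BH-adjusted GSEA p-values are filled across the cohort's lines.
    """
    params = params or GseaParams()
    mean_profile = cohort_mean_profile(cohort)
    rho = correlation_metric(lines, mean_profile, min_common_genes=min_common_genes)
    baseline = disease_baseline(clds)
    sig = set(cohort_signature)
    records = []
    for sid in lines.sample_ids:
        ranked = ranked_fold_changes(lines.data[sid], baseline, params)
        es, nes, p = gsea_preranked(ranked, sig, params)
        records.append(PrioritizationRecord(str(sid), cohort_id, rho=float(rho[sid]),
                                            es=es, nes=nes, p_value=p))
    adj = bh_adjust([r.p_value for r in records])
    for r, q in zip(records, adj):
        r.adj_p = float(q)
    return integrate_ranks(records, top_k=top_k)


def prioritize_stage_or_subtype(lines: ExpressionMatrix, cohort: ExpressionMatrix,
                                labels: Mapping[str, str], clds: ExpressionMatrix,
                                params: Optional[GseaParams] = None,
                                top_k: int = 5,
                                min_common_genes: int = 100
                                ) -> dict[str, list[PrioritizationRecord]]:
    """Per-stage (or per-subtype) prioritization within one cohort.

    For each label: correlation of every line to the label's mean profile, and
    GSEA of the label's fourfold signature against the line's fold-change
    ranking; ranks integrated as in :func:`integrate_ranks`.  Labels with an
    empty signature fall back to a correlation-only ranking with a warning.
    """
    params = params or GseaParams()
    label_values = set(labels.values())
    if len(label_values) < 2:
        raise ValueError("need at least two stage/subtype labels")
    signatures = stage_signature(cohort, labels)
    baseline = disease_baseline(clds)
    out: dict[str, list[PrioritizationRecord]] = {}
    for label in sorted(label_values):
        members = [s for s, l in labels.items() if l == label and s in cohort.sample_ids]
        profile = cohort.data[members].mean(axis=1)
        rho = correlation_metric(lines, profile, min_common_genes=min_common_genes)
        sig = signatures.get(label, set())
        records = []
        if not sig:
            logger.warning("label %r has an empty fourfold signature; "
                           "falling back to correlation-only ranking", label)
            order = rho.sort_values(ascending=False)
            for i, (sid, r) in enumerate(order.items(), start=1):
                rec = PrioritizationRecord(str(sid), label, rho=float(r))
                rec.rank_corr = rec.combined_rank = float(i)
                rec.final_rank = i
                rec.selected = i <= top_k
                records.append(rec)
            out[label] = records
            continue
        for sid in lines.sample_ids:
            ranked = ranked_fold_changes(lines.data[sid], baseline, params)
            es, nes, p = gsea_preranked(ranked, sig, params)
            records.append(PrioritizationRecord(str(sid), label, rho=float(rho[sid]),
                                                es=es, nes=nes, p_value=p))
        adj = bh_adjust([r.p_value for r in records])
        for r, q in zip(records, adj):
            r.adj_p = float(q)
        out[label] = integrate_ranks(records, top_k=top_k)
    return out


def records_to_frame(records: Sequence[PrioritizationRecord]) -> pd.DataFrame:
    """Tabulate prioritization records (Supplementary-Data-style columns)."""
    return pd.DataFrame([{
        "cell_line": r.cell_line_id, "cohort": r.cohort_id, "rho": r.rho,
        "es": r.es, "nes": r.nes, "p_value": r.p_value, "adj_p": r.adj_p,
        "rank_corr": r.rank_corr, "rank_gsea": r.rank_gsea,
        "combined_rank": r.combined_rank, "final_rank": r.final_rank,
        "selected": r.selected,
    } for r in records]).set_index("cell_line")
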