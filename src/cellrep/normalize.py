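"""Expression normalization: pTPM, TMM scaling to nTPM, and centered log space.

The normalization chain mirrors standard bulk RNA-seq practice for
cross-sample comparison:

1. ``to_ptpm`` restricts a TPM matrix to protein-coding genes and rescales each
   sample so the coding genes sum to one million (pTPM).
2. ``tmm_factors`` computes trimmed-mean-of-M-values scaling factors against a
   reference sample (the sample whose detected-gene upper quartile is the
   median across samples), with two-sided trimming of the log-ratios (M) and
   average intensities (A) and inverse-variance weighting of the surviving
   log-ratios.
3. ``apply_tmm`` divides each sample by its factor, yielding nTPM.

For activity scoring, ``size_factors_median_of_ratios`` and ``log_center``
produce per-gene-centered log2 expression from counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Pseudo-library size implied by the pTPM unit (columns sum to 1e6).
PTPM_LIBRARY = 1.0e6


@dataclass
class TmmParams:
    """Tuning knobs for TMM factor estimation.

    logratio_trim
        Fraction of the most extreme log2 ratios (M) discarded on *each* side.
    abs_intensity_trim
        Fraction of the most extreme average log intensities (A) discarded on
        each side.
    do_weighting
        Weight surviving M values by the inverse of their asymptotic binomial
        (delta-method) variance; uniform weights otherwise.
    reference_sample
        Fix the reference sample by ID instead of the automatic
        median-upper-quartile rule.
    """

    logratio_trim: float = 0.3
    abs_intensity_trim: float = 0.05
    do_weighting: bool = True
    reference_sample: Optional[str] = None

    def __post_init__(self) -> None:
        for name, v in (("logratio_trim", self.logratio_trim),
                        ("abs_intensity_trim", self.abs_intensity_trim)):
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5), got {v}")


def to_ptpm(tpm: ExpressionMatrix, coding_ids: Iterable[str]) -> ExpressionMatrix:
    """Restrict to protein-coding genes and rescale each sample to sum 1e6.

    Raises
    ------
    ValueError
        If a sample has zero total coding expression (naming the sample), or
        if ``coding_ids`` contains genes absent from the matrix.
    """
    tpm.require_unit("TPM")
    ids = pd.Index(coding_ids)
    missing = ids.difference(tpm.gene_ids)
    if len(missing):
        raise ValueError(f"coding IDs absent from matrix: {list(missing[:5])}")
    sub = tpm.data.loc[ids]
    colsums = sub.sum(axis=0)
    zero = colsums.index[colsums <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero coding expression: {list(zero[:5])}")
    scaled = sub * (PTPM_LIBRARY / colsums)
    return ExpressionMatrix(scaled, "pTPM")


def select_tmm_reference(m: ExpressionMatrix) -> str:
    """Pick the reference sample for TMM: median upper-quartile column.

    For each sample, the upper quartile (75th percentile) of its positive
    expression values is computed; the sample whose statistic is the median of
    these (lower median for even counts) is returned.  Ties go to the
    lexicographically smallest sample ID.
    """
    if m.n_samples < 1:
        raise ValueError("need at least one sample")
    stats = {}
    for sid in m.sample_ids:
        col = m.data[sid].to_numpy()
        pos = col[col > 0]
        stats[sid] = float(np.quantile(pos, 0.75)) if pos.size else 0.0
    order = sorted(stats.items(), key=lambda kv: (kv[1], kv[0]))
    # lower median; ties within equal statistics resolved by ID via the sort key
    med = order[(len(order) - 1) // 2]
    tied = sorted(sid for sid, v in stats.items() if v == med[1])
    return tied[0]


def _tmm_factor_one(x: np.ndarray, r: np.ndarray, params: TmmParams,
                    sample_id: str = "?") -> float:
    """Unscaled TMM factor of sample ``x`` against reference ``r``.

    Genes must be aligned; only genes positive in both samples contribute.
    Trimming keeps genes inside both the M-rank window and the A-rank window
    (two-sided, rank-based).  With fewer than 10 survivors the untrimmed set is
    used with a warning.
    """
    both = (x > 0) & (r > 0)
    if not both.any():
        raise ValueError(f"sample {sample_id!r} shares no expressed genes with the reference")
    xk = x[both]
    xr = r[both]
    M = np.log2(xk / xr)
    A = 0.5 * np.log2(xk * xr / (PTPM_LIBRARY * PTPM_LIBRARY))
    n = M.size

    def keep_mask(v: np.ndarray, trim: float) -> np.ndarray:
        ranks = pd.Series(v).rank(method="first").to_numpy()
        lo = np.floor(n * trim) + 1
        hi = n + 1 - lo
        return (ranks >= lo) & (ranks <= hi)

    keep = keep_mask(M, params.logratio_trim) & keep_mask(A, params.abs_intensity_trim)
    if keep.sum() < 10:
        warnings.warn(
            f"TMM: only {int(keep.sum())} genes survive trimming for sample "
            f"{sample_id!r}; falling back to the untrimmed gene set",
            RuntimeWarning,
            stacklevel=3,
        )
        logger.warning("tmm_factors sample=%s decision=untrimmed-fallback survivors=%d",
                       sample_id, int(keep.sum()))
        keep = np.ones(n, dtype=bool)
    Mk = M[keep]
    if params.do_weighting:
        # delta-method binomial variance of M on the pseudo-library scale
        var = ((PTPM_LIBRARY - xk[keep]) / (PTPM_LIBRARY * xk[keep])
               + (PTPM_LIBRARY - xr[keep]) / (PTPM_LIBRARY * xr[keep]))
        w = 1.0 / var
    else:
        w = np.ones_like(Mk)
    return float(2.0 ** (np.sum(w * Mk) / np.sum(w)))


def tmm_factors(m: ExpressionMatrix, ref: Optional[str] = None,
                params: Optional[TmmParams] = None) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample's factor is exactly 1 before the geometric-mean
    rescaling, making the reference choice immaterial up to a global constant.
    """
    m.require_unit("pTPM")
    params = params or TmmParams()
    if ref is None:
        ref = params.reference_sample or select_tmm_reference(m)
    if ref not in m.sample_ids:
        raise ValueError(f"reference sample {ref!r} not in matrix")
    rcol = m.data[ref].to_numpy(dtype=float)
    raw = {}
    for sid in m.sample_ids:
        if sid == ref:
            raw[sid] = 1.0
        else:
            raw[sid] = _tmm_factor_one(m.data[sid].to_numpy(dtype=float), rcol,
                                       params, sample_id=str(sid))
    f = pd.Series(raw, dtype=float).reindex(m.sample_ids)
    gm = float(np.exp(np.mean(np.log(f.to_numpy()))))
    return f / gm


def apply_tmm(m: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Divide each sample by its TMM factor; the result is nTPM."""
    m.require_unit("pTPM")
    factors = factors.reindex(m.sample_ids)
    if factors.isna().any():
        raise ValueError("factors missing for some samples")
    if (factors <= 0).any():
        bad = factors.index[factors <= 0].tolist()
        raise ValueError(f"nonpositive TMM factor for sample(s): {bad[:5]}")
    return ExpressionMatrix(m.data / factors, "nTPM")


def tpm_to_ntpm(tpm: ExpressionMatrix, coding_ids: Optional[Iterable[str]] = None,
                params: Optional[TmmParams] = None) -> ExpressionMatrix:
    """Convenience chain TPM -> pTPM -> nTPM.

    ``coding_ids`` defaults to all genes in the matrix (appropriate when the
    input is already restricted to protein-coding genes).
    """
    if coding_ids is None:
        coding_ids = tpm.gene_ids
    ptpm = to_ptpm(tpm, coding_ids)
    factors = tmm_factors(ptpm, params=params)
    return apply_tmm(ptpm, factors)


def size_factors_median_of_ratios(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq convention, unrescaled).

    Per gene positive in *all* samples, the geometric mean across samples is
    the pseudo-reference; each sample's factor is the median over those genes
    of count / geometric mean.
    """
    counts.require_unit("counts")
    X = counts.data.to_numpy(dtype=float)
    all_pos = (X > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene is positive in all samples; cannot form size factors")
    Xp = X[all_pos]
    loggeo = np.mean(np.log(Xp), axis=1, keepdims=True)
    ratios = Xp / np.exp(loggeo)
    return pd.Series(np.median(ratios, axis=0), index=counts.sample_ids, dtype=float)


def log_center(counts: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """log2(count / size factor + 1), then center each gene to mean zero.

    Every output row sums to zero by construction; this is the input expected
    by the activity-scoring linear models.
    """
    counts.require_unit("counts")
    factors = factors.reindex(counts.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    logged = np.log2(counts.data / factors + 1.0)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    return ExpressionMatrix(centered, "centered-log")
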