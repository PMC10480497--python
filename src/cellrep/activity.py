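"""Pathway and cytokine activity inference from centered log expression.

Given a gene-by-signature weight matrix W (0 = gene not in signature) and
per-gene-centered log2 expression X, three linear-model scores are computed
per (sample, signature):

* ``ulm_scores`` — univariate: regress the sample's expression on one
  signature's weights; the score is the slope t-statistic.
* ``mlm_scores`` — multivariate: one regression per sample with *all*
  signatures as covariates; scores are the partial-coefficient t-statistics.
* ``wsum_scores`` — weighted sum with a gene-label permutation z-score.

``consensus_scores`` standardizes each method per signature across samples and
averages them; a consensus |z| > 1 flags a significant pathway activity.
``permutation_activity`` is the cytokine-style scorer: a ridge-penalized
multivariate fit per sample with a gene-label permutation null, z-scores and
two-sided permutation p-values (p < 0.05 significant).

``activity_mse`` and ``prioritize_by_mse`` support matching cell lines to
cohorts by activity-profile similarity (mean squared error, lower = closer).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

#: t-statistics from numerically perfect fits are capped at this magnitude.
T_CAP = 1.0e6
CONSENSUS_Z_THRESHOLD = 1.0
PERMUTATION_P_THRESHOLD = 0.05


@dataclass
class ActivityTable:
    """Sample-by-signature activity scores with significance flags."""

    z: pd.DataFrame              # samples x signatures
    significant: pd.DataFrame    # same shape, boolean
    method: str
    p_values: Optional[pd.DataFrame] = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.z.index

    @property
    def signature_ids(self) -> pd.Index:
        return self.z.columns

    def n_significant(self) -> int:
        return int(self.significant.to_numpy().sum())

    def to_tsv(self, path) -> None:
        out = self.z.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


class SignatureMatrix:
    """Gene-by-signature weight matrix; zero weight means 'not in signature'."""

    def __init__(self, weights: pd.DataFrame):
        if weights.index.has_duplicates:
            raise ValueError("duplicate gene IDs in signature matrix")
        nnz = (weights != 0).sum(axis=0)
        thin = nnz.index[nnz < 3].tolist()
        if thin:
            raise ValueError(f"signature(s) with < 3 nonzero weights: {thin[:5]}")
        self.weights = weights

    @property
    def gene_ids(self) -> pd.Index:
        return self.weights.index

    @property
    def signature_ids(self) -> pd.Index:
        return self.weights.columns

    def to_tsv(self, path) -> None:
        out = self.weights.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def _aligned(x: ExpressionMatrix, w: SignatureMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    x.require_unit("centered-log")
    genes = x.gene_ids.intersection(w.gene_ids)
    if len(genes) < 3:
        raise ValueError("fewer than 3 genes shared between expression and signatures")
    return x.data.loc[genes], w.weights.loc[genes]


def ulm_scores(x: ExpressionMatrix, w: SignatureMatrix) -> pd.DataFrame:
    """Univariate linear model t-statistics, samples x signatures.

    Signatures sharing fewer than 3 genes with the expression matrix are
    skipped with a log entry.
    """
    X, W = _aligned(x, w)
    g = X.shape[0]
    out = {}
    Xc = X - X.mean(axis=0)
    for sig in W.columns:
        wv = W[sig].to_numpy(dtype=float)
        if (wv != 0).sum() < 3:
            logger.info("ulm: signature %r shares < 3 genes; skipped", sig)
            continue
        wc = wv - wv.mean()
        sxx = float(wc @ wc)
        if sxx == 0:
            out[sig] = np.zeros(X.shape[1])
            continue
        beta = (wc @ Xc.to_numpy()) / sxx
        # residual variance per sample for y = a + b*w
        ss_tot = (Xc.to_numpy() ** 2).sum(axis=0)
        ss_reg = beta ** 2 * sxx
        df = g - 2
        sigma2 = np.maximum(ss_tot - ss_reg, 0.0) / df
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                         np.sign(beta) * T_CAP)
        out[sig] = np.clip(t, -T_CAP, T_CAP)
    return pd.DataFrame(out, index=X.columns)


def mlm_scores(x: ExpressionMatrix, w: SignatureMatrix) -> pd.DataFrame:
    """Multivariate linear model partial t-statistics, samples x signatures.

    One ordinary-least-squares fit per sample with all signature columns (plus
    an intercept) as covariates; degrees of freedom = genes - signatures - 1.
    """
    X, W = _aligned(x, w)
    g, k = W.shape
    if g <= k + 1:
        raise ValueError(f"need more shared genes ({g}) than signatures + 1 ({k + 1})")
    D = np.column_stack([np.ones(g), W.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        corr = np.corrcoef(W.to_numpy(dtype=float).T)
        np.fill_diagonal(corr, 0.0)
        pairs = [(str(W.columns[i]), str(W.columns[j]))
                 for i, j in zip(*np.where(np.abs(corr) > 0.9999)) if i < j]
        raise ValueError(f"signature matrix is rank deficient; collinear: {pairs[:5]}")
    XtX_inv = np.linalg.inv(D.T @ D)
    H = XtX_inv @ D.T
    B = H @ X.to_numpy()                      # (k+1) x samples
    resid = X.to_numpy() - D @ B
    df = g - k - 1
    sigma2 = (resid ** 2).sum(axis=0) / df
    diag = np.sqrt(np.diag(XtX_inv))[1:, None]  # drop intercept
    se = diag * np.sqrt(sigma2)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[1:, :] / np.where(se > 0, se, 1.0),
                     np.sign(B[1:, :]) * T_CAP)
    t = np.clip(t, -T_CAP, T_CAP)
    return pd.DataFrame(t.T, index=X.columns, columns=W.columns)


def wsum_scores(x: ExpressionMatrix, w: SignatureMatrix, n_perm: int = 1000,
                seed: int = 0) -> pd.DataFrame:
    """Weighted-sum permutation z-scores, samples x signatures.

    raw(s, j) = sum_g W[g, s] * X[g, j]; the null permutes the gene labels of
    the expression matrix ``n_perm`` times (one shared gene permutation per
    iteration).  z = (raw - null mean) / null sd; zero null sd yields z = 0
    with a warning.
    """
    X, W = _aligned(x, w)
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    Wv = W.to_numpy(dtype=float)
    raw = Wv.T @ Xv                              # signatures x samples
    null_sum = np.zeros_like(raw)
    null_sq = np.zeros_like(raw)
    g = Xv.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(g)
        nr = Wv.T @ Xv[perm]
        null_sum += nr
        null_sq += nr ** 2
    mean = null_sum / n_perm
    var = np.maximum(null_sq / n_perm - mean ** 2, 0.0)
    sd = np.sqrt(var)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn("wsum: zero permutation sd for some entries; z set to 0",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero_sd, 0.0, (raw - mean) / np.where(zero_sd, 1.0, sd))
    return pd.DataFrame(z.T, index=X.columns, columns=W.columns)


def consensus_scores(method_scores: Mapping[str, pd.DataFrame],
                     z_threshold: float = CONSENSUS_Z_THRESHOLD) -> ActivityTable:
    """Standardize each method per signature across samples and average.

    A method contributing zero variance for a signature is excluded for that
    signature (logged).  ``significant`` flags |consensus z| > ``z_threshold``.
    """
    if len(method_scores) < 2:
        raise ValueError("consensus needs at least two methods")
    frames = list(method_scores.values())
    shape = frames[0].shape
    for name, f in method_scores.items():
        if f.shape != shape or not f.columns.equals(frames[0].columns):
            raise ValueError(f"method {name!r} has mismatched shape")
    acc = pd.DataFrame(0.0, index=frames[0].index, columns=frames[0].columns)
    counts = pd.DataFrame(0.0, index=frames[0].index, columns=frames[0].columns)
    for name, f in method_scores.items():
        mu = f.mean(axis=0)
        sd = f.std(axis=0, ddof=0)
        usable = sd > 0
        dropped = sd.index[~usable].tolist()
        if dropped:
            logger.info("consensus: method %r excluded for zero-variance "
                        "signature(s) %s", name, dropped[:5])
        zs = (f - mu) / sd.where(usable, 1.0)
        zs.loc[:, ~usable] = 0.0
        acc += zs
        counts.loc[:, usable] += 1.0
    if (counts.to_numpy() == 0).any():
        raise ValueError("some signature has zero variance under every method")
    z = acc / counts
    return ActivityTable(z=z, significant=z.abs() > z_threshold, method="consensus")


def score_consensus(x: ExpressionMatrix, w: SignatureMatrix, n_perm: int = 1000,
                    seed: int = 0,
                    z_threshold: float = CONSENSUS_Z_THRESHOLD) -> ActivityTable:
    """Convenience wrapper: ulm + mlm + wsum, integrated into a consensus."""
    scores = {
        "ulm": ulm_scores(x, w),
        "mlm": mlm_scores(x, w),
        "wsum": wsum_scores(x, w, n_perm=n_perm, seed=seed),
    }
    return consensus_scores(scores, z_threshold=z_threshold)


def permutation_activity(x: ExpressionMatrix, w: SignatureMatrix,
                         ridge_lambda: float = 1.0e4, n_perm: int = 10000,
                         seed: int = 0,
                         p_threshold: float = PERMUTATION_P_THRESHOLD
                         ) -> ActivityTable:
    """Ridge-regression activity with gene-label permutation significance.

    Per sample j, coefficients solve (W'W + lambda I) b = W' x_j.  The null
    re-solves with gene labels of x permuted; z = (b - null mean) / null sd
    and the two-sided p-value is the smoothed null exceedance frequency of
    |b - null mean|.  Significance: p < ``p_threshold``.
    """
    if ridge_lambda <= 0:
        raise ValueError("ridge_lambda must be positive")
    X, W = _aligned(x, w)
    Wv = W.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    g, k = Wv.shape
    A = np.linalg.inv(Wv.T @ Wv + ridge_lambda * np.eye(k)) @ Wv.T  # k x g
    coef = A @ Xv                                                   # k x samples
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_perm,) + coef.shape)
    for i in range(n_perm):
        nulls[i] = A @ Xv[rng.permutation(g)]
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0)
    zero_sd = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero_sd, 0.0, (coef - mean) / np.where(zero_sd, 1.0, sd))
    centered_obs = np.abs(coef - mean)
    exceed = (np.abs(nulls - mean[None]) >= centered_obs[None]).sum(axis=0)
    p = (exceed + 1) / (n_perm + 1)
    p = np.where(np.abs(coef) == 0, 1.0, p)
    zdf = pd.DataFrame(z.T, index=X.columns, columns=W.columns)
    pdf = pd.DataFrame(p.T, index=X.columns, columns=W.columns)
    return ActivityTable(z=zdf, significant=pdf < p_threshold,
                         method="permutation", p_values=pdf)


def activity_mse(a: ActivityTable, b: ActivityTable) -> pd.DataFrame:
    """Mean squared error over shared signatures for every (a-sample,
    b-sample) pair; rows = samples of ``a``, columns = samples of ``b``."""
    shared = a.signature_ids.intersection(b.signature_ids)
    if len(shared) == 0:
        raise ValueError("no shared signatures")
    A = a.z[shared].to_numpy(dtype=float)
    B = b.z[shared].to_numpy(dtype=float)
    # ||ai - bj||^2 / k expanded for vectorization
    sq = (A ** 2).sum(1)[:, None] + (B ** 2).sum(1)[None, :] - 2 * A @ B.T
    return pd.DataFrame(np.maximum(sq, 0.0) / len(shared),
                        index=a.sample_ids, columns=b.sample_ids)


def prioritize_by_mse(pathway_mse: pd.Series, cytokine_mse: pd.Series,
                      ) -> pd.DataFrame:
    """Combine pathway- and cytokine-MSE rankings for one cohort.

    Both inputs are indexed by cell line (MSE against the cohort, lower =
    closer).  Lines missing from either table are excluded with a log entry.
    Ranks ascend with MSE; the combined score is the average rank; ties break
    by lower pathway MSE then lexicographic ID.
    """
    common = pathway_mse.index.intersection(cytokine_mse.index)
    dropped = pathway_mse.index.symmetric_difference(cytokine_mse.index)
    if len(dropped):
        logger.info("prioritize_by_mse: excluded lines missing a table: %s",
                    list(dropped[:5]))
    if len(common) == 0:
        raise ValueError("no cell line present in both MSE tables")
    pm = pathway_mse.loc[common]
    cm = cytokine_mse.loc[common]
    rank_p = pm.rank(method="average")
    rank_c = cm.rank(method="average")
    combined = (rank_p + rank_c) / 2.0
    df = pd.DataFrame({
        "pathway_mse": pm, "cytokine_mse": cm,
        "rank_pathway": rank_p, "rank_cytokine": rank_c,
        "combined_rank": combined,
    })
    df = df.iloc[np.lexsort((df.index.astype(str), df["pathway_mse"],
                             df["combined_rank"]))]
    df["final_rank"] = np.arange(1, len(df) + 1)
    return df
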