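"""Statistical comparison machinery.

Purity filtering of tumor cohorts, hypergeometric overrepresentation of gene
sets with Benjamini-Hochberg correction, Spearman correlation between
disease-level cell-line profiles (CLDs) and tumor cohorts with a
matched-vs-unmatched signed-rank test, group-wise correlation contrasts,
complete-linkage clustering on the 1 - rho distance, and a PCA first-neighbor
consistency check between two panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

#: Tumor purity threshold: samples are kept only if purity strictly exceeds it.
PURITY_THRESHOLD = 0.7


@dataclass
class OverlapResult:
    set_a_label: str
    set_b_label: str
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    p_value: float
    adj_p: float = float("nan")


def filter_by_purity(ann: SampleAnnotation,
                     threshold: float = PURITY_THRESHOLD) -> list[str]:
    """Sample IDs whose tumor purity strictly exceeds ``threshold``.

    Samples at exactly the threshold are removed (they count as highly
    infiltrated by immune and stromal cells).
    """
    if "purity" not in ann.table.columns:
        raise ValueError("annotation has no 'purity' column")
    purity = ann.table["purity"]
    if purity.isna().any():
        bad = ann.table.index[purity.isna()].tolist()
        raise ValueError(f"missing purity for sample(s): {bad[:5]}")
    return [str(s) for s in ann.table.index[purity > threshold]]


def hypergeom_overlap(a: set, b: set, universe: set,
                      label_a: str = "a", label_b: str = "b") -> OverlapResult:
    """One-sided hypergeometric tail P(X >= |a & b|) for two gene sets.

    X ~ Hypergeometric(N=|universe|, K=|a|, n=|b|).
    """
    a, b, universe = set(a), set(b), set(universe)
    if not a <= universe or not b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    N, K, n = len(universe), len(a), len(b)
    k = len(a & b)
    # survival function at k-1 gives P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(label_a, label_b, N, K, n, k, min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_matrix(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho between every column of ``a`` and every column of ``b``
    over the shared gene (row) intersection, ties averaged."""
    genes = a.index.intersection(b.index)
    if len(genes) == 0:
        raise ValueError("no shared genes")
    ra = a.loc[genes].rank(axis=0)
    rb = b.loc[genes].rank(axis=0)
    ra = (ra - ra.mean()) / ra.std(ddof=0)
    rb = (rb - rb.mean()) / rb.std(ddof=0)
    rho = ra.T.to_numpy() @ rb.to_numpy() / len(genes)
    return pd.DataFrame(rho, index=a.columns, columns=b.columns)


def _signed_rank_less(diffs: np.ndarray, exact_max_n: int = 25) -> float:
    """One-sided Wilcoxon signed-rank p-value for H1: location < 0.

    Exact distribution for n <= ``exact_max_n`` (and no ties/zeros), normal
    approximation with continuity correction above.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    n = d.size
    exact_ok = n <= exact_max_n and np.unique(np.abs(d)).size == np.abs(d).size
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(d, alternative="less", method=method, correction=True)
    return float(res.pvalue)


def cld_cohort_correlation(clds: ExpressionMatrix, cohorts: ExpressionMatrix,
                           match_map: Mapping[str, str]
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of every CLD against every cohort profile, plus a
    per-CLD one-sided signed-rank test that the correlations to unmatched
    cohorts are lower than the matched correlation.

    ``match_map`` maps CLD label -> matched cohort label.  CLDs without a
    matched cohort are skipped (with a log entry) in the test but still appear
    in the correlation matrix.

    Returns (correlation matrix, test table with columns matched_cohort,
    matched_rho, n_unmatched, p_value).
    """
    rho = spearman_matrix(clds.data, cohorts.data)
    rows = []
    for cld in rho.index:
        cohort = match_map.get(str(cld))
        if cohort is None or cohort not in rho.columns:
            logger.info("cld_cohort_correlation: CLD %r has no matched cohort; skipped",
                        cld)
            continue
        matched = float(rho.loc[cld, cohort])
        unmatched = rho.loc[cld].drop(labels=[cohort]).to_numpy(dtype=float)
        p = _signed_rank_less(unmatched - matched) if unmatched.size else float("nan")
        rows.append({"cld": str(cld), "matched_cohort": str(cohort),
                     "matched_rho": matched, "n_unmatched": int(unmatched.size),
                     "p_value": p})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests = tests.set_index("cld")
    return rho, tests


def groupwise_correlation_contrast(m: ExpressionMatrix, ann: SampleAnnotation,
                                   groupings: Mapping[str, str] = None,
                                   group_column_a: str = "disease",
                                   group_column_b: str = "collection_site",
                                   split_column: str = "primary_or_metastasis",
                                   ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Within-group pairwise Spearman correlations pooled per grouping, and
    two-sided rank-sum tests between the pooled distributions.

    Three groupings are formed: primary lines grouped by disease, metastatic
    lines grouped by disease, and metastatic lines grouped by collection site.
    A group with a single sample contributes no pairs.
    """
    ann_sub = ann.table.loc[[s for s in m.sample_ids if s in ann.sample_ids]]
    is_met = ann_sub[split_column].astype(str).str.lower().isin(
        {"metastasis", "metastatic", "true", "1"})

    def pooled(sample_mask: pd.Series, column: str) -> np.ndarray:
        vals: list[float] = []
        sub = ann_sub[sample_mask]
        n_groups_used = 0
        for label, grp in sub.groupby(column):
            sids = [s for s in grp.index if s in m.sample_ids]
            if len(sids) < 2:
                continue
            n_groups_used += 1
            rho = spearman_matrix(m.data[sids], m.data[sids]).to_numpy()
            iu = np.triu_indices(len(sids), k=1)
            vals.extend(rho[iu].tolist())
        if n_groups_used < 1:
            raise ValueError(f"grouping by {column!r} has no group with >= 2 samples")
        return np.asarray(vals)

    pools = {
        "primary-by-disease": pooled(~is_met, group_column_a),
        "metastatic-by-disease": pooled(is_met, group_column_a),
        "metastatic-by-site": pooled(is_met, group_column_b),
    }
    rows = []
    names = list(pools)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = pools[names[i]], pools[names[j]]
            if len(a) and len(b):
                if np.array_equal(np.sort(a), np.sort(b)) and np.unique(a).size == 1:
                    p = 1.0  # identical constant pools: no evidence of a shift
                else:
                    p = float(stats.ranksums(a, b).pvalue)
            else:
                p = float("nan")
            rows.append({"grouping_a": names[i], "grouping_b": names[j],
                         "median_a": float(np.median(a)) if len(a) else float("nan"),
                         "median_b": float(np.median(b)) if len(b) else float("nan"),
                         "p_value": p})
    return pools, pd.DataFrame(rows)


def hcluster_profiles(m: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage agglomeration on the distance 1 - Spearman rho.

    Returns the SciPy linkage matrix and the column labels in input order.
    Raises on constant columns (correlation undefined).
    """
    if m.n_samples < 2:
        raise ValueError("clustering requires at least two columns")
    const = m.data.nunique(axis=0) <= 1
    if const.any():
        bad = m.data.columns[const].tolist()
        raise ValueError(f"constant column(s), correlation undefined: {bad[:5]}")
    rho = spearman_matrix(m.data, m.data).to_numpy()
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry against float noise
    Z = linkage(squareform(D, checks=False), method="complete")
    return Z, [str(c) for c in m.sample_ids]


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree string."""
    tree = to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"


def pc_neighbor_check(m: ExpressionMatrix, pairs: Sequence[tuple[str, str]],
                      variance_kept: float = 0.8) -> tuple[float, int]:
    """PCA-space first-neighbor agreement between paired samples of two panels.

    Genes are z-scored across samples, PCA retains the smallest number of
    components whose cumulative explained variance reaches ``variance_kept``,
    and for each (left, right) pair the Euclidean first neighbor of the left
    member among *all* right-panel samples is found.  Returns the fraction of
    pairs whose first neighbor is their counterpart, and the number of PCs
    retained.
    """
    if not (0.0 < variance_kept <= 1.0):
        raise ValueError("variance_kept must lie in (0, 1]")
    for l, r in pairs:
        if l not in m.sample_ids or r not in m.sample_ids:
            raise ValueError(f"pair ({l!r}, {r!r}) not fully present in matrix")
    X = m.data.to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=1, keepdims=True)) / sd
    # samples as observations
    pca = PCA(n_components=min(m.n_samples - 1, m.n_genes), svd_solver="full")
    Y = pca.fit_transform(Xz.T)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pc = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    n_pc = min(n_pc, Y.shape[1])
    Y = Y[:, :n_pc]
    pos = {str(s): i for i, s in enumerate(m.sample_ids)}
    right_ids = [r for _, r in pairs]
    right_idx = np.array([pos[r] for r in right_ids])
    hits = 0
    for l, r in pairs:
        d = np.linalg.norm(Y[right_idx] - Y[pos[l]], axis=1)
        if right_ids[int(np.argmin(d))] == r:
            hits += 1
    return hits / len(pairs), n_pc
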