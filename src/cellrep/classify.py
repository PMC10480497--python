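"""Gene expression distribution and specificity classification.

Two taxonomies are assigned per gene:

* **Distribution** — across individual cell lines: in how many samples is the
  gene detected (expression >= 1 nTPM)?  Categories: ``not-detected``,
  ``single``, ``some`` (more than one but less than a third), ``many`` (at
  least a third but not all), ``all``.

* **Specificity** — across disease-level profiles (CLDs: the per-gene average
  over all cell lines sharing a primary cancer type).  Categories, evaluated
  in precedence order:

  1. ``enriched`` — one group has at least ``fold`` (default 4) times higher
     expression than any other group, and is itself detected;
  2. ``group-enriched`` — a group of 2-10 groups whose *mean* is at least
     ``fold`` times the maximum outside the group, every member detected;
  3. ``enhanced`` — one or more groups with at least ``fold`` times the *mean*
     of all other groups, each detected;
  4. ``low-specificity`` — detected in at least one group but none of the above;
  5. ``not-detected`` — below the detection cutoff (1 nTPM) everywhere.

Ratio denominators are clamped below at 0.01 nTPM so zero expression outside a
group yields a large finite fold rather than infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleAnnotation

#: Detection cutoff in nTPM: a gene is detected in a sample/group iff value >= 1.
DETECTION_CUTOFF = 1.0
#: Fold-change threshold defining elevated expression.
FOLD_THRESHOLD = 4.0
#: Floor applied to ratio denominators (nTPM).
DENOM_CLAMP = 0.01
#: Largest group size considered for the group-enriched category.
MAX_GROUP_SIZE = 10

SPECIFICITY_CATEGORIES = (
    "enriched", "group-enriched", "enhanced", "low-specificity", "not-detected",
)
DISTRIBUTION_CATEGORIES = ("single", "some", "many", "all", "not-detected")
ELEVATED_CATEGORIES = ("enriched", "group-enriched", "enhanced")


@dataclass
class DistributionCall:
    gene_id: str
    category: str
    n_detected: int
    n_samples: int


@dataclass
class SpecificityCall:
    gene_id: str
    category: str
    defining_groups: list[str] = field(default_factory=list)
    fold: float = float("nan")


def merge_panels(a: ExpressionMatrix, b: ExpressionMatrix,
                 common_ids: Mapping[str, str]) -> ExpressionMatrix:
    """Merge two nTPM panels, averaging each pair of common samples.

    ``common_ids`` maps sample IDs of ``a`` to their counterparts in ``b``.
    Each pair collapses into a single column (under the ``a`` ID) holding the
    per-gene arithmetic mean; unique samples pass through, so the output has
    ``|a| + |b| - |common|`` columns.
    """
    a.require_unit("nTPM")
    b.require_unit("nTPM")
    genes = a.gene_ids.intersection(b.gene_ids)
    if len(genes) == 0:
        raise ValueError("panels share no genes")
    for ka, kb in common_ids.items():
        if ka not in a.sample_ids:
            raise ValueError(f"common sample {ka!r} absent from first panel")
        if kb not in b.sample_ids:
            raise ValueError(f"common sample {kb!r} absent from second panel")
    da = a.data.loc[genes]
    db = b.data.loc[genes]
    cols: dict[str, pd.Series] = {}
    b_used = set(common_ids.values())
    for sid in a.sample_ids:
        if sid in common_ids:
            cols[str(sid)] = (da[sid] + db[common_ids[sid]]) / 2.0
        else:
            cols[str(sid)] = da[sid]
    for sid in b.sample_ids:
        if sid not in b_used:
            cols[str(sid)] = db[sid]
    return ExpressionMatrix(pd.DataFrame(cols, index=genes), "nTPM")


def aggregate_cld(m: ExpressionMatrix, ann: SampleAnnotation,
                  by: str = "disease") -> ExpressionMatrix:
    """Average expression per disease group: one output column per CLD."""
    m.require_unit("nTPM")
    missing = m.sample_ids.difference(ann.sample_ids)
    if len(missing):
        raise ValueError(f"samples without annotation: {list(missing[:5])}")
    groups = ann.groups(by)
    cols = {}
    for label in sorted(groups):
        members = [s for s in groups[label] if s in m.sample_ids]
        if not members:
            raise ValueError(f"disease group {label!r} has no samples in the matrix")
        cols[label] = m.data[members].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols, index=m.gene_ids), "nTPM")


def classify_distribution(row: Sequence[float] | pd.Series,
                          cutoff: float = DETECTION_CUTOFF,
                          gene_id: str = "") -> DistributionCall:
    """Classify one gene's detection pattern across individual samples."""
    x = np.asarray(row, dtype=float)
    n = x.size
    if n < 1:
        raise ValueError("need at least one sample")
    k = int((x >= cutoff).sum())
    if k == 0:
        cat = "not-detected"
    elif k == 1:
        cat = "single"
    elif k == n:
        cat = "all"
    elif k < n / 3.0:
        cat = "some"
    else:
        cat = "many"
    return DistributionCall(gene_id, cat, k, n)


def classify_specificity(row: pd.Series, fold: float = FOLD_THRESHOLD,
                         cutoff: float = DETECTION_CUTOFF,
                         max_group_size: int = MAX_GROUP_SIZE,
                         require_each_member: bool = False,
                         gene_id: str = "") -> SpecificityCall:
    """Classify one gene's expression specificity across groups (CLDs).

    ``row`` is indexed by group label.  The group-enriched search sorts groups
    by descending expression and grows the candidate set from the top,
    accepting the smallest set (2 <= size <= ``max_group_size``) whose mean is
    at least ``fold`` times the maximum outside and whose members are all
    detected.  With ``require_each_member`` every member (not just the group
    mean) must clear ``fold`` times the outside maximum.
    """
    if len(row) < 2:
        raise ValueError("specificity requires at least two groups")
    gid = gene_id or str(getattr(row, "name", ""))
    labels = np.asarray(row.index)
    x = row.to_numpy(dtype=float)
    # deterministic order: descending expression, label as tie-break
    order = np.lexsort((labels, -x))
    xs, ls = x[order], labels[order]
    n = x.size

    # (1) enriched: top group >= fold * next-highest
    denom1 = max(xs[1], DENOM_CLAMP)
    if xs[0] >= cutoff and xs[0] >= fold * denom1:
        return SpecificityCall(gid, "enriched", [str(ls[0])], float(xs[0] / denom1))

    # (2) group-enriched: grow S from the top
    for size in range(2, min(max_group_size, n - 1) + 1):
        members = xs[:size]
        if members[-1] < cutoff:
            break  # further members only smaller: no detected superset exists
        outside = max(xs[size], DENOM_CLAMP)
        stat = members.min() if require_each_member else members.mean()
        if stat >= fold * outside:
            return SpecificityCall(
                gid, "group-enriched", [str(l) for l in ls[:size]],
                float(stat / outside))

    # (3) enhanced: group >= fold * mean of the others
    total = x.sum()
    means_others = np.maximum((total - x) / (n - 1), DENOM_CLAMP)
    hit = (x >= cutoff) & (x >= fold * means_others)
    if hit.any():
        folds = x[hit] / means_others[hit]
        glabels = labels[hit]
        order2 = np.lexsort((glabels, -x[hit]))  # descending expression, label ties
        return SpecificityCall(gid, "enhanced",
                               [str(g) for g in glabels[order2]],
                               float(folds.max()))

    # (4)/(5)
    if (x >= cutoff).any():
        return SpecificityCall(gid, "low-specificity", [], float("nan"))
    return SpecificityCall(gid, "not-detected", [], float("nan"))


def classify_matrix(cld: ExpressionMatrix, fold: float = FOLD_THRESHOLD,
                    cutoff: float = DETECTION_CUTOFF,
                    **kwargs) -> dict[str, SpecificityCall]:
    """Specificity calls for every gene of a CLD matrix."""
    cld.require_unit("nTPM")
    return {
        str(gid): classify_specificity(cld.data.loc[gid], fold=fold, cutoff=cutoff,
                                       gene_id=str(gid), **kwargs)
        for gid in cld.gene_ids
    }


def distribution_matrix(m: ExpressionMatrix,
                        cutoff: float = DETECTION_CUTOFF) -> dict[str, DistributionCall]:
    """Distribution calls for every gene across individual samples."""
    m.require_unit("nTPM")
    return {
        str(gid): classify_distribution(m.data.loc[gid].to_numpy(), cutoff=cutoff,
                                        gene_id=str(gid))
        for gid in m.gene_ids
    }


def elevated_set(calls: Mapping[str, SpecificityCall], group: str,
                 known_groups: Optional[Iterable[str]] = None) -> set[str]:
    """Elevated genes of a group: union of enriched, group-enriched and
    enhanced genes having ``group`` among their defining groups."""
    if known_groups is not None and group not in set(known_groups):
        raise ValueError(f"unknown group label {group!r}")
    return {
        gid for gid, call in calls.items()
        if call.category in ELEVATED_CATEGORIES and group in call.defining_groups
    }


def stage_signature(cohort: ExpressionMatrix, stage_labels: Mapping[str, str],
                    fold: float = FOLD_THRESHOLD,
                    cutoff: float = DETECTION_CUTOFF) -> dict[str, set[str]]:
    """Per-stage signatures: genes with ``fold`` times higher mean expression
    in one stage than in any other stage, and mean >= the detection cutoff.

    ``stage_labels`` maps sample ID -> stage label.
    """
    cohort.require_unit("nTPM")
    stages: dict[str, list[str]] = {}
    for sid, st in stage_labels.items():
        stages.setdefault(str(st), []).append(str(sid))
    if len(stages) < 2:
        raise ValueError("stage signatures require at least two stages")
    means = pd.DataFrame({
        st: cohort.data[[s for s in sids if s in cohort.sample_ids]].mean(axis=1)
        for st, sids in stages.items()
    })
    out: dict[str, set[str]] = {st: set() for st in stages}
    M = means.to_numpy()
    for j, st in enumerate(means.columns):
        others = np.delete(M, j, axis=1)
        denom = np.maximum(others.max(axis=1), DENOM_CLAMP)
        hit = (M[:, j] >= cutoff) & (M[:, j] >= fold * denom)
        out[str(st)] = set(means.index[hit].astype(str))
    return out


def calls_to_frame(spec_calls: Mapping[str, SpecificityCall],
                   dist_calls: Optional[Mapping[str, DistributionCall]] = None
                   ) -> pd.DataFrame:
    """Tabulate classification calls (one row per gene) for TSV export."""
    rows = []
    for gid, c in spec_calls.items():
        row = {
            "gene_id": gid,
            "specificity": c.category,
            "defining_groups": ";".join(c.defining_groups),
            "fold": c.fold,
        }
        if dist_calls and gid in dist_calls:
            d = dist_calls[gid]
            row["distribution"] = d.category
            row["n_detected"] = d.n_detected
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
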