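"""Core containers: gene-by-sample expression matrices and sample annotations.

An :class:`ExpressionMatrix` is a thin, unit-aware wrapper around a pandas
DataFrame with genes as rows and samples as columns.  The ``unit`` field tracks
where a matrix sits in the normalization chain (``counts`` -> ``TPM`` ->
``pTPM`` -> ``nTPM``, or ``centered-log`` for activity scoring) so downstream
stages can refuse inputs at the wrong stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: Recognized expression units, in normalization order (centered-log is apart).
UNITS = ("counts", "TPM", "pTPM", "nTPM", "centered-log")


class UnitError(ValueError):
    """Raised when an operation receives a matrix in the wrong unit."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a declared unit.

    Parameters
    ----------
    data
        DataFrame with gene IDs as the index and sample IDs as columns.
    unit
        One of :data:`UNITS`.  All units except ``centered-log`` require
        nonnegative values.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        if self.unit != "centered-log" and (self.data.to_numpy() < 0).any():
            raise ValueError(f"negative values not allowed in unit {self.unit!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def require_unit(self, *units: str) -> None:
        if self.unit not in units:
            raise UnitError(f"expected unit in {units}, got {self.unit!r}")

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(gene_ids)
        missing = ids.difference(self.data.index)
        if len(missing):
            raise KeyError(f"genes absent from matrix: {list(missing[:5])}")
        return ExpressionMatrix(self.data.loc[ids], self.unit)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(sample_ids)
        missing = ids.difference(self.data.columns)
        if len(missing):
            raise KeyError(f"samples absent from matrix: {list(missing[:5])}")
        return ExpressionMatrix(self.data[ids], self.unit)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.unit)

    # ---- I/O: tab-separated text, genes as rows, first column = gene ID ----

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, unit)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"unit={self.unit!r})"
        )


@dataclass
class SampleAnnotation:
    """Per-sample metadata table.

    Required column: ``disease``.  Optional columns used by different stages:
    ``rrid``, ``panel``, ``primary_or_metastasis``, ``collection_site``,
    ``lineage``, ``purity`` (tumor cohorts), ``stage``.
    The DataFrame index holds the sample IDs.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample IDs in annotation")
        if "disease" not in self.table.columns:
            raise ValueError("annotation requires a 'disease' column")
        if self.table["disease"].isna().any() or (self.table["disease"] == "").any():
            bad = self.table.index[
                self.table["disease"].isna() | (self.table["disease"] == "")
            ].tolist()
            raise ValueError(f"empty disease label for samples: {bad[:5]}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def disease_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "disease"])

    def groups(self, column: str = "disease") -> dict[str, list[str]]:
        """Map each label in ``column`` to the list of its sample IDs."""
        out: dict[str, list[str]] = {}
        for sid, label in self.table[column].items():
            out.setdefault(str(label), []).append(str(sid))
        return out

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleAnnotation":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list, ignoring blank lines."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT text (set name, description, tab-separated IDs)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path,
              descriptions: Optional[dict[str, str]] = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(map(str, genes))]) + "\n")
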