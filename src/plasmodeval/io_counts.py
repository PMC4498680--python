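"""Plain-text I/O for count matrices, sample metadata, dissimilarities and trees.

All on-disk formats are tab-separated UTF-8 text without quoting:

* count matrix — header row of sample IDs, first column named ``gene_id``;
* sample metadata — columns ``sample_id``, ``group``, ``block``;
* dissimilarity matrix — square TSV with sample IDs on both axes;
* dendrogram — a lossless node table (leaf and merge rows) plus Newick export.

Gene order is never assumed sorted; downstream operations align by ``gene_id``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleMeta",
    "read_counts",
    "write_counts",
    "read_meta",
    "write_meta",
    "read_dissimilarity",
    "write_dissimilarity",
]


class ValidationError(ValueError):
    """Raised when an in-memory object violates its invariants."""


class ParseError(ValueError):
    """Raised when an on-disk table cannot be parsed; names the offending cell."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Integer gene × sample count table.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers (genes/transcripts).
    sample_ids : list of str
        Unique column identifiers (samples).
    counts : ndarray of shape (n_genes, n_samples)
        Nonnegative integer read counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not len(self.sample_ids):
            raise ValidationError("CountMatrix requires at least one sample")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be nonnegative")
        _check_unique(self.gene_ids, "gene_id")
        _check_unique(self.sample_ids, "sample_id")
        self.counts = counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    def drop_all_zero(self) -> "CountMatrix":
        """Remove genes whose counts are zero in every sample (idempotent)."""
        keep = self.counts.sum(axis=1) > 0
        return CountMatrix([g for g, k in zip(self.gene_ids, keep) if k],
                           list(self.sample_ids), self.counts[keep])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in gene_ids]
        except KeyError as e:
            raise ValidationError(f"unknown gene_id {e.args[0]!r}") from None
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[rows])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as e:
            raise ValidationError(f"unknown sample_id {e.args[0]!r}") from None
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, cols])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (self.gene_ids == other.gene_ids and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))


@dataclass
class SampleMeta:
    """Per-sample metadata: group (e.g. strain/treatment) and block (e.g. flowcell)."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "group", "block")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing columns {missing}")
        self.frame = self.frame.loc[:, list(self.REQUIRED)].astype(str).reset_index(drop=True)
        _check_unique(self.frame["sample_id"].tolist(), "sample_id")

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str, str]]) -> "SampleMeta":
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED)))

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def group_of(self, sample_id: str) -> str:
        return self._lookup(sample_id, "group")

    def block_of(self, sample_id: str) -> str:
        return self._lookup(sample_id, "block")

    def _lookup(self, sample_id: str, col: str) -> str:
        rows = self.frame.loc[self.frame["sample_id"] == str(sample_id), col]
        if rows.empty:
            raise ValidationError(f"sample {sample_id!r} not in metadata")
        return rows.iloc[0]

    def validate_against(self, cm: CountMatrix) -> None:
        """Every sample in *cm* must have exactly one metadata row."""
        missing = set(cm.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    def subset(self, sample_ids: Sequence[str]) -> "SampleMeta":
        frame = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMeta(frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMeta):
            return NotImplemented
        return self.frame.equals(other.frame)


def read_counts(path: str | Path, drop_all_zero: bool = False) -> CountMatrix:
    """Read a gene × sample count TSV.

    The file must have a header row of sample IDs (first cell is the gene-ID
    column name) and one row per gene; every data cell must parse as a
    nonnegative integer.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    counts = np.zeros(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            try:
                value = int(str(cell))
            except (TypeError, ValueError):
                raise ParseError(
                    f"cell at gene {gene_ids[i]!r}, sample {sample_ids[j]!r} "
                    f"is not an integer: {cell!r}") from None
            if value < 0:
                raise ParseError(
                    f"cell at gene {gene_ids[i]!r}, sample {sample_ids[j]!r} "
                    f"is negative: {value}")
            counts[i, j] = value
    cm = CountMatrix(gene_ids, sample_ids, counts)
    return cm.drop_all_zero() if drop_all_zero else cm


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as TSV (header ``gene_id`` + sample IDs)."""
    cm.to_frame().to_csv(path, sep="\t")


def read_meta(path: str | Path) -> SampleMeta:
    return SampleMeta(pd.read_csv(path, sep="\t", dtype=str))


def write_meta(meta: SampleMeta, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def write_dissimilarity(sample_ids: Sequence[str], values: np.ndarray,
                        path: str | Path) -> None:
    pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                 columns=list(sample_ids)).to_csv(path, sep="\t")


def read_dissimilarity(path: str | Path) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(s) for s in frame.index]
    if ids != [str(s) for s in frame.columns]:
        raise ParseError("dissimilarity TSV row and column sample IDs differ")
    return ids, frame.to_numpy(dtype=float)
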