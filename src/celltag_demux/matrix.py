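"""Cell x CellTag UMI count matrix container with Matrix Market and CSV I/O.

The matrix is the central exchange object of the pipeline: extraction builds
it, collapse merges its columns, and the classifier consumes it. Counts are
UMI-deduplicated non-negative integers; rows are droplet cell barcodes and
columns are CellTag barcode sequences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["TagCountMatrix", "read_matrix", "write_matrix"]

_MTX_FILE = "matrix.mtx"
_CELLS_FILE = "cells.tsv"
_TAGS_FILE = "tags.tsv"


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(set(ids.tolist())) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids.tolist() if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class TagCountMatrix:
    """Sparse cells x tags matrix of UMI counts.

    Parameters
    ----------
    cell_ids
        Ordered, unique droplet barcodes (rows).
    tag_seqs
        Ordered, unique CellTag sequences (columns).
    counts
        Non-negative integer matrix, shape ``(n_cells, n_tags)``; any
        scipy-sparse or dense array is accepted and stored as CSR.
    """

    cell_ids: np.ndarray
    tag_seqs: np.ndarray
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.tag_seqs = np.asarray(self.tag_seqs, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.cell_ids), len(self.tag_seqs)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.tag_seqs)} tags"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.tag_seqs, "tag sequences")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_tags(self) -> int:
        return len(self.tag_seqs)

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.cell_ids, columns=self.tag_seqs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TagCountMatrix":
        return cls(
            cell_ids=df.index.to_numpy(dtype=object),
            tag_seqs=df.columns.to_numpy(dtype=object),
            counts=sp.csr_matrix(df.to_numpy()),
        )

    def tag_totals(self) -> dict[str, int]:
        """Total UMI count per tag, as the collapse stage expects."""
        totals = np.asarray(self.counts.sum(axis=0)).ravel()
        return {t: int(c) for t, c in zip(self.tag_seqs, totals)}

    def reindex_cells(self, cell_ids) -> "TagCountMatrix":
        """Conform the matrix to ``cell_ids``: known rows are reused, cells
        with no extracted tags get zero rows (downstream they classify as
        non-determined)."""
        _check_unique(np.asarray(cell_ids, dtype=object), "cell ids")
        index = {c: i for i, c in enumerate(self.cell_ids)}
        out = sp.lil_matrix((len(cell_ids), self.n_tags), dtype=np.int64)
        for r, c in enumerate(cell_ids):
            if c in index:
                out[r] = self.counts[index[c]]
        return TagCountMatrix(
            np.asarray(list(cell_ids), dtype=object), self.tag_seqs.copy(), out.tocsr()
        )

    def select_cells(self, cell_ids) -> "TagCountMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in index]
        if missing:
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        rows = [index[c] for c in cell_ids]
        return TagCountMatrix(
            np.asarray(list(cell_ids), dtype=object),
            self.tag_seqs.copy(),
            self.counts[rows],
        )

    def equals(self, other: "TagCountMatrix") -> bool:
        return (
            np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.tag_seqs, other.tag_seqs)
            and (self.counts != other.counts).nnz == 0
        )


def write_matrix(matrix: TagCountMatrix, path: str, format: str = "mtx") -> None:
    """Write a matrix as a Matrix Market triplet directory or a dense CSV.

    ``mtx`` writes ``matrix.mtx`` + ``cells.tsv`` + ``tags.tsv`` (10x-style
    triplet layout) into directory ``path``; ``csv`` writes a single dense
    file with tags as the header row and cell ids as the first column.
    """
    if format == "mtx":
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(os.path.join(path, _MTX_FILE), matrix.counts.tocoo(), field="integer")
        pd.Series(matrix.cell_ids).to_csv(
            os.path.join(path, _CELLS_FILE), sep="\t", index=False, header=False
        )
        pd.Series(matrix.tag_seqs).to_csv(
            os.path.join(path, _TAGS_FILE), sep="\t", index=False, header=False
        )
    elif format == "csv":
        matrix.to_dataframe().to_csv(path, index_label="cell_id")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")


def read_matrix(path: str, format: str = "mtx") -> TagCountMatrix:
    """Read a matrix written by :func:`write_matrix` (inverse on both formats)."""
    if format == "mtx":
        mtx_path = os.path.join(path, _MTX_FILE)
        counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
        cells = _read_id_column(os.path.join(path, _CELLS_FILE))
        tags = _read_id_column(os.path.join(path, _TAGS_FILE))
        if counts.shape != (len(cells), len(tags)):
            raise ValueError(
                f"{mtx_path} is {counts.shape[0]}x{counts.shape[1]} but "
                f"{_CELLS_FILE} lists {len(cells)} cells and {_TAGS_FILE} "
                f"lists {len(tags)} tags"
            )
        return TagCountMatrix(cells, tags, counts)
    if format == "csv":
        df = pd.read_csv(path, index_col=0, dtype={0: str})
        df.index = df.index.astype(str)
        return TagCountMatrix.from_dataframe(df)
    raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")


def _read_id_column(path: str) -> np.ndarray:
    if os.path.getsize(path) == 0:
        return np.asarray([], dtype=object)
    return (
        pd.read_csv(path, sep="\t", header=None, dtype=str)[0].to_numpy(dtype=object)
    )
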