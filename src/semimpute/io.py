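"""Expression-matrix containers and on-disk formats.

Matrices are oriented genes-as-rows, cells-as-columns, matching the GEO
convention for scRNA-seq count tables.  Zeros are kept explicit in dense
formats and implicit in MatrixMarket; whether a zero is a true zero or a
dropout is never decided at I/O time.

Supported formats:

* ``csv`` / ``tsv`` — first row holds cell ids, first column gene ids.
* ``mtx`` — MatrixMarket coordinate format with ``<stem>.genes.txt`` and
  ``<stem>.cells.txt`` one-name-per-line sidecar files.
* cluster labels — two-column TSV ``(cell_id, label)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "Stage",
    "ExpressionMatrix",
    "DropoutMask",
    "ClusterLabels",
    "read_expression",
    "write_expression",
    "derive_mask",
    "read_cluster_labels",
    "write_cluster_labels",
]


class Stage(str, enum.Enum):
    """Pipeline stage of an expression matrix."""

    RAW_COUNTS = "raw_counts"
    NORMALIZED = "normalized"
    LOG_TRANSFORMED = "log_transformed"


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} id {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """A non-negative gene-by-cell expression matrix.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_cells)``; counts or log-normalized
        expression depending on ``stage``.  Zeros encode both true zeros and
        dropouts.
    gene_ids, cell_ids
        Unique identifiers matching the two axes.
    stage
        Where in the preprocessing pipeline the values live.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    stage: Stage = Stage.RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if isinstance(self.stage, str):
            self.stage = Stage(self.stage)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError(
                f"id lengths ({len(self.gene_ids)} genes, {len(self.cell_ids)} "
                f"cells) do not match matrix shape {self.values.shape}"
            )
        bad = np.argwhere(np.isnan(self.values))
        if bad.size:
            g, c = bad[0]
            raise ValueError(
                f"NaN entry at gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )
        bad = np.argwhere(self.values < 0)
        if bad.size:
            g, c = bad[0]
            raise ValueError(
                f"negative entry {self.values[g, c]} at gene "
                f"{self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, stage: Stage | None = None) -> "ExpressionMatrix":
        """Copy of self with new values (and optionally a new stage)."""
        return replace(
            self,
            values=values,
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            stage=self.stage if stage is None else stage,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class DropoutMask:
    """Binary observation mask M: 1 exactly where the matrix is non-zero."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        self.values = self.values.astype(float)


@dataclass
class ClusterLabels:
    """Integer cluster assignment for each cell, values in ``0..k-1``."""

    labels: np.ndarray
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        uniq = np.unique(self.labels)
        self.k = len(uniq)
        if self.k and not np.array_equal(uniq, np.arange(self.k)):
            raise ValueError(
                f"labels must cover 0..k-1 with every value present; got {uniq}"
            )

    def __len__(self) -> int:
        return len(self.labels)


_FORMATS = ("csv", "tsv", "mtx")


def _infer_format(path: Path, format: str | None) -> str:
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    return format


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.txt"), stem.with_suffix(".cells.txt")


def read_expression(
    path: str | Path,
    format: str | None = None,
    stage: Stage = Stage.RAW_COUNTS,
) -> ExpressionMatrix:
    """Read a gene-by-cell expression matrix.

    The format is inferred from the file suffix unless given explicitly.
    Negative, NaN, or duplicate-id inputs are rejected with a message naming
    the offending coordinate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    format = _infer_format(path, format)
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            stage=stage,
        )
    genes_path, cells_path = _sidecars(path)
    for p in (genes_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(f"missing mtx sidecar file {p}")
    mat = scipy.io.mmread(path)
    values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    gene_ids = genes_path.read_text().splitlines()
    cell_ids = cells_path.read_text().splitlines()
    return ExpressionMatrix(values, gene_ids, cell_ids, stage=stage)


def write_expression(m: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write ``m`` so that :func:`read_expression` round-trips it.

    Values are serialized with enough precision for round-trip equality at
    1e-9 relative tolerance.  Empty matrices are rejected.
    """
    path = Path(path)
    if m.n_genes == 0 or m.n_cells == 0:
        raise ValueError(f"refusing to write empty matrix of shape {m.values.shape}")
    format = _infer_format(path, format)
    if format in ("csv", "tsv"):
        m.to_frame().to_csv(path, sep="," if format == "csv" else "\t", float_format="%.12g")
        return
    genes_path, cells_path = _sidecars(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values), precision=12)
    genes_path.write_text("\n".join(m.gene_ids) + "\n")
    cells_path.write_text("\n".join(m.cell_ids) + "\n")


def derive_mask(m: ExpressionMatrix) -> DropoutMask:
    """Binary mask M with M[i,j] = 1 iff m[i,j] > 0.

    The Hadamard product ``M ∘ m`` reproduces ``m`` exactly, so the mask
    separates observed entries from zeros (true zeros and dropouts alike).
    """
    return DropoutMask((m.values > 0).astype(float))


def read_cluster_labels(path: str | Path, cell_ids: Sequence[str] | None = None) -> ClusterLabels:
    """Read a two-column TSV ``(cell_id, label)``.

    If ``cell_ids`` is given, rows are reordered to that ordering and every id
    must be present.  Raw label values are compacted to ``0..k-1`` preserving
    their sorted order.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype={"cell_id": str})
    if cell_ids is not None:
        missing = [c for c in cell_ids if c not in set(df["cell_id"])]
        if missing:
            raise ValueError(f"label file {path} is missing cell ids: {missing}")
        df = df.set_index("cell_id").loc[list(cell_ids)].reset_index()
    codes = pd.Categorical(df["label"]).codes
    return ClusterLabels(np.asarray(codes, dtype=int))


def write_cluster_labels(labels: ClusterLabels, cell_ids: Sequence[str], path: str | Path) -> None:
    if len(labels) != len(cell_ids):
        raise ValueError("labels and cell_ids have different lengths")
    pd.DataFrame({"cell_id": list(cell_ids), "label": labels.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )
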