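"""Preprocessing: filtering, library-size normalization, gene selection, log transform.

The pipeline runs in a fixed order — filter genes, filter cells, normalize
each cell to a common total, keep the most variable genes, then log-transform
— and never turns a zero into a non-zero, so the observation mask derived from
the raw counts remains valid downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, Stage

__all__ = [
    "PreprocessConfig",
    "filter_matrix",
    "normalize_library_size",
    "select_genes",
    "log_transform",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    """Thresholds and scales for the preprocessing pipeline.

    Attributes
    ----------
    min_cells_expressed
        A gene is kept only if it is non-zero in at least this many cells.
    min_genes_expressed
        A cell is kept only if it expresses at least this many genes.
    n_top_genes
        Number of highest-variance genes to keep after normalization, or
        ``"all"`` to keep every gene.
    scale_factor
        Target per-cell total after library-size normalization.
    log_offset
        Pseudo-count of the log transform; 1 gives log1p.
    """

    min_cells_expressed: int = 3
    min_genes_expressed: int = 200
    n_top_genes: int | str = "all"
    scale_factor: float = 10_000.0
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.min_cells_expressed < 0 or self.min_genes_expressed < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.scale_factor <= 0 or self.log_offset <= 0:
            raise ValueError("scale_factor and log_offset must be positive")
        if self.n_top_genes != "all" and int(self.n_top_genes) <= 0:
            raise ValueError("n_top_genes must be positive or 'all'")


def filter_matrix(m: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Drop under-expressed genes, then under-expressing cells.

    Genes non-zero in fewer than ``min_cells_expressed`` cells are removed
    first; cells expressing fewer than ``min_genes_expressed`` of the
    remaining genes are removed second.
    """
    cfg = cfg or PreprocessConfig()
    if m.stage is not Stage.RAW_COUNTS:
        raise ValueError(f"filter_matrix expects raw counts, got stage={m.stage.value}")
    expressed = m.values > 0
    gene_keep = expressed.sum(axis=1) >= cfg.min_cells_expressed
    n_genes = int(gene_keep.sum())
    cell_keep = expressed[gene_keep].sum(axis=0) >= cfg.min_genes_expressed
    n_cells = int(cell_keep.sum())
    if n_genes == 0 or n_cells == 0:
        raise ValueError(
            f"filtering removed everything: {n_genes} genes and {n_cells} cells survive"
        )
    return ExpressionMatrix(
        m.values[np.ix_(gene_keep, cell_keep)],
        [g for g, k in zip(m.gene_ids, gene_keep) if k],
        [c for c, k in zip(m.cell_ids, cell_keep) if k],
        stage=Stage.RAW_COUNTS,
    )


def normalize_library_size(m: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Scale each cell so its total equals ``scale_factor``.

    Removes sequencing-depth differences between cells; zeros stay exactly
    zero.  Cells with zero total must have been removed by filtering first.
    """
    cfg = cfg or PreprocessConfig()
    if m.stage is not Stage.RAW_COUNTS:
        raise ValueError(f"normalize_library_size expects raw counts, got stage={m.stage.value}")
    totals = m.values.sum(axis=0)
    if (totals == 0).any():
        bad = [m.cell_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"cells with zero total counts (filter first): {bad}")
    return m.with_values(m.values * (cfg.scale_factor / totals), stage=Stage.NORMALIZED)


def select_genes(m: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Keep the ``n_top_genes`` genes with highest log-expression variance.

    Variance is computed on ``log(value + log_offset)`` across cells, a simple
    dispersion proxy for variable-gene selection.  Ties are broken in favour
    of earlier-indexed genes and the original gene order is preserved.
    """
    cfg = cfg or PreprocessConfig()
    if m.stage is not Stage.NORMALIZED:
        raise ValueError(f"select_genes expects normalized values, got stage={m.stage.value}")
    if cfg.n_top_genes == "all":
        return m.with_values(m.values.copy())
    n_top = int(cfg.n_top_genes)
    if n_top > m.n_genes:
        raise ValueError(f"n_top_genes={n_top} exceeds available genes ({m.n_genes})")
    var = np.log(m.values + cfg.log_offset).var(axis=1)
    # stable sort on -var keeps original order among ties
    order = np.argsort(-var, kind="stable")[:n_top]
    keep = np.zeros(m.n_genes, dtype=bool)
    keep[order] = True
    return ExpressionMatrix(
        m.values[keep],
        [g for g, k in zip(m.gene_ids, keep) if k],
        list(m.cell_ids),
        stage=Stage.NORMALIZED,
    )


def log_transform(m: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Entrywise ``log(value + log_offset) - log(log_offset)``.

    The shift keeps zeros at exactly zero for any offset (for offset 1 this is
    plain log1p), so the observation mask survives the transform.
    """
    cfg = cfg or PreprocessConfig()
    if m.stage is not Stage.NORMALIZED:
        raise ValueError(f"log_transform expects normalized values, got stage={m.stage.value}")
    if cfg.log_offset == 1.0:
        values = np.log1p(m.values)
    else:
        values = np.log(m.values + cfg.log_offset) - np.log(cfg.log_offset)
    values[m.values == 0] = 0.0
    return m.with_values(values, stage=Stage.LOG_TRANSFORMED)


def preprocess(m: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Full pipeline: filter → normalize → select genes → log transform."""
    cfg = cfg or PreprocessConfig()
    return log_transform(select_genes(normalize_library_size(filter_matrix(m, cfg), cfg), cfg), cfg)
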