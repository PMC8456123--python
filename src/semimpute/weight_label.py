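"""Imputation weight labels: consensus-clustering imputation or external files.

The semi-supervised cost needs a weight-label matrix F — a fully imputed
version of the input whose values act as soft targets for the zero entries
during training.  F can come from any external imputer (loaded from disk and
aligned by id), or from the built-in consensus imputer: cells are clustered
repeatedly by k-means over a range of k, each zero entry is estimated by the
mean of its gene over the cells sharing its cluster (zeros included in the
mean), and the estimates are averaged across all clustering runs.

Both sources obey the fill-only contract: wherever the input is non-zero, the
label equals the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array

from .io import ExpressionMatrix, Stage, read_expression

__all__ = [
    "WeightLabelMatrix",
    "ConsensusConfig",
    "ConsensusImputer",
    "consensus_impute",
    "load_label",
]

DEFAULT_K_VALUES = (10, 11, 12, 13, 14, 15)


@dataclass
class WeightLabelMatrix:
    """Weight label F, same shape/ordering as the matrix it labels."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    source: str  # "external_file" or "consensus"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("label shape does not match id lengths")
        if np.isnan(self.values).any() or (self.values < 0).any():
            raise ValueError("label values must be finite and non-negative")


@dataclass
class ConsensusConfig:
    """Clustering schedule of the consensus imputer.

    ``k_values`` mirrors the default k range of consensus-clustering
    imputation (10..15), clipped below the number of cells at run time.
    """

    k_values: Sequence[int] = field(default_factory=lambda: list(DEFAULT_K_VALUES))
    n_runs_per_k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs_per_k < 1:
            raise ValueError("n_runs_per_k must be >= 1")
        if any(k < 2 for k in self.k_values):
            raise ValueError("every k must be >= 2")
        if not self.k_values:
            raise ValueError("k_values must be non-empty")


class ConsensusImputer(BaseEstimator, TransformerMixin):
    """Consensus-clustering imputer for zero entries.

    Follows the sklearn sample convention: arrays are cells × genes.  For
    each (k, replicate) pair, cells are k-means-clustered on their expression
    vectors; a zero entry's run estimate is the mean of its gene over the
    cells in its cluster, including the zeros of cluster members — when a
    gene is silent throughout a cluster the estimate is 0 and the entry is
    left untouched.  The final fill value averages the estimates over all
    runs; non-zero entries pass through unchanged.

    Parameters
    ----------
    k_values : sequence of int, default (10, ..., 15)
        Cluster counts to try; each must be >= 2 and < n_cells.
    n_runs_per_k : int, default 2
        k-means replicates per k, each with its own derived seed.
    random_state : int, default 0
        Base seed; runs are seeded deterministically from it.
    """

    def __init__(self, k_values: Sequence[int] | None = None, n_runs_per_k: int = 2,
                 random_state: int = 0):
        self.k_values = k_values
        self.n_runs_per_k = n_runs_per_k
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        ks = list(self.k_values) if self.k_values is not None else [
            k for k in DEFAULT_K_VALUES if k < X.shape[0]
        ]
        if not ks:
            raise ValueError("no valid k: need at least 3 cells for the default k range")
        ConsensusConfig(k_values=ks, n_runs_per_k=self.n_runs_per_k, seed=self.random_state)
        if max(ks) > X.shape[0]:
            raise ValueError(f"k={max(ks)} exceeds number of cells ({X.shape[0]})")
        self.k_values_ = ks
        return self

    def transform(self, X) -> np.ndarray:
        X = check_array(X, ensure_min_samples=2)
        if not hasattr(self, "k_values_"):
            self.fit(X)
        n_cells = X.shape[0]
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            len(self.k_values_) * self.n_runs_per_k
        )
        estimates = np.zeros_like(X)
        n_runs = 0
        for i, k in enumerate(self.k_values_):
            for r in range(self.n_runs_per_k):
                seed = int(seeds[i * self.n_runs_per_k + r]) % (2**31)
                labels = self._cluster_once(X, k, seed)
                if len(np.unique(labels)) < k:
                    labels = self._cluster_once(X, k, seed + 1)  # re-seed once
                    if len(np.unique(labels)) < k:
                        raise RuntimeError(f"empty cluster for k={k} after re-seeding")
                # per-cluster per-gene means, zeros of members included
                onehot = np.zeros((n_cells, k))
                onehot[np.arange(n_cells), labels] = 1.0
                means = (onehot.T @ X) / onehot.sum(axis=0)[:, None]
                estimates += means[labels]
                n_runs += 1
        estimates /= n_runs
        return np.where(X > 0, X, estimates)

    @staticmethod
    def _cluster_once(X: np.ndarray, k: int, seed: int) -> np.ndarray:
        return KMeans(n_clusters=k, n_init=1, random_state=seed).fit_predict(X)


def consensus_impute(m: ExpressionMatrix, cfg: ConsensusConfig | None = None) -> WeightLabelMatrix:
    """Build a weight label for ``m`` with the built-in consensus imputer.

    ``m`` must be log-transformed; the label lives on the same scale.
    """
    if m.stage is not Stage.LOG_TRANSFORMED:
        raise ValueError(f"consensus_impute expects log-transformed input, got {m.stage.value}")
    if cfg is None:
        ks = [k for k in DEFAULT_K_VALUES if k < m.n_cells]
        cfg = ConsensusConfig(k_values=ks or [2])
    imputer = ConsensusImputer(
        k_values=list(cfg.k_values), n_runs_per_k=cfg.n_runs_per_k, random_state=cfg.seed
    )
    filled = imputer.fit(m.values.T).transform(m.values.T).T
    return WeightLabelMatrix(filled, list(m.gene_ids), list(m.cell_ids), source="consensus")


def load_label(path: str | Path, target: ExpressionMatrix) -> WeightLabelMatrix:
    """Load an externally imputed matrix as the weight label for ``target``.

    Rows and columns are aligned to the target's gene/cell ordering by id;
    every target id must be present in the file.  Entries where the target is
    non-zero are overwritten with the target's own values, enforcing the
    fill-only contract regardless of what the external imputer did there.
    """
    ext = read_expression(path, stage=target.stage)
    missing_genes = sorted(set(target.gene_ids) - set(ext.gene_ids))
    missing_cells = sorted(set(target.cell_ids) - set(ext.cell_ids))
    if missing_genes or missing_cells:
        parts = []
        if missing_genes:
            parts.append(f"genes {missing_genes[:5]}")
        if missing_cells:
            parts.append(f"cells {missing_cells[:5]}")
        raise ValueError(f"label file {path} is missing ids: " + "; ".join(parts))
    frame = ext.to_frame().loc[target.gene_ids, target.cell_ids]
    values = np.where(target.values > 0, target.values, frame.to_numpy(dtype=float))
    return WeightLabelMatrix(values, list(target.gene_ids), list(target.cell_ids),
                             source="external_file")
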