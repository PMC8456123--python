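"""Clustering-based evaluation of imputation quality.

The downstream protocol embeds cells with t-SNE, clusters the embedding with
k-means, and compares the predicted partition with the known cell types via
four pair-counting agreement indexes — Rand, adjusted Rand (ARI),
Fowlkes–Mallows (FM) and Jaccard — all computed from first principles from
the pair contingency (a, b, c, d):

    a : cell pairs grouped together in both partitions
    b : together in truth, apart in prediction
    c : apart in truth, together in prediction
    d : apart in both

    Rand    = (a + d) / (a + b + c + d)
    Jaccard = a / (a + b + c)
    FM      = a / sqrt((a + b)(a + c))
    ARI     = (a − E[a]) / (max_a − E[a]),  the permutation-model
              chance correction with E[a] = (a+b)(a+c)/(a+b+c+d) and
              max_a = ((a+b) + (a+c)) / 2.

The pair counts a, b, c, d are derived from the label contingency table; ARI
therefore needs the label vectors (through :func:`clustering_indexes`), while
the other three indexes are pure functions of the four counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .io import ClusterLabels, ExpressionMatrix

__all__ = [
    "PairContingency",
    "MetricReport",
    "pair_counts",
    "indexes_from_counts",
    "clustering_indexes",
    "cluster_cells",
    "evaluate_imputation",
]


@dataclass
class PairContingency:
    """Unordered-pair counts underlying the agreement indexes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("pair counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class MetricReport:
    rand: float
    ari: float
    fm: float
    jaccard: float


def _check_pair(truth: ClusterLabels, pred: ClusterLabels) -> tuple[np.ndarray, np.ndarray]:
    t, p = truth.labels, pred.labels
    if len(t) != len(p):
        raise ValueError(f"label lengths differ: {len(t)} vs {len(p)}")
    if len(t) < 2:
        raise ValueError("need at least 2 items to count pairs")
    return t, p


def _contingency(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    n_ij = np.zeros((t.max() + 1, p.max() + 1), dtype=np.int64)
    np.add.at(n_ij, (t, p), 1)
    return n_ij


def pair_counts(truth: ClusterLabels, pred: ClusterLabels) -> PairContingency:
    """Count unordered cell pairs by how the two partitions treat them.

    Computed from the r×s label contingency table: a = Σ C(n_ij, 2),
    a+b = Σ C(n_i·, 2), a+c = Σ C(n_·j, 2), with d the remainder of the
    n(n−1)/2 pairs.
    """
    t, p = _check_pair(truth, pred)
    n = len(t)
    n_ij = _contingency(t, p)

    def comb2(x: np.ndarray) -> int:
        return int((x.astype(np.int64) * (x - 1) // 2).sum())

    a = comb2(n_ij)
    ab = comb2(n_ij.sum(axis=1))
    ac = comb2(n_ij.sum(axis=0))
    total = n * (n - 1) // 2
    return PairContingency(a=a, b=ab - a, c=ac - a, d=total - ab - ac + a)


def indexes_from_counts(pc: PairContingency, ari: float | None = None) -> MetricReport:
    """Rand/Jaccard/FM from the four counts; ARI must be supplied.

    Degenerate denominators (no pair grouped together by either partition)
    yield 0 for Jaccard and FM.
    """
    rand = (pc.a + pc.d) / pc.total
    jaccard = pc.a / (pc.a + pc.b + pc.c) if pc.a + pc.b + pc.c else 0.0
    denom = (pc.a + pc.b) * (pc.a + pc.c)
    fm = pc.a / np.sqrt(denom) if denom else 0.0
    if ari is None:
        expected = (pc.a + pc.b) * (pc.a + pc.c) / pc.total
        max_a = ((pc.a + pc.b) + (pc.a + pc.c)) / 2.0
        ari = 1.0 if max_a == expected else (pc.a - expected) / (max_a - expected)
    return MetricReport(rand=float(rand), ari=float(ari), fm=float(fm), jaccard=float(jaccard))


def clustering_indexes(truth: ClusterLabels, pred: ClusterLabels) -> MetricReport:
    """All four agreement indexes between two partitions of the same cells."""
    pc = pair_counts(truth, pred)
    return indexes_from_counts(pc)


def cluster_cells(
    m: ExpressionMatrix,
    k: int,
    reduce: str = "tsne",
    seed: int = 0,
) -> ClusterLabels:
    """Cluster cells by k-means, optionally after 2-D t-SNE embedding.

    t-SNE uses perplexity ``min(30, (n_cells − 1) / 3)`` and the given seed;
    k-means runs 10 restarts.  Deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > m.n_cells:
        raise ValueError(f"k={k} exceeds number of cells ({m.n_cells})")
    if reduce not in ("tsne", "none"):
        raise ValueError(f"unknown reduction {reduce!r}")
    X = m.values.T  # cells as samples
    if reduce == "tsne":
        perplexity = min(30.0, (m.n_cells - 1) / 3.0)
        X = TSNE(
            n_components=2, perplexity=perplexity, init="pca", random_state=seed
        ).fit_transform(X)
    raw = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    # compact to 0..k'-1 in first-appearance order for the ClusterLabels contract
    _, labels = np.unique(raw, return_inverse=True)
    return ClusterLabels(labels)


def evaluate_imputation(
    imputed: ExpressionMatrix,
    truth_labels: ClusterLabels,
    k: int | None = None,
    seed: int = 0,
    reduce: str = "tsne",
) -> MetricReport:
    """t-SNE → k-means on the imputed matrix, scored against known labels.

    ``k`` defaults to the number of ground-truth cell types.
    """
    if len(truth_labels) != imputed.n_cells:
        raise ValueError(
            f"{len(truth_labels)} labels for {imputed.n_cells} cells"
        )
    if k is None:
        k = truth_labels.k
    pred = cluster_cells(imputed, k=k, reduce=reduce, seed=seed)
    return clustering_indexes(truth_labels, pred)
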