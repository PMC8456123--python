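"""Synthetic clustered scRNA-seq counts with known labels and dropout.

The generator emulates the structure the imputation experiments rely on:

* discrete cell populations with distinct expression profiles — each cluster
  shares a lognormal base gene-mean vector, with a fraction of genes given
  cluster-specific fold-changes (up or down);
* multiplicative library-size variation via lognormal per-cell size factors;
* negative-binomial count noise (gamma–Poisson mixture with a common
  dispersion), which already produces biologically/statistically "real"
  zeros at lowly expressed genes;
* genuinely silent genes, all-zero by construction, which a good imputer
  must leave untouched;
* zero inflation from dropout events: each positive entry is independently
  zeroed with a fixed probability (an optional expression-dependent mode
  makes lowly expressed entries drop out more often).

Both the pre-dropout truth and the observed matrix are returned, along with
the exact dropout coordinates, so recovery can be scored by masked RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ClusterLabels, ExpressionMatrix, Stage

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "masked_rmse"]


@dataclass
class SimulationConfig:
    """Knobs of the clustered-count generator.

    Attributes
    ----------
    n_genes, n_cells, n_clusters
        Matrix dimensions and number of cell populations.
    de_fraction
        Fraction of genes given a cluster-specific fold-change, per cluster.
    de_strength
        Multiplicative fold-change magnitude of those genes (applied up or
        down with equal probability).
    mean_expression
        Median of the lognormal base gene means (counts per cell before size
        factors).
    mean_sdlog
        Log-scale spread of the base gene means.
    dispersion
        Negative-binomial size parameter θ (variance = μ + μ²/θ); smaller
        values mean noisier counts.
    libsize_sdlog
        Log-scale spread of the per-cell size factors.
    dropout_rate
        Probability that a positive entry is zeroed by a dropout event.
    dropout_expression_dependent
        If true, an entry's dropout probability decays with its magnitude
        (``rate · exp(−count / mean_expression)`` rescaled to average to
        ``dropout_rate``), mimicking capture inefficiency at low expression.
    silent_gene_fraction
        Fraction of genes forced all-zero in the truth matrix.
    seed
        Generator seed; the whole dataset is deterministic given it.
    """

    n_genes: int = 2000
    n_cells: int = 300
    n_clusters: int = 3
    de_fraction: float = 0.2
    de_strength: float = 3.0
    mean_expression: float = 2.0
    mean_sdlog: float = 1.0
    dispersion: float = 2.0
    libsize_sdlog: float = 0.3
    dropout_rate: float = 0.3
    dropout_expression_dependent: bool = False
    silent_gene_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_cells:
            raise ValueError("n_clusters must be <= n_cells")
        if self.n_clusters < 1 or self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("dimensions must be positive")
        for name in ("de_fraction", "dropout_rate", "silent_gene_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if min(self.mean_expression, self.dispersion, self.de_strength) <= 0:
            raise ValueError("mean_expression, dispersion and de_strength must be > 0")


@dataclass
class SimulatedDataset:
    """Truth/observed matrix pair with labels and dropout coordinates."""

    truth: ExpressionMatrix
    observed: ExpressionMatrix
    labels: ClusterLabels
    dropout_positions: np.ndarray  # (n_dropouts, 2) int array of (gene, cell)
    silent_genes: np.ndarray  # gene indices forced all-zero by construction

    @property
    def dropout_mask(self) -> np.ndarray:
        mask = np.zeros(self.truth.values.shape, dtype=bool)
        if len(self.dropout_positions):
            mask[self.dropout_positions[:, 0], self.dropout_positions[:, 1]] = True
        return mask


def simulate(cfg: SimulationConfig | None = None) -> SimulatedDataset:
    """Draw a clustered count matrix and its dropout-corrupted observation."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    g, n, k = cfg.n_genes, cfg.n_cells, cfg.n_clusters

    base_means = rng.lognormal(np.log(cfg.mean_expression), cfg.mean_sdlog, size=g)
    profiles = np.tile(base_means[:, None], (1, k))
    n_de = int(round(cfg.de_fraction * g))
    for j in range(k):
        de_genes = rng.choice(g, size=n_de, replace=False)
        folds = np.where(rng.random(n_de) < 0.5, cfg.de_strength, 1.0 / cfg.de_strength)
        profiles[de_genes, j] *= folds

    # balanced cluster assignment, shuffled; every cluster is non-empty
    labels = rng.permutation(np.arange(n) % k)
    size_factors = rng.lognormal(0.0, cfg.libsize_sdlog, size=n)
    mu = profiles[:, labels] * size_factors[None, :]

    # gamma-Poisson mixture = negative binomial with size theta
    lam = rng.gamma(cfg.dispersion, mu / cfg.dispersion)
    truth = rng.poisson(lam).astype(float)

    n_silent = int(round(cfg.silent_gene_fraction * g))
    silent = rng.choice(g, size=n_silent, replace=False)
    truth[silent] = 0.0

    positive = truth > 0
    if cfg.dropout_expression_dependent:
        p_drop = np.exp(-truth / cfg.mean_expression)
        mean_p = p_drop[positive].mean() if positive.any() else 1.0
        p_drop = np.clip(p_drop * (cfg.dropout_rate / mean_p), 0.0, 1.0)
        dropped = positive & (rng.random((g, n)) < p_drop)
    else:
        dropped = positive & (rng.random((g, n)) < cfg.dropout_rate)
    observed = np.where(dropped, 0.0, truth)

    gene_ids = [f"gene_{i}" for i in range(g)]
    cell_ids = [f"cell_{j}" for j in range(n)]
    return SimulatedDataset(
        truth=ExpressionMatrix(truth, gene_ids, cell_ids, stage=Stage.RAW_COUNTS),
        observed=ExpressionMatrix(observed, list(gene_ids), list(cell_ids), stage=Stage.RAW_COUNTS),
        labels=ClusterLabels(labels),
        dropout_positions=np.argwhere(dropped),
        silent_genes=np.sort(silent),
    )


def masked_rmse(imputed, truth, positions) -> float:
    """Root-mean-square error restricted to the given (gene, cell) positions.

    ``imputed`` and ``truth`` may be :class:`ExpressionMatrix` or arrays;
    ``positions`` may be an (n, 2) index array, an iterable of coordinate
    pairs, or a boolean mask.
    """
    a = imputed.values if isinstance(imputed, ExpressionMatrix) else np.asarray(imputed, float)
    b = truth.values if isinstance(truth, ExpressionMatrix) else np.asarray(truth, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    pos = np.asarray(list(positions) if isinstance(positions, set) else positions)
    if pos.dtype == bool:
        if pos.shape != a.shape:
            raise ValueError("boolean position mask must match matrix shape")
        diff = a[pos] - b[pos]
    else:
        if pos.size == 0:
            raise ValueError("positions must be non-empty")
        pos = pos.reshape(-1, 2)
        diff = a[pos[:, 0], pos[:, 1]] - b[pos[:, 0], pos[:, 1]]
    if diff.size == 0:
        raise ValueError("positions must be non-empty")
    return float(np.sqrt(np.mean(diff**2)))
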