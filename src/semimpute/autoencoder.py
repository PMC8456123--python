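"""Semi-supervised masked autoencoder for dropout imputation.

The model is a three-layer perceptron (input, hidden, output) acting on each
cell's gene-expression vector r:

    reconstruction   y = D σ(E r + b_E) + b_D        (σ = sigmoid)
    imputed output   x̃ = relu(y)

trained by full-batch RMSProp gradient descent on the masked cost

    L = Σ_{R>0} (R − Y)²  +  δ · Σ_{R=0, F>0} (F − Y)²  +  (λ/2)(‖E‖²_F + ‖D‖²_F)

where R is the observed (log-transformed) matrix, Y the reconstruction, and
F the imputation weight label from a reference imputer.  The first term fits
the observed non-zero entries; the second — the semi-supervised part — pulls
the reconstruction of zero entries toward the label's fill values, on the
view that a zero with a large label value is likely a dropout rather than a
true zero.  Rectification is applied only at impute time, not inside the
training loss.

Gradients are computed by explicit backpropagation (no autograd); their
correctness is pinned against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import ExpressionMatrix, Stage
from .weight_label import WeightLabelMatrix

__all__ = [
    "TrainConfig",
    "AutoencoderParams",
    "TrainingTrace",
    "AutoencoderImputer",
    "init_params",
    "reconstruct",
    "cost",
    "cost_gradient",
    "train",
    "impute",
    "save_checkpoint",
    "load_checkpoint",
]

RMSPROP_DECAY = 0.9
RMSPROP_EPS = 1e-8


@dataclass
class TrainConfig:
    """Hyper-parameters of the model and its training loop.

    Attributes
    ----------
    lambda_reg
        λ — L2 regularization coefficient on the encoder/decoder weights
        (biases are not regularized).
    delta_weight
        δ — weight of the imputation-label term in the cost.
    hidden_dim
        Latent-space dimension; ``None`` means ``min(512, n_genes)``.
    learning_rate
        RMSProp step size.  RMSProp normalizes gradients per parameter, so
        this directly bounds per-iteration parameter movement.
    threshold
        Convergence rule: stop when the change of the cost between successive
        iterations drops below this value (absolute by default).
    max_iters
        Iteration cap if the threshold is never reached.
    seed
        Seed of the random-normal weight initialization.
    init_std
        Standard deviation of the initial weights.
    use_bias
        Include encoder/decoder biases; ``False`` recovers the pure linear
        maps ``D σ(E r)``.
    weight_term_on
        Entries the label term sums over: ``"zeros"`` (default; zero entries
        with a positive label value) or ``"observed"`` (the literal masked
        reading, which makes the term proportional to the fidelity term since
        F equals R on observed entries).
    relative_threshold
        Apply the convergence rule to the relative rather than absolute
        change of the cost.
    """

    lambda_reg: float = 1.0
    delta_weight: float = 1.0
    hidden_dim: int | None = None
    learning_rate: float = 1e-3
    threshold: float = 1e-4
    max_iters: int = 10_000
    seed: int = 0
    init_std: float = 0.01
    use_bias: bool = True
    weight_term_on: Literal["zeros", "observed"] = "zeros"
    relative_threshold: bool = False

    def __post_init__(self) -> None:
        if self.lambda_reg < 0 or self.delta_weight < 0:
            raise ValueError("lambda_reg and delta_weight must be >= 0")
        for name in ("learning_rate", "threshold", "max_iters", "init_std"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hidden_dim is not None and self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.weight_term_on not in ("zeros", "observed"):
            raise ValueError("weight_term_on must be 'zeros' or 'observed'")

    def resolve_hidden_dim(self, n_genes: int) -> int:
        return self.hidden_dim if self.hidden_dim is not None else min(512, n_genes)


@dataclass
class AutoencoderParams:
    """Encoder/decoder weights: E (hidden × genes), D (genes × hidden), biases."""

    E: np.ndarray
    D: np.ndarray
    b_E: np.ndarray
    b_D: np.ndarray

    def __post_init__(self) -> None:
        h, g = self.E.shape
        if self.D.shape != (g, h) or self.b_E.shape != (h,) or self.b_D.shape != (g,):
            raise ValueError(
                f"inconsistent parameter shapes: E{self.E.shape} D{self.D.shape} "
                f"b_E{self.b_E.shape} b_D{self.b_D.shape}"
            )
        for a in (self.E, self.D, self.b_E, self.b_D):
            if not np.isfinite(a).all():
                raise ValueError("non-finite parameter entries")

    def copy(self) -> "AutoencoderParams":
        return AutoencoderParams(self.E.copy(), self.D.copy(), self.b_E.copy(), self.b_D.copy())


@dataclass
class TrainingTrace:
    """Loss per iteration plus the stopping outcome.

    ``losses[t]`` is the cost after the (t+1)-th parameter update;
    ``initial_loss`` is the cost at the initial parameters, so the first
    convergence comparison has a predecessor even after one iteration.
    """

    losses: list[float]
    converged: bool
    n_iters: int
    initial_loss: float = field(default=np.nan)


def _as_values(m) -> np.ndarray:
    if isinstance(m, (ExpressionMatrix, WeightLabelMatrix)):
        return m.values
    return np.asarray(m, dtype=float)


def init_params(n_genes: int, cfg: TrainConfig) -> AutoencoderParams:
    """Random-normal initialization of E and D; biases start at zero."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    h = cfg.resolve_hidden_dim(n_genes)
    rng = np.random.default_rng(cfg.seed)
    return AutoencoderParams(
        E=rng.normal(0.0, cfg.init_std, size=(h, n_genes)),
        D=rng.normal(0.0, cfg.init_std, size=(n_genes, h)),
        b_E=np.zeros(h),
        b_D=np.zeros(n_genes),
    )


def _forward(R: np.ndarray, p: AutoencoderParams) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and unrectified reconstruction, cells as columns."""
    H = expit(p.E @ R + p.b_E[:, None])
    return H, p.D @ H + p.b_D[:, None]


def reconstruct(R, p: AutoencoderParams) -> np.ndarray:
    """Unrectified reconstruction D·σ(E·r + b_E) + b_D per cell column.

    This is the quantity the training loss sees; rectification happens only
    in :func:`impute`.
    """
    values = _as_values(R)
    if values.shape[0] != p.E.shape[1]:
        raise ValueError(
            f"matrix has {values.shape[0]} genes but encoder expects {p.E.shape[1]}"
        )
    return _forward(values, p)[1]


def _masks(R: np.ndarray, F: np.ndarray, weight_term_on: str) -> tuple[np.ndarray, np.ndarray]:
    observed = R > 0
    if weight_term_on == "zeros":
        label_mask = (~observed) & (F > 0)
    else:  # literal masked reading: both terms on observed entries
        label_mask = observed
    return observed, label_mask


def cost(R, F, p: AutoencoderParams, cfg: TrainConfig) -> float:
    """Masked semi-supervised cost L at parameters ``p``."""
    Rv, Fv = _as_values(R), _as_values(F)
    if Rv.shape != Fv.shape:
        raise ValueError(f"R shape {Rv.shape} and F shape {Fv.shape} differ")
    _, Y = _forward(Rv, p)
    observed, label_mask = _masks(Rv, Fv, cfg.weight_term_on)
    fidelity = float(((Rv - Y) ** 2)[observed].sum())
    label = float(((Fv - Y) ** 2)[label_mask].sum())
    reg = 0.5 * cfg.lambda_reg * (float((p.E**2).sum()) + float((p.D**2).sum()))
    return fidelity + cfg.delta_weight * label + reg


def cost_gradient(R, F, p: AutoencoderParams, cfg: TrainConfig) -> tuple[float, AutoencoderParams]:
    """Cost and its analytic gradient via backpropagation.

    Returns the gradient as an :class:`AutoencoderParams` of the same shapes.
    """
    Rv, Fv = _as_values(R), _as_values(F)
    if Rv.shape != Fv.shape:
        raise ValueError(f"R shape {Rv.shape} and F shape {Fv.shape} differ")
    H, Y = _forward(Rv, p)
    observed, label_mask = _masks(Rv, Fv, cfg.weight_term_on)
    fidelity = float(((Rv - Y) ** 2)[observed].sum())
    label = float(((Fv - Y) ** 2)[label_mask].sum())
    reg = 0.5 * cfg.lambda_reg * (float((p.E**2).sum()) + float((p.D**2).sum()))
    loss = fidelity + cfg.delta_weight * label + reg

    G = 2.0 * np.where(observed, Y - Rv, 0.0)
    G += 2.0 * cfg.delta_weight * np.where(label_mask, Y - Fv, 0.0)
    dD = G @ H.T + cfg.lambda_reg * p.D
    db_D = G.sum(axis=1) if cfg.use_bias else np.zeros_like(p.b_D)
    dH = p.D.T @ G
    dZ = dH * H * (1.0 - H)
    dE = dZ @ Rv.T + cfg.lambda_reg * p.E
    db_E = dZ.sum(axis=1) if cfg.use_bias else np.zeros_like(p.b_E)
    return loss, AutoencoderParams(dE, dD, db_E, db_D)


def train(R, F, cfg: TrainConfig | None = None) -> tuple[AutoencoderParams, TrainingTrace]:
    """Full-batch RMSProp descent on the masked cost.

    Stops when the change of the cost between successive iterations falls
    below ``cfg.threshold`` (convergence) or at ``cfg.max_iters``.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    Rv = _as_values(R)
    if isinstance(R, ExpressionMatrix) and R.stage is not Stage.LOG_TRANSFORMED:
        raise ValueError(f"train expects log-transformed input, got {R.stage.value}")
    p = init_params(Rv.shape[0], cfg)
    initial_loss = cost(Rv, F, p, cfg)

    v = {k: np.zeros_like(getattr(p, k)) for k in ("E", "D", "b_E", "b_D")}
    losses: list[float] = []
    prev = initial_loss
    converged = False
    for it in range(cfg.max_iters):
        loss, g = cost_gradient(Rv, F, p, cfg)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at iteration {it}")
        for k in ("E", "D", "b_E", "b_D"):
            grad = getattr(g, k)
            v[k] = RMSPROP_DECAY * v[k] + (1.0 - RMSPROP_DECAY) * grad**2
            getattr(p, k)[...] -= cfg.learning_rate * grad / (np.sqrt(v[k]) + RMSPROP_EPS)
        loss = cost(Rv, F, p, cfg)  # post-update cost, recorded in the trace
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at iteration {it}")
        losses.append(loss)
        change = abs(loss - prev)
        if cfg.relative_threshold:
            change /= max(abs(prev), np.finfo(float).tiny)
        if change < cfg.threshold:
            converged = True
            break
        prev = loss
    return p, TrainingTrace(losses, converged, len(losses), initial_loss)


def impute(
    R,
    p: AutoencoderParams,
    mode: Literal["fill_zeros_only", "full_reconstruction"] = "fill_zeros_only",
):
    """Rectified imputed matrix x̃ = relu(D σ(E r + b_E) + b_D).

    With ``fill_zeros_only`` (default) observed non-zero entries are kept
    verbatim and only zeros are replaced, so genuinely expressed values —
    and, at silent genes, observed biology — are never modified; with
    ``full_reconstruction`` every entry is the rectified reconstruction.
    Output is non-negative everywhere.
    """
    if mode not in ("fill_zeros_only", "full_reconstruction"):
        raise ValueError(f"unknown impute mode {mode!r}")
    values = _as_values(R)
    X_tilde = np.maximum(reconstruct(values, p), 0.0)
    if mode == "fill_zeros_only":
        X_tilde = np.where(values > 0, values, X_tilde)
    if isinstance(R, ExpressionMatrix):
        return R.with_values(X_tilde)
    return X_tilde


class AutoencoderImputer(BaseEstimator, TransformerMixin):
    """Sklearn-style estimator wrapping the semi-supervised autoencoder.

    Arrays follow the sklearn sample convention (cells × genes); internally
    each cell is one sample vector of gene values.  ``fit`` trains the
    encoder/decoder on the masked cost; ``transform`` returns the imputed
    matrix.  Passing a weight label ``F`` to ``fit`` (same shape as X, e.g.
    from :class:`~semimpute.weight_label.ConsensusImputer`) enables the
    semi-supervised label term; without one the model is a plain masked
    autoencoder (δ effectively 0).

    Parameters mirror :class:`TrainConfig`; fitted attributes are ``E_``,
    ``D_``, ``b_E_``, ``b_D_``, ``loss_trace_``, ``initial_loss_``,
    ``converged_`` and ``n_iter_``.
    """

    def __init__(
        self,
        hidden_dim: int | None = None,
        lambda_reg: float = 1.0,
        delta_weight: float = 1.0,
        learning_rate: float = 1e-3,
        threshold: float = 1e-4,
        max_iters: int = 10_000,
        init_std: float = 0.01,
        use_bias: bool = True,
        weight_term_on: str = "zeros",
        relative_threshold: bool = False,
        mode: str = "fill_zeros_only",
        random_state: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.lambda_reg = lambda_reg
        self.delta_weight = delta_weight
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.max_iters = max_iters
        self.init_std = init_std
        self.use_bias = use_bias
        self.weight_term_on = weight_term_on
        self.relative_threshold = relative_threshold
        self.mode = mode
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            lambda_reg=self.lambda_reg,
            delta_weight=self.delta_weight if self.delta_weight is not None else 0.0,
            hidden_dim=self.hidden_dim,
            learning_rate=self.learning_rate,
            threshold=self.threshold,
            max_iters=self.max_iters,
            seed=self.random_state,
            init_std=self.init_std,
            use_bias=self.use_bias,
            weight_term_on=self.weight_term_on,
            relative_threshold=self.relative_threshold,
        )

    def fit(self, X, y=None, F=None):
        X = check_array(X)
        if (X < 0).any():
            raise ValueError("expression values must be non-negative")
        cfg = self._config()
        if F is None:
            F = X  # label term then vanishes on zeros: pure masked autoencoder
            if cfg.weight_term_on == "zeros":
                cfg.delta_weight = 0.0
        else:
            F = check_array(F)
            if F.shape != X.shape:
                raise ValueError(f"F shape {F.shape} does not match X shape {X.shape}")
        params, trace = train(X.T, np.asarray(F).T, cfg)
        self.E_, self.D_ = params.E, params.D
        self.b_E_, self.b_D_ = params.b_E, params.b_D
        self.n_features_in_ = X.shape[1]
        self.loss_trace_ = np.asarray(trace.losses)
        self.initial_loss_ = trace.initial_loss
        self.converged_ = trace.converged
        self.n_iter_ = trace.n_iters
        return self

    @property
    def params_(self) -> AutoencoderParams:
        check_is_fitted(self, "E_")
        return AutoencoderParams(self.E_, self.D_, self.b_E_, self.b_D_)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "E_")
        X = check_array(X)
        return impute(X.T, self.params_, mode=self.mode).T


def save_checkpoint(
    path: str | Path,
    params: AutoencoderParams,
    cfg: TrainConfig,
    gene_ids: list[str],
    cell_ids: list[str],
) -> None:
    """Single-archive checkpoint: weights, biases, config, and id lists."""
    meta = {"config": asdict(cfg), "gene_ids": gene_ids, "cell_ids": cell_ids}
    np.savez(
        path,
        E=params.E,
        D=params.D,
        b_E=params.b_E,
        b_D=params.b_D,
        meta=np.array(json.dumps(meta)),
    )


def load_checkpoint(path: str | Path) -> tuple[AutoencoderParams, TrainConfig, list[str], list[str]]:
    with np.load(path, allow_pickle=False) as z:
        params = AutoencoderParams(z["E"], z["D"], z["b_E"], z["b_D"])
        meta = json.loads(str(z["meta"]))
    return params, TrainConfig(**meta["config"]), meta["gene_ids"], meta["cell_ids"]
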