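"""End-to-end glue: preprocess → weight label → train → impute, plus the
simulated dropout-recovery benchmark used for evaluation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .autoencoder import TrainConfig, TrainingTrace, impute, train
from .evaluation import evaluate_imputation
from .io import ExpressionMatrix, Stage
from .preprocess import PreprocessConfig, log_transform, normalize_library_size, preprocess
from .simulate import SimulatedDataset, SimulationConfig, masked_rmse, simulate
from .weight_label import ConsensusConfig, WeightLabelMatrix, consensus_impute, load_label

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "BENCHMARK_TRAIN_CONFIG",
    "dropout_benchmark",
]


@dataclass
class PipelineResult:
    imputed: ExpressionMatrix
    preprocessed: ExpressionMatrix
    label: WeightLabelMatrix
    trace: TrainingTrace
    timings: dict[str, float]

    @property
    def final_loss(self) -> float:
        return self.trace.losses[-1] if self.trace.losses else self.trace.initial_loss


def run_pipeline(
    m: ExpressionMatrix,
    pre_cfg: PreprocessConfig | None = None,
    train_cfg: TrainConfig | None = None,
    consensus_cfg: ConsensusConfig | None = None,
    label_file: str | Path | None = None,
    mode: str = "fill_zeros_only",
) -> PipelineResult:
    """Run the full imputation pipeline on a raw count matrix.

    The weight label comes from ``label_file`` when given, otherwise from the
    built-in consensus imputer.
    """
    train_cfg = train_cfg or TrainConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if m.stage is Stage.RAW_COUNTS:
        pp = preprocess(m, pre_cfg)
    elif m.stage is Stage.LOG_TRANSFORMED:
        pp = m  # already preprocessed upstream
    else:
        raise ValueError("input must be raw counts or already log-transformed")
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if label_file is not None:
        label = load_label(label_file, pp)
    else:
        if consensus_cfg is None:
            label = consensus_impute(pp)
        else:
            label = consensus_impute(pp, consensus_cfg)
    timings["weight_label"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    params, trace = train(pp, label, train_cfg)
    timings["train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    imputed = impute(pp, params, mode=mode)
    timings["impute"] = time.perf_counter() - t0
    return PipelineResult(imputed, pp, label, trace, timings)


# Benchmark-scale training configuration: a 64-unit hidden layer and a few
# hundred RMSProp iterations at step 5e-3 are enough for the few-thousand-gene
# simulated matrices the benchmark uses.
BENCHMARK_TRAIN_CONFIG = TrainConfig(
    hidden_dim=64,
    learning_rate=5e-3,
    max_iters=400,
    lambda_reg=1.0,
    delta_weight=1.0,
)


def _log_scale_pair(sim: SimulatedDataset, scale_factor: float = 10_000.0):
    """Observed and truth matrices on a shared log1p scale.

    Each cell of both matrices is scaled by the factor that brings the
    *observed* cell total to ``scale_factor``, so observed entries that were
    not dropped match the truth exactly and differences at dropout positions
    reflect the dropout alone.
    """
    cfg = PreprocessConfig(min_cells_expressed=0, min_genes_expressed=0,
                           scale_factor=scale_factor)
    obs_log = log_transform(normalize_library_size(sim.observed, cfg), cfg)
    scale = scale_factor / sim.observed.values.sum(axis=0)
    truth_log = sim.truth.with_values(
        np.log1p(sim.truth.values * scale[None, :]), stage=Stage.LOG_TRANSFORMED
    )
    return obs_log, truth_log


def dropout_benchmark(
    seed: int,
    sim_cfg: SimulationConfig | None = None,
    train_cfg: TrainConfig | None = None,
    with_unsupervised: bool = True,
    with_clustering: bool = True,
) -> dict[str, float]:
    """Score dropout recovery on one simulated dataset.

    Simulates clustered counts with known dropout positions, puts observed
    and truth on a common log scale, builds the consensus weight label,
    trains the semi-supervised autoencoder, and reports masked RMSE at the
    dropout positions for the trained model (``rmse_pipeline``), the
    consensus label alone (``rmse_consensus``) and the do-nothing all-zeros
    baseline (``rmse_zeros``); optionally also the pure unsupervised
    autoencoder (δ=0, ``rmse_unsupervised``), the clustering agreement before
    and after imputation (``ari_raw``/``ari_imputed``) and the silent-gene
    ratio (mean imputed value on genes all-zero by construction over mean
    imputed value at dropout positions of expressed genes).
    """
    sim_cfg = replace(sim_cfg or SimulationConfig(), seed=seed)
    train_cfg = replace(train_cfg or BENCHMARK_TRAIN_CONFIG, seed=seed)
    sim = simulate(sim_cfg)
    obs_log, truth_log = _log_scale_pair(sim)
    pos = sim.dropout_positions

    label = consensus_impute(obs_log, ConsensusConfig(seed=seed))
    params, trace = train(obs_log, label, train_cfg)
    imputed = impute(obs_log, params, mode="fill_zeros_only")

    out: dict[str, float] = {
        "rmse_pipeline": masked_rmse(imputed, truth_log, pos),
        "rmse_consensus": masked_rmse(label.values, truth_log.values, pos),
        "rmse_zeros": masked_rmse(obs_log, truth_log, pos),
        "final_loss": trace.losses[-1],
        "n_iters": float(trace.n_iters),
        "n_dropouts": float(len(pos)),
    }

    drop_vals = imputed.values[pos[:, 0], pos[:, 1]]
    silent_vals = imputed.values[sim.silent_genes]
    out["silent_gene_mean"] = float(silent_vals.mean())
    out["dropout_fill_mean"] = float(drop_vals.mean())
    out["silent_ratio"] = out["silent_gene_mean"] / out["dropout_fill_mean"]

    if with_unsupervised:
        cfg0 = replace(train_cfg, delta_weight=0.0)
        params0, _ = train(obs_log, label, cfg0)
        imputed0 = impute(obs_log, params0, mode="fill_zeros_only")
        out["rmse_unsupervised"] = masked_rmse(imputed0, truth_log, pos)

    if with_clustering:
        k = sim.labels.k
        out["ari_raw"] = evaluate_imputation(obs_log, sim.labels, k=k, seed=seed).ari
        out["ari_imputed"] = evaluate_imputation(imputed, sim.labels, k=k, seed=seed).ari
    return out
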