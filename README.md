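# semimpute

Semi-supervised autoencoder imputation of dropout zeros in single-cell
RNA-seq expression matrices.

scRNA-seq count matrices are riddled with zeros, and many of them are
*dropouts* — transcripts that were expressed but not captured — rather than
true biological silence. Left in place, dropouts distort visualization,
clustering and differential expression. `semimpute` fills them with a
single-hidden-layer autoencoder whose training cost is *semi-supervised*: in
addition to reconstructing the observed (non-zero) entries, it is guided at
the zero entries by an **imputation weight label** `F` — a fully imputed
version of the matrix produced by a simpler reference imputer (the built-in
consensus-clustering imputer, or any external method loaded from a file).

## The model

Let `X` be the gene × cell matrix of true expression, `M` the binary
observation mask, and `R = M ∘ X` the observed matrix (`∘` is the Hadamard
product). Each cell's vector `r` is passed through an encoder and decoder,

    y = D σ(E r + b_E) + b_D            (σ = sigmoid)

and the parameters minimize the masked cost

    L = Σ_{R>0} (R − Y)²  +  δ Σ_{R=0, F>0} (F − Y)²  +  (λ/2)(‖E‖²_F + ‖D‖²_F)

by full-batch RMSProp gradient descent (explicit backpropagation, random
normal initialization, stopping when the change of `L` between successive
iterations falls below a threshold). The first term fits the observed
entries; the second pulls the reconstruction of zero entries toward the
label's fill values — the idea being that a zero with a large label value is
likely a dropout, while one the reference imputer also leaves near zero is
likely a true zero. The imputed matrix is the rectified reconstruction

    X̃ = relu(D σ(E R + b_E) + b_D)

which guarantees non-negative output; by default only zeros are replaced
(`fill_zeros_only`), so observed values — including the observed silence of
unexpressed genes — are never modified.

The package also provides the surrounding pipeline: preprocessing
(gene/cell filtering, library-size normalization, variance-based gene
selection, zero-preserving log transform), the consensus-clustering weight
label (repeated k-means over a range of k; each zero is estimated by its
gene's mean over the cells sharing its cluster, averaged across runs), a
clustered-count simulator with known dropout positions, and the downstream
evaluation protocol (t-SNE + k-means, scored by Rand, adjusted Rand,
Fowlkes–Mallows and Jaccard indexes computed from pair counts).

## Worked example

```python
import numpy as np
from semimpute import (SimulationConfig, simulate, ConsensusConfig, consensus_impute,
                       TrainConfig, train, impute, evaluate_imputation, masked_rmse)
from semimpute.pipeline import _log_scale_pair

sim = simulate(SimulationConfig(n_genes=500, n_cells=120, n_clusters=3,
                                dropout_rate=0.3, seed=0))
obs_log, truth_log = _log_scale_pair(sim)      # shared log1p scale
label = consensus_impute(obs_log, ConsensusConfig(seed=0))
cfg = TrainConfig(hidden_dim=32, learning_rate=5e-3, max_iters=300, seed=0)
params, trace = train(obs_log, label, cfg)
imputed = impute(obs_log, params)              # fill_zeros_only

pos = sim.dropout_positions
print(f"masked RMSE, zeros       : {masked_rmse(obs_log, truth_log, pos):.3f}")
print(f"masked RMSE, label alone : {masked_rmse(label.values, truth_log.values, pos):.3f}")
print(f"masked RMSE, imputed     : {masked_rmse(imputed, truth_log, pos):.3f}")
rep = evaluate_imputation(imputed, sim.labels, seed=0)
print(f"clustering after imputing: rand={rep.rand:.3f} ARI={rep.ari:.3f} "
      f"FM={rep.fm:.3f} Jaccard={rep.jaccard:.3f}")
```

prints

```
masked RMSE, zeros       : 3.413
masked RMSE, label alone : 1.859
masked RMSE, imputed     : 1.238
clustering after imputing: rand=0.989 ARI=0.975 FM=0.983 Jaccard=0.967
```

Reading the numbers: leaving the 11,780 dropout zeros untouched costs RMSE
3.41 (log scale) against the pre-dropout truth; the consensus label alone
recovers them to 1.86; the trained autoencoder improves that to 1.24, and
t-SNE + k-means on the imputed matrix recovers the three simulated cell
populations almost perfectly (ARI 0.975).

The same pipeline is available from the shell:

```bash
semimpute simulate --output sim --n-genes 500 --n-cells 120 --seed 0
semimpute impute --input sim.observed.csv --output imputed.csv \
    --label-from consensus --hidden-dim 32 --max-iters 300 --seed 0
semimpute evaluate --input imputed.csv --labels sim.labels.tsv --seed 0
```

Every run writes a JSON manifest (resolved config, seed, per-stage timings,
final loss) next to its output, and identical seeds reproduce outputs
bitwise. Estimator-style interfaces (`AutoencoderImputer`,
`ConsensusImputer` with `fit`/`transform` on cells × genes arrays) are
provided for use inside scikit-learn pipelines.

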