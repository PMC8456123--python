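# Methods

## Model

`semimpute` treats an observed gene × cell expression matrix as `R = M ∘ X`,
where `X` is the complete expression matrix to be estimated and `M` is the
binary mask of non-zero entries. A zero in `R` is ambiguous: it may be a
true biological zero or a dropout. The imputer is a three-layer perceptron
(input, hidden, output) applied per cell,

    h = σ(E r + b_E),   y = D h + b_D,

with a sigmoid hidden layer and linear output during training. Training
minimizes

    L(E, D, b) = Σ_{(i,j): R_ij > 0} (R_ij − Y_ij)²
               + δ · Σ_{(i,j): R_ij = 0, F_ij > 0} (F_ij − Y_ij)²
               + (λ/2) (‖E‖²_F + ‖D‖²_F)

where `F` is the imputation weight label: a fully imputed version of `R`
from a reference imputer, equal to `R` at every non-zero entry (the
fill-only contract, enforced on load). The label term is what makes the
model semi-supervised — at zeros, where reconstruction is otherwise
unconstrained, it supplies a soft target. After training, the imputed
matrix is `X̃ = relu(Y)`; rectification is applied only at output, never
inside the loss. Two output modes exist: `fill_zeros_only` (default)
replaces only zeros and keeps observed entries verbatim; `full_reconstruction`
returns `relu(Y)` everywhere.

Two deliberate asymmetries are worth flagging because they are easy to get
wrong: (1) the training loss uses the *unrectified* reconstruction while the
output is rectified; (2) the fidelity and label terms partition the matrix
by the mask — the label term acts only where `R = 0` and `F > 0`. An
alternative literal reading, in which both terms range over the non-zero
entries (making the label term proportional to the fidelity term, since
`F = R` there), is available via `weight_term_on="observed"`.

## Training

Full-batch gradient descent with explicit backpropagation and RMSProp
updates (decay 0.9, epsilon 1e-8). Weights are initialized i.i.d. normal
with standard deviation `init_std`; biases start at zero and are excluded
from the regularizer (`use_bias=False` recovers the pure linear maps).
Training stops when `|L_t − L_{t−1}|` falls below `threshold` (a relative
variant is available) or at `max_iters`. The trace records the cost after
every update plus the initial cost, so the first convergence comparison has
a predecessor. Analytic gradients are pinned against central finite
differences in the test suite (relative error < 1e-4).

Defaults: `hidden_dim = min(512, n_genes)`, `learning_rate = 1e-3`,
`λ = 1`, `δ = 1`, `threshold = 1e-4` (absolute), `max_iters = 10000`,
`init_std = 0.01`. The learning rate deserves a note: RMSProp normalizes
each gradient coordinate to roughly unit magnitude, so the step size bounds
total parameter movement by `learning_rate × max_iters`; 1e-3 × 10,000
allows the decoder biases to reach the scale of mean log-expression on
library-normalized log1p data, which a much smaller rate cannot.

## Preprocessing

Fixed order: gene filter (expressed in ≥ `min_cells_expressed` cells, default
3) → cell filter (≥ `min_genes_expressed` expressed genes, default 200) →
library-size normalization (each cell scaled to `scale_factor = 10,000`
total) → optional selection of the `n_top_genes` genes with highest variance
of log expression (default: keep all; variance of log is a simple,
replaceable dispersion proxy; ties keep the earlier gene) → log transform
`log(x + offset) − log(offset)` (default offset 1, i.e. log1p). The shifted
log maps zeros to exactly zero for any offset, so no stage ever converts a
zero to a non-zero and the observation mask derived from raw counts remains
valid after preprocessing. Thresholds are field-standard defaults; none are
stated by the imputation model itself.

## Consensus weight label

The built-in label source follows the consensus-clustering imputation
principle: cluster cells repeatedly and estimate each zero from similar
cells. For every `k` in `k_values` (default 10–15, clipped below the number
of cells) and each of `n_runs_per_k` replicates (default 2), cells are
clustered by k-means on their log-expression vectors with a seed derived
deterministically from the base seed. A zero entry's run estimate is the
mean of its gene over the cells in its cluster, *including* the zeros of
cluster members — so a gene silent throughout a cluster gets estimate 0 and
stays untouched — and the final fill value averages the run estimates.
Non-zero entries pass through unchanged. The averaging over many `k` above
the true cluster number effectively averages over sub-clusters of similar
cells. Any external imputer's output can be used instead via
`load_label` / `--label-file`; it is aligned by gene/cell id and forced to
the fill-only contract.

Including cluster members' zeros in the mean makes the label systematically
*underestimate* expression at dropout positions by roughly the zero fraction
of the cluster. This is inherent to the averaging rule, and it matters for
the semi-supervision trade-off discussed under Limitations.

## Evaluation protocol

Downstream quality is measured by clustering: t-SNE to 2 components
(perplexity `min(30, (n_cells − 1)/3)`, PCA initialization, seeded) followed
by k-means (10 restarts, seeded), with `k` taken from the ground-truth
labels. Agreement with the true partition is computed from first principles
via the pair contingency (a, b, c, d) over all unordered cell pairs: Rand
`(a+d)/total`, Jaccard `a/(a+b+c)`, Fowlkes–Mallows `a/√((a+b)(a+c))`
(both 0 on a degenerate denominator), and the adjusted Rand index with the
permutation-model chance correction `(a − E)/(max − E)`,
`E = (a+b)(a+c)/total`, `max = (2a+b+c)/2`, defined as 1 when `max = E`.
The implementation is verified against an exhaustive pair-loop oracle on
all partitions of up to 6 items and against scikit-learn's ARI.

## Synthetic data

The simulator generates what the method's evaluation needs and nothing
more: `n_clusters` populations sharing lognormal base gene means
(median `mean_expression = 2`, sdlog 1), a `de_fraction = 0.2` subset of
genes per cluster scaled by fold `de_strength = 3` up or down, lognormal
cell size factors (sdlog 0.3), negative-binomial counts (gamma–Poisson,
dispersion θ = 2), a `silent_gene_fraction = 0.05` of genes forced all-zero,
and uniform random dropout at `dropout_rate` applied to positive entries
(an expression-dependent mode, off by default, makes low counts drop out
more often). Truth, observed matrix, labels and exact dropout coordinates
are all returned, so recovery is scored by masked RMSE at the dropout
positions, with truth and observed placed on a shared log scale (both scaled
by the factors that bring the *observed* cell totals to 10,000, so
non-dropped entries match exactly).

What it does not emulate: batch effects, continuous trajectories or doublet
cells, gene–gene correlation beyond the cluster structure, and realistic
sequencing-depth/expression dependence of dropout under the default uniform
mode. Tests passing on this generator therefore demonstrate correct
mechanics and recovery under clean cluster structure, not performance on
arbitrary real data.

## Benchmark configuration

The dropout-recovery benchmark (`semimpute.pipeline.dropout_benchmark`, also
driven by `scripts/acceptance.py`) runs at 3 clusters, 2000 genes, 300
cells, 30% dropout, with training scaled for desk-top runs: hidden_dim 64,
learning rate 5e-3, 400 iterations. At this size one replicate (consensus
label, two trainings, two t-SNE evaluations) takes well under a minute on a
single CPU. Under these conditions the trained pipeline recovers dropouts
markedly better than the all-zeros baseline and than its own consensus
label (median masked RMSE ≈ 0.80 vs 1.11 vs 2.19 over ten replicates),
leaves silent genes essentially untouched (mean imputed value on silent
genes < 1% of the mean fill at dropout positions), and clusters at least as
well as the raw data.

## Known limitations

* **Label guidance can hurt pointwise recovery.** On this simulator the pure
  masked autoencoder (δ = 0) recovers dropouts slightly better (median
  masked RMSE ≈ 0.66) than the semi-supervised model (δ = 1, ≈ 0.80): the
  consensus label's downward bias makes it a worse target than what the
  autoencoder already infers from observed entries, and the label term pulls
  zero-entry reconstructions toward it. The δ-term earns its keep only when
  the label is at least as accurate as the autoencoder's own generalization
  — e.g. with a stronger external imputer as the label source, or on data
  whose structure the autoencoder alone cannot learn. δ is exposed
  precisely so users can tune this trade-off.
* Silent genes are preserved because their decoder rows receive no gradient
  (their entries appear in neither cost term) and so stay at their small
  random initialization; this argument, like the observed-value
  preservation, holds for `fill_zeros_only` but not `full_reconstruction`.
* Full-batch training keeps the procedure deterministic but limits matrix
  size to what fits in memory a few times over; there is no minibatching,
  no multi-hidden-layer variant, and no GPU path.
* k for k-means is taken from the ground-truth labels; no model selection
  for the number of clusters is implemented.
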