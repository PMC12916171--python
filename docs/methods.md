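# Methods

`grnlag` infers directed transcription-factor (TF) → target interactions from a
single-cell expression matrix whose cells are ordered along a pseudotime
trajectory. The premise is that a genuine regulatory interaction manifests as a
time-lagged correlation: the regulator's expression pattern reappears in its
target a roughly constant number of cells later along the trajectory. The
pipeline turns each candidate pair into a two-dimensional "delay portrait",
sharpens it against context-specific backgrounds, and classifies it with a
small recurrent-convolutional network trained on a gold standard of known
edges.

## Preprocessing

Given a normalized genes × cells matrix (cells sorted by pseudotime, or
re-sorted from a supplied per-cell pseudotime table with a stable sort):

1. genes expressed (value > 0) in at most ⌊T/10⌋ of the T cells are removed —
   the boundary gene is removed, i.e. "expressed in ≤ 10 % of cells" is read
   literally;
2. the `top_n` (default 1000, capped at the gene count) most variable genes
   are kept, ties at the cutoff resolved in favour of the earlier gene.
   Variance is computed on the values as loaded; a `log1p` flag ranks on
   log-transformed values instead, since upstream normalizations differ;
3. gold-standard edges are restricted to pairs with both endpoints among the
   surviving genes; self-loops are dropped at load time;
4. positives are all surviving gold edges; an equal number of negatives is
   drawn uniformly, without replacement and seeded, from {(tf, g)} where tf is
   a regulator appearing in the gold standard, g ≠ tf is any surviving gene,
   and (tf, g) is not a gold edge. Restricting candidate regulators to known
   TFs keeps the negative class a "TF–gene pair" in the same sense as the
   positive class;
5. samples are split 3:1:1 (train/validation/test), stratified by class with a
   seeded shuffle; remainders after the floor division go to the training set.

## Neighbor-averaged smoothing

Each gene's vector is replaced by the mean of its k (default 10) most-similar
genes' vectors, similarity being the Pearson correlation across cells
(Spearman, Kendall and a binned mutual-information estimator with ⌈√T⌉
equal-width bins are available; on smooth trajectories they select nearly the
same neighbors). The gene itself is excluded from its own neighbor pool —
including it would make k = 1 a no-op and defeat the smoothing — but an
`include_self` flag restores the alternative reading. Zero-variance genes get
similarity 0 everywhere. For data that really are a shared trend plus
independent noise, averaging k neighbors shrinks the noise variance roughly
k-fold, which is the effect the test suite asserts.

## Time-delay correlation matrix

For a pair (TF i, target j) with window geometry (p, q, m, n, w):

- the k-th TF segment spans cells (k−1)m+1 … (k−1)m+w (1-based inclusive),
- the target segment at delay l spans (k−1)m+(l−1)n+1 … (k−1)m+(l−1)n+w,

and M[k, l] is the Pearson correlation of the two segments, so column l
collects evidence for a lag of (l−1)·n cells. Delays are one-sided (the
target lags the TF); the matrix is therefore *not* symmetric under swapping
the pair, which is what gives the method directionality. Segments with zero
variance contribute correlation 0 rather than NaN — the natural "no signal"
value for the enhancement stage — and entries are clamped to [−1, 1] against
rounding. The implementation standardizes each window to zero mean and unit
norm once and takes dot products; the tests compare it to a per-entry
`scipy.stats.pearsonr` double loop at 1e−10.

The minimal trajectory length that populates all p × q segment pairs is
(p−1)m + (q−1)n + w (`required_cells`). When no explicit geometry is given,
`default_window_config` keeps p = q = 64, m = n = 5 and solves
w = T − (p−1)m − (q−1)n, the widest window that uses the whole trajectory;
if that leaves w < 3 it halves p and q (finally reducing the steps to 1)
until feasible, logging the adjustment. Named presets carry the published
per-dataset widths for the real mHSC/hESC/hHep benchmarks.

## Dual-background enhancement

Each entry ρ at row u, column v of M is standardized against two
context-specific background distributions in the spirit of the context
likelihood of relatedness (CLR) method — no lookup tables or fitted nulls,
just the empirical row and column statistics:

    z_row = max(0, (ρ − μ_u) / σ_u)      u-th row mean / std
    z_col = max(0, (ρ − μ_v) / σ_v)      v-th column mean / std
    Z[u, v] = sqrt(z_row² + z_col²)

Entries below either background are clipped to zero, so Z is nonnegative and
sparser than M; entries that stand out against both backgrounds are
amplified. Standard deviations are population (ddof = 0) by default, with a
`ddof` flag. A zero-variance row or column contributes a zero component —
a constant background carries no discriminative signal. The combination rule
is the Euclidean (root-sum-of-squares) form used by CLR; a
`combine="sum_of_squares"` flag preserves the plain sum of squared z-scores
for comparison. Z is invariant to shifting or positively rescaling M, since
z-scores are affine-free.

## Classifier

The (enhanced) p × q matrix is read as a length-p sequence of q-dimensional
steps — TF windows advance along pseudotime, so rows are the natural
recurrent axis (a `transpose_input` flag flips this). The default
architecture is:

- bidirectional GRU, 128 units per direction, returning the full sequence
  (p × 256 map);
- two valid 3×3 convolutions with 64 and 32 filters, ReLU activations;
- one 2×2 max pool, dropout 0.25;
- dense 512 → ReLU → dense 128 → ReLU → dropout 0.5 → dense 1, sigmoid.

Variant builders cover the ablations: GRU/LSTM/SimpleRNN backbones, a
CNN-only model (the raw matrix is the 2-D map), a recurrent-only model
(no convolutions), and deeper convolution stacks up to four layers.

Because no deep-learning framework is a dependency of this package, the
layers are implemented directly on numpy with explicit backpropagation
(including backpropagation through time for the recurrent cells and an
im2col convolution); every layer's gradient is validated against central
finite differences in the test suite. All randomness — initialization
(Glorot for input weights, orthogonal for recurrent matrices), dropout
masks, batch order — flows through seeded generators, so training is
reproducible bit-for-bit for a fixed seed. Arithmetic is float32 by default
(float64 available via `dtype`).

Training minimizes binary cross-entropy with SGD: learning rate 0.01 decayed
by 0.95 per epoch, momentum 0.9, batch size 32, at most 60 epochs. The
parameters kept are those of the epoch with the best validation AUPR; ties —
routine when the validation set is a dozen pairs and AUPR saturates at 1.0
within a few epochs — are broken by the lower validation cross-entropy, so a
saturated validation set does not freeze near-untrained weights. Early
stopping triggers after 10 epochs without an AUPR improvement. A NaN loss
aborts with advice to lower the learning rate. The kernel/pool sizes,
dropout rates, schedule and epoch budget are this package's defaults, all
overridable in the model config.

## Evaluation and export

Metrics are the standard threshold-free ranking scores for GRN benchmarks:
AUROC (midrank tie handling; equal to the exhaustive concordant-pair
fraction, which the tests verify by brute force), AUPR (step-interpolated
precision–recall integration, i.e. average precision), Precision@k for a
configurable k list, Early Precision (precision among the top-P pairs,
P = number of positives), and the size of the largest top-ranked prefix
whose empirical precision stays ≥ 1 − α (α = 0.05), an FDR-controlled
subnetwork. A confusion table at threshold 0.5 is also reported. These
definitions follow common GRN-benchmarking practice.

The pseudotime-perturbation analysis jitters each cell's pseudotime by
μ·N(0, 1), stably re-sorts the cells, counts how many cells changed rank
(`shift_count`), and reruns featurization, training and evaluation on the
permuted trajectory; μ = 0 reproduces the unperturbed run exactly, and the
mean shift count is nondecreasing in μ.

Network export ranks all scored pairs, keeps the top |gold| edges, and
labels each with its provenance in priority order: `known` (gold edge), then
the label of the first matching supplied reference network, else `novel`.
Ties at the cutoff break by (score, tf, target) so exports are
deterministic.

## Synthetic benchmark

The generator plants the exact structure the method assumes. Each TF gets a
smooth latent trajectory — a sum of three sinusoids with wavelengths at least
`smoothness` cells, amplitudes U(0.5, 1), random phases. Each planted edge
copies the regulator's trajectory into the target, shifted right by a lag
drawn from `lag_range` (constant-padding the first lag cells) and scaled by
`effect`; each target has at most one incoming edge so its lag is
well-defined. Decoy genes carry independent smooth trajectories. Independent
Gaussian noise (sd `noise_sd`) is added to every gene, values are shifted
per-gene to be nonnegative, and pseudotime is 1..T. Signals and noise come
from separate seeded streams, so regenerating with the same seed and a
different noise level isolates the injected noise exactly — the
noise-calibration test uses this.

The default benchmark is 60 genes (10 TFs), 600 cells, 30 planted edges,
lags 5–40 cells, effect 1, noise sd 0.5, smoothness 50, seed 7. Under the
auto-solved geometry this yields 32 × 32 delay matrices with w = 290 and 60
labelled pairs (36/12/12 after the split).

What the generator does *not* emulate: count noise (dropout/zero-inflation),
branching trajectories, indirect or combinatorial regulation, and spurious
correlation structure among unrelated genes beyond what smooth random
signals produce. Passing the planted-edge recovery tests therefore shows the
machinery is implemented correctly and can detect lagged signal at realistic
noise, not that the method attains any particular accuracy on real tissue
data.

A consequence worth stating plainly: at this noise level the raw delay
matrices already separate planted from decoy pairs almost perfectly (segment
correlations over 290-cell windows are barely dented by unit-scale noise),
so on this benchmark the smoothing and enhancement stages have little room
to improve over the sliding-window baseline — their benefit on real data
comes from suppressing correlated structure that the generator deliberately
does not contain. The end-to-end test asserts absolute recovery thresholds
(held-out AUROC ≥ 0.75, AUPR ≥ 0.6 for the combined configuration); with 12
held-out pairs the metrics move in steps of ~0.03–0.08, which is why
orderings *between* configurations are not stable at this scale.

## Problem sizes used by the test suite

Unit and property tests run on purpose-built small instances (24 genes, 240
cells, 16 × 16 windows; classifiers with 8 GRU units) so the whole suite
stays interactive; the end-to-end acceptance checks run the full default
benchmark above with the default 128-unit model. The acceptance script
recomputes the window-geometry identity exactly and instantly.

## Known limitations

- Negative pseudotime lags (target leading the TF) are out of scope; run the
  pair in the opposite orientation instead.
- The auto-solved window geometry ties w to T; very short trajectories fall
  back to coarse 8 × 8 or smaller matrices, where the classifier has little
  texture to work with.
- Training is CPU-bound numpy; it is sized for hundreds-of-pairs gold
  standards, not genome-scale all-versus-all scans.
- The mutual-information similarity uses a fixed equal-width binning; for
  heavily zero-inflated data a rank-based measure is the safer choice.
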