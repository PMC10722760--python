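# Methods

`mdlink` predicts microbe-disease associations from a binary bipartite
network. This note records the model, its assumptions, the tunable
parameters, the synthetic benchmark, and the numerical and design choices
made where the design was genuinely open.

## Problem setting

The input is a binary matrix **Y** with `N_m` microbe rows and `N_d`
disease columns; `Y[i,j] = 1` records a curated association. Known
catalogues of this kind are sparse (a few percent density) and heavily
scale-imbalanced (many more microbes than diseases). Zero entries are
*unlabelled*, not confirmed negatives, which shapes both the negative
sampling and the evaluation protocol below.

## Similarity kernels and fusion

Four kernels are computed per node set and averaged element-wise into the
fused matrices **FuD** (diseases) and **FuM** (microbes):

* **Semantic (DS, diseases)** — from an ontology DAG. Each term `k` in the
  ancestor closure `T(d)` (which includes `d` itself) contributes
  `SC_d(k) = max over children k' of k inside T(d) of FC * SC_d(k')`, with
  `SC_d(d) = 1`; unrolled this is the maximum of `FC^L` over upward paths.
  `DS(i,j)` is the shared-ancestor contribution mass normalised by the sum
  of the two semantic values `SemV = sum of contributions`. The decay
  factor `FC` defaults to 0.5 and must lie in (0, 1). Diseases absent from
  the DAG get 0 off-diagonal and 1 on the diagonal (a conservative neutral
  value). Note that DS is *not* monotone in FC in general: for an
  ancestor-descendant pair where the descendant has extra unshared
  ancestors, raising FC inflates the denominator faster than the shared
  mass; monotonicity does hold for pairs with identical proper-ancestor
  closures, where DS = s/(1+s). The test-suite pins both facts.
* **Functional (FMS, microbes)** — best-match semantic similarity between
  the two microbes' disease sets, averaged over both directions and
  normalised by `p + q`. Microbes with no diseases get 0 off-diagonal; the
  diagonal is fixed at 1 (the defining formula is 0/0 there).
* **GIP (GDS/GMS)** — `exp(-gamma * ||p_i - p_j||^2)` on binary profiles,
  with `gamma = alpha / mean squared profile norm` and `alpha = 1` by
  default. An all-zero profile matrix makes the bandwidth degenerate and is
  reported as an explicit error.
* **Cosine (CDS/CMS)** — with the convention that any comparison involving
  an all-zero profile is 0, including that profile's own diagonal entry
  (avoids 0/0).
* **Sigmoid kernel (SDS/SMS)** — `tanh(p_i . p_j / norm)` where `norm`
  defaults to the size of the *own* node set (`N_d` for diseases, `N_m`
  for microbes). This follows the method's published constants (134 and
  1177 at reference scale) literally, even though the profile length is the
  other set's size; both norms are configurable.

Profile orientation is fixed throughout: microbe profiles are rows of Y
(length `N_d`), disease profiles are columns (length `N_m`). This is the
only orientation consistent with Y's dimensions.

## Low-rank features: bipartite GCN

Both fused matrices are linearly projected to a common width `h1` (256).
Each graph-convolution layer combines a neighbourhood-aggregation term
(`P~ @ H_D @ W1` for microbes and transposed for diseases) with a
local-structure term (`((P~ @ H_D) * H_M) @ W2 + b1`), followed by ReLU,
where `P~ = D1^{-1/2} Y D2^{-1/2}` with degrees + 1 so normalisation never
divides by zero. Two layers are used (`h1=256 -> h1`, then `h1 -> h2=128`)
— deeper stacks over-smooth node representations on graphs this small.
The published second local-structure line gates the disease update with
the *microbe* activations, which is dimensionally impossible; it is
implemented symmetrically with the first line (gate with `H_D`), flagged
as a presumed typo.

Training reconstructs Y through `logistic(LM @ LD^T)` with a balanced
binary cross-entropy: all positive pairs plus an equally sized uniform
negative sample, redrawn each epoch by default (a fixed-negative mode is
available). The published loss writes the negative term as `(1 - log y^)`,
which is unbounded below and not a likelihood; the default objective uses
`log(1 - y^)` and the literal form is kept behind `loss="literal"` for
comparison. Predictions are clamped to `[1e-7, 1 - 1e-7]` before logs.
Optimisation is full-batch Adam (1000 epochs, lr 0.001), dropout 0.5
applied between the two graph-conv layers during training only, parameters
Glorot-uniform from a seeded generator. Forward/backward passes are
explicit NumPy; at these scales full-batch NumPy training is fast and
bitwise reproducible, and final embeddings are computed without dropout.

## High-rank features: deep sparse auto-encoder

Each candidate pair `(m_i, d_j)` gets an initial vector
`FuD[j] ++ FuM[i]` (width `N_d + N_m`; 1311 at reference scale, all
entries already in [0, 1] so no rescaling is needed before sigmoid
outputs). A 4-layer sigmoid encoder (reference ladder
1311-1152-576-288-144; other input widths interpolate geometrically down
to the 144-d code) and a mirrored 4-layer sigmoid decoder are trained to
reconstruct the input. The published decoder ends at width "1131", taken
as a transposition typo for 1311.

The loss is `MSE(x, x^) + theta * KL(norm(x) || norm(x^))`, where both
vectors are epsilon-smoothed (1e-7) and normalised to sum 1 row-wise — the
raw KL of the published form is undefined for unnormalised vectors. The
weight `theta` is not recoverable from the method description; the default
is 1.0 and `theta = 0` gives a plain reconstruction loss. Training is
full-batch Adam, 150 epochs, initial lr 0.01, halved when the loss has not
improved for 10 epochs. Gradients are analytic and verified against finite
differences in the test-suite. The bottleneck code is the pair's 144-d
high-rank feature.

## Classifier: cascade forest

Final pair features are `LD[j] ++ LM[i] ++ code` (400-d under defaults;
the LRF/HRF ablations take the embedding or code slice respectively). The
cascade forest stacks layers of 4 forests (2 random forests + 2
completely-random forests, i.e. extra-trees with single-feature splits),
17 trees each, entropy criterion. Layer `t` receives the original features
plus layer `t-1`'s class-probability outputs; within each layer those
probabilities are produced out-of-fold (5-fold stratified CV), so no
training row is augmented by a model that saw it. Depth grows until the
internal CV accuracy stops improving (patience 1, max 10 layers) and the
best depth is kept. Inference replays the augmentation with the full-data
forests and averages the last layer's probabilities. Multi-grained
scanning is omitted: the features are unordered vectors, not
sequences/images. Only the tree count and criterion are fixed by the
method description; layer composition and the stopping rule follow common
cascade-forest practice and are all configurable.

## Negative sampling

Training negatives are drawn from the zero entries of Y. The default
strategy clusters the candidate pool into 23 clusters (KMeans) in the
space of initial pair vectors and draws `ceil(n_total / n_clusters)` from
each non-empty cluster, truncating (or topping up) uniformly at random to
exactly `n_total` (default: the number of positives, i.e. balanced
training). Clustering spreads the negatives across feature space rather
than concentrating them where unlabelled pairs are dense. Alternative
strategies: plain random, Gaussian mixture, spectral co-clustering and
spectral bi-clustering (row labels). Which feature space the original
method clustered in is unstated; the initial pair vectors are used because
they exist for every candidate and match the cited lineage of this
sampling scheme.

## Evaluation protocols

Cross-validation is stratified 10-fold over the balanced sample set.
Negatives are selected once, before folding, from the full-Y bundle's
features (their Y entries are zero either way). Two modes:

* **faithful** (default) — similarity, GCN and DAE train once on the full
  Y; test-fold positives are visible to these unsupervised stages. This
  matches how association predictors are typically evaluated and is the
  protocol behind the method's published magnitudes.
* **masked** — per fold, the test fold's positive entries are zeroed in Y
  before the similarity bundle, the GCN and the DAE train; the DAE's row
  set is unchanged but all its inputs derive from the masked Y. No
  held-out label can reach any trained stage (the suite asserts this by a
  flip test). Masked numbers are systematically lower and are the honest
  measure of generalisation.

Metrics: accuracy/precision/recall/F1 at threshold 0.5 on the
positive-class probability, AUC with the Mann-Whitney tie convention, and
AUPR by step interpolation (one operating point per unique threshold).

Case-study ranking supports the two published protocols: *known* (train on
everything, rank the disease's unobserved microbes; training positives are
excluded from the output) and *novel* (zero the disease's entire column
before every training stage, then rank all microbes). Ties keep microbe
input order so ranked lists are reproducible.

## Synthetic benchmark

`make_benchmark()` generates a 200 x 40 network (seed 13) with 4 planted
co-clusters: microbes and diseases are assigned uniformly to blocks and an
edge appears with probability `p_in = 0.3` inside a paired block and
`p_out = 0.01` outside, giving ~3-4% density and a 5:1 scale imbalance
(the curated catalogues are ~2.9% and ~8.8:1). A disease ontology DAG is
built with one root, one ancestor term per block and the diseases attached
beneath their block ancestor (with random within-block chains), so
semantic similarity correlates with the planted structure the way real
ontologies correlate with real co-association patterns. The scale was
chosen so a full masked-mode 10-fold cross-validation runs in minutes on a
single CPU.

What the generator does *not* emulate: heavy-tailed degree distributions,
curation biases (well-studied diseases have inflated degrees), overlapping
or nested communities, and name-level noise from merging catalogues.
Passing the recovery tests therefore shows the pipeline recovers planted
block structure under realistic sparsity — not that it reproduces
performance on any curated dataset.

An important property of the benchmark: given the block assignments,
within-block edges are iid Bernoulli, so the Bayes-optimal ranker is the
planted-block indicator itself. On the benchmark's balanced masked-mode
folds that oracle attains mean AUC ~0.854 (about 9.5% of positives are
background noise edges and ~19.7% of sampled negatives fall inside paired
blocks, and nothing can rank within those tie groups). Learned-model AUCs
on this benchmark must be read against that ceiling rather than against
1.0.

## Numerical choices and degenerate inputs

* Seeds: every stochastic component (generator, GCN init/dropout/negative
  draws, DAE init, cascade forests and folds, negative sampling, fold
  assignment) takes an explicit seed; `PipelineConfig.reseeded(s)` derives
  per-stage seeds from one integer. Same seed, same output, bitwise.
* GIP distances are computed via the Gram matrix with clipping at 0;
  kernels are symmetrised by averaging with their transpose to remove
  last-ulp asymmetry.
* The normalised adjacency is computed entry-wise as
  `Y[i,j]/sqrt((r_i+1)(c_j+1))` (matches the closed form exactly).
* All-zero profile matrices raise; empty DAE inputs raise; single-class
  label vectors raise in both the cascade and the metrics.
* Tie-breaks: ranked outputs use stable sort (input order); fold
  remainders are rotated across folds so no fold systematically gets the
  larger chunks.

## Known limitations

* The GCN and DAE are full-batch NumPy implementations; they are exact and
  reproducible but not GPU-accelerated, which bounds practical scale to
  roughly the reference dataset size (~1200 x 150).
* Faithful-mode results inherit the leakage of the standard protocol; use
  masked mode for honest generalisation estimates.
* The semantic kernel requires the ontology to use the same identifiers as
  the association file; no name normalisation is attempted.
* Compressing pairs to embedding + code features loses some information
  relative to the raw fused-similarity rows on small planted benchmarks
  (a strong forest on the raw initial features is a few AUC points above
  the cascade on compressed features there); the compression pays off only
  at scales where the raw pair vector is large.
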