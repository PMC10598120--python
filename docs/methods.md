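# Methods

## The problem

Cohorts of transcriptome profiles for complex-disease prediction — blood
expression in Alzheimer's disease, tumor expression for early- vs late-stage
classification — typically hold a few hundred samples and 15,000–20,000
genes. Direct classifiers overfit badly in this regime. Deep metric learning
sidesteps part of the problem: from *n* samples one can form up to *n³*
triplets (anchor, positive, negative), giving an effectively larger training
signal for an embedding function that pulls same-class samples together and
pushes classes apart; a small classifier then operates on the embedding.

`tripletgene` implements a joint triplet objective with a *strict semi-hard
constraint* (JTSC): semi-hard triplet mining that is double-checked under an
anchor–positive role switch, combined with a switching loss and an angular
loss on top of the classic triplet loss.

## Triplet categories and the switching constraint

For embedded vectors `x_a, x_p, x_n` and margin `m`, let
`dp2 = ||x_a − x_p||²` and `dn2 = ||x_a − x_n||²`. A triplet is

* **hard** when `dn2 < dp2` (the negative is closer than the positive),
* **easy** when `dn2 − dp2 ≥ m` (the triplet loss is exactly zero),
* **semi-hard** otherwise (`0 ≤ dn2 − dp2 < m`).

Categories are computed on *squared* distances so the easy boundary coincides
exactly with the zero of the hinge loss; ties are resolved as: `dn2 == dp2`
is semi-hard (gap 0 < m) and `dn2 − dp2 == m` is easy (loss exactly 0).

Because anchor and positive come from the same class, the labeling of the
pair is arbitrary — yet the category is not symmetric in it. The strict
miner re-categorizes each semi-hard triplet with anchor and positive
exchanged (distances measured from the positive) and retains only triplets
that are semi-hard in *both* orientations. The retained set is invariant
under swapping anchor and positive in every triplet, which is both a unit
test and a brute-force-verified property.

## Losses

All hinge terms use `[t]+ = max(t, 0)`:

    l_triplet   = [ ||x_a − x_p||² − ||x_a − x_n||² + m ]+
    l_switching = [ ||x_p − x_a||² − ||x_p − x_n||² + m ]+
    l_angular   = [ ||x_a − x_p||² − 4 tan²(α) ||x_n − x_c||² ]+ ,  x_c = (x_a + x_p)/2
    l_joint     = l_triplet + l_switching + l_angular

The switching loss is identically the triplet loss of the swapped triplet
(tested to 1e-12 over random triplets). The angular loss is a pure function
of the triangle geometry: it is translation- and rotation-invariant, and its
hinge saturates to zero once the negative is far from the anchor–positive
midpoint. Batch reduction is the arithmetic mean, making the loss magnitude
independent of batch size.

The cosine ablation replaces the distance inside `l_triplet`, `l_switching`
and the categorizer by `1 − cos`; `l_angular` keeps its Euclidean
construction since it is defined geometrically and has no cosine analogue.
Loss-term toggles reproduce the ablation variants (triplet only, +angular,
+constraint, etc.) through `LossConfig` and `TrainingConfig.strict_mining`.

## Embedding network

A 1D convolutional embedder with the stride equal to the window length, so
windows do not overlap and each conv position summarizes one block of genes.
Clinical covariates are *interleaved*: genes are cut into windows of
`kernel_size` values (default ≈ 1% of the gene count; trailing window
zero-padded) and the full clinical vector is replicated after every window,
so every kernel computation sees the covariates. The stack is

    conv(window = kernel_size + n_clinical, stride = window, n_filters)
    → ReLU → max pool(pool_size, ceil mode) → flatten
    → fully connected → embedding_dim → L2 normalization

Weights are Xavier-uniform from `init_seed`. Filter count (8), pool size (2)
and the rectifier are configurable defaults; none is dictated by the method
itself. Ceil-mode pooling keeps a conv output of length 1 alive for the
degenerate `kernel_size > n_genes` case.

**Embedding normalization.** The margin `m = 0.5` is an absolute quantity on
squared distances, so the embedding needs a pinned scale for the easy /
semi-hard / hard partition to be meaningful at initialization and stable
during training. We follow the standard convention for margin-based triplet
losses and L2-normalize the embedding output (squared distances then live in
[0, 4]); the normalization is part of the differentiated graph. It can be
disabled (`normalize_embedding=False`), in which case the margin's meaning
depends on the raw activation scale. The forward/backward passes, including
this normalization, are plain NumPy; the analytic gradients are verified
against central finite differences to 1e-4 relative error.

## Training loop

Per epoch: embed all training samples; categorize all `n_triplets` triplets
(built once, class-balanced: half disease anchors, half control anchors,
positives drawn uniformly excluding the anchor, with replacement across
triplets); apply the strict filter; optionally add the `hard_supplement_k`
hard triplets of least loss; shuffle the retained set with a per-epoch
derived seed; run Adam (β₁=0.9, β₂=0.999) mini-batch updates of size 300 on
the mean joint loss. Only retained triplets ever contribute gradients.

The monitored validation loss is the mean joint loss over the validation
triplet set's strict semi-hard subset, defined as 0 when that subset is
empty — a fully learned embedding then terminates via patience. Mining per
epoch is the default; `mine_per_batch=True` re-filters each mini-batch with
the weights current at that step.

Stopping: (a) validation loss not decreased for `patience` (default 30)
epochs; (b) retained-triplet count below `min_semi_hard` (default 50); or
(c) `max_epochs`. The best-validation-epoch weights are restored on exit. If
the very first epoch yields zero retained triplets *and* `min_semi_hard` is
0, training raises with the category counts (the data are already resolved
or the margin is inappropriate); with the default floor the run simply stops
via (b).

## Downstream classification and evaluation

A one-layer sigmoid head (Xavier-initialized, full-batch Adam on binary
cross-entropy) maps the embedding to a class-1 probability. Metrics: AUC in
the rank / Mann–Whitney formulation with ties counted ½; AUPRC by the
step-wise interpolation-free rule; F1 at a fixed 0.5 probability threshold
(0 when precision + recall is 0). The threshold and the interpolation-free
AUPRC are conventions chosen for bit-for-bit reproducibility. Both metrics
are backed by brute-force oracles in the tests.

`cross_validate` runs stratified k-fold: per fold the feature standardizer
(mean 0, population SD 1, zero-variance columns → 0) is fit on the training
portion only, 20% of the training portion becomes the early-stopping
validation set, the embedding and classifier are trained, and metrics are
taken on the untouched test fold. Fitting normalization per training fold
prevents leakage; fitting it once on the whole matrix is available through
`normalize_features` for single-split workflows.

## Preprocessing conventions

* Duplicate gene identifiers collapse to the column mean (idempotent,
  first-occurrence order preserved).
* Marital status encodes to integers in [−2, 2] with unknown → 0. The exact
  per-category values are a convention, shipped as
  `DEFAULT_MARITAL_MAPPING = {never married: −2, divorced: −1, unknown: 0,
  widowed: 1, married: 2}` and overridable.
* Sex encodes {0, 1}; three or more distinct values are an error.
* Tumor stage I (any sub-stage: IA, IB, …) labels 0 (early); II/III/IV label
  1 (late); missing or unparsable stages raise so callers can exclude the
  sample.
* Pathway-style gene reordering takes a user-supplied group → genes map:
  grouped genes become contiguous (a gene in several groups is placed once,
  at its first group), ungrouped genes follow in original order; the output
  is always a permutation.

## Synthetic data: what it does and does not show

The generator draws background genes i.i.d. standard normal in both classes
and shifts the first `n_informative` gene means by `effect_size` SD in the
disease class; optional clinical covariates are age (Normal(70, 5) controls /
Normal(75, 5) cases), sex (Bernoulli ½) and a marital code (uniform on
−2..2). The default study condition used throughout the tests and the
acceptance script — 200 samples, 1,000 genes, 50 informative at effect size
1.5, 2,000 triplets, margin 0.5, α = 45°, embedding dimension 30, learning
rate 0.01, at most 150 epochs — is a deliberately scaled-down analogue of
the real cohorts (hundreds of samples, tens of thousands of genes, 50,000+
triplets), sized so a full 5-fold evaluation runs in seconds on one CPU.

The generator does **not** model gene–gene correlation, platform or batch
effects, heavy-tailed intensities, or label noise. Passing tests therefore
demonstrate the correctness of the mining, losses, gradients and harness,
and that the pipeline recovers a known separable signal — not performance on
real cohorts.

## Known limitations

* Single binary outcome; no multi-class mining.
* The NumPy network is exact but not GPU-accelerated; at the full 50,000-
  triplet, 17,000-gene scale an epoch is minutes, not seconds.
* `select_hard_supplement` implements the capped least-loss hard-inclusion
  mode; it reproduces the mechanism, not any claim about its benefit.
* With `learning_rate = 0` the loop still runs (useful for stopping-logic
  tests); no warning is emitted.
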