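# Methods

## Problem setting

In X-ray single-particle imaging (SPI), each femtosecond pulse produces one
detector frame — a "speckle pattern" — whose class depends on what the pulse
hit: exactly one particle (*single-hit*, the frames used for 3-D
reconstruction), two or more particles (*multi-hit*), or something that is
not the sample, e.g. parasitic scattering from the injector (*non-sample-hit*).
High-repetition-rate facilities need these frames classified in near real
time with very few labeled examples per class, and the classifier must keep
working when large detector regions are masked or missing.

`speckfew` addresses this with metric learning: a small convolutional
network embeds every pattern onto the unit hypersphere in R^128, trained so
that same-class patterns sit close in squared L2 distance and
different-class patterns sit at least a margin α apart. Classification is
then N-way X-shot: embed the query, compute plain Euclidean distances to X
labeled supports per class, average per class, and predict the class with
the smallest mean distance.

## Embedding model

Two valid (no-padding) 5×5 stride-1 convolutions, each followed by ReLU,
batch normalization and 2×2/stride-2 max pooling, then two fully connected
layers (hidden width 512) and an explicit division by the L2 norm. On a
96×96 input the spatial side lengths are 96 → 92 → 46 → 42 → 21. The
embedding dimension is 128. Channel widths (32/32) and the FC hidden width
are configuration, not architecture constants: only kernel sizes, strides,
the layer order (batch norm *after* ReLU) and the embedding size are fixed
by design. Batch normalization uses batch statistics during training and
exponential running statistics (momentum 0.1) at inference, so inference is
deterministic.

All weight matrices are initialized i.i.d. N(0, 0.2²); biases and
batch-norm shifts start at zero. Optimization is Adam with learning rate
10⁻³ (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸).

The network and its backward pass are implemented directly on numpy arrays
(im2col convolutions, explicit layer-by-layer gradients). Every layer's
analytic gradient is verified against central-difference numerical
gradients in the test suite; this is the correctness anchor for the whole
training stack.

## Triplet loss and semi-hard mining

For a triplet (anchor a, positive p, negative n) with unit-norm embeddings,
the loss is `max(0, d(a,p) − d(a,n) + α)` with d the squared L2 distance.
Because embeddings live on the unit sphere, d ∈ [0, 4], so the largest
admissible margin is α = 4. The default margin is α = 0.2 (squared-L2
units), a conventional choice for this loss family; it is configuration.

Negatives are classified as *hard* (d(a,n) ≤ d(a,p)), *easy*
(d(a,n) ≥ d(a,p) + α, zero loss and zero gradient) or *semi-hard*
(in between). Boundary ties are assigned to semi-hard so the accepted band
is the closed complement of the open easy/hard regions. Mining happens per
mini-batch: embeddings are computed in inference mode, anchor/positive
pairs are drawn uniformly — from the same particle sample when several
samples are present (the multi-sample rule) — and a uniformly random
semi-hard negative is attached. When a pair has no semi-hard negative the
fallback takes the *easiest hard* negative (largest d(a,n) among
d(a,n) ≤ d(a,p)), and a random valid-label negative only if no hard
negative exists either; fallback counts are logged per epoch. Batches are
stratified by (class, sample) so the same-sample rule is always satisfiable.

Validation loss is computed on *random* triplets, fixed once per run, so it
measures embedding quality independently of the mining policy. The
best-validation-loss parameters are restored at the end of training.

## Threshold baseline

The comparison model is the classic CNN-plus-MLP binary hit classifier:
the same convolutional trunk, two FC layers producing a single logit, a
sigmoid P(single-hit), trained with cross-entropy on binary relabeled
targets (multi-hit and non-sample-hit → non-single-hit), and a decision
threshold of 0.9 at prediction time.

## Speckle-pattern simulator

The forward model is a far-field, flat-Ewald (small-angle) coherent sum
over point scatterers with unit form factors:
I(q) = s·|Σ_copies Σ_atoms w·exp(i q·(R r + t))|², with the transverse
momentum transfer q taken per pixel from the detector geometry. This keeps
the invariants the classifier cares about — Friedel symmetry I(q) = I(−q),
k² scaling of the forward peak for k in-phase scatterers, and
inter-particle interference fringes for multi-hits — at desk scale. Ewald
curvature, element-specific form factors, polarization/solid-angle
corrections and solvent background are deliberately out of scope: they
change realism, not any tested invariant.

Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| detector | 172×172 px | pnCCD-like SPI geometry |
| photon energy | 1.66 keV (λ ≈ 7.47 Å) | soft-X-ray SPI regime |
| photons/pulse | 10¹² | typical focused XFEL pulse |
| pixel / distance | 75 µm / 3 mm | gives ~3–10 px fringes for a 50 Å toy particle; a scale stand-in, since real experiments use larger particles at larger distances with the same angular sampling |
| intensity scale | 6.7×10⁻¹⁴ per photon | puts a default single-hit near 10⁵ detected photons before jitter, a realistic Poisson regime |
| toy particle | 50 atoms in a 25 Å ball | desk-scale stand-in for 10⁴–10⁵-atom PDB entries (real entries load via the PDB reader) |
| multi-hit copies | 2–4, equal probability | double/triple/quadruple hits pooled into one multi-hit class |
| copy displacements | uniform direction, radius 45–150 Å | a few particle diameters; sets inter-particle fringe spacing |
| beam stop | 6×8 px at beam center | fixed detector artifact |
| panel gap | 4 columns at the midline | module seam |
| fluence jitter | log-normal, median 1, σ = 0.5 | long-right-tail stand-in for a measured per-pulse photon histogram; an empirical sample set is pluggable |
| Gaussian noise | σ = 0.15 | read-out noise on the normalized O(1) scale |
| crop | 96×96, window start ⌊(dim−size)/2⌋ | fixed convention for bit-exact tests |

Processing order per pattern: diffraction → fluence jitter → Poisson shot
noise → masks → center crop → per-image standardization (mean 0, variance 1
over unmasked pixels; constant images map to zeros) → additive Gaussian
noise. Standardization is scale-invariant, so fluence effects survive only
through photon-counting statistics — which is exactly the physical effect
of interest in the fluence scan. The order of masking vs Poisson sampling
is a convention (masked pixels carry no photons either way); it is fixed
here and documented rather than configurable.

Non-sample hits are a *functional proxy*: 1–3 broad anisotropic Gaussian
streaks with random orientation, scaled to a hit-like total intensity.
This reproduces the smooth, low-spatial-frequency character of parasitic
scattering (verified by comparing above-half-Nyquist band power against
single-hit speckle) without modeling its physics.

Every random operation takes an explicit seed; dataset generation derives
one seed per pattern from the master seed through `SeedSequence` spawn
keys, so datasets are bit-reproducible and insensitive to generation order.

## Augmentation and the leakage rule

Four augmentations: in-plane rotation (bilinear, exact array rotation at
multiples of 90°), random rectangular masking, center zooming and integer
shifting, all shape-preserving with constant fill 0 (matching
masked-detector semantics). Ranges are configuration with defaults
(rotation 0–360°, 1–3 mask blocks of 6–20 px, zoom 0.85–1.15, shift ±5 px).

Because augmented copies are highly correlated with their source, the
train/val/test partition is made *before* augmentation, at the source
level, stratified by class; every augmented copy inherits its source's
partition and records its `source_id`. A dedicated audit
(`augment.audit_split`) re-checks that no source spans two partitions and
is run inside `split_then_augment` itself, in the test suite over
randomized configurations, and as a CLI subcommand.

## Evaluation protocols

*Few-shot*: supports are drawn without replacement per class, embedded,
and all remaining patterns are queries. Plain Euclidean distance is used
for the class averages (squared distance is an option; the two can rank
classes differently once averaged). Ties break to the lexicographically
smallest label.

*Fluence scan*: noise-free test patterns are rescaled by factors
10⁻²…10² (×10^0.5 steps) *before* shot noise and normalization, then
classified at 1/5/20 shots. Because normalization removes the scale
itself, the factor acts purely through counting statistics: at 10⁻² a
pattern carries ~10³ photons spread over 9216 crop pixels and the speckle
structure drowns in shot noise.

*Detector ablation*: a contiguous square containing `fraction` of the crop
area is kept (top-left by default, mimicking lost panels; random placement
available) and everything else is set to 0 on queries *and* supports; both
the embedding classifier and the threshold baseline see identical masked
inputs, and the embedding predictions are binary-relabeled for a
confusion matrix compatible with the baseline. Masking supports as well as
queries reflects a pipeline that never sees the missing panels; evaluating
with unmasked supports is possible by passing pre-masked images directly.

Metrics: accuracy = trace/total of the confusion matrix; per-class
F1 = 2PR/(P+R) with the 0 convention when undefined; the aggregate is the
macro mean, with per-class values always available so any other
aggregation is recomputable.

## The benchmark studies

Two self-contained end-to-end benchmarks share the same conditions — 200
patterns per class at 96×96 with full detector realism, a 50/20/30
source-level split, 10 epochs of triplet training (batch 48, 48 mined
triplets per batch) — and train in a few CPU-minutes each:

- **Fringe-spacing study** (`study.run_size_study`): the well-separated
  two-class benchmark for the few-shot learning property. The classes are
  single hits of two toy particles whose radii differ by 2× (20 vs 40 Å),
  so the speckle fringe spacing — inversely proportional to particle size —
  is distinct class-wide. At these conditions held-out 5-shot accuracy
  reaches ≥ 0.95 and mean accuracy is non-decreasing in the shot count
  (1 ≤ 5 ≤ 20 within bootstrap error, combining support-draw spread with
  per-query binomial noise).
- **Hit study** (`study.run_study`): single-hit vs multi-hit patterns of
  one 50-atom particle, emulating online training on one sample of
  interest; the binary threshold baseline (8 epochs) is trained on the
  same patterns so the missing-detector ablation is a paired comparison.
  Under 25%-area ablation the embedding classifier's accuracy drop is
  bounded by the baseline's drop. Note that single/multi accuracy
  saturates in the low 0.9s here: at unlucky fluence-jitter draws the
  inter-particle fringes of a multi-hit sink below the shot-noise floor
  and the pattern is genuinely ambiguous — a property of the data, not of
  the classifier (a nearest-centroid classifier using *all* supports
  plateaus at the same level).

No augmentation is applied in the studies by default — the synthetic
classes do not need it, and measured accuracy is unchanged with it —
but `n_augment_per_source` enables it.

## What the synthetic data does and does not show

The simulator reproduces the *statistical structure* of SPI data: three
hit classes, coherent interference, realistic photon counting, fluence
jitter with a long tail, beam-stop/gap masks and large missing-detector
fractions. It does not reproduce real-data difficulty: toy particles are
small and rigid, there are no pseudo-single-hit oligomers, no detector
calibration artifacts, no water/injector background beyond the streak
proxy, and class boundaries are cleaner than at a beamline. Passing the
benchmark therefore demonstrates that the machinery (loss, mining,
embedding, few-shot protocol, ablation robustness *direction*) works as
specified — not that the absolute accuracies transfer to experimental
data.

## Numerical choices and degenerate inputs

- float32 throughout the network; float64 in the simulator and metrics.
- L2 normalization adds 10⁻¹² to the norm; constant images normalize to
  zeros rather than dividing by zero.
- Max-pool gradient splits equally between tied maxima.
- Non-positive fluence multipliers are redrawn (bounded retries).
- Semi-hard selection with a single-class batch, validation sets missing a
  class, empty support classes, and crops larger than the image all raise
  errors rather than degrade silently.
- Tie-breaks (few-shot argmin, difficulty-band boundaries) are fixed and
  documented above.

## Known limitations

- The numpy network trains small models happily but is not meant for large
  architectures or datasets; there is no GPU path.
- `fit` keeps the whole dataset in memory (fine at study scale, matching
  the cache-everything approach appropriate for ~10³–10⁴ small images).
- The flat-Ewald model loses accuracy at wide scattering angles; the
  default geometry keeps angles small.
- The fluence scan re-derives per-pattern noise independently per factor;
  factors are therefore not variance-paired across the grid.
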