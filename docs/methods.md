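# Methods

This note documents the models, estimators and numerical choices behind
`eegfuse`, and what the synthetic-data experiments do and do not
demonstrate.

## Data model and arrangement

A trial is an N_e × N_s voltage matrix in microvolts (channels × samples;
the canonical geometry is 128 × 250: one second at 250 Hz). Trials carry a
1-based class label and an image (stimulus) id; repeated presentations of
an image share the id, and `average_presentations` collapses them to one
trial per image by the arithmetic mean, trading trial count for SNR. All
downstream stages treat a trial as a bag of channel rows — no spatial
model across electrodes is imposed.

Continuous recordings enter through EDF (read via MNE), are band-pass
filtered 0.3–30 Hz, and epoched on an event list. The filter is a
4th-order Butterworth applied forward–backward (`sosfiltfilt`), i.e.
zero-phase with squared magnitude response; only the band is part of the
protocol, the family/order is our choice for a flat passband and modest
transition (single-pass |H| at 50 Hz ≈ 0.086). Epoch windows are
half-open `[onset, onset + round(window·fs))` with 0-based indexing, so a
1-s window at 250 Hz contains exactly 250 samples. No baseline correction
is applied; stimulus and rest epochs are cut identically.

## Convolutional feature extraction

Each channel row is expanded by a bank of M = 100 shared 1-D kernels of
length 130, valid (no-padding) cross-correlation, bias 0, logistic-sigmoid
nonlinearity, then non-overlapping mean pooling of width 11:
L_out = 250 − 130 + 1 = 121 map samples → ⌊121/11⌋ = 11 pooled values,
i.e. 1100 features per row and N_e × 1100 per trial. Design points:

- **Kernels are random, not trained.** W ~ N(0, init_sd²) i.i.d. with
  init_sd = 1 and fixed seed. The bank is a fixed random projection into
  many smoothed, band-limited views of each row; all discrimination is
  deferred to selection + classification. No loss or backpropagation
  exists anywhere in the package.
- **Cross-correlation, not flipped convolution.** For symmetric-law random
  kernels the distinction is immaterial; stated for reproducibility.
- **Valid convolution and remainder-discarding pooling** are forced by
  the geometry: any padding would break 121 = 11 × 11 exactly.
- **Sigmoid vs tanh.** Both are available (`activation=`); sigmoid is the
  default. An `identity` activation exists purely as a test hook for
  linear-algebra oracles.
- Outputs are bounded ((0,1) for sigmoid), so downstream KDEs never see
  heavy tails from this path.

The wavelet baseline replaces steps above with a full multilevel DWT
(PyWavelets; default db4, maximum feasible level, zero-padding boundary)
concatenated across channels; the raw baseline simply flattens the trial.

## Feature selection

Per class pair, each feature is scored with the standard Welch two-sample
statistic and Welch–Satterthwaite degrees of freedom, two-sided p.
Features with p ≥ α (default 0.05) are excluded; survivors are ranked by
ascending p, ties broken by |t| descending then feature index. Nested
subsets (default ladder 50…5000 step 50, 100 levels) are prefixes of the
ranking, so the sweep is monotone by construction. For K > 2 classes the
pipeline computes all K(K−1)/2 pairwise rankings on the training fold and
uses the union of the per-pair top-n sets (sorted, deduplicated).

Numerical edge cases: two constant equal groups give (t, p) = (0, 1); zero
spread with unequal means gives t = ±∞, p = 0 and a `degenerate` flag —
such a feature is trivially separative on the training fold and is allowed
to rank first. Selection runs strictly inside each training fold; no test
trial is ever read (asserted by mutation tests).

The ranking criterion (p ascending) and |t| descending differ only across
features with different Welch df; we rank by p.

## LRBSF: likelihood-ratio-based score fusion

Each class c is modelled by per-feature Gaussian KDEs fitted on training
trials only. For a selected feature j with training values x₁…x_n:

    f̂_{c,j}(x) = (1/n) Σ_i φ((x − x_i)/h_{c,j}) / h_{c,j}

with Silverman's rule h = 0.9·min(sd, IQR/1.34)·n^(−1/5) per feature per
class (zero-spread candidates dropped; a fully degenerate feature falls
back to 1e−6 × the pooled feature scale so the density stays proper).
Scores fuse by class-conditional independence:

    S_c(x) = Σ_j log f̂_{c,j}(x_j)

Two classes decide M₁ iff S₁ − S₀ ≥ log η; the boundary belongs to M₁.
η defaults to 1 (the natural operating point); optionally η is tuned to
maximize training accuracy over midpoints of sorted distinct training
scores (ties resolved toward η = 1) — tuning is off in all calibration
experiments because it adds optimization bias. K-class decisions take
argmax_c S_c, ties to the smallest class id; for K = 2 and η = 1 the two
rules coincide exactly.

Densities are floored at 1e−300 before the log, so a far-out test value
contributes a large finite penalty (≈ −690 nats) instead of −∞; this also
makes the floored region flat, which the monotonicity property tests rely
on. The independence assumption is wrong in detail (pooled features of one
map are correlated) but is the standard naive-Bayes trade-off at ~20–50
training trials per class, where a joint density in 50+ dimensions is
hopeless.

## Evaluation protocol

Monte-Carlo cross-validation: n_reps = 100 stratified random splits into
90% train / 10% test (per-class test counts: ⌊f·n_c⌋ plus round-robin
remainder; every class keeps at least one test trial). Selection and
densities are refitted per split. The split stream is a pure function of
(seed, labels, test fraction), so the SVM baseline run at the same seed
sees identical folds. Accuracy is reported per subset size as the mean
over repetitions; for pairs, sensitivity/specificity come from the
rep-summed confusion with the pair's first class as positive. When a
multi-size sweep is reported, the headline number is the maximum of the
mean curve — this maximum is optimistically biased across many sizes, so
calibration experiments use a single size (50) instead.

Chance levels: the analytic threshold is the (1−α) quantile of the
binomial null accuracy, m = BinomPPF(1−α; n, 1/K), e.g. 58% at n = 100,
K = 2, α = 0.05; the empirical threshold is the same quantile over
n_permutations = 1000 draws of uniform random guessing against balanced
true labels ('higher' quantile rule, so the reported value is attainable).
Uniform guessing is equivalent to label permutation for an uninformative
classifier and avoids refitting per permutation.

Method comparison uses two-sided paired t-tests (proposed vs each
baseline over aligned conditions) and a one-way ANOVA across all methods
(scipy implementations).

## Synthetic data generator

The generator emulates a visual object-category study design: K = 5 balanced classes
× 52 images × 2 presentations, 128 channels, 1-s epochs at 250 Hz. Each
trial is class template + noise:

- **Template**: a Gaussian-windowed half-sine bump (peak = amplitude,
  support latency ± width) on a fixed channel subset; defaults are 5 µV
  peak, 50 ms width, latencies staggered 100 ms apart from 120 ms, on the
  first quarter of channels. The defaults are chosen as ERP-like and
  detectable-but-not-trivial; the emulated experiment reports no effect
  size, so these are testability choices, fixed once.
- **Noise**: a seeded mixture of spectrally shaped 1/f ("pink") noise
  (random phases, unit variance) and white noise, weighted
  √0.6 / √0.4, scaled by noise_sd = 10 µV — an EEG-like background level.

Setting every amplitude to zero yields exchangeable classes (the null
model). The generator does **not** model eye-blink or muscle artifacts,
electrode drift, volume-conduction correlations between channels, or
inter-subject variability; consequently, passing calibration and
separability tests demonstrates correctness of the pipeline's statistics,
not attainable accuracy on real recordings. Real-data accuracies require
real data.

## Problem sizes in the test and acceptance runs

Calibration and sanity experiments run at a reduced geometry chosen to
exercise the full pipeline with comfortable margins: 16 channels, 20
images per class, 2 presentations, subset size 50, 100 Monte-Carlo
repetitions. One important subtlety: the Monte-Carlo CV mean on a *single*
data set of 40–100 trials retains dataset-level variance (measured SD ≈ 6
accuracy points for the 2-class setting, ≈ 5 for the 5-class setting)
that repeated splitting cannot remove, although the protocol itself is
unbiased (verified over 40 independent replicates). Null-calibration
results are therefore averaged over several independently generated data
sets, and the associated standard error is computed *between* replicates,
floored by the binomial sampling bound √(p(1−p)/(R·n_trials)) so that a
chance collapse of the empirical SE at small R cannot manufacture a
failure.

## Known limitations

- Random (untrained) kernels mean feature quality depends on the seed;
  M = 100 maps makes this stable in practice but single-map configurations
  are noisy.
- The KDE independence assumption ignores within-map feature correlation;
  scores are therefore overconfident in absolute terms (decisions, not
  probabilities, are the output).
- η tuning uses training accuracy and is biased upward on the training
  fold; it is off by default.
- The wavelet baseline's feature count depends on wavelet/level/boundary
  choices; no attempt is made to match any particular historical count.
- EDF support is read-only and assumes a uniform sampling rate across
  channels.
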