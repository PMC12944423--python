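# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `miaug`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Three-class motor-imagery (MI) decoding: each fixed-length multichannel EEG
epoch is labeled LEFT (imagined left-hand movement), RIGHT, or REST.  The
physiological signal is event-related desynchronization (ERD): imagining a
hand movement attenuates band-limited mu (8–12 Hz) and beta (18–26 Hz)
oscillations over the *contralateral* sensorimotor cortex.  The package
benchmarks how augmenting the training set changes a CNN classifier's
held-out accuracy under three train/test protocols.

## Synthetic MI-EEG generator

Each epoch is the sum of three components, per channel, in µV:

1. **1/f^α background** — spectral synthesis with random phases, amplitude
   ∝ f^(−α/2) (α = `noise_exponent`, default 1.0), normalized to unit RMS
   and scaled by the subject's `baseline_amp` (log-normal around 10 µV RMS)
   and a per-channel log-normal gain (σ = 0.1).
2. **Sensorimotor rhythms** — one mu and one beta sinusoid per hemisphere
   group, frequency drawn uniformly in-band per epoch, phase uniform, with
   a Hann amplitude envelope (avoids sharp onset artifacts that would make
   classes trivially separable by edge detection).  Default amplitudes
   10 µV (mu) and 4 µV (beta) on the group channels.  For LEFT the
   right-hemisphere group's amplitude is multiplied by `1 − erd_depth`
   (symmetrically for RIGHT); REST is unattenuated.  `erd_depth` is drawn
   per subject from U(0.7, 0.95) — a deliberately strong-ERD cohort, as in
   BCI studies that prescreen responsive subjects, chosen once so the
   generated data are decodably above chance at desk scale.
3. **Mains interference** — optional 60 Hz sinusoid (default 2 µV),
   common-mode: identical amplitude and phase on all channels, matching
   capacitive mains coupling and giving the notch stage something real to
   remove.

Sensorimotor groups are *name lists* (left: C3, C5, C1, CP3, FC3; right:
C4, C6, C2, CP4, FC4) on a 64-channel 10–10 montage; reduced montages are
drawn from a priority ordering that always retains both groups.  There is
no volume-conduction/leadfield model, no inter-channel correlation beyond
the common-mode line, and no ocular/muscular artifacts.  Consequently,
passing tests show that the pipeline's machinery (splitting, augmentation
arithmetic, training, statistics) behaves correctly and that the
classifier can exploit lateralized band-power differences; they do not
demonstrate accuracy levels transferable to real recordings.

Determinism: the dataset is a pure function of `SyntheticSpec` (including
its seed); profiles and epochs are drawn from explicit
`numpy.random.Generator` streams.

## EEGNet

Architecture as summarized in the README.  Implementation notes:

- **Same padding** on both temporal convolutions (required for the
  640 → 160 → 20 reduction; even kernels pad one extra sample on the
  right, as in common deep-learning frameworks).
- The depthwise spatial kernel spans **all** channels, collapsing the
  electrode axis to 1; block 2 is a plain (not separable) convolution.
- Convolutions carry no bias (batch norm follows immediately).
- Weights: He-normal for convolutions, Glorot-uniform for the dense layer;
  float32 throughout.
- Early stopping monitors the **training** loss (no validation split): the
  held-out partition is treated as strictly untouchable, so model selection
  may only look at the training side.  Patience defaults to 50 epochs with
  best-weight restore; a 500-epoch/patience-100 regime is available via
  `EEGNetConfig(max_epochs=500, patience=100)`.
- All gradients are hand-written and verified against central finite
  differences (directional derivative agreement ≲ 1e-8 in float64).

### Scaled-down configuration

Desk-scale benchmarks use `scaled_down_config()`: 8 channels × 128 samples
(0.8 s at 160 Hz), temporal kernel 16, pooling still 4×/8×, dropout 0.25
(the full 0.5 is tuned for ~500-epoch training sets; at a few hundred
epochs it slows convergence disproportionately), 10–20 training epochs.
Learning rate, batch size, optimizer, and loss keep their full-scale
values.  The full 64 × 640 Table-style configuration is used for all
architecture-conformance checks.

## Augmentation operators

All operators copy out (inputs are never modified), preserve shape and
metadata, and draw randomness from an explicit seeded generator.
Probability-gated operators (masking, channels dropout, channel shuffle,
band stop at p = 0.5; sign flip at p = 0.3) fire with probability p and
otherwise pass the requested copy through unchanged — so the cascade layer
always delivers exactly the requested number of augmented epochs and the
1:r ratio stays exact.

Choices where the operator definition leaves room:

- **Masking / dropout counts** use `floor` (0.10·640 = 64 samples;
  0.10·64 = 6 channels).
- **Masking** blanks one segment common to all channels (a global
  short-term artifact); per-channel segments are available via
  `per_channel=True`.
- **Gaussian noise** scales per channel (channel amplitude heterogeneity).
- **Band stop** draws whose upper edge would reach Nyquist are clipped just
  below it (cannot trigger with the default ranges at fs = 160); the filter
  is applied to the whole epoch, gated by p.
- **DWT perturbation** uses `mode="periodization"`, making the db4
  transform orthonormal: per-subband noise with std = 0.05 × subband
  coefficient std maps 1:1 into signal energy (Parseval), so the relative
  RMS perturbation is ≈ the factor, and factor 0 reconstructs exactly.
  Per-subband scaling keeps the perturbation frequency-proportional.
- **Fourier surrogate** randomizes each channel independently (inter-channel
  phase coherence is deliberately destroyed); DC and (for even lengths) the
  Nyquist bin are untouched so the output is exactly real.

## Generative augmenters

Class-conditional VAE and GAN trained on the *training partition only*,
with shared optimizer-level hyperparameters: Adam lr 0.0002, batch 32,
50 epochs, latent dimension 100.  Epochs are flattened and standardized by
the training set's global mean/std; the one-hot class label is concatenated
at the encoder/discriminator input and at the latent input.  The networks
are compact single-hidden-layer MLPs (ELU, 128 units by default): only the
optimizer-level hyperparameters are externally fixed, and a small dense
topology trains stably at both full and reduced epoch sizes while keeping
the hand-written backpropagation transparent; the topology is
config-swappable.  The GAN uses non-saturating BCE losses with Adam
β₁ = 0.5 (standard for adversarial training); generator and discriminator
losses are recorded per epoch.  Sampling is restricted to labels seen in
training and tags epochs with the subject sentinel `"synthetic"`.
Degraded accuracy under generative augmentation is reported like any other
result — never clamped or filtered.

## Splitting and leakage control

All three strategies use 80:20 with round-half-away-from-zero on the train
fraction.  The intra-patient split is class-stratified per subject (avoids
empty test classes at small n); a subject's lone epoch of some class goes
to the training side.  Whether splits are redrawn per repeat is a flag
(`resplit_each_run`, default true).  `verify_no_leakage` checks index
disjointness, index range, and — for leave-p-out — subject disjointness,
and reports the offending indices rather than merely failing.

## Statistics

- One-way ANOVA via the standard between/within decomposition
  (`scipy.stats.f_oneway`); the degenerate all-means-equal case returns
  F = 0, p = 1 instead of NaN.
- BH-FDR via the step-up procedure (`statsmodels`); the test suite checks
  it against a brute-force implementation of the definition.
- Cohen's d uses the classical (n−1)-weighted pooled SD.
- Quantiles use linear interpolation (type 7), so IQR = Q3 − Q1 under the
  default NumPy convention.
- Comparison families are explicit index groupings supplied by the caller
  (`compare_to_baseline(..., family=...)`); each family is adjusted
  independently.

## Numerical notes and edge cases

- The 60 Hz notch is realized as a 4th-order Butterworth band-stop
  (58–62 Hz) applied forward–backward (zero phase).  A maximally flat
  band-stop still has passband gain slightly below 1 near the band edges,
  so a second application changes band-edge energy measurably: on
  synthetic EEG the relative RMS change of a second pass is ~1.5e-2.  The
  filter is *approximately* idempotent and the test suite asserts the
  honest bound (5e-2), not an idealized one.
- Filter attenuation is asserted on the target FFT bin, not on whole-signal
  RMS, because zero-phase filtering of a finite epoch leaves edge
  transients that dominate the residual RMS.
- Ratio and split arithmetic use round-half-away-from-zero; stratified
  source selection uses largest-remainder apportionment with deterministic
  ties, and samples without replacement unless a class must contribute more
  epochs than it has.
- EDF export quantizes to 16 bits over each channel's physical range; the
  round-trip error bound is one quantization step.  Recordings must span a
  whole number of 1 s data records.
- Training aborts with a diagnostic if the loss becomes non-finite; failed
  benchmark repeats are excluded with a warning and counted, never
  silently retried.

## Benchmark problem sizes

The end-to-end suites use 5 subjects × 20 epochs/class (300 epochs) at
8 × 128 resolution, 12 augmenters + baseline × 3 strategies × 3 repeats at
ratio 1:1, with 10 training epochs per run and reduced generative models
(latent 16, 15 epochs, 64 hidden units).  These sizes are the package's
own desk-scale choices: large enough that the baseline is decodably above
chance and every code path (including both generative models) executes,
small enough to iterate on a laptop.  A full-scale study would raise
repeats to 50 and training to the 500-epoch regime.

## Known limitations

- The synthetic generator's realism gap (no leadfield, no artifacts, no
  nonstationarity across a session) means absolute accuracies and
  augmentation rankings on synthetic data say nothing quantitative about
  real recordings — the generator validates machinery, not neuroscience.
- The NumPy networks are CPU-only and single-threaded-friendly; they are
  not intended for large-scale sweeps.
- k-fold/nested cross-validation, re-referencing, artifact rejection and
  automatic cascade search are out of scope.
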