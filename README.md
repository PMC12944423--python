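# miaug — augmentation benchmarking for motor-imagery EEG classification

`miaug` is a research pipeline for studying how data-augmentation strategies
affect three-class motor-imagery (MI) decoding from EEG.  It is aimed at
BCI researchers who want to compare augmentation operators, cascades of
operators, and evaluation protocols under controlled, leakage-free
conditions — without first committing to a large recording campaign:
everything runs end-to-end on a built-in synthetic MI-EEG generator, and
real EDF+ recordings (e.g. the 64-channel, 160 Hz BCI2000-style motor
imagery runs with T0/T1/T2 cue annotations) can be ingested through the
same interfaces.

## What is in the box

**Classifier.**  EEGNet, the compact two-block convolutional network for
EEG.  For an input of C = 64 channels and T = 640 samples, block 1 applies
F1 = 8 temporal filters (kernel 1×64, same padding), batch norm, a
depthwise spatial convolution over all channels with depth multiplier
D = 2 (giving F1·D = 16 maps), ELU, average pooling 1×4 and dropout 0.5;
block 2 applies F2 = 16 filters (kernel 1×16), batch norm, ELU, average
pooling 1×8 and dropout.  The temporal dimension shrinks 640 → 160 → 20,
so a 320-long flattened vector feeds the fully connected output layer.
Training: Adam (lr 0.001), categorical cross-entropy, batch size 32, early
stopping on training loss (patience 50) with best-weight restore.  The
network runs on a small self-contained NumPy layer core with hand-written
gradients, pinned by finite-difference gradient checks.

**Augmenters.**  Twelve methods: random masking (10 % of samples zeroed),
cyclic time shift (±20 samples), amplitude scaling U(0.9, 1.1), Gaussian
noise (std = 0.05 × signal std), sign flip (p = 0.3), channels dropout
(10 % of channels), channel shuffle, random Butterworth band-stop
(center U[10, 40] Hz, bandwidth U[1, 5] Hz, order 4, zero-phase), db4
wavelet-coefficient perturbation (factor 0.05), Fourier phase-randomization
surrogates, and class-conditional VAE and GAN generators (latent dim 100,
Adam lr 0.0002, batch 32, 50 epochs).

**Cascades and ratios.**  Operators compose sequentially in 1–3 stages;
the original:generated ratio r (study values 1:0.25 … 1:1) appends exactly
`round(r·N)` augmented epochs, class-stratified, to an N-epoch training set.

**Splits.**  Pooled Random Split, Patient Leave-P-Out (whole subjects held
out) and Intra-Patient Then Pool, all 80:20, with an explicit no-leakage
verifier.  Augmentation is applied strictly after splitting, to the
training side only — the API makes the test partition unreachable.

**Statistics.**  Repeated-run accuracy distributions, confusion matrices,
one-way ANOVA, Benjamini–Hochberg FDR adjustment per comparison family,
Cohen's d (pooled SD), and median/IQR summaries, exported as tidy and
summary CSV tables.

## Worked example

```bash
python examples/train_eegnet.py
```

prints the architecture trace and a quick training run on synthetic data:

```
full-size EEGNet shape trace (64 ch x 640 samples):
  TemporalConv           (8, 64, 640)
  ...
  AvgPoolTime            (16, 1, 20)
  Flatten                (320,)
  Dense                  (3,)

trained 15 epochs (loss 1.154 -> 0.692, best epoch 14)
held-out accuracy: 58.3%  (chance level for 3 classes: 33.3%)
```

The trace confirms the documented geometry (640 → 160 → 20 temporal
samples, 320 flattened features, 3 class scores); the held-out accuracy on
a pooled 80:20 split of the synthetic dataset is well above the 33.3 %
chance level, i.e. the generated event-related desynchronization is
decodable.  `examples/run_benchmark.py` runs a miniature benchmark
(baseline vs. three augmenters at ratio 1:1) and prints the summary table
with mean accuracy and median (IQR) per configuration together with
BH-adjusted ANOVA p-values and effect sizes; `examples/ingest_edf.py`
shows the EDF+ round trip, channel exclusion, 60 Hz notch, cue-aligned
epoching and rest-class balancing on a synthetic recording.

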