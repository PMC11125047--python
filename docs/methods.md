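# Methods

This note documents the models, parameter choices and numerical
decisions behind `wearsynth`, and what the synthetic test-bed does and
does not establish about real wearable data.

## Fixture cohorts

The fixture generator (`wearsynth.fixtures`) emulates a wrist-device
lab stress study: per subject, 2160 s (36 min) of six-channel data at
the documented Empatica E4 native rates (ACC 32 Hz, BVP 64 Hz, EDA 4 Hz,
TEMP 4 Hz — the rates are a device-documentation assumption, not a
measured quantity, and are configurable) plus a per-second label track
with three states (neutral 0, stress 1, amusement 2).

* **Stress schedule.** 2–4 contiguous stress blocks per session; the
  total stress duration is fixed to `round(stress_fraction · T)`
  (default 30 %), block lengths and gaps drawn uniformly under that
  budget, so the realized fraction is exact up to rounding. 10 % of
  non-stress seconds are relabeled amusement so the label merge is
  non-trivially exercised.
* **Signal model.** Each channel is baseline + label-dependent shift +
  AR(1) noise (`x_t = ρ x_{t−1} + √(1−ρ²) ε_t`, ρ = 0.9). Defaults:
  EDA 2.0 µS baseline, +2.0 µS under stress, noise sd 0.25 µS; TEMP
  33.5 °C, −0.8 °C under stress, sd 0.10 °C; BVP is a unit-amplitude
  sinusoid whose instantaneous frequency switches 1.1 → 1.5 Hz under
  stress (phase-continuous, integrated per sample), sd 0.30; ACC is
  zero-mean AR(1) noise, sd 0.15. These magnitudes are chosen once as
  physiologically plausible stress responses of the respective sensors
  (EDA rises strongly, skin temperature drops slightly, heart rate
  rises).
* **Determinism.** Every subject stream derives from
  `(spec.seed, crc32(subject_id))`, so cohorts are bit-reproducible.

What the fixtures deliberately do **not** model: cardiovascular pulse
morphology, motion artifacts, sensor drift/drop-outs, inter-subject
baseline heterogeneity beyond the noise process, and the label noise of
a real protocol. Passing tests therefore demonstrate that the pipeline
recovers *planted, clean* effects; they do not certify performance
levels on real cohorts, whose effects are weaker and messier.

## Preparation

Channels are downsampled to 1 Hz with spectral (Fourier) resampling,
which preserves DC and low-frequency content; the trailing partial
second is dropped. Neutral and amusement merge into non-stress.
Min–max scaling to [0, 1] uses per-signal global extrema; the scope is
the *training subjects of the current LOSO fold*, and held-out subjects
are scaled with the training statistics and clipped — computing
statistics per fold avoids test-set leakage (a config switch allows
cohort-level statistics). A constant signal maps to 0 everywhere.
Windows are 0-based half-open 60-s intervals every 30 or 60 s
(count = ⌊(T−60)/stride⌋+1); window labels are per-second majorities,
with the exact 30/30 tie assigned to stress by default (favoring
detector sensitivity; configurable).

## Conditional GAN

Generator: per-timestep i.i.d. standard-normal noise (dimension 50 by
default; a single-vector latent is available) concatenated with the
label as a per-timestep one-hot, through two stacked LSTM layers
(width 128 each) and a per-timestep dense sigmoid head emitting six
values — so any output lies in [0,1]^{60×6} architecturally.
Discriminator: window concatenated with the same one-hot, two stacked
LSTM layers (128, 64), last hidden state through a dense sigmoid.

Losses: non-saturating adversarial BCE plus the diversity term on
consecutive within-batch generator pairs,
`−min(τ, ‖G(z₁)−G(z₂)‖/‖z₁−z₂‖)` with τ = 1, weighted by λ = 8. Tuned
defaults: Adam, learning rate 2·10⁻⁴, batch 64, 1600 epochs.
A small numerical floor (1e-12) keeps the pairwise distance gradient
finite at coincident outputs; identical latents are rejected.

**DP-CGAN.** Private training replaces only the discriminator's
optimizer: per-microbatch (batch 8 = 8 microbatches, i.e. exactly
per-example) gradients over one real + one fake sample are clipped to
`C = 1`, summed, noised with `N(0, (σC)²)` and divided by the expected
batch size; batches are Poisson-sampled at rate `q = batch/n` to match
the accountant's assumption. The generator keeps plain Adam — it never
touches real data. Private schedule: learning rate 1e-3, 420 epochs.

## Privacy accounting

`epsilon_spent` uses the Rényi-DP bound of the Poisson-subsampled
Gaussian mechanism at integer orders α ∈ [2, 256] (binomial-expansion
form), composed linearly over steps and converted to (ε, δ) with the
improved conversion ε = RDP(α) + log(1−1/α) − (log δ + log α)/(α−1),
minimized over orders. In the degenerate q = 1 case the composition of
identical Gaussian mechanisms *is* a Gaussian mechanism at σ/√steps,
and the exact analytic (ε, δ) curve is used instead of the RDP bound.
`calibrate_noise` binary-searches σ ∈ [0.3, 100] (60 iterations,
relative tolerance 1e-3) for the smallest σ meeting the target ε; an
unreachable target raises.

The sliding-window rule: 30-s sliding roughly doubles the window count
without new unique seconds, so accounting uses the unique count
(n ≤ 496 at WESAD scale) with `2×` epochs, while actual training runs
the configured epochs over the sliding set. δ defaults to the largest
power of ten strictly below 1/n (1e-3 at n = 496).

## Spectral features and classifiers

Per signal, 60-s windows are cut into subwindows whose length times the
signal's upper frequency bound equals 210 (ACC 30 Hz/7 s, BVP and EDA
7 Hz/30 s, TEMP 6 Hz/35 s); each subwindow's one-sided DFT magnitude is
placed on the fixed 210-bin grid (spacing 1/subwindow_s), bins above
the data's Nyquist are exact zeros, no taper is applied, and spectra
are averaged over subwindows. The nominal 0.25-s subwindow stride is
finer than the 1 Hz grid, so the effective stride is
`max(1, round(0.25·fs))` samples — one sample at 1 Hz. The squared
magnitudes averaged per signal give the "spectral power" feature of the
logistic-regression baseline and the stress/non-stress
average-percentage-change statistic `100·|a−b|/((a+b)/2)`.

Classifiers (inputs standardized per feature within `fit`):

* **CNN** — three 1-D convolution blocks over the 210-bin axis
  (widths 32/64/128, kernel 5, same padding, max-pool 2) + dense 128 +
  sigmoid; 10 epochs.
* **CNN-LSTM** — the same trunk, then LSTM 128 and LSTM 64 between the
  convolutional part and the dense head; 20 epochs.
* **TSCT** — the six per-signal spectra as a 6-token sequence,
  projected to width 64 with a learned positional embedding, two
  post-norm encoder blocks (4 heads, feed-forward 128), mean-pooled;
  110 epochs.

All use batch 50, learning rate 1e-3, inverse-class-frequency weights
normalized to mean 1, threshold 0.5. Degenerate precision/recall
denominators report 0 with an explicit flag. The exact internals of the
CNN and TSCT stacks are this package's own defaults (fully
configurable); only their block structure is fixed by convention.

The networks run on an in-repo numpy reverse-mode autodiff core
(`wearsynth.nn`) written for exactly these architectures; every layer's
gradient is verified against finite differences in the test suite, and
all computation is float64.

## LOSO harness

One fold per subject; the fold's GAN and classifier never see the test
subject (training the GAN inside the fold is the LOSO-conform setup; a
clearly-labeled `shared_gan` shortcut exists for cheap smoke runs).
Fold seeds derive from `(base_seed, crc32(subject_id), repeat)`;
synthetic subjects are regenerated per repeat. Aggregates are
unweighted means over folds, then over repeats, with SD across repeats.
The baseline sweep fits a logistic regression per LOSO fold on mean
spectral power for each of the 63 non-empty signal subsets, skipping
(and flagging) single-class folds. Whether large synthetic cohorts are
drawn once per fold or once per repeat is an open choice; per-repeat is
the default, matching the repeat-averaging rationale.

## Problem sizes in the test suite

Tests and the acceptance script run reduced configurations chosen as
the package's own desk-scale defaults: cohorts of 4–8 subjects,
GAN widths 32/32 and 32/16 with 16-dimensional noise and 50 epochs for
the correlation-sign check, classifier widths down to (8, 16) with
15–30 epochs, and C2ST calibration over 20 independent cohort pairs of
500 windows each. The full-scale configuration (15 subjects, widths
128, 1600 GAN epochs, 10 repeats) is reachable through the same APIs.

A two-sample-test subtlety worth knowing: both samples must be scaled
with *shared* normalization statistics. Scaling each draw by its own
min/max injects a detectable preprocessing difference between
identically distributed samples and inflates C2ST accuracy.

## Known limitations

* The WESAD adapter is exercised only at the unit level (label mapping,
  per-second reduction); full-dataset quantities require the external
  download.
* DP training is slow (per-example gradients in pure numpy), so private
  end-to-end runs in the suite use token epoch counts; the accounting
  itself is exact regardless of scale.
* The accountant's σ values need not match any particular external
  implementation; equivalence is enforced at the (ε, δ) interface.
* t-SNE output is treated as a visualization contract, not a tested
  numeric.
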