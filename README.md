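# wearsynth

Privacy-preserving synthesis and evaluation of multimodal wearable
stress data.

Wrist-worn devices (e.g. the Empatica E4) record six channels —
three-axis acceleration (ACC), blood volume pulse (BVP), electrodermal
activity (EDA) and skin temperature (TEMP) — from which short windows
can be classified as *stress* vs *non-stress*. Real cohorts of this
kind are small and privacy-sensitive. `wearsynth` implements a full
pipeline for generating **labeled synthetic sensor windows** with a
conditional GAN, optionally under a **differential-privacy (DP)
guarantee**, and for measuring whether the synthetic data are (a)
statistically faithful and (b) useful for training stress classifiers.

## The models

**Data representation.** Each subject session is Fourier-downsampled to
1 Hz, relabeled to binary stress (neutral and amusement merge into
non-stress), min–max scaled to [0, 1] per signal, and cut into 60-s
windows (optionally sliding every 30 s) labeled by per-second majority
vote — a window is a matrix `W ∈ [0,1]^{60×6}`.

**Conditional GAN.** A generator `G(z, y)` maps per-timestep Gaussian
noise `z` plus a broadcast one-hot stress label `y` through two stacked
LSTM layers and a sigmoid head to a window; a discriminator `D(W, y)`
(two stacked LSTM layers) scores real vs fake. Training plays the usual
min–max game `min_G max_D E[log D(x,y)] + E[log(1 − D(G(z,y),y))]`, and
the generator loss adds a diversity-sensitive term

    L_div = −min(τ, ‖G(z₁,y) − G(z₂,y)‖ / ‖z₁ − z₂‖),   weight λ = 8,

which rewards output spread per unit latent spread (capped at τ = 1) to
counter mode collapse.

**DP-CGAN.** Only the discriminator touches real data, so only its
optimizer is replaced by DP-Adam: per-example gradients are clipped to
an L2 norm `C = 1` and Gaussian noise `σC` is added, with `σ` calibrated
by a Rényi-DP accountant so that the whole training run spends at most
the target budget `ε ∈ {10, 1, 0.1}` at `δ = 1e-3`. Overlapping 30-s
sliding windows duplicate data points, so accounting uses the *unique*
window count `n ≤ 496` with doubled epochs (the unique-window rule), and
`δ` is chosen as the largest power of ten strictly below `1/n`.

**Evaluation.** Synthetic quality is assessed with PCA/t-SNE
embeddings, Pearson signal–label correlation matrices (with p-values),
per-stratum value densities and a Gaussian-Naive-Bayes **classifier
two-sample test** (held-out accuracy ≈ 0.5 ⇔ indistinguishable).
Utility is measured by leave-one-subject-out (LOSO) stress
classification — precision, recall and `F1 = 2·P·R/(P+R)` — with three
training strategies: **ORIG** (real windows only), **TSTR** (train on
synthetic, test on real) and **AUGM** (real + synthetic), using CNN,
CNN-LSTM or transformer (TSCT) classifiers over 6×210 averaged FFT
spectra.

Because no public cohort ships with the package, a seeded **fixture
generator** produces E4-like cohorts with the physiological effect
directions the literature reports (EDA up, TEMP down, BVP faster under
stress) at the study's class balance (~30 % stress seconds); an
optional adapter (`wearsynth.wesad`) reads the native WESAD per-subject
bundles if you have downloaded them.

## Worked example

```python
import numpy as np
from wearsynth import (FixtureSpec, generate_cohort, prepare_cohort,
                       ConditionalGan, synthesize_subjects,
                       correlation_with_p, c2st, SIGNALS)

spec = FixtureSpec(seed=11)                      # 36-min subjects, 30 % stress
cohort = generate_cohort(spec, n_subjects=6)
windows, stats = prepare_cohort(cohort, stride_s=60)
print(f"prepared {len(windows)} windows, stress share {windows.labels.mean():.3f}")

gan = ConditionalGan(epochs=50, noise_dim=16, gen_widths=(32, 32),
                     disc_widths=(32, 16), random_state=3)
gan.fit(windows)

synth = synthesize_subjects(gan, n_subjects=10, random_state=5).all_windows()
rep = correlation_with_p(synth)
eda, temp = SIGNALS.index("eda"), SIGNALS.index("temp")
print(f"synthetic r(EDA, stress) = {rep.r[eda, 6]:+.3f}  "
      f"r(TEMP, stress) = {rep.r[temp, 6]:+.3f}")
print(f"C2ST accuracy vs real fixtures: {c2st(windows, synth, seed=0).accuracy:.3f}")
```

prints

```
prepared 216 windows, stress share 0.292
synthetic r(EDA, stress) = +0.718  r(TEMP, stress) = -0.759
C2ST accuracy vs real fixtures: 1.000
```

After only 50 epochs on a 6-subject cohort the generator already
reproduces the physiological correlation structure — EDA positively and
TEMP negatively correlated with the stress label — while the C2ST shows
the samples are still individually distinguishable from real windows
(a fully converged GAN drives this toward 0.5). Longer training with
the default configuration (`ConditionalGan()`: λ = 8, learning rate
2·10⁻⁴, batch 64, 1600 epochs, widths 128/128 and 128/64) closes the
gap at a correspondingly higher compute cost.

A `wearsynth` command-line interface wraps each stage
(`fixtures`, `prep`, `train-gan`, `synth`, `eval-quality`, `featurize`,
`loso`); run `wearsynth --help`.

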