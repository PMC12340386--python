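# Methods

## The problem

Glaucoma is detected by comparing an eye's circumpapillary nerve fiber
layer thickness (NFLT) profile — thickness sampled on a 3.4 mm circle
around the optic disc, in temporal-superior-nasal-inferior-temporal
(TSNIT) order — against a normative reference. A single population
reference ignores two large sources of healthy inter-eye variation:

* **vascular anatomy** — the superior and inferior thickness peaks sit
  at the arcuate axon bundles, which collocate with the major vascular
  arcades, and arcade positions vary by tens of degrees between eyes;
* **transverse magnification** — in a long (myopic) eye the nominal
  3.4 mm scan circle lands farther from the disc, where the NFL is
  thinner in a roughly reciprocal fashion, so healthy myopic eyes are
  flagged as "abnormally thin" (the red-disease false-positive problem).

This package generates an *individualized baseline*: a per-eye normal
reference NFLT profile predicted from the eye's own vascular pattern,
magnification factors (axial length AL, spherical equivalent SE, disc
area) and demographics (age, sex) plus scan quality (SSI).

## The dual conditional VAE

Two conditional variational autoencoders are trained jointly on healthy
eyes:

* the **VP-CVAE** encodes the binary vascular-pattern profile into a
  latent (mu2, sigma2) and reconstructs it (binary cross-entropy);
* the **NFLT-CVAE** encodes the thickness profile into (mu1, sigma1)
  and reconstructs it (squared error).

Both are conditioned on standardized scalars; the two are coupled along
two distinct paths: the VP encoder's convolutional feature vector is an
extra condition of the NFLT *encoder*, and the VP sampling-layer output
z2 is an extra condition of the NFLT *decoder*. Three variants differ
only in their scalar conditions: **BASE** (age, sex, SSI), **MAG**
(BASE + disc area, measured AL, SE) and **REG** (MAG with AL and SE
replaced by estimates from a regression CNN, for settings where
biometry is unavailable).

Training loss (weighted mean over the batch; eyes of two-eye
participants carry weight 1/2 so each participant totals 1):

    L = MSE_NFLT + BCE_VP + KL_VP + KL_NFL        (+ MSE_AL + MSE_SE for REG)

The reconstruction terms are **summed over the 128 profile points** and
the KL terms summed over latent dimensions — the evidence-lower-bound
scaling. This matters: averaging the reconstruction over points instead
makes reconstruction so cheap relative to the KL that the VP latent
collapses to the prior and the generated baseline loses its peak
alignment entirely (we measured KL_VP dropping to ~0.003 and the
vessel-peak collocation disappearing). Per-point means are still logged
for readability.

Optimization: Adam at learning rate 1e-3. The recipe's optimizer decay
(0.001) and L2 factor (0.02) are both applied as decoupled weight decay
on the update, i.e. the per-step shrinkage is lr*(0.001+0.02) on weight
matrices (never biases); a raw loss-side penalty of 0.02 * sum(w^2)
would dominate the reconstruction gradient under Adam's per-parameter
normalization. Dropout 0.5 is applied in the encoder fully connected
stems; decoder dropout is a config switch defaulting off, because a
stochastic decoder blurs the deterministic generation path. 10% of the
training participants (grouped, never split across the boundary) are
held back as internal validation; the checkpoint with the best
validation loss is kept, with early stopping after 25 stagnant epochs
(max 120).

### Architecture

1-D convolutions with **circular padding** (the profile lives on a
closed circle), kernel 5, stride 2, channels 16-32-64, LeakyReLU(0.1);
decoders mirror this with nearest-neighbour upsampling + stride-1
circular convolution (a checkerboard-free stand-in for transposed
convolution) fed by a 64-wide FC stem. Latent sizes: 8 (VP), 16 (NFLT).
All of this is configurable; none of it is prescribed by the problem.

One deliberate choice: the thickness latent Z1 enters the decoder
through a **linear additive head** rather than the nonlinear stem. The
generating stage decodes at Z1 = 0 as a one-pass surrogate for
averaging decodes over z1 ~ N(0, I); with Z1 inside the nonlinear stem
the decoder develops a sizeable nonlinear response to what is (per its
KL of ~0.1 nats) an essentially information-free latent, and the Z1 = 0
decode missed the Monte-Carlo average by ~4 um RMS. With the linear
head the shortcut equals the expectation exactly, and we measure the
residual gap at ~0.1 um (pure Monte-Carlo error).

The networks are built on a small reverse-mode autodiff core
(`rnflbase.nnet`) written for this package: ~15 array operations with
explicit vector-Jacobian products, verified elementwise against central
finite differences. Convolution uses a channels-last im2col whose patch
tensor is contiguous, so forward and both gradients are single GEMMs
plus a K-pass scatter.

## Generating stage

Only the VP encoder and the NFLT decoder run: Z1 = 0, Z2 = mu2 (the VP
posterior mean; sigma2 is discarded), dropout off. The baseline is
therefore a pure function of (eye, checkpoint) — repeated calls are
bit-identical. Quadrant summaries use the standard 90-degree TSNIT
arcs (temporal centered on index 0).

For transfer to a cohort with a different population profile (e.g. a
different racial composition), the baseline can be multiplied pointwise
by the ratio of emmetropic population-mean profiles between the target
and training cohorts. The raw pointwise ratio of small-sample means is
noisy, so it is smoothed with a 5-sample circular moving average
(window configurable).

## The magnification rCNN

Inputs: the vascular-pattern and RPE-elevation polar annulus maps
(disc-centered diameters 2-4 mm, 16 radii x 64 angles) plus the
demographic scalars; never the ILM surface, which glaucoma deforms. The
per-eye mean elevation is subtracted from the RPE map, so estimates
depend on curvature (the AL signal) and are exactly invariant to
constant elevation offsets. Three circularly padded conv blocks run
along the angular axis (radii stacked as channels), global average
pooling, FC head to standardized (AL, SE); inverse-standardized AL is
clamped to a physiological 20-32 mm window. The rCNN is trained first
on measured AL/SE and frozen; the REG CVAE then trains against its
predictions, with MSE_AL/MSE_SE reported as loss components (the
sequential reading of the training protocol; a joint-training switch
exists but has no principled default).

## The regression comparator

Weighted least squares of each thickness target (overall, 4 quadrants,
each of the 128 points) on [1, age, female, SSI, AL·1(SE<0),
AL·1(SE>=0), 1(SE<0)] — a broken-stick AL term with the break at
emmetropia (SE = 0 D) and separate myopic/hyperopic slopes plus a
segment offset. Continuity at the break is not enforced: the break is
defined on SE while the slope acts on AL, so a continuity knot is not
well defined. Eyes of two-eye participants carry weight 1/2; the fit is
solved jointly for all 133 targets by a single weighted `lstsq`.
Adjusting an eye subtracts the fitted covariate deltas relative to a
reference covariate point (training-pool weighted means; the reference
sits in the SE >= 0 segment); the normal reference is the weighted mean
of adjusted training eyes. On noiseless model-generated data the
adjustment maps every eye to the same value exactly.

## Evaluation protocol

Five references are compared: Average (training mean, no adjustment),
MLR, BASE, MAG, REG. A single per-eye **deviation score** d = observed
- predicted reference unifies them (the reference is the training mean
for Average, the covariate-predicted value for MLR, and the generated
baseline for the DL variants). Cross-validation is grouped by
participant — both eyes share a fold — so between-eye correlation
cannot leak across the train/test boundary. Per fold and per model:

* prediction error = participant-weighted RMS of d on the test fold
  (per target; profile errors also pooled as the root mean of pointwise
  mean squares);
* the fifth-percentile cutoff = empirical quantile (linear
  interpolation, h = (n-1)p + 1) of d in the **training-fold
  emmetropia** pool. Those deviations are computed *out of fit*: an
  inner 2-fold split of the training fold refits the models so that
  every training eye's deviation comes from a model that never saw it.
  This matters because the vascular pattern is effectively a
  participant fingerprint — in-fit deviations shrink as training
  proceeds (we measured the train-fold emmetropia SD falling from 5.2
  to 4.2 um while the test SD stayed at 5.2), which makes the cutoff
  too tight and inflates every false-positive rate. Folds too small to
  refit fall back to in-fit deviations with a flag in the report;
* false-positive rate = fraction of healthy test eyes with d below the
  cutoff, stratified by refraction group (high myopia SE < -6, low
  myopia [-6, -1), emmetropia [-1, 1], hyperopia > 1; boundaries to the
  less extreme group);
* cutoff margin = training-emmetropia mean deviation minus the cutoff
  (for Gaussian deviations this tends to 1.645 sigma; a smaller margin
  means a tighter detection threshold).

Significance machinery is out of scope; participant-resampled
percentile bootstrap contrasts (1000 reps) are provided instead.

## The synthetic cohort generator

The clinical cohorts behind the method are not public, so all tests run
on a seeded generator that embodies the structure the models assume.
Per eye, the noiseless baseline is

    [floor + nasal tilt + superior bump + inferior bump] * (AL_ref / AL)
      + slope_age*(age - 50) + 0.89*female + 0.04*(SSI - 65)

with wrapped-Gaussian (von-Mises-shaped, kappa = 6) bumps centered at
the eye's arcade angles. Arcade angles are drawn per participant
(superior ~ N(90, 12) deg, inferior ~ N(270, 12)) with 3-degree
within-participant jitter, so fellow eyes share anatomy. Vessels are
placed as an artery/vein pair flanking each arcade plus two minor nasal
vessels, both on the profile and in the annulus maps; the RPE map
carries an AL-dependent curvature (8 um/mm) that is the rCNN's signal.
Shape constants (floor 72.86 um, bump amplitudes 85.08/89.86 um, tilt
1.14 um) were solved once so that the emmetropic reference eye
reproduces published healthy East-Asian quadrant means (T 78, S 127,
N 76, I 130 um); covariate slopes default to the published
overall-average regression slopes (age -0.14 um/yr, female +0.89 um,
SSI +0.04 um/unit). Group marginals (age, sex, AL, SE, disc area, mix
0.118/0.348/0.442/0.092) follow the published per-group table; SE is
drawn with a within-group correlation of -0.6 against AL, so each
group's published SE mean/SD is matched while the strong cohort-level
SE-AL link emerges from the group means.

Two AL-effect modes exist: `reciprocal` (default; the physical
magnification model above, which produces the red-disease pattern) and
`linear` (additive broken-stick slopes -2.65/-1.47 um/mm, used to test
the regression's parameter recovery under its own model).

Noise has three tiers: a participant-level offset (SD 4 um, shared by
fellow eyes), an eye-level offset (SD 3 um) and i.i.d. pointwise
measurement noise (SD 8 um). Default cohort: 400 participants, 68%
contributing both eyes, N = 128 points.

What the generator does **not** emulate: realistic vascular trees and
vessel-width biology, the SSI-segmentation interaction, disease (no
glaucomatous eyes exist anywhere in scope), race structure, scanner
artifacts, and the weaker real-world mapping from annulus maps to AL
(the generator's curvature signal is strong, so rCNN recovery here is
far better than one should expect on real OCT). Passing tests therefore
show that the implementation is faithful and that the method behaves as
designed *under its own assumptions* — not that it meets any clinical
performance bar.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: cohorts of
120-420 participants, 2-fold cross-validation, 3 seeds for majority
checks, 40-120 training epochs; the regression-recovery cohort uses
~2000 eyes. The quality filter (SSI < 35, cropping flag, overall NFLT
below the healthy mean minus 4 SD), vessel-width normalization
(largest-remainder apportionment to exactly round(0.25*N) vessel
pixels, each surviving run keeping >= 1 pixel, remainder ties to the
wider run), and standardization statistics are always frozen on the
training fold and reapplied verbatim to test eyes. VP decoder
probabilities are produced from logits (numerically stable BCE);
sigma is parameterized as log-sigma everywhere, so KL inputs are
strictly positive by construction. Degenerate inputs (all-zero vessel
profiles, zero-SD features, empty refraction groups) raise or are
flagged rather than silently defaulting; an empty group's FPR is
reported as missing, never as 0.

## Known limitations

* The dual CVAE trains on a numpy autodiff core: fine at desk scale,
  not meant for GPU-scale data.
* The Z1-linear decoder head makes the latent-mean shortcut exact but
  limits how much *nonlinear* per-eye residual structure the NFLT
  latent could express; at the synthetic noise levels this costs
  nothing measurable.
* The generator's marginals are calibrated only to published
  means/SDs; joint structure beyond the SE-AL and arcade-vessel
  couplings is invented.
* The cross-cohort ratio adjustment is validated only for identity and
  synthetic-scale ratios; no second cohort with a genuinely different
  profile shape exists in scope.
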