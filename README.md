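# rnflbase

Individualized baseline profiles for circumpapillary retinal nerve
fiber layer thickness (NFLT).

## The problem

OCT-based glaucoma detection compares an eye's NFLT profile — thickness
sampled on a 3.4 mm circle around the optic disc, in TSNIT order —
against a normative reference. A one-size-fits-all population reference
ignores two large healthy variations: the superior/inferior thickness
peaks follow the eye's own vascular arcades, and axial myopia lowers
transverse magnification so the scan circle lands farther from the disc
where the layer is thinner. The result is the "red disease" problem:
healthy myopic eyes flagged as abnormally thin.

`rnflbase` builds a per-eye normal reference instead. A pair of coupled
conditional variational autoencoders (CVAEs) is trained on healthy
eyes: one reconstructs the binary vascular-pattern profile, the other
the thickness profile, conditioned on the first's latent code and on
standardized covariates. Variants differ in their conditions — BASE
(age, sex, scan signal strength), MAG (+ disc area, measured axial
length AL and spherical equivalent SE) and REG (MAG with AL/SE
estimated from peripapillary annulus maps by a regression CNN). At
generation time only the vascular-pattern encoder and the thickness
decoder run, with the thickness latent forced to Z1 = 0 and the
vascular latent at its posterior mean Z2 = mu2, so the baseline is a
deterministic function of the eye:

    baseline(eye) = decode_NFLT(Z1 = 0, Z2 = mu2(vp), conditions(eye))

Training minimizes `MSE_NFLT + BCE_VP + KL_VP + KL_NFL` (+ `MSE_AL +
MSE_SE` for REG), with eyes of two-eye participants weighted 1/2. A
broken-stick multiple linear regression (separate AL slopes for the
myopic SE < 0 and hyperopic SE >= 0 segments) serves as the classical
comparator, and a participant-grouped cross-validation protocol
compares five references — Average, MLR, BASE, MAG, REG — by RMS
prediction error, fifth-percentile cutoffs from the emmetropia group,
refraction-stratified false-positive rates (FPR) and cutoff margins.

The clinical cohorts behind the method are not public; the package
ships a seeded synthetic cohort generator (`rnflbase.simulate`) with
vessel-collocated peaks, reciprocal AL magnification, published
covariate slopes, fellow-eye correlation and three noise tiers, plus
the noiseless ground truth per eye for recovery testing. See
`docs/methods.md` for the model, the generator and their limits.

## Worked example

```python
import rnflbase as rb
from rnflbase.cvae import CVAEHyperParams, train_model

cfg = rb.SimConfig(n_participants=150, seed=3)
eyes, truths = rb.generate_cohort(cfg)
prepped, stats, log = rb.prep_cohort(eyes)      # quality filter + vessel normalization
model, _ = train_model(prepped, "mag",
                       CVAEHyperParams(max_epochs=40, patience=15),
                       seed=1, stats=stats)

eye = next(e for e in prepped if e.se < -3)   # a myopic eye: the hard case
ref = rb.generate_baseline(eye, model)
print(f"overall {ref.overall:.1f} um, superior {ref.superior:.1f}, "
      f"inferior {ref.inferior:.1f}")
```

Running `examples/02_train_and_generate_baseline.py` (which is this
example with diagnostics) prints:

```
257 of 257 eyes pass the quality filter
best internal-validation epoch: 40

individualized baseline for P00002_left (AL 25.00 mm, SE -3.9 D):
  overall 97.1 um  (noiseless truth 93.5 um)
  superior 116.0  inferior 117.5 um
  superior peak at 84 deg; true arcade at 83 deg
```

The baseline's overall level tracks the eye's noiseless truth (the
myopic eye is reproduced thin — no false alarm), and its superior peak
sits at the eye's own arcade angle rather than the population's 90
degrees. `examples/04_evaluate_models.py` runs the cross-validated
five-model comparison and prints the prediction-error and FPR tables;
`examples/01_simulate_cohort.py` and `examples/03_mlr_reference.py`
cover the generator and the regression comparator.

A thin CLI mirrors the pipeline stages
(`rnflbase simulate / prep / train / rcnn-train / generate / mlr /
evaluate / run`); `rnflbase run --config experiment.yaml` executes all
of them with a manifest of artifact hashes.

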