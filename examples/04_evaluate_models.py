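"""Cross-validated comparison of normal-reference models.

Compares the unadjusted population Average, the broken-stick regression
(MLR) and the MAG generative baseline on one synthetic cohort: weighted
RMS prediction errors, fifth-percentile cutoffs from the training-fold
emmetropia pool, and refraction-stratified false-positive rates. Takes a
few minutes (it trains one CVAE per fold).
"""

import numpy as np

import rnflbase as rb
from rnflbase.evaluate import run_evaluation

cfg = rb.SimConfig(n_participants=250, seed=13)
eyes, truths = rb.generate_cohort(cfg)
report = run_evaluation(eyes, k=2, seed=4, models=("average", "mlr", "mag"))

print("pooled prediction error (um):")
print(f"{'model':<9}{'overall':>9}{'profile':>9}")
for m in report.models:
    print(f"{m:<9}{report.rms[m]['overall']:>9.2f}"
          f"{report.rms[m]['profile_pooled']:>9.2f}")

print("\noverall-thickness false-positive rate by refraction group")
print("(healthy eyes below the 5th-percentile emmetropia cutoff):")
for m in report.models:
    row = "  ".join(
        f"{g}: {100 * report.fpr[m][g]['overall']:.1f}%"
        for g in ("emmetropia", "low_myopia", "high_myopia")
        if report.fpr[m][g]["overall"] is not None)
    print(f"  {m:<9}{row}")

print("\ncutoff margin, overall (reference mean - cutoff, um):")
for m in report.models:
    print(f"  {m:<9}{np.mean(report.margins[m]['overall']):.1f}")
print("\nAn uncorrected Average reference flags a large share of healthy")
print("high-myopic eyes (red disease); the magnification-aware baseline")
print("returns the rate to its nominal 5% while tightening the margin.")
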