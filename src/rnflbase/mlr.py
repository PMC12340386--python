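"""Multiple linear regression comparator with a broken-stick AL term.

The regression relates each thickness target (overall mean, the four
quadrant means and every profile point) to age, sex, SSI and axial
length, with the AL slope broken at emmetropia: eyes with SE < 0 D form
the myopia segment, eyes with SE >= 0 D the hyperopia segment, each with
its own AL slope plus a segment offset (continuity at the break is not
enforced — the break is on SE while the slope is on AL, so a knot is
ill-defined). Eyes of two-eye participants carry weight 1/2.

The regression-based normal reference is the weighted mean of all
training eyes after adjusting each to a common reference covariate
point (training-pool means by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cvae import participant_weights
from .prep import quadrant_means

TARGETS = ("overall", "temporal", "superior", "nasal", "inferior")
# design: [1, age, female, ssi, AL*1(SE<0), AL*1(SE>=0), 1(SE<0)]
_P = 7


@dataclass
class MLRCoefficients:
    """One coefficient row per target: 5 summaries + N profile points."""
    beta: np.ndarray                 # (5 + N, 7)
    n_points: int
    reference: dict = field(default_factory=dict)  # age/sex/ssi/al + segment

    def row(self, target):
        return self.beta[_target_index(target, self.n_points)]

    def to_dict(self):
        return {"beta": self.beta.tolist(), "n_points": self.n_points,
                "reference": self.reference}

    @classmethod
    def from_dict(cls, d):
        return cls(beta=np.asarray(d["beta"], dtype=float),
                   n_points=int(d["n_points"]), reference=dict(d["reference"]))


def _target_index(target, n_points):
    if isinstance(target, str):
        return TARGETS.index(target)
    idx = int(target)
    if not 0 <= idx < n_points:
        raise IndexError(f"profile point {idx} out of range")
    return 5 + idx


def _design_row(age, sex, ssi, al, se):
    myopic = 1.0 if se < 0 else 0.0
    return np.array([1.0, age, sex, ssi, al * myopic, al * (1.0 - myopic), myopic])


def _targets_matrix(eyes):
    ys = []
    for e in eyes:
        o, t, s, n, i = quadrant_means(e.nflt_profile)
        ys.append(np.concatenate([[o, t, s, n, i], e.nflt_profile]))
    return np.stack(ys)  # (n_eyes, 5 + N)


def fit_mlr(train_eyes, reference=None) -> MLRCoefficients:
    """Weighted least squares jointly for all targets.

    `reference` optionally overrides the adjustment reference covariates
    (dict with age/sex/ssi/al and `myopic` segment flag); defaults to
    weighted training means with the hyperopia (SE >= 0) segment.
    """
    if len(train_eyes) < 50:
        raise ValueError("need >= 50 eyes spanning both SE segments")
    n_my = sum(1 for e in train_eyes if e.se < 0)
    n_hy = len(train_eyes) - n_my
    if n_my < 10:
        raise ValueError("myopia segment has fewer than 10 eyes")
    if n_hy < 10:
        raise ValueError("hyperopia segment has fewer than 10 eyes")

    X = np.stack([_design_row(e.age, e.sex, e.ssi, e.al, e.se)
                  for e in train_eyes])
    Y = _targets_matrix(train_eyes)
    w = participant_weights(train_eyes)
    sw = np.sqrt(w)[:, None]
    beta, *_ = np.linalg.lstsq(X * sw, Y * sw, rcond=None)
    n_points = len(train_eyes[0].nflt_profile)

    if reference is None:
        wm = lambda v: float(np.sum(w * v) / w.sum())
        reference = {
            "age": wm(np.array([e.age for e in train_eyes])),
            "sex": wm(np.array([e.sex for e in train_eyes])),
            "ssi": wm(np.array([e.ssi for e in train_eyes])),
            "al": wm(np.array([e.al for e in train_eyes])),
            "myopic": 0.0,  # reference sits in the SE >= 0 segment
        }
    return MLRCoefficients(beta=beta.T, n_points=n_points, reference=dict(reference))


def adjust_to_reference(eye, coeffs: MLRCoefficients):
    """Adjusted thickness per target: observed minus the fitted covariate
    deltas relative to the reference point, using the eye's own SE-segment
    AL slope (plus the segment-offset delta). On noiseless model-generated
    data this maps every eye to the same value per target."""
    ref = coeffs.reference
    myopic = 1.0 if eye.se < 0 else 0.0
    # delta of the design row against the reference design row
    d_age = eye.age - ref["age"]
    d_sex = eye.sex - ref["sex"]
    d_ssi = eye.ssi - ref["ssi"]
    # AL enters through its segment column; reference AL sits in ref segment
    delta = np.zeros(_P)
    delta[1:4] = (d_age, d_sex, d_ssi)
    delta[4] = eye.al * myopic - ref["al"] * ref["myopic"]
    delta[5] = eye.al * (1.0 - myopic) - ref["al"] * (1.0 - ref["myopic"])
    delta[6] = myopic - ref["myopic"]

    o, t, s, n, i = quadrant_means(eye.nflt_profile)
    observed = np.concatenate([[o, t, s, n, i], eye.nflt_profile])
    return observed - coeffs.beta @ delta


def mlr_reference_value(train_eyes, coeffs: MLRCoefficients):
    """Normal reference per target: participant-weighted mean of adjusted
    training eyes."""
    w = participant_weights(train_eyes)
    adjusted = np.stack([adjust_to_reference(e, coeffs) for e in train_eyes])
    return (w[:, None] * adjusted).sum(axis=0) / w.sum()


def predict_reference_for_eye(eye, coeffs: MLRCoefficients, reference_value):
    """Per-eye predicted thickness: the reference value moved back to the
    eye's covariates (the inverse of `adjust_to_reference`), so that
    observed - predicted == adjusted - reference."""
    adj = adjust_to_reference(eye, coeffs)
    o, t, s, n, i = quadrant_means(eye.nflt_profile)
    observed = np.concatenate([[o, t, s, n, i], eye.nflt_profile])
    return reference_value + (observed - adj)
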