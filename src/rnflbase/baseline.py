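"""Generating stage: the individualized baseline profile.

Only the VP encoder and the NFLT decoder are used. The thickness latent
is forced to Z1 = 0 (the latent-mean shortcut for averaging decodes over
z1 ~ N(0, I)) and the vascular latent to Z2 = mu2, the VP encoder's mean
vector, with no sampling — so the baseline is a deterministic function
of the eye and the checkpoint. Dropout is disabled at inference.

The optional cross-cohort adjustment rescales a baseline pointwise by
the ratio of emmetropic population-mean profiles between a target cohort
and the training cohort (e.g. to transfer across races); the raw ratio
is smoothed with a short circular moving average because pointwise
ratios of small-sample means are noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cvae import DualCVAE, make_conditions
from .prep import quadrant_means


@dataclass
class BaselineReference:
    profile: np.ndarray          # (N,) um
    overall: float
    temporal: float
    superior: float
    nasal: float
    inferior: float
    variant: str
    checkpoint_id: str = ""
    adjustment: str = "none"     # "none" | "cross_cohort"

    @classmethod
    def from_profile(cls, profile, variant, checkpoint_id="", adjustment="none"):
        o, t, s, n, i = quadrant_means(profile)
        return cls(profile=np.asarray(profile, dtype=float), overall=o,
                   temporal=t, superior=s, nasal=n, inferior=i,
                   variant=variant, checkpoint_id=checkpoint_id,
                   adjustment=adjustment)


def _encode_mu2(eye, model: DualCVAE, rcnn):
    stats = model.stats
    cond = make_conditions(eye, model.variant, stats, rcnn)[None]
    from .nnet import autograd as ag
    xv = ag.constant(eye.vp_profile.astype(float)[None, :, None])
    mu2, _, _ = model.encode_vp(xv, ag.constant(cond), training=False)
    return mu2.data, cond


def generate_baseline(eye, model: DualCVAE, rcnn=None,
                      checkpoint_id="", stats_hash=None) -> BaselineReference:
    """Deterministic individualized baseline for one prepped eye
    (vessel-normalized, measured scale); bit-identical across calls."""
    if model.variant == "reg" and rcnn is None:
        raise ValueError("REG variant requires an rcnn model")
    if stats_hash is not None and stats_hash != model.stats.content_hash():
        raise ValueError("standardization stats hash mismatch between "
                         "eye preprocessing and checkpoint")
    mu2, cond = _encode_mu2(eye, model, rcnn)
    if model.hp.ablate_vp_coupling:
        mu2 = np.zeros_like(mu2)
    z1 = np.zeros((1, model.hp.latent_nfl))
    z_prof = model.decode_nfl(z1, mu2, cond).data[0]
    profile = model.stats.profile_inverse(z_prof)
    return BaselineReference.from_profile(profile, model.variant, checkpoint_id)


def mc_average_baseline(eye, model: DualCVAE, n_samples, rng, rcnn=None):
    """Monte-Carlo reference: mean over n_samples decodes with
    z1 ~ N(0, I) and Z2 = mu2 fixed. Validates the Z1 = 0 shortcut."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mu2, cond = _encode_mu2(eye, model, rcnn)
    z1 = rng.standard_normal((n_samples, model.hp.latent_nfl))
    z2 = np.repeat(mu2, n_samples, axis=0)
    c = np.repeat(cond, n_samples, axis=0)
    profs = model.decode_nfl(z1, z2, c).data
    return model.stats.profile_inverse(profs.mean(axis=0))


def smooth_ratio_profile(target_mean_profile, train_mean_profile, window=5):
    """Pointwise emmetropia-mean ratio, circularly smoothed."""
    ratio = np.asarray(target_mean_profile, dtype=float) / \
        np.asarray(train_mean_profile, dtype=float)
    if window > 1:
        kernel = np.ones(window) / window
        n = len(ratio)
        padded = np.concatenate([ratio[-(window // 2):], ratio,
                                 ratio[:window // 2]])
        ratio = np.convolve(padded, kernel, mode="valid")[:n]
    return ratio


def cross_cohort_adjust(baseline: BaselineReference, ratio_profile):
    """Proportional adjustment: profile * ratio, summaries recomputed."""
    ratio = np.asarray(ratio_profile, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("ratio_profile entries must be positive")
    if len(ratio) != len(baseline.profile):
        raise ValueError("ratio_profile length mismatch")
    return BaselineReference.from_profile(
        baseline.profile * ratio, baseline.variant,
        checkpoint_id=baseline.checkpoint_id, adjustment="cross_cohort")
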