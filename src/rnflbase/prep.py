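"""Preprocessing: quality filtering, vessel-width normalization, feature
standardization, refraction grouping and quadrant summaries.

Scan-quality rule: a scan is rejected when its signal strength index is
below 35, when the acquisition flagged retina cropping, or when the
overall mean thickness falls more than 4 population standard deviations
below the healthy-population mean (the extreme-thinness exclusion).

Vessel-width normalization keeps a constant ratio of vessel to
non-vessel pixels so that disease-related vessel attenuation cannot leak
into the generated baseline: every vessel run is rescaled about its own
center by a common factor and integerized by largest-remainder
apportionment (each surviving vessel keeps at least one pixel).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .records import EyeRecord, copy_record


class RefractionGroup(str, enum.Enum):
    high_myopia = "high_myopia"
    low_myopia = "low_myopia"
    emmetropia = "emmetropia"
    hyperopia = "hyperopia"


def assign_refraction_group(se: float) -> RefractionGroup:
    """Partition of the SE axis: <-6 / [-6,-1) / [-1,1] / >1 diopters.

    Boundaries are assigned to the less extreme group (ties at -6 go to
    low myopia, at -1 and +1 to emmetropia).
    """
    if not np.isfinite(se):
        raise ValueError("SE must be finite")
    if se < -6.0:
        return RefractionGroup.high_myopia
    if se < -1.0:
        return RefractionGroup.low_myopia
    if se <= 1.0:
        return RefractionGroup.emmetropia
    return RefractionGroup.hyperopia


# ---------------------------------------------------------------------------
# quality filter

SSI_MIN = 35.0
THIN_SD_MULTIPLE = 4.0


@dataclass
class PopulationStats:
    """Mean and SD of overall thickness in the healthy training pool."""
    overall_mean: float
    overall_sd: float

    @classmethod
    def from_records(cls, eyes):
        overall = np.array([float(np.mean(e.nflt_profile)) for e in eyes])
        return cls(overall_mean=float(overall.mean()), overall_sd=float(overall.std()))


def quality_filter(eye: EyeRecord, population_stats: PopulationStats):
    """Return (accepted, reason). Reasons: low_ssi | cropping | extreme_thin
    | missing_field | ok. Decisions depend only on the eye and the frozen
    population stats, so they are order-independent across a cohort."""
    if eye.ssi is None or not np.isfinite(eye.ssi):
        return False, "missing_field"
    if eye.ssi < SSI_MIN:
        return False, "low_ssi"
    if eye.cropped:
        return False, "cropping"
    overall = float(np.mean(eye.nflt_profile))
    floor = population_stats.overall_mean - THIN_SD_MULTIPLE * population_stats.overall_sd
    if overall < floor:
        return False, "extreme_thin"
    return True, "ok"


def filter_cohort(eyes, population_stats=None):
    """Apply the quality filter; returns (kept, log) where log rows are
    (eye_id, accepted, reason)."""
    if population_stats is None:
        population_stats = PopulationStats.from_records(eyes)
    kept, log = [], []
    for e in eyes:
        ok, reason = quality_filter(e, population_stats)
        log.append((e.eye_id, ok, reason))
        if ok:
            kept.append(e)
    return kept, log


# ---------------------------------------------------------------------------
# vessel-width normalization

def _find_runs_circular(vp):
    """Maximal runs of 1s on a circular binary array.

    Returns a list of (start, width); a run may wrap past the end. If the
    whole array is 1 a single full-length run is returned.
    """
    vp = np.asarray(vp).astype(int)
    n = len(vp)
    if vp.sum() == n:
        return [(0, n)]
    # rotate so position 0 is a zero, find linear runs, rotate back
    zero = int(np.argmin(vp))
    rolled = np.roll(vp, -zero)
    runs = []
    diff = np.diff(np.concatenate(([0], rolled, [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        runs.append(((s + zero) % n, e - s))
    runs.sort()
    return runs


def normalize_vessel_widths(vp_profile, target_ratio: float = 0.25):
    """Rescale every vessel run about its own center so the total vessel
    pixel count is exactly round(target_ratio * N).

    Widths are apportioned by largest remainder with each surviving run
    keeping >= 1 pixel; remainder ties break toward the wider original
    run. Already-normalized input is returned unchanged (fixed point,
    which also makes the operation idempotent).
    """
    vp = np.asarray(vp_profile).astype(int)
    n = len(vp)
    if not 0.0 < target_ratio < 1.0:
        raise ValueError("target_ratio must be in (0, 1)")
    runs = _find_runs_circular(vp)
    if not runs:
        raise ValueError("no_vessels")
    target_total = int(round(target_ratio * n))
    total = int(vp.sum())
    if total == target_total:
        return vp.copy()
    if target_total < len(runs):
        raise ValueError("ratio_too_small")

    widths = np.array([w for _, w in runs], dtype=float)
    scaled = widths * (target_total / total)
    floors = np.maximum(np.floor(scaled).astype(int), 1)
    # floors may overshoot when many runs are pinned at 1
    while floors.sum() > target_total:
        shrinkable = np.flatnonzero(floors > 1)
        j = shrinkable[np.argmin(scaled[shrinkable] - floors[shrinkable])]
        floors[j] -= 1
    remainders = scaled - floors
    extra = target_total - int(floors.sum())
    # largest remainder first; ties toward the wider original run
    order = sorted(range(len(runs)),
                   key=lambda i: (-remainders[i], -widths[i], i))
    new_widths = floors.copy()
    for i in order[:extra]:
        new_widths[i] += 1

    centers = [s + (w - 1) / 2.0 for s, w in runs]  # may exceed n (wrap runs)
    out = np.zeros(n, dtype=int)
    placed = []  # (start, width) already placed, in circular pixel terms
    for c, w in sorted(zip(centers, new_widths)):
        start = int(round(c - (w - 1) / 2.0))
        start = _resolve_collision(placed, start, w, n)
        for k in range(w):
            out[(start + k) % n] = 1
        placed.append((start, w))
    assert out.sum() == target_total, "apportionment lost pixels to overlap"
    return out


def _resolve_collision(placed, start, w, n):
    """Shift a run minimally so it does not overlap previously placed runs."""
    def overlaps(s):
        cells = {(s + k) % n for k in range(w)}
        for ps, pw in placed:
            if cells & {(ps + k) % n for k in range(pw)}:
                return True
        return False
    if not overlaps(start):
        return start
    for delta in range(1, n):
        for s in (start + delta, start - delta):
            if not overlaps(s):
                return s
    raise ValueError("ratio_too_small")  # no free slot: circle saturated


# ---------------------------------------------------------------------------
# standardization

SCALAR_FEATURES = ("age", "sex", "ssi", "disc_area", "al", "se")


@dataclass
class StandardizationStats:
    """Frozen z-scoring statistics, estimated on training data only."""
    scalar_mean: dict = field(default_factory=dict)
    scalar_sd: dict = field(default_factory=dict)
    profile_mean: float = 0.0
    profile_sd: float = 1.0

    @classmethod
    def fit(cls, eyes):
        stats = cls()
        for feat in SCALAR_FEATURES:
            vals = np.array([float(getattr(e, feat)) for e in eyes])
            m, s = float(vals.mean()), float(vals.std())
            if s <= 0:
                raise ValueError(f"degenerate feature with zero SD: {feat}")
            stats.scalar_mean[feat] = m
            stats.scalar_sd[feat] = s
        allp = np.concatenate([e.nflt_profile for e in eyes])
        stats.profile_mean = float(allp.mean())
        stats.profile_sd = float(allp.std())
        if stats.profile_sd <= 0:
            raise ValueError("degenerate feature with zero SD: nflt_profile")
        return stats

    def scalar(self, eye, feat):
        return (float(getattr(eye, feat)) - self.scalar_mean[feat]) / self.scalar_sd[feat]

    def scalar_value(self, value, feat):
        return (value - self.scalar_mean[feat]) / self.scalar_sd[feat]

    def profile(self, p):
        return (np.asarray(p, dtype=float) - self.profile_mean) / self.profile_sd

    def profile_inverse(self, z):
        return np.asarray(z, dtype=float) * self.profile_sd + self.profile_mean

    def content_hash(self) -> str:
        import hashlib
        import json
        payload = json.dumps({
            "m": {k: round(v, 12) for k, v in sorted(self.scalar_mean.items())},
            "s": {k: round(v, 12) for k, v in sorted(self.scalar_sd.items())},
            "pm": round(self.profile_mean, 12), "ps": round(self.profile_sd, 12),
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self):
        return {"scalar_mean": self.scalar_mean, "scalar_sd": self.scalar_sd,
                "profile_mean": self.profile_mean, "profile_sd": self.profile_sd}

    @classmethod
    def from_dict(cls, d):
        return cls(scalar_mean=dict(d["scalar_mean"]), scalar_sd=dict(d["scalar_sd"]),
                   profile_mean=float(d["profile_mean"]), profile_sd=float(d["profile_sd"]))


def standardize(eyes, stats: StandardizationStats | None = None):
    """Fit stats on `eyes` when absent, then return standardized copies
    (scalars and profile z-scored) plus the stats used.

    The inverse transform is :meth:`StandardizationStats.profile_inverse`
    for profiles and mean/SD re-scaling for scalars.
    """
    fitted = stats is None
    if fitted:
        stats = StandardizationStats.fit(eyes)
    out = []
    for e in eyes:
        c = copy_record(e)
        for feat in SCALAR_FEATURES:
            setattr(c, feat, stats.scalar(e, feat))
        c.nflt_profile = stats.profile(e.nflt_profile)
        out.append(c)
    return out, stats


# ---------------------------------------------------------------------------
# quadrant summaries

QUADRANTS = ("temporal", "superior", "nasal", "inferior")


def quadrant_means(nflt_profile):
    """(overall, temporal, superior, nasal, inferior) means of a TSNIT
    profile; temporal is the 90-degree arc centered on index 0."""
    p = np.asarray(nflt_profile, dtype=float)
    n = len(p)
    if n % 4:
        raise ValueError("profile length must be divisible by 4")
    q = n // 4
    rolled = np.roll(p, q // 2)  # temporal arc becomes the first block
    t, s, na, i = (rolled[k * q:(k + 1) * q].mean() for k in range(4))
    return float(p.mean()), float(t), float(s), float(na), float(i)


def prep_cohort(eyes, stats=None, population_stats=None, target_ratio=0.25):
    """filter -> vessel-normalize -> fit standardization stats.

    Returns (prepped, stats, filter_log). Prepped records stay on the
    measured scale; the fitted (or passed-through, for test folds)
    :class:`StandardizationStats` are applied by the models themselves,
    so the z-scoring is always done with frozen training statistics.
    """
    kept, log = filter_cohort(eyes, population_stats)
    if not kept:
        raise ValueError("no eyes after filtering")
    normed = []
    for e in kept:
        c = copy_record(e)
        c.vp_profile = normalize_vessel_widths(e.vp_profile, target_ratio)
        normed.append(c)
    if stats is None:
        stats = StandardizationStats.fit(normed)
    return normed, stats, log
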