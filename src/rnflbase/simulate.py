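"""Synthetic cohort generator with known ground truth.

The clinical cohorts behind the method are not public, so recovery tests
run on simulated eyes that embody the statistical structure the models
assume:

* a canonical TSNIT thickness profile — a temporal/nasal floor plus
  superior and inferior wrapped-Gaussian arcuate bumps whose centers are
  the eye's major vascular arcade angles (vessel-collocated peaks);
* transverse-magnification scaling — the nominal 3.4 mm scan circle
  lands at radius r = r0 * (AL / AL_ref), and thickness falls roughly
  reciprocally with radius, so the whole profile scales by AL_ref / AL
  (``al_mode="reciprocal"``); alternatively a piecewise-linear AL effect
  with separate myopic/hyperopic slopes (``al_mode="linear"``) for
  exercising the broken-stick regression;
* additive covariate effects (age, sex, SSI) applied uniformly along the
  profile, with defaults matching the overall-average slopes reported
  for the source population (-0.14 um/yr age, +0.89 um female,
  +0.04 um/SSI-unit);
* three noise tiers: a participant-level offset shared by both eyes, an
  eye-level offset, and i.i.d. pointwise measurement noise;
* per-group marginals (age, sex, AL, SE, disc area) matching the
  published cohort table, with SE generated from AL through a linear
  link so the SE/AL coupling the broken-stick model needs is present.

All profiles are stored in right-eye TSNIT orientation (index 0 =
temporal midpoint, superior at 90 deg); left eyes are generated mirrored
and stored already-mirrored, so laterality never changes the convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0 as bessel_i0

from .records import EyeRecord, SimTruth

AL_REF_MM = 23.82  # emmetropic model-eye axial length giving unit magnification


@dataclass
class GroupParams:
    """Marginal distributions of one refraction group (means/SDs)."""
    frac: float
    age: tuple[float, float]
    female_frac: float
    al: tuple[float, float]
    se: tuple[float, float]
    disc_area: tuple[float, float]


# Group marginals follow the published healthy-cohort table
# (hyperopia / emmetropia / low myopia / high myopia).
_DEFAULT_GROUPS = {
    "hyperopia":   GroupParams(0.118, (59.2, 11.2), 0.522, (23.3, 1.2), (2.0, 1.5), (2.2, 0.4)),
    "emmetropia":  GroupParams(0.348, (49.9, 13.6), 0.618, (23.6, 1.0), (0.1, 0.5), (2.2, 0.4)),
    "low_myopia":  GroupParams(0.442, (41.9, 13.8), 0.544, (25.1, 0.9), (-3.1, 1.4), (1.9, 0.4)),
    "high_myopia": GroupParams(0.092, (41.1, 11.5), 0.566, (26.6, 1.0), (-7.8, 1.6), (1.7, 0.4)),
}


@dataclass
class SimConfig:
    n_participants: int = 400
    two_eye_fraction: float = 0.68
    n_points: int = 128                     # N samples on the 3.4 mm circle
    seed: int = 17

    groups: dict = field(default_factory=lambda: {k: dataclasses.replace(v)
                                                  for k, v in _DEFAULT_GROUPS.items()})
    # within-group SE/AL correlation; across groups the strong negative
    # SE-AL link emerges from the group means themselves
    rho_se_al: float = -0.6

    # canonical profile shape (um), calibrated so the emmetropic reference
    # eye reproduces the published quadrant means
    floor: float = 72.86
    nasal_tilt: float = 1.14                # temporal minus nasal half-difference
    amp_superior: float = 85.08
    amp_inferior: float = 89.86
    bump_kappa: float = 6.0                 # wrapped-Gaussian concentration
    arcade_sup: tuple[float, float] = (90.0, 12.0)   # mean, SD degrees (participant level)
    arcade_inf: tuple[float, float] = (270.0, 12.0)
    arcade_eye_sd: float = 3.0              # within-participant arcade jitter, degrees

    # covariate effects, uniform along the profile (reference covariates)
    slope_age: float = -0.14                # um / yr
    offset_female: float = 0.89             # um
    slope_ssi: float = 0.04                 # um / SSI unit
    age_ref: float = 50.0
    ssi_ref: float = 65.0
    ssi_dist: tuple[float, float] = (65.0, 8.0)
    ssi_clip: tuple[float, float] = (38.0, 95.0)

    # axial-length effect
    al_mode: str = "reciprocal"             # "reciprocal" | "linear"
    slope_al_myopia: float = -2.65          # um / mm, used when al_mode="linear"
    slope_al_hyperopia: float = -1.47
    al_eye_sd: float = 0.25                 # within-participant AL spread, mm

    # vessels (profile pixels); a major artery/vein pair flanks each arcade
    major_width: tuple[int, int] = (4, 7)   # inclusive integer range
    minor_width: tuple[int, int] = (2, 4)
    major_offset_deg: float = 9.0           # pair half-separation around arcade
    n_minor: int = 2                        # small nasal vessels

    # annulus maps (radii span disc-centered diameters 2-4 mm)
    map_shape: tuple[int, int] = (16, 64)   # (radii, angles)
    rpe_curv_base: float = 10.0             # um
    rpe_curv_per_mm: float = 8.0            # um per mm of AL above reference
    rpe_noise_sd: float = 2.0               # um

    # noise tiers (um)
    noise_point_sd: float = 8.0
    noise_eye_sd: float = 3.0
    noise_participant_sd: float = 4.0
    min_thickness: float = 1.0              # clip floor after noise

    def validate(self):
        fracs = [g.frac for g in self.groups.values()]
        if abs(sum(fracs) - 1.0) > 1e-8:
            raise ValueError("group fractions must sum to 1")
        for name in ("noise_point_sd", "noise_eye_sd", "noise_participant_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.al_mode not in ("reciprocal", "linear"):
            raise ValueError(f"unknown al_mode {self.al_mode!r}")
        if self.n_points % 4:
            raise ValueError("n_points must be divisible by 4")

    # -- analytic moments of the canonical shape ------------------------
    def canonical_overall(self, al: float = AL_REF_MM) -> float:
        """Expected overall mean thickness of the noiseless baseline at the
        reference covariates, for a (male, age_ref, ssi_ref) eye."""
        mean_bump = float(np.exp(-self.bump_kappa) * bessel_i0(self.bump_kappa))
        overall = self.floor + (self.amp_superior + self.amp_inferior) * mean_bump
        if self.al_mode == "reciprocal":
            overall *= AL_REF_MM / al
        return overall

    @classmethod
    def mlr_recovery(cls, n_participants=1190, seed=17, **kw):
        """Cohort for broken-stick regression recovery: linear AL effect
        with the published myopic/hyperopic slopes."""
        return cls(n_participants=n_participants, seed=seed,
                   al_mode="linear", **kw)


def _theta_deg(n_points):
    return np.arange(n_points) * 360.0 / n_points


def _bump(theta_deg, center_deg, kappa):
    """Wrapped-Gaussian (von-Mises-shaped) bump, peak value 1."""
    d = np.deg2rad(theta_deg - center_deg)
    return np.exp(kappa * (np.cos(d) - 1.0))


def _place_run(vp, center_deg, width, n):
    c = int(round(center_deg / 360.0 * n)) % n
    start = c - (width - 1) // 2
    for k in range(width):
        vp[(start + k) % n] = 1


def sample_participant(config: SimConfig, rng, pid: str, group=None) -> dict:
    """Draw participant-level covariates shared by both eyes (refraction
    stratum, demographics, axial length, arcade anatomy, random effect).
    `group` forces the stratum (for stratified sampling in tests)."""
    if group is None:
        names = list(config.groups)
        fracs = np.array([config.groups[k].frac for k in names])
        group = names[rng.choice(len(names), p=fracs / fracs.sum())]
    g = config.groups[group]
    return {
        "participant_id": pid,
        "group": group,
        "age": float(np.clip(rng.normal(*g.age), 18.0, 95.0)),
        "sex": int(rng.random() < g.female_frac),
        "al_part": float(rng.normal(*g.al)),
        "arcade_sup": float(rng.normal(*config.arcade_sup)),
        "arcade_inf": float(rng.normal(*config.arcade_inf)),
        "part_offset": float(rng.normal(0.0, config.noise_participant_sd))
        if config.noise_participant_sd > 0 else 0.0,
    }


def sample_eye(config: SimConfig, participant: dict, rng,
               eye: str = "right") -> tuple[EyeRecord, SimTruth]:
    """Sample one eye given participant covariates. Deterministic for a
    given rng state; the returned SimTruth holds the noiseless baseline."""
    n = config.n_points
    g = config.groups[participant["group"]]

    al = participant["al_part"] + rng.normal(0.0, config.al_eye_sd)
    rho = config.rho_se_al
    se = (g.se[0] + rho * g.se[1] / g.al[1] * (al - g.al[0])
          + rng.normal(0.0, g.se[1] * np.sqrt(1.0 - rho ** 2)))
    disc_area = float(np.clip(rng.normal(*g.disc_area), 0.8, 4.0))
    ssi = float(np.clip(rng.normal(*config.ssi_dist), *config.ssi_clip))

    jitter = config.arcade_eye_sd
    th_sup = participant["arcade_sup"] + (rng.normal(0.0, jitter) if jitter else 0.0)
    th_inf = participant["arcade_inf"] + (rng.normal(0.0, jitter) if jitter else 0.0)

    theta = _theta_deg(n)
    shape = (config.floor + config.nasal_tilt * np.cos(np.deg2rad(theta))
             + config.amp_superior * _bump(theta, th_sup, config.bump_kappa)
             + config.amp_inferior * _bump(theta, th_inf, config.bump_kappa))

    scale = al / AL_REF_MM  # scan-circle radius relative to the reference eye
    if config.al_mode == "reciprocal":
        baseline = shape / scale
    else:
        slope = config.slope_al_myopia if se < 0 else config.slope_al_hyperopia
        baseline = shape + slope * (al - AL_REF_MM)

    baseline = (baseline
                + config.slope_age * (participant["age"] - config.age_ref)
                + config.offset_female * participant["sex"]
                + config.slope_ssi * (ssi - config.ssi_ref))
    baseline = np.maximum(baseline, config.min_thickness)

    eye_offset = rng.normal(0.0, config.noise_eye_sd) if config.noise_eye_sd > 0 else 0.0
    point_noise = (rng.normal(0.0, config.noise_point_sd, size=n)
                   if config.noise_point_sd > 0 else np.zeros(n))
    observed = baseline + participant["part_offset"] + eye_offset + point_noise
    observed = np.maximum(observed, config.min_thickness)

    # vessels: artery/vein pair flanking each arcade + minor nasal vessels
    vp = np.zeros(n, dtype=int)
    widths = []
    for th in (th_sup, th_inf):
        for sign in (-1.0, 1.0):
            w = int(rng.integers(config.major_width[0], config.major_width[1] + 1))
            _place_run(vp, th + sign * config.major_offset_deg, w, n)
            widths.append((th + sign * config.major_offset_deg, w))
    for _ in range(config.n_minor):
        th = rng.uniform(150.0, 210.0)
        w = int(rng.integers(config.minor_width[0], config.minor_width[1] + 1))
        _place_run(vp, th, w, n)
        widths.append((th, w))

    vp_map, rpe_map = _make_maps(config, rng, widths, al)

    record = EyeRecord(
        participant_id=participant["participant_id"], eye=eye,
        age=participant["age"], sex=participant["sex"],
        al=float(al), se=float(se), disc_area=disc_area, ssi=ssi,
        nflt_profile=observed, vp_profile=vp,
        vp_map=vp_map, rpe_map=rpe_map,
    )
    truth = SimTruth(
        baseline_profile=baseline,
        arcade_angles=(float(th_sup % 360.0), float(th_inf % 360.0)),
        magnification_scale=float(scale),
        covariate_slopes={"age": config.slope_age, "female": config.offset_female,
                          "ssi": config.slope_ssi},
    )
    return record, truth


def _make_maps(config, rng, vessel_widths, al):
    """Polar annulus maps: binary vessel stripes and an RPE elevation dome
    whose curvature grows with axial length (the rCNN's signal)."""
    n_r, n_a = config.map_shape
    vp_map = np.zeros((n_r, n_a), dtype=np.int8)
    for th, w in vessel_widths:
        c = int(round(th / 360.0 * n_a)) % n_a
        w_map = max(1, round(w * n_a / config.n_points))
        for k in range(w_map):
            vp_map[:, (c - (w_map - 1) // 2 + k) % n_a] = 1
    rho = np.linspace(0.0, 1.0, n_r)[:, None]      # radial position in annulus
    curv = config.rpe_curv_base + config.rpe_curv_per_mm * (al - AL_REF_MM)
    rpe = curv * (rho - 0.5) ** 2 * np.ones((1, n_a))
    rpe = rpe + rng.normal(0.0, config.rpe_noise_sd, size=(n_r, n_a))
    return vp_map, rpe


def generate_cohort(config: SimConfig) -> tuple[list[EyeRecord], list[SimTruth]]:
    """Generate the full cohort; deterministic for a fixed config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    eyes, truths = [], []
    for i in range(config.n_participants):
        part = sample_participant(config, rng, pid=f"P{i:05d}")
        both = rng.random() < config.two_eye_fraction
        sides = ("right", "left") if both else (("right",) if rng.random() < 0.5
                                                else ("left",))
        for side in sides:
            rec, tr = sample_eye(config, part, rng, eye=side)
            eyes.append(rec)
            truths.append(tr)
    return eyes, truths
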