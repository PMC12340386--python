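"""Per-eye data records and cohort I/O.

An :class:`EyeRecord` is the universal input unit: the circumpapillary
nerve-fiber-layer thickness (NFLT) profile sampled on the 3.4 mm circle,
the binary vascular-pattern (VP) profile on the same circle, small polar
annulus maps around the disc (VP occupancy and RPE elevation over
diameters 2-4 mm), and the scalar covariates used as model conditions.

Profiles are stored in TSNIT angular order with index 0 at the temporal
midpoint, right-eye orientation; left eyes are mirrored at generation
time and stored already-mirrored.

Cohort I/O: scalars + profiles go to a flat CSV (one row per eye); the
2-D maps and simulation ground truth go to an HDF5 archive keyed by eye
id (columns ``nflt_000..`` / ``vp_000..``; HDF5 groups ``maps/<eye_id>``
and ``truth/<eye_id>``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class EyeRecord:
    participant_id: str
    eye: str                    # "left" | "right"
    age: float                  # years
    sex: int                    # 1 = female
    al: float                   # axial length, mm
    se: float                   # spherical equivalent, diopters
    disc_area: float            # mm^2
    ssi: float                  # signal strength index, 0-100
    nflt_profile: np.ndarray    # (N,) um on the 3.4 mm circle
    vp_profile: np.ndarray      # (N,) binary
    vp_map: np.ndarray | None = None    # (R, A) binary annulus map
    rpe_map: np.ndarray | None = None   # (R, A) elevation, um
    cropped: bool = False       # acquisition retina-cropping flag

    @property
    def eye_id(self) -> str:
        return f"{self.participant_id}_{self.eye}"

    def validate(self):
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be left|right, got {self.eye!r}")
        if not 0.0 <= self.ssi <= 100.0:
            raise ValueError(f"ssi out of [0, 100]: {self.ssi}")
        if np.any(self.nflt_profile <= 0):
            raise ValueError("nflt_profile must be strictly positive")
        if not np.isin(self.vp_profile, (0, 1)).all():
            raise ValueError("vp_profile must be binary")
        if len(self.nflt_profile) != len(self.vp_profile):
            raise ValueError("profile length mismatch")


@dataclass
class SimTruth:
    """Noiseless generative state of a simulated eye (the recovery oracle)."""

    baseline_profile: np.ndarray        # (N,) um, noiseless
    arcade_angles: tuple[float, float]  # superior, inferior centers (deg)
    magnification_scale: float          # r / r0 (> 0)
    covariate_slopes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cohort <-> table

_SCALAR_COLS = ["participant_id", "eye", "age", "sex", "al", "se",
                "disc_area", "ssi", "cropped"]


def cohort_to_frame(eyes: list[EyeRecord]) -> pd.DataFrame:
    if not eyes:
        return pd.DataFrame(columns=_SCALAR_COLS)
    n = len(eyes[0].nflt_profile)
    rows = []
    for e in eyes:
        row = {c: getattr(e, c) for c in _SCALAR_COLS}
        row.update({f"nflt_{i:03d}": e.nflt_profile[i] for i in range(n)})
        row.update({f"vp_{i:03d}": int(e.vp_profile[i]) for i in range(n)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[EyeRecord]:
    nflt_cols = sorted(c for c in df.columns if c.startswith("nflt_"))
    vp_cols = sorted(c for c in df.columns if c.startswith("vp_"))
    eyes = []
    for _, row in df.iterrows():
        eyes.append(EyeRecord(
            participant_id=str(row["participant_id"]),
            eye=str(row["eye"]),
            age=float(row["age"]), sex=int(row["sex"]),
            al=float(row["al"]), se=float(row["se"]),
            disc_area=float(row["disc_area"]), ssi=float(row["ssi"]),
            nflt_profile=row[nflt_cols].to_numpy(dtype=float),
            vp_profile=row[vp_cols].to_numpy(dtype=float).round().astype(int),
            cropped=bool(row.get("cropped", False)),
        ))
    return eyes


def save_cohort(eyes, truths, out_dir, maps=True):
    """Write cohort CSV plus an HDF5 archive of maps and ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(eyes).to_csv(out_dir / "cohort.csv", index=False)
    with h5py.File(out_dir / "arrays.h5", "w") as f:
        for e, t in zip(eyes, truths if truths else [None] * len(eyes)):
            if maps and e.vp_map is not None:
                g = f.create_group(f"maps/{e.eye_id}")
                g.create_dataset("vp_map", data=e.vp_map, compression="gzip")
                g.create_dataset("rpe_map", data=e.rpe_map, compression="gzip")
            if t is not None:
                g = f.create_group(f"truth/{e.eye_id}")
                g.create_dataset("baseline_profile", data=t.baseline_profile)
                g.attrs["arcade_sup"] = t.arcade_angles[0]
                g.attrs["arcade_inf"] = t.arcade_angles[1]
                g.attrs["magnification_scale"] = t.magnification_scale
    return out_dir


def load_cohort(in_dir):
    """Inverse of :func:`save_cohort`; returns (eyes, truths_or_None)."""
    in_dir = Path(in_dir)
    eyes = frame_to_cohort(pd.read_csv(in_dir / "cohort.csv"))
    truths = None
    h5path = in_dir / "arrays.h5"
    if h5path.exists():
        truths = []
        with h5py.File(h5path, "r") as f:
            for e in eyes:
                if "maps" in f and e.eye_id in f["maps"]:
                    g = f[f"maps/{e.eye_id}"]
                    e.vp_map = g["vp_map"][()]
                    e.rpe_map = g["rpe_map"][()]
                if "truth" in f and e.eye_id in f["truth"]:
                    g = f[f"truth/{e.eye_id}"]
                    truths.append(SimTruth(
                        baseline_profile=g["baseline_profile"][()],
                        arcade_angles=(float(g.attrs["arcade_sup"]),
                                       float(g.attrs["arcade_inf"])),
                        magnification_scale=float(g.attrs["magnification_scale"]),
                    ))
        if not truths:
            truths = None
    return eyes, truths


def copy_record(e: EyeRecord) -> EyeRecord:
    return dataclasses.replace(
        e,
        nflt_profile=np.array(e.nflt_profile),
        vp_profile=np.array(e.vp_profile),
        vp_map=None if e.vp_map is None else np.array(e.vp_map),
        rpe_map=None if e.rpe_map is None else np.array(e.rpe_map),
    )
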