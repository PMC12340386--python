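"""Pipeline orchestration: simulate -> prep -> train -> generate ->
evaluate from one YAML config, with a run manifest.

The manifest records the config hash, per-stage seeds, every artifact
path with a content hash, and timestamps. Stages whose outputs already
exist with a matching config hash are skipped; deterministic stages
reproduce identical hashes when re-run.

Config schema (all sections optional; defaults shown in
``default_config``)::

    simulate: {n_participants, two_eye_fraction, seed, al_mode, ...}
    prep:     {target_ratio}
    train:    {variants: [base, mag, reg], seed, max_epochs, ...}
    evaluate: {k, seed, models: [...], max_epochs}
    out_dir:  path
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as ev
from .cvae import CVAEHyperParams, save_checkpoint, train_model
from .prep import PopulationStats, prep_cohort
from .rcnn import RCNNHyperParams, save_rcnn_checkpoint, train_rcnn
from .records import load_cohort, save_cohort
from .simulate import SimConfig, generate_cohort

_KNOWN_KEYS = {"simulate", "prep", "train", "evaluate", "out_dir"}


def default_config():
    return {
        "simulate": {"n_participants": 400, "seed": 17},
        "prep": {"target_ratio": 0.25},
        "train": {"variants": ["mag"], "seed": 7, "max_epochs": 60},
        "evaluate": {"k": 2, "seed": 3, "models": ["average", "mlr", "mag"],
                     "max_epochs": 60},
        "out_dir": "runs/default",
    }


def _config_hash(cfg) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def validate_config(cfg: dict):
    bad = sorted(set(cfg) - _KNOWN_KEYS)
    if bad:
        raise ValueError(f"unknown config keys: {bad}")
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    bad = sorted(set(cfg.get("simulate", {})) - sim_fields)
    if bad:
        raise ValueError(f"unknown simulate keys: {bad}")
    for v in cfg.get("train", {}).get("variants", []):
        if v not in ("base", "mag", "reg"):
            raise ValueError(f"unknown variant {v!r}")


class RunManifest:
    def __init__(self, path):
        self.path = Path(path)
        self.data = {"config_hash": None, "seeds": {}, "artifacts": {},
                     "tool_version": _version(), "timestamps": {},
                     "state": "running"}

    def record(self, stage, artifact_path):
        self.data["artifacts"][str(artifact_path)] = _file_hash(artifact_path)
        self.data["timestamps"][stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.save()

    def save(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _version():
    from . import __version__
    return __version__


def run_pipeline(config: dict | str | Path, force=False) -> RunManifest:
    """Execute the staged pipeline described by `config` (dict or YAML
    path); returns the RunManifest. Existing up-to-date artifacts are
    skipped unless `force`."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = default_config()
    for k, v in (config or {}).items():
        if isinstance(v, dict) and k in cfg:
            cfg[k].update(v)
        else:
            cfg[k] = v
    validate_config(cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    manifest = RunManifest(out / "manifest.json")
    manifest.data["config_hash"] = chash
    stamp = out / ".config_hash"
    up_to_date = (not force) and stamp.exists() and stamp.read_text() == chash

    try:
        # simulate
        cohort_dir = out / "cohort"
        sim_cfg = SimConfig(**cfg["simulate"])
        manifest.data["seeds"]["simulate"] = sim_cfg.seed
        if not (up_to_date and (cohort_dir / "cohort.csv").exists()):
            eyes, truths = generate_cohort(sim_cfg)
            save_cohort(eyes, truths, cohort_dir)
        eyes, truths = load_cohort(cohort_dir)
        manifest.record("simulate", cohort_dir / "cohort.csv")

        # prep
        pop = PopulationStats.from_records(eyes)
        prepped, stats, log = prep_cohort(
            eyes, population_stats=pop,
            target_ratio=cfg["prep"]["target_ratio"])
        prep_log = out / "filter_log.csv"
        with open(prep_log, "w") as f:
            f.write("eye_id,accepted,reason\n")
            for eid, ok, reason in log:
                f.write(f"{eid},{int(ok)},{reason}\n")
        manifest.record("prep", prep_log)

        # train requested variants on the full cohort
        tcfg = cfg["train"]
        manifest.data["seeds"]["train"] = tcfg["seed"]
        hp = CVAEHyperParams(max_epochs=tcfg.get("max_epochs", 60),
                             n_points=sim_cfg.n_points)
        rcnn_model = None
        for variant in tcfg.get("variants", []):
            ckpt = out / f"model_{variant}.npz"
            if up_to_date and ckpt.exists():
                manifest.record(f"train_{variant}", ckpt)
                continue
            if variant == "reg" and rcnn_model is None:
                rcnn_model, _ = train_rcnn(prepped, RCNNHyperParams(
                    max_epochs=tcfg.get("max_epochs", 60)),
                    seed=tcfg["seed"] + 101, stats=stats)
                rpath = out / "rcnn.npz"
                save_rcnn_checkpoint(rcnn_model, rpath, chash)
                manifest.record("train_rcnn", rpath)
            model, tlog = train_model(prepped, variant, hp, seed=tcfg["seed"],
                                      stats=stats,
                                      rcnn=rcnn_model if variant == "reg" else None)
            save_checkpoint(model, ckpt, chash)
            tlog.to_csv(out / f"trainlog_{variant}.csv")
            manifest.record(f"train_{variant}", ckpt)

        # evaluate
        ecfg = cfg["evaluate"]
        manifest.data["seeds"]["evaluate"] = ecfg["seed"]
        report = ev.run_evaluation(
            eyes, k=ecfg["k"], seed=ecfg["seed"], models=tuple(ecfg["models"]),
            cvae_hp=CVAEHyperParams(max_epochs=ecfg.get("max_epochs", 60),
                                    n_points=sim_cfg.n_points),
            rcnn_hp=RCNNHyperParams(max_epochs=ecfg.get("max_epochs", 60)),
            target_ratio=cfg["prep"]["target_ratio"])
        rpath = out / "eval_report.json"
        rpath.write_text(json.dumps(report.to_dict(), indent=2))
        manifest.record("evaluate", rpath)
        _write_tables(report, out)
        manifest.record("tables", out / "prediction_error.csv")

        stamp.write_text(chash)
        manifest.data["state"] = "complete"
    except Exception:
        manifest.data["state"] = "failed"
        manifest.save()
        raise
    manifest.save()
    return manifest


def _write_tables(report, out):
    import pandas as pd
    rows = [{"model": m, **report.rms[m]} for m in report.models]
    pd.DataFrame(rows).to_csv(out / "prediction_error.csv", index=False)
    rows = []
    for m in report.models:
        for g, targets in report.fpr[m].items():
            rows.append({"model": m, "group": g, **targets})
    pd.DataFrame(rows).to_csv(out / "fpr.csv", index=False)
    rows = [{"model": m,
             **{t: float(np.mean(v)) for t, v in report.margins[m].items()}}
            for m in report.models]
    pd.DataFrame(rows).to_csv(out / "cutoff_margin.csv", index=False)
    pts = {m: report.rms_profile_points[m] for m in report.models}
    pd.DataFrame(pts).to_csv(out / "profile_error_points.csv", index=False)
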