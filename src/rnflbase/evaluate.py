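"""Cross-validated comparison of the five normal-reference models.

Models: population Average (no adjustment), MLR (broken-stick covariate
adjustment), and the three generative variants (BASE, MAG, REG). For
every model a per-eye *deviation score* d = observed - predicted
reference unifies the evaluation: prediction errors are weighted RMS of
d, the fifth-percentile cutoff is the empirical quantile of d in the
training-fold emmetropia pool, the false-positive rate is the fraction
of healthy test eyes with d below that cutoff, and the cutoff margin is
the training-emmetropia mean deviation minus the cutoff.

Cross-validation is grouped by participant (both eyes share a fold) so
between-eye correlation cannot leak across the train/test boundary.
Inferential machinery is replaced by participant-resampled percentile
bootstrap contrasts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cvae import CVAEHyperParams, participant_weights, train_model
from .baseline import generate_baseline
from .mlr import fit_mlr, mlr_reference_value, predict_reference_for_eye
from .prep import (PopulationStats, assign_refraction_group, prep_cohort,
                   quadrant_means)
from .rcnn import IdentityMagnification, RCNNHyperParams, train_rcnn

MODELS = ("average", "mlr", "base", "mag", "reg")
TARGETS = ("overall", "temporal", "superior", "nasal", "inferior")
GROUPS = ("hyperopia", "emmetropia", "low_myopia", "high_myopia")


# ---------------------------------------------------------------------------
# folds

@dataclass
class FoldAssignment:
    k: int
    assignment: dict        # participant_id -> fold index
    seed: int

    def fold_of(self, eye):
        return self.assignment[eye.participant_id]


def kfold_split(eyes, k, seed) -> FoldAssignment:
    """Participant-grouped k-fold partition; fold sizes differ by <= 1
    participant; deterministic under seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    pids = sorted({e.participant_id for e in eyes})
    if len(pids) < k:
        raise ValueError(f"need >= {k} participants, have {len(pids)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(pids)
    assignment = {}
    for fold, chunk in enumerate(np.array_split(pids, k)):
        for pid in chunk:
            assignment[pid] = fold
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# metrics

def prediction_error_rms(true_values, predicted, weights=None):
    """Weighted RMS of (true - predicted) along axis 0.

    For 2-D inputs (eyes x targets) returns per-target RMS; the pooled
    profile error is the root of the mean over points of the pointwise
    weighted mean squares.
    """
    t = np.asarray(true_values, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.size == 0:
        raise ValueError("empty set")
    w = np.ones(t.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    sq = (t - p) ** 2
    msq = (w.reshape(-1, *([1] * (sq.ndim - 1))) * sq).sum(axis=0) / w.sum()
    return np.sqrt(msq)


def pooled_profile_rms(pointwise_rms):
    """Pool per-point RMS into one number: root mean of pointwise mean
    squares."""
    r = np.asarray(pointwise_rms, dtype=float)
    return float(np.sqrt(np.mean(r ** 2)))


def percentile_cutoff(deviations, p=5.0):
    """Empirical quantile with linear interpolation (h = (n-1)p + 1)."""
    d = np.asarray(deviations, dtype=float)
    if len(d) < 20:
        raise ValueError("need >= 20 emmetropic training eyes for a cutoff")
    if not 0.0 < p < 100.0:
        raise ValueError("p must be in (0, 100)")
    return float(np.percentile(d, p))


def false_positive_rate(deviations, cutoff):
    """Fraction (and count) of healthy eyes below the cutoff; None when
    the group is empty (never reported as 0)."""
    d = np.asarray(deviations, dtype=float)
    if d.size == 0:
        return None, 0, 0
    flagged = int(np.sum(d < cutoff))
    return flagged / d.size, flagged, int(d.size)


def cutoff_margin(reference_mean, cutoff):
    """Reference mean minus cutoff; smaller = tighter detection
    threshold. Invariant to adding a constant to all deviations."""
    return float(reference_mean - cutoff)


def binomial_ci(p0, n, level=0.95):
    """Normal-approximation binomial CI for a proportion at truth p0."""
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p0 * (1.0 - p0) / n)
    return p0 - half, p0 + half


# ---------------------------------------------------------------------------
# per-model reference prediction

def _observed_matrix(eyes):
    rows = []
    for e in eyes:
        o, t, s, n, i = quadrant_means(e.nflt_profile)
        rows.append(np.concatenate([[o, t, s, n, i], e.nflt_profile]))
    return np.stack(rows)


def _dl_predictions(eyes, model, rcnn):
    rows = []
    for e in eyes:
        ref = generate_baseline(e, model, rcnn=rcnn)
        rows.append(np.concatenate([[ref.overall, ref.temporal, ref.superior,
                                     ref.nasal, ref.inferior], ref.profile]))
    return np.stack(rows)


class _FoldModels:
    """Everything fitted on one training fold."""

    def __init__(self, train_eyes, stats, models, cvae_hp, rcnn_hp, seed,
                 identity_rcnn=False):
        self.models = models
        w = participant_weights(train_eyes)
        obs = _observed_matrix(train_eyes)
        self.train_mean = (w[:, None] * obs).sum(axis=0) / w.sum()
        self.mlr = self.mlr_ref = None
        if "mlr" in models:
            self.mlr = fit_mlr(train_eyes)
            self.mlr_ref = mlr_reference_value(train_eyes, self.mlr)
        self.rcnn = None
        if "reg" in models:
            self.rcnn = (IdentityMagnification() if identity_rcnn
                         else train_rcnn(train_eyes, rcnn_hp, seed=seed + 101,
                                         stats=stats)[0])
        self.dl = {}
        for i, variant in enumerate(v for v in ("base", "mag", "reg")
                                    if v in models):
            self.dl[variant], _ = train_model(
                train_eyes, variant, cvae_hp, seed=seed + 7 * (i + 1),
                stats=stats, rcnn=self.rcnn if variant == "reg" else None)

    def predict(self, eyes, model_name):
        if model_name == "average":
            return np.tile(self.train_mean, (len(eyes), 1))
        if model_name == "mlr":
            return np.stack([predict_reference_for_eye(e, self.mlr, self.mlr_ref)
                             for e in eyes])
        variant = model_name
        return _dl_predictions(eyes, self.dl[variant],
                               self.rcnn if variant == "reg" else None)


# ---------------------------------------------------------------------------
# report

@dataclass
class EvalReport:
    models: tuple
    k: int
    seed: int
    n_points: int
    rms: dict = field(default_factory=dict)           # model -> target -> float
    rms_profile_points: dict = field(default_factory=dict)  # model -> (N,) list
    fpr: dict = field(default_factory=dict)           # model -> group -> target -> rate|None
    fpr_counts: dict = field(default_factory=dict)
    cutoffs: dict = field(default_factory=dict)       # model -> target -> per-fold list
    margins: dict = field(default_factory=dict)       # model -> target -> per-fold list
    contrasts: dict = field(default_factory=dict)     # "m_vs_average" -> {estimate, ci}
    flags: list = field(default_factory=list)

    def to_dict(self):
        return {"models": list(self.models), "k": self.k, "seed": self.seed,
                "n_points": self.n_points, "rms": self.rms,
                "rms_profile_points": self.rms_profile_points,
                "fpr": self.fpr, "fpr_counts": self.fpr_counts,
                "cutoffs": self.cutoffs, "margins": self.margins,
                "contrasts": self.contrasts, "flags": self.flags}


def _out_of_fit_deviations(train, stats, models, cvae_hp, rcnn_hp, seed,
                           identity_rcnn, predictions_hook):
    """Out-of-fit deviations for every training-fold eye via an inner
    2-fold split: each half is predicted by models fitted on the other
    half. This removes the within-fold memorization bias that makes
    in-fit deviations narrower than test deviations (and cutoffs too
    tight). Inner CVAE training is capped at 60 epochs to keep the
    inner models close to the outer regime at half the data."""
    inner = kfold_split(train, 2, seed=seed)
    inner_hp = dataclasses.replace(cvae_hp,
                                   max_epochs=min(cvae_hp.max_epochs, 60))
    dev = {m: np.zeros((len(train), 5 + cvae_hp.n_points)) for m in models}
    for j in range(2):
        itr = [e for e in train if inner.fold_of(e) != j]
        ite_idx = [i for i, e in enumerate(train) if inner.fold_of(e) == j]
        ite = [train[i] for i in ite_idx]
        ifitted = _FoldModels(itr, stats, models, inner_hp, rcnn_hp,
                              seed=seed + 10 * j,
                              identity_rcnn=identity_rcnn)
        obs = _observed_matrix(ite)
        for m in models:
            pred = ifitted.predict(ite, m)
            if predictions_hook is not None:
                pred = predictions_hook(m, ite, pred)
            dev[m][ite_idx] = obs - pred
    return dev


def run_evaluation(eyes, k=5, seed=3, models=MODELS, cvae_hp=None,
                   rcnn_hp=None, target_ratio=0.25, identity_rcnn=False,
                   honest_cutoffs=True, n_boot=1000,
                   predictions_hook=None) -> EvalReport:
    """Full cross-validated evaluation on a raw cohort.

    Per fold: quality-filter and vessel-normalize with training-fold
    population stats, fit standardization stats on the training fold,
    fit/train the requested models, predict references for the test
    fold, and pool deviations across folds. The fifth-percentile cutoff
    comes from the training-fold emmetropia pool; with `honest_cutoffs`
    those deviations are computed out-of-fit through an inner split
    (falling back to in-fit deviations, with a flag, when the fold is
    too small to refit). `predictions_hook(model_name, eyes, predicted)`
    lets callers substitute oracle predictions in tests.
    """
    cvae_hp = cvae_hp or CVAEHyperParams()
    rcnn_hp = rcnn_hp or RCNNHyperParams()
    folds = kfold_split(eyes, k, seed)

    pooled = {m: {"dev": [], "w": [], "group": [], "flag": [], "pid": []}
              for m in models}
    cutoffs = {m: {t: [] for t in TARGETS} for m in models}
    margins = {m: {t: [] for t in TARGETS} for m in models}
    flags = []

    for fold in range(k):
        train_raw = [e for e in eyes if folds.fold_of(e) != fold]
        test_raw = [e for e in eyes if folds.fold_of(e) == fold]
        pop = PopulationStats.from_records(train_raw)
        train, stats, _ = prep_cohort(train_raw, population_stats=pop,
                                      target_ratio=target_ratio)
        test, _, _ = prep_cohort(test_raw, stats=stats, population_stats=pop,
                                 target_ratio=target_ratio)
        fitted = _FoldModels(train, stats, models, cvae_hp, rcnn_hp,
                             seed=seed * 1000 + fold, identity_rcnn=identity_rcnn)

        obs_train = _observed_matrix(train)
        obs_test = _observed_matrix(test)
        w_test = participant_weights(test)
        groups_test = [assign_refraction_group(e.se).value for e in test]
        emm_train_idx = [i for i, e in enumerate(train)
                         if assign_refraction_group(e.se).value == "emmetropia"]

        cut_dev = None
        if honest_cutoffs:
            try:
                cut_dev = _out_of_fit_deviations(
                    train, stats, models, cvae_hp, rcnn_hp,
                    seed=seed * 77 + fold, identity_rcnn=identity_rcnn,
                    predictions_hook=predictions_hook)
            except ValueError as err:
                flags.append(f"fold {fold}: in-fit cutoffs ({err})")

        for m in models:
            pred_test = fitted.predict(test, m)
            if predictions_hook is not None:
                pred_test = predictions_hook(m, test, pred_test)
            dev_test = obs_test - pred_test

            if cut_dev is not None:
                emm_dev = cut_dev[m][emm_train_idx]
            else:  # in-fit fallback for folds too small to refit
                pred_train = fitted.predict(train, m)
                if predictions_hook is not None:
                    pred_train = predictions_hook(m, train, pred_train)
                emm_dev = (obs_train - pred_train)[emm_train_idx]
            for ti, t in enumerate(TARGETS):
                cut = percentile_cutoff(emm_dev[:, ti], 5.0)
                cutoffs[m][t].append(cut)
                margins[m][t].append(cutoff_margin(emm_dev[:, ti].mean(), cut))
            fold_cuts = np.array([cutoffs[m][t][-1] for t in TARGETS])

            pooled[m]["dev"].append(dev_test)
            pooled[m]["w"].append(w_test)
            pooled[m]["group"].extend(groups_test)
            pooled[m]["pid"].extend(e.participant_id for e in test)
            pooled[m].setdefault("eye_ids", []).extend(e.eye_id for e in test)
            pooled[m]["flag"].append(dev_test[:, :5] < fold_cuts[None, :])

    report = EvalReport(models=tuple(models), k=k, seed=seed,
                        n_points=cvae_hp.n_points)
    for m in models:
        dev = np.concatenate(pooled[m]["dev"])
        w = np.concatenate(pooled[m]["w"])
        rms = prediction_error_rms(dev, np.zeros_like(dev), w)
        report.rms[m] = {t: float(rms[i]) for i, t in enumerate(TARGETS)}
        report.rms[m]["profile_pooled"] = pooled_profile_rms(rms[5:])
        report.rms_profile_points[m] = rms[5:].tolist()
        report.cutoffs[m] = {t: cutoffs[m][t] for t in TARGETS}
        report.margins[m] = {t: margins[m][t] for t in TARGETS}

        flag = np.concatenate(pooled[m]["flag"])
        groups = np.array(pooled[m]["group"])
        report.fpr[m] = {}
        report.fpr_counts[m] = {}
        for g in GROUPS:
            gi = groups == g
            report.fpr[m][g] = {}
            report.fpr_counts[m][g] = {}
            for ti, t in enumerate(TARGETS):
                if gi.sum() == 0:
                    report.fpr[m][g][t] = None
                    report.fpr_counts[m][g][t] = (0, 0)
                    report.flags.append(f"empty group {g} for {m}/{t}")
                else:
                    n_flag = int(flag[gi, ti].sum())
                    report.fpr[m][g][t] = n_flag / int(gi.sum())
                    report.fpr_counts[m][g][t] = (n_flag, int(gi.sum()))
    report._pooled = pooled  # per-eye deviations for downstream analyses
    if n_boot and "average" in models:
        for m in models:
            if m == "average":
                continue
            report.contrasts[f"{m}_vs_average"] = bootstrap_rms_contrast(
                report, m, "average", n_boot=n_boot, seed=seed)
    return report


# ---------------------------------------------------------------------------
# profile-region statistics and bootstrap contrasts

def arcade_point_mask(n_points, arcade_angles, halfwidth_deg=30.0):
    """Boolean mask of profile points within +-halfwidth of either arcade."""
    theta = np.arange(n_points) * 360.0 / n_points
    mask = np.zeros(n_points, dtype=bool)
    for a in arcade_angles:
        d = np.abs((theta - a + 180.0) % 360.0 - 180.0)
        mask |= d <= halfwidth_deg
    return mask


def arcade_rms(report: EvalReport, model, eyes, truths, folds=None,
               halfwidth_deg=30.0):
    """Pooled RMS prediction error restricted to +-halfwidth around each
    test eye's own arcade angles (needs simulation ground truth)."""
    pooled = report._pooled[model]
    dev = np.concatenate(pooled["dev"])[:, 5:]
    w = np.concatenate(pooled["w"])
    truth_by_id = {e.eye_id: t for e, t in zip(eyes, truths)}
    # pooled order is fold-major over test eyes; rebuild matching ids
    ids = pooled["eye_ids"]
    num = den = 0.0
    for i, eid in enumerate(ids):
        t = truth_by_id[eid]
        mask = arcade_point_mask(dev.shape[1], t.arcade_angles, halfwidth_deg)
        num += w[i] * float(np.mean(dev[i, mask] ** 2))
        den += w[i]
    return float(np.sqrt(num / den))


def bootstrap_rms_contrast(report: EvalReport, model_a, model_b, n_boot=1000,
                           seed=0, target="profile_pooled"):
    """Participant-resampled percentile bootstrap CI for RMS(a) - RMS(b)."""
    rng = np.random.default_rng(seed)
    pa, pb = report._pooled[model_a], report._pooled[model_b]
    dev_a = np.concatenate(pa["dev"])
    dev_b = np.concatenate(pb["dev"])
    w = np.concatenate(pa["w"])
    pids = np.array(pa["pid"])
    upids = np.unique(pids)
    idx_of = {p: np.flatnonzero(pids == p) for p in upids}

    def stat(sel_pids):
        idx = np.concatenate([idx_of[p] for p in sel_pids])
        if target == "profile_pooled":
            sa = np.sqrt(np.mean((w[idx, None] * dev_a[idx, 5:] ** 2).sum(0)
                                 / w[idx].sum()))
            sb = np.sqrt(np.mean((w[idx, None] * dev_b[idx, 5:] ** 2).sum(0)
                                 / w[idx].sum()))
        else:
            ti = TARGETS.index(target)
            sa = np.sqrt((w[idx] * dev_a[idx, ti] ** 2).sum() / w[idx].sum())
            sb = np.sqrt((w[idx] * dev_b[idx, ti] ** 2).sum() / w[idx].sum())
        return sa - sb

    boots = np.array([stat(rng.choice(upids, size=len(upids), replace=True))
                      for _ in range(n_boot)])
    return {"estimate": stat(upids),
            "ci": (float(np.percentile(boots, 2.5)),
                   float(np.percentile(boots, 97.5)))}
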