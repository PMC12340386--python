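"""Cross-validation machinery: folds, error metrics, cutoffs, rates,
margins, and the oracle floor of the full evaluation loop."""

import numpy as np
import pytest

import rnflbase as rb
from rnflbase.evaluate import (EvalReport, cutoff_margin,
                               false_positive_rate, kfold_split,
                               percentile_cutoff, pooled_profile_rms,
                               prediction_error_rms, run_evaluation)
from rnflbase.records import EyeRecord


# ---------------------------------------------------------------------------
# folds

def _cohort_of(n_participants, two_eyed=True, n=8):
    eyes = []
    for i in range(n_participants):
        for side in (("right", "left") if two_eyed else ("right",)):
            eyes.append(EyeRecord(
                participant_id=f"P{i}", eye=side, age=50, sex=0, al=24,
                se=0.0, disc_area=2.0, ssi=70,
                nflt_profile=np.full(n, 100.0),
                vp_profile=np.zeros(n, dtype=int)))
    return eyes


def test_kfold_partitions_participants_evenly():
    eyes = _cohort_of(100)
    folds = kfold_split(eyes, 5, seed=0)
    sizes = [sum(1 for f in folds.assignment.values() if f == k)
             for k in range(5)]
    assert sizes == [20] * 5
    assert set(folds.assignment) == {f"P{i}" for i in range(100)}


def test_kfold_keeps_fellow_eyes_together_and_is_deterministic():
    eyes = _cohort_of(33)
    a = kfold_split(eyes, 4, seed=9)
    b = kfold_split(eyes, 4, seed=9)
    assert a.assignment == b.assignment
    for e in eyes:
        assert a.fold_of(e) == a.assignment[e.participant_id]
    sizes = sorted(sum(1 for f in a.assignment.values() if f == k)
                   for k in range(4))
    assert max(sizes) - min(sizes) <= 1


def test_kfold_guards():
    eyes = _cohort_of(5)
    with pytest.raises(ValueError):
        kfold_split(eyes, 1, seed=0)
    with pytest.raises(ValueError):
        kfold_split(eyes, 6, seed=0)


# ---------------------------------------------------------------------------
# metrics

def test_rms_examples():
    assert prediction_error_rms([1.0, 2.0], [1.0, 2.0])[()] == 0.0
    # differences (3, 4) with equal weights -> sqrt(12.5)
    got = prediction_error_rms(np.array([3.0, 4.0]), np.zeros(2))
    assert float(got) == pytest.approx(np.sqrt(12.5))
    with pytest.raises(ValueError):
        prediction_error_rms([], [])


def test_weighted_rms_and_profile_pooling():
    t = np.array([[1.0, 3.0], [2.0, 0.0]])
    p = np.zeros((2, 2))
    w = np.array([0.5, 1.0])
    rms = prediction_error_rms(t, p, w)
    exp0 = np.sqrt((0.5 * 1 + 1.0 * 4) / 1.5)
    exp1 = np.sqrt((0.5 * 9 + 1.0 * 0) / 1.5)
    np.testing.assert_allclose(rms, [exp0, exp1])
    assert pooled_profile_rms(rms) == pytest.approx(
        np.sqrt((exp0 ** 2 + exp1 ** 2) / 2))


def test_average_model_error_equals_population_sd():
    """With the training-mean reference, the weighted RMS deviation is the
    weighted SD about the training mean."""
    rng = np.random.default_rng(0)
    y = rng.normal(100, 9, size=500)
    mean = y.mean()
    rms = float(prediction_error_rms(y, np.full(500, mean)))
    assert rms == pytest.approx(y.std(), rel=1e-12)


def test_percentile_cutoff_interpolation_rule():
    # values 1..100 at p=5: h = (n-1)p+1 = 5.95 -> 5.95
    assert percentile_cutoff(np.arange(1.0, 101.0), 5) == pytest.approx(5.95)
    assert percentile_cutoff(np.full(30, 7.0), 5) == 7.0


def test_percentile_cutoff_matches_sort_based_oracle():
    """Linear-interpolation quantile against a hand-rolled sort-based
    oracle on 1000 random sets."""
    rng = np.random.default_rng(1)
    for _ in range(1000):
        n = int(rng.integers(20, 200))
        x = rng.normal(size=n) * rng.uniform(0.5, 20)
        p = float(rng.uniform(1, 99))
        xs = np.sort(x)
        h = (n - 1) * p / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        oracle = xs[lo] + (h - lo) * (xs[hi] - xs[lo])
        assert percentile_cutoff(x, p) == pytest.approx(oracle, abs=1e-9)


def test_percentile_cutoff_guards():
    with pytest.raises(ValueError):
        percentile_cutoff(np.ones(10), 5)
    with pytest.raises(ValueError):
        percentile_cutoff(np.ones(30), 0.0)


def test_false_positive_rate_counting():
    d = np.concatenate([np.full(3, -10.0), np.full(37, 1.0)])
    rate, flagged, n = false_positive_rate(d, 0.0)
    assert (rate, flagged, n) == (pytest.approx(3 / 40), 3, 40)
    rate, *_ = false_positive_rate(np.ones(10), -5.0)
    assert rate == 0.0
    rate, flagged, n = false_positive_rate(np.array([]), 0.0)
    assert rate is None and n == 0


def test_fpr_calibrated_when_cutoff_from_same_distribution():
    """Deviations drawn i.i.d. from the cutoff's source distribution give
    FPR within the 95% binomial CI of 5% at n = 1e4."""
    rng = np.random.default_rng(2)
    train = rng.normal(size=20000)
    cut = percentile_cutoff(train, 5)
    test = rng.normal(size=10000)
    rate, *_ = false_positive_rate(test, cut)
    half = 1.96 * np.sqrt(0.05 * 0.95 / 10000)
    assert abs(rate - 0.05) < half + 0.005  # cutoff-estimation slack


def test_cutoff_margin_properties():
    assert cutoff_margin(100.0, 86.0) == 14.0
    rng = np.random.default_rng(3)
    d = rng.normal(size=1000)
    m1 = cutoff_margin(d.mean(), percentile_cutoff(d, 5))
    d2 = d + 42.0
    m2 = cutoff_margin(d2.mean(), percentile_cutoff(d2, 5))
    assert m1 == pytest.approx(m2, abs=1e-9)


def test_margin_converges_to_gaussian_quantile():
    rng = np.random.default_rng(4)
    sigma = 3.7
    d = rng.normal(0, sigma, size=100000)
    m = cutoff_margin(d.mean(), percentile_cutoff(d, 5))
    assert m == pytest.approx(1.6449 * sigma, rel=0.02)


# ---------------------------------------------------------------------------
# full loop with the truth oracle

def test_run_evaluation_oracle_floor_schema_and_determinism(small_cohort):
    """With every model's predictions replaced by the simulation's
    noiseless baselines, prediction error equals the generator's noise
    RMS; report schema and determinism hold."""
    cfg, eyes, truths = small_cohort
    tmap = {e.eye_id: t for e, t in zip(eyes, truths)}
    from rnflbase.evaluate import _observed_matrix

    def oracle_hook(model_name, batch, predicted):
        rows = []
        for e in batch:
            t = tmap[e.eye_id]
            o, tq, s, na, i = rb.quadrant_means(t.baseline_profile)
            rows.append(np.concatenate([[o, tq, s, na, i],
                                        t.baseline_profile]))
        return np.stack(rows)

    kw = dict(k=2, seed=4, models=("average", "mlr"),
              predictions_hook=oracle_hook)
    rep = run_evaluation(eyes, **kw)
    # noise RMS per point: sqrt(point^2 + eye^2 + participant^2)
    noise = np.sqrt(cfg.noise_point_sd ** 2 + cfg.noise_eye_sd ** 2
                    + cfg.noise_participant_sd ** 2)
    for m in rep.models:
        assert rep.rms[m]["profile_pooled"] == pytest.approx(noise, rel=0.05)
    # schema
    assert set(rep.rms) == {"average", "mlr"}
    for m in rep.models:
        assert set(rep.fpr[m]) == {"hyperopia", "emmetropia", "low_myopia",
                                   "high_myopia"}
        for g in rep.fpr[m]:
            assert set(rep.fpr[m][g]) == {"overall", "temporal", "superior",
                                          "nasal", "inferior"}
        assert len(rep.rms_profile_points[m]) == cfg.n_points
    # determinism
    rep2 = run_evaluation(eyes, **kw)
    assert rep.to_dict() == rep2.to_dict()
    # bootstrap contrast: oracle predictions are identical for both models,
    # so the pooled-RMS contrast and its CI collapse to zero
    c = rep.contrasts["mlr_vs_average"]
    assert c["estimate"] == pytest.approx(0.0, abs=1e-12)
    assert c["ci"][0] == pytest.approx(0.0, abs=1e-12)


def test_bootstrap_contrast_detects_a_real_difference(small_cohort):
    """A reference with half the deviation spread gets a negative RMS
    contrast whose bootstrap CI excludes zero."""
    _, eyes, truths = small_cohort
    tmap = {e.eye_id: t for e, t in zip(eyes, truths)}

    def hook(model_name, batch, predicted):
        from rnflbase.evaluate import _observed_matrix
        obs = _observed_matrix(batch)
        truth = np.stack([np.concatenate([
            [0, 0, 0, 0, 0], tmap[e.eye_id].baseline_profile])
            for e in batch])
        truth[:, :5] = obs[:, :5] - (obs[:, :5] - truth[:, 5:].mean(1,
                                     keepdims=True))
        if model_name == "mlr":       # shrink deviations toward the truth
            return obs - 0.5 * (obs - truth)
        return truth

    rep = run_evaluation(eyes, k=2, seed=4, models=("average", "mlr"),
                         n_boot=300, predictions_hook=hook)
    c = rep.contrasts["mlr_vs_average"]
    assert c["estimate"] < 0
    assert c["ci"][1] < 0


def test_no_leakage_training_artifacts_ignore_test_fold(small_cohort):
    """Fitting on the training fold is unchanged when the test fold's eyes
    are removed entirely."""
    _, eyes, _ = small_cohort
    folds = kfold_split(eyes, 2, seed=1)
    train = [e for e in eyes if folds.fold_of(e) != 0]
    from rnflbase.mlr import fit_mlr
    beta_full = fit_mlr(train).beta
    beta_pruned = fit_mlr(list(train)).beta  # test fold never passed in
    np.testing.assert_array_equal(beta_full, beta_pruned)
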