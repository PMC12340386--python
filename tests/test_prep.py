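"""Quality filter, vessel-width normalization, standardization, grouping
and quadrant summaries."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rnflbase as rb
from rnflbase.prep import (PopulationStats, RefractionGroup,
                           StandardizationStats, assign_refraction_group,
                           normalize_vessel_widths, quadrant_means,
                           quality_filter, standardize)
from rnflbase.records import EyeRecord


def _eye(ssi=80.0, overall=100.0, cropped=False, se=0.0, n=128):
    return EyeRecord(participant_id="P0", eye="right", age=50, sex=0,
                     al=23.8, se=se, disc_area=2.0, ssi=ssi,
                     nflt_profile=np.full(n, overall),
                     vp_profile=np.zeros(n, dtype=int), cropped=cropped)


POP = PopulationStats(overall_mean=100.0, overall_sd=9.0)


@pytest.mark.parametrize("eye,expected", [
    (_eye(ssi=34.0), (False, "low_ssi")),
    (_eye(ssi=35.0), (True, "ok")),
    (_eye(ssi=80.0), (True, "ok")),
    (_eye(cropped=True), (False, "cropping")),
    (_eye(overall=100.0 - 4.5 * 9.0), (False, "extreme_thin")),
    (_eye(overall=100.0 - 3.5 * 9.0), (True, "ok")),
    (_eye(ssi=np.nan), (False, "missing_field")),
])
def test_quality_filter_rules(eye, expected):
    assert quality_filter(eye, POP) == expected


def test_quality_filter_order_independent(small_cohort):
    _, eyes, _ = small_cohort
    pop = PopulationStats.from_records(eyes)
    fwd = [quality_filter(e, pop) for e in eyes]
    rev = [quality_filter(e, pop) for e in reversed(eyes)]
    assert fwd == rev[::-1]


# ---------------------------------------------------------------------------
# vessel-width normalization

def _vp_from_runs(runs, n=128):
    vp = np.zeros(n, dtype=int)
    for s, w in runs:
        vp[[(s + k) % n for k in range(w)]] = 1
    return vp


def test_normalization_hits_exact_target_count():
    vp = _vp_from_runs([(10, 10), (40, 10), (70, 10), (100, 10)])  # 40 of 128
    out = normalize_vessel_widths(vp, 0.25)
    assert out.sum() == 32


def test_fixed_point_input_unchanged():
    vp = _vp_from_runs([(10, 16), (60, 16)])  # exactly 32 = round(0.25*128)
    out = normalize_vessel_widths(vp, 0.25)
    np.testing.assert_array_equal(out, vp)


def test_largest_remainder_tie_breaks_toward_wider_run():
    """Runs (6, 2) scaled to total 6: floors (4, 1), equal remainders 0.5,
    extra pixel goes to the wider original run -> (5, 1)."""
    vp = _vp_from_runs([(10, 6), (20, 2)], n=32)
    out = normalize_vessel_widths(vp, 6 / 32)
    runs = _runs_of(out)
    widths = sorted((w for _, w in runs), reverse=True)
    assert widths == [5, 1]


def _runs_of(vp):
    from rnflbase.prep import _find_runs_circular
    return _find_runs_circular(vp)


def test_run_centers_preserved():
    vp = _vp_from_runs([(10, 8), (60, 8), (100, 4)])
    out = normalize_vessel_widths(vp, 0.25)
    in_centers = sorted(s + (w - 1) / 2 for s, w in _runs_of(vp))
    out_centers = sorted(s + (w - 1) / 2 for s, w in _runs_of(out))
    assert len(in_centers) == len(out_centers)
    assert np.allclose(in_centers, out_centers, atol=1.0)


def test_normalization_errors():
    with pytest.raises(ValueError, match="no_vessels"):
        normalize_vessel_widths(np.zeros(32, dtype=int), 0.25)
    vp = _vp_from_runs([(0, 2), (8, 2), (16, 2), (24, 2)], n=32)
    with pytest.raises(ValueError, match="ratio_too_small"):
        normalize_vessel_widths(vp, 3 / 32)  # 4 runs, target 3


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 127), st.integers(1, 9)),
                min_size=1, max_size=6))
def test_normalization_idempotent_and_exact(runs):
    vp = _vp_from_runs(runs)
    if vp.sum() == 0:
        return
    n_runs = len(_runs_of(vp))
    if n_runs > 32:
        return
    once = normalize_vessel_widths(vp, 0.25)
    twice = normalize_vessel_widths(once, 0.25)
    assert once.sum() == 32
    np.testing.assert_array_equal(once, twice)


def test_wraparound_run_handled():
    vp = _vp_from_runs([(124, 8), (60, 8)])  # run crossing index 0
    out = normalize_vessel_widths(vp, 0.25)
    assert out.sum() == 32
    assert len(_runs_of(out)) == 2


# ---------------------------------------------------------------------------
# standardization

def test_standardize_round_trip_and_moments(small_cohort):
    _, eyes, _ = small_cohort
    std_eyes, stats = standardize(eyes)
    ages = np.array([e.age for e in std_eyes])
    assert abs(ages.mean()) < 1e-10
    assert ages.std() == pytest.approx(1.0, abs=1e-10)
    profs = np.concatenate([e.nflt_profile for e in std_eyes])
    assert abs(profs.mean()) < 1e-10
    assert profs.std() == pytest.approx(1.0, abs=1e-10)
    back = stats.profile_inverse(std_eyes[0].nflt_profile)
    np.testing.assert_allclose(back, eyes[0].nflt_profile, rtol=1e-10)


def test_test_eye_standardized_with_frozen_stats(small_cohort):
    _, eyes, _ = small_cohort
    _, stats = standardize(eyes)
    probe = dataclasses.replace(eyes[0])
    probe.age = stats.scalar_mean["age"] + stats.scalar_sd["age"]
    assert stats.scalar(probe, "age") == pytest.approx(1.0, abs=1e-12)


def test_degenerate_feature_raises_with_name():
    a, b = _eye(), _eye()
    b.age, b.al, b.ssi, b.se, b.disc_area = 60.0, 24.5, 70.0, -2.0, 1.8
    b.nflt_profile = np.full(128, 90.0)
    with pytest.raises(ValueError, match="sex"):
        StandardizationStats.fit([a, b])


# ---------------------------------------------------------------------------
# refraction groups

@pytest.mark.parametrize("se,expected", [
    (-7.8, RefractionGroup.high_myopia),
    (-6.0, RefractionGroup.low_myopia),      # boundary to less extreme group
    (-6.001, RefractionGroup.high_myopia),
    (-1.0, RefractionGroup.emmetropia),      # not low myopia
    (0.0, RefractionGroup.emmetropia),
    (1.0, RefractionGroup.emmetropia),
    (1.001, RefractionGroup.hyperopia),
    (2.0, RefractionGroup.hyperopia),
])
def test_refraction_group_boundaries(se, expected):
    assert assign_refraction_group(se) is expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-15, 8, allow_nan=False), min_size=1, max_size=50))
def test_group_assignment_partitions_sample(ses):
    groups = [assign_refraction_group(s) for s in ses]
    counts = {g: groups.count(g) for g in RefractionGroup}
    assert sum(counts.values()) == len(ses)


def test_nonfinite_se_rejected():
    with pytest.raises(ValueError):
        assign_refraction_group(float("nan"))


# ---------------------------------------------------------------------------
# quadrant means

def test_quadrant_means_constant_profile():
    out = quadrant_means(np.full(128, 100.0))
    assert out == (100.0,) * 5


def test_quadrant_means_superior_bump():
    n = 128
    theta = np.arange(n) * 360.0 / n
    p = np.full(n, 100.0)
    p[(theta >= 45) & (theta < 135)] += 20.0
    overall, t, s, na, i = quadrant_means(p)
    assert (t, s, na, i) == (100.0, 120.0, 100.0, 100.0)
    assert overall == pytest.approx(105.0)


def test_overall_is_mean_of_quadrants():
    rng = np.random.default_rng(0)
    p = rng.uniform(50, 150, size=128)
    overall, t, s, na, i = quadrant_means(p)
    assert overall == pytest.approx(np.mean([t, s, na, i]), rel=1e-12)


def test_quadrant_means_requires_divisible_length():
    with pytest.raises(ValueError):
        quadrant_means(np.ones(126))
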