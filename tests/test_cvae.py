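"""Conditions, latent sampling, KL closed form, composite loss, and the
training contract of the coupled CVAEs."""

import numpy as np
import pytest

from rnflbase.cvae import (CVAEHyperParams, DualCVAE, LatentParams,
                           _batch_arrays, compute_loss, kl_divergence,
                           load_checkpoint, make_conditions,
                           participant_weights, sample_latent,
                           save_checkpoint, train_model)
from rnflbase.rcnn import IdentityMagnification


# ---------------------------------------------------------------------------
# conditions

def test_condition_vector_lengths_per_variant(prepped_small):
    prepped, _, stats = prepped_small
    eye = prepped[0]
    assert len(make_conditions(eye, "base", stats)) == 3
    assert len(make_conditions(eye, "mag", stats)) == 6


def test_mag_condition_order_and_values(prepped_small):
    prepped, _, stats = prepped_small
    eye = prepped[0]
    c = make_conditions(eye, "mag", stats)
    expected = [stats.scalar(eye, f)
                for f in ("age", "sex", "ssi", "disc_area", "al", "se")]
    np.testing.assert_allclose(c, expected, rtol=1e-12)


def test_reg_with_identity_stub_equals_mag(prepped_small):
    prepped, _, stats = prepped_small
    eye = prepped[0]
    c_mag = make_conditions(eye, "mag", stats)
    c_reg = make_conditions(eye, "reg", stats, rcnn=IdentityMagnification())
    np.testing.assert_allclose(c_reg, c_mag, rtol=1e-12)


def test_reg_without_rcnn_rejected(prepped_small):
    prepped, _, stats = prepped_small
    with pytest.raises(ValueError):
        make_conditions(prepped[0], "reg", stats)
    with pytest.raises(ValueError):
        make_conditions(prepped[0], "nonsense", stats)


# ---------------------------------------------------------------------------
# latent sampling

def test_sample_latent_degenerate_and_deterministic():
    lp = LatentParams(mu=np.array([1.0, -2.0]), sigma=np.zeros(2))
    z = sample_latent(lp, np.random.default_rng(0))
    np.testing.assert_array_equal(z, lp.mu)
    lp = LatentParams(mu=np.zeros(4), sigma=np.ones(4))
    z1 = sample_latent(lp, np.random.default_rng(7))
    z2 = sample_latent(lp, np.random.default_rng(7))
    np.testing.assert_array_equal(z1, z2)


def test_sample_latent_moments():
    """1e5 reparameterized draws: mean within 4*sigma/sqrt(n) of mu and
    SD within 2% of sigma, per coordinate."""
    mu = np.array([0.5, -1.0, 2.0])
    sigma = np.array([0.3, 1.0, 2.5])
    lp = LatentParams(mu=mu, sigma=sigma)
    rng = np.random.default_rng(123)
    draws = np.stack([sample_latent(lp, rng) for _ in range(100_000)])
    np.testing.assert_array_less(np.abs(draws.mean(0) - mu),
                                 4 * sigma / np.sqrt(1e5))
    np.testing.assert_allclose(draws.std(0), sigma, rtol=0.02)


def test_negative_sigma_rejected():
    with pytest.raises(ValueError):
        LatentParams(mu=np.zeros(2), sigma=np.array([1.0, -0.1]))


# ---------------------------------------------------------------------------
# KL divergence

@pytest.mark.parametrize("mu,sigma,expected", [
    (np.zeros(3), np.ones(3), 0.0),
    (np.array([1.0]), np.array([1.0]), 0.5),
    (np.array([0.0]), np.array([0.5]),
     0.5 * (0.25 - 1.0 - np.log(0.25))),  # ~0.3181
])
def test_kl_closed_form_values(mu, sigma, expected):
    assert kl_divergence(LatentParams(mu=mu, sigma=sigma)) == \
        pytest.approx(expected, abs=1e-12)


def test_kl_matches_formula_on_random_latents():
    rng = np.random.default_rng(0)
    for _ in range(200):
        d = rng.integers(1, 12)
        mu = rng.normal(size=d)
        sigma = np.exp(rng.normal(scale=0.7, size=d))
        expected = 0.5 * np.sum(mu ** 2 + sigma ** 2 - 1 - np.log(sigma ** 2))
        got = kl_divergence(LatentParams(mu=mu, sigma=sigma))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got >= -1e-12


def test_kl_zero_iff_standard_normal():
    rng = np.random.default_rng(1)
    for _ in range(50):
        mu = rng.normal(size=4) * 0.1
        sigma = np.exp(rng.normal(size=4) * 0.1)
        kl = kl_divergence(LatentParams(mu=mu, sigma=sigma))
        if np.allclose(mu, 0) and np.allclose(sigma, 1):
            assert kl == 0.0
        elif not (np.allclose(mu, 0) and np.allclose(sigma, 1)):
            assert kl > 0.0
    with pytest.raises(ValueError):
        kl_divergence(LatentParams(mu=np.zeros(1), sigma=np.zeros(1)))


# ---------------------------------------------------------------------------
# composite loss

def _forward_batch(prepped, stats, variant="mag", n=6, seed=0, rcnn=None):
    hp = CVAEHyperParams(channels=(4, 8), fc_width=16, latent_vp=3,
                         latent_nfl=4, dropout=0.0)
    model = DualCVAE(variant, hp, seed=seed)
    xn, xv, cond, w, res = _batch_arrays(prepped[:n], variant, stats, rcnn)
    out = model.forward(xn, xv, cond, np.random.default_rng(3), training=True)
    return model, out, xn, xv, w, res


def test_loss_components_match_independent_reimplementation(prepped_small):
    """Hand-coded numpy MSE/BCE/KL on the same tensors agree with the
    returned components to 1e-6 relative."""
    prepped, _, stats = prepped_small
    _, out, xn, xv, w, _ = _forward_batch(prepped, stats)
    total, comps = compute_loss(out, xn, xv, w, "mag")

    recon = out["nfl_recon"].data
    mse = np.sum(w * np.sum((recon - xn) ** 2, axis=1)) / w.sum()
    p = 1.0 / (1.0 + np.exp(-out["vp_logits"].data))
    bce_pt = -(xv * np.log(p) + (1 - xv) * np.log(1 - p))
    bce = np.sum(w * bce_pt.sum(axis=1)) / w.sum()

    def kl(mu, logsig):
        s2 = np.exp(2 * logsig)
        return np.sum(w * (0.5 * (mu ** 2 + s2 - 1 - 2 * logsig)).sum(1)) / w.sum()

    assert comps["mse_nflt"] == pytest.approx(mse, rel=1e-6)
    assert comps["bce_vp"] == pytest.approx(bce, rel=1e-6)
    assert comps["kl_vp"] == pytest.approx(
        kl(out["mu2"].data, out["logsig2"].data), rel=1e-6)
    assert comps["kl_nfl"] == pytest.approx(
        kl(out["mu1"].data, out["logsig1"].data), rel=1e-6)
    assert float(total.data) == pytest.approx(mse + bce + comps["kl_vp"]
                                              + comps["kl_nfl"], rel=1e-6)


def test_perfect_reconstruction_loss_floor(prepped_small):
    """Exact reconstructions with standard-normal latents: total loss is at
    the BCE epsilon floor."""
    prepped, _, stats = prepped_small
    _, out, xn, xv, w, _ = _forward_batch(prepped, stats)
    from rnflbase.nnet import autograd as ag
    big = 30.0
    out = dict(out)
    out["nfl_recon"] = ag.constant(xn)
    out["vp_logits"] = ag.constant(np.where(xv > 0.5, big, -big))
    out["mu1"] = ag.constant(np.zeros_like(out["mu1"].data))
    out["logsig1"] = ag.constant(np.zeros_like(out["logsig1"].data))
    out["mu2"] = ag.constant(np.zeros_like(out["mu2"].data))
    out["logsig2"] = ag.constant(np.zeros_like(out["logsig2"].data))
    total, comps = compute_loss(out, xn, xv, w, "mag")
    assert float(total.data) < 1e-8


def test_reg_total_is_mag_total_plus_al_se_terms(prepped_small):
    prepped, _, stats = prepped_small
    stub = IdentityMagnification()
    model, out, xn, xv, w, res = _forward_batch(prepped, stats, variant="reg",
                                                rcnn=stub)
    t_reg, c_reg = compute_loss(out, xn, xv, w, "reg", al_se_residuals=res)
    t_mag, _ = compute_loss(out, xn, xv, w, "mag")
    assert float(t_reg.data) == pytest.approx(
        float(t_mag.data) + c_reg["mse_al"] + c_reg["mse_se"], rel=1e-12)
    # identity stub: zero residuals
    assert c_reg["mse_al"] == 0.0 and c_reg["mse_se"] == 0.0


def test_gradient_sanity_on_four_eye_batch(prepped_small):
    """Finite differences against backprop on a random parameter subset,
    1e-4 relative (parameters nudged off LeakyReLU kinks first)."""
    prepped, _, stats = prepped_small
    hp = CVAEHyperParams(channels=(4, 8), fc_width=16, latent_vp=3,
                         latent_nfl=4, dropout=0.0)
    model = DualCVAE("mag", hp, seed=0)
    nudge = np.random.default_rng(9)
    for p in model.parameters():
        p.data = p.data + nudge.normal(0.0, 1e-2, size=p.data.shape)
    xn, xv, cond, w, _ = _batch_arrays(prepped[:4], "mag", stats, None)

    def loss():
        out = model.forward(xn, xv, cond, np.random.default_rng(3),
                            training=True)
        t, _ = compute_loss(out, xn, xv, w, "mag")
        return t

    loss().backward()
    rng = np.random.default_rng(5)
    params = model.parameters()
    for p in [params[i] for i in rng.choice(len(params), size=8, replace=False)]:
        i = np.unravel_index(rng.integers(p.data.size), p.data.shape)
        g = p.grad[i]
        h = 1e-5
        orig = p.data[i]
        p.data[i] = orig + h
        lp = float(loss().data)
        p.data[i] = orig - h
        lm = float(loss().data)
        p.data[i] = orig
        fd = (lp - lm) / (2 * h)
        assert g == pytest.approx(fd, rel=1e-4, abs=1e-7)


# ---------------------------------------------------------------------------
# training contract

def test_participant_weight_halving(prepped_small):
    prepped, _, _ = prepped_small
    w = participant_weights(prepped)
    totals = {}
    for e, wi in zip(prepped, w):
        totals[e.participant_id] = totals.get(e.participant_id, 0.0) + wi
    assert all(t == pytest.approx(1.0) for t in totals.values())
    counts = {}
    for e in prepped:
        counts[e.participant_id] = counts.get(e.participant_id, 0) + 1
    for e, wi in zip(prepped, w):
        assert wi == pytest.approx(0.5 if counts[e.participant_id] == 2 else 1.0)


def test_training_deterministic_and_progresses(prepped_small, tiny_hp):
    prepped, _, stats = prepped_small
    m1, log1 = train_model(prepped, "base", tiny_hp, seed=5, stats=stats)
    m2, log2 = train_model(prepped, "base", tiny_hp, seed=5, stats=stats)
    np.testing.assert_array_equal(
        np.array(log1.series("val", "total")),
        np.array(log2.series("val", "total")))
    for a, b in zip(m1.state_arrays(), m2.state_arrays()):
        np.testing.assert_array_equal(a, b)
    vals = log1.series("val", "total")
    assert vals[-1] < vals[0]


def test_training_requires_enough_participants(prepped_small, tiny_hp):
    prepped, _, stats = prepped_small
    few = [e for e in prepped if e.participant_id in
           sorted({x.participant_id for x in prepped})[:5]]
    with pytest.raises(ValueError, match="too_small"):
        train_model(few, "base", tiny_hp, seed=0, stats=stats)


def test_checkpoint_round_trip(tmp_path, trained_mag_small, prepped_small):
    model, _ = trained_mag_small
    prepped, _, stats = prepped_small
    path = tmp_path / "m.npz"
    save_checkpoint(model, path, config_hash="abc")
    loaded = load_checkpoint(path)
    assert loaded.variant == "mag"
    for a, b in zip(model.state_arrays(), loaded.state_arrays()):
        np.testing.assert_array_equal(a, b)
    assert loaded.stats.content_hash() == stats.content_hash()
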