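"""Coupled conditional variational autoencoders for thickness profiles.

Two CVAEs are trained jointly. The vascular-pattern (VP) CVAE encodes
the binary vessel profile into a latent (mu2, sigma2) and reconstructs
it; the thickness (NFLT) CVAE encodes the thickness profile into
(mu1, sigma1) and reconstructs it. The two are coupled along two
distinct paths:

* the VP encoder's convolutional feature vector h_vp is an extra
  condition of the NFLT *encoder*;
* the VP sampling-layer output z2 is an extra condition of the NFLT
  *decoder*.

At generation time only the VP encoder and the NFLT decoder are used,
with Z1 = 0 and Z2 = mu2 (see :mod:`rnflbase.baseline`).

Scalar conditions per variant: BASE uses (age, sex, SSI); MAG adds
(disc_area, AL, SE); REG is MAG with AL and SE replaced by the
magnification-regression CNN's estimates. All conditions are
standardized with training-set statistics.

Training loss (per batch, weighted mean over eyes):
``MSE_NFLT + BCE_VP + KL_VP + KL_NFL`` with ``+ MSE_AL + MSE_SE``
appended for the REG variant (the frozen rCNN's residuals, reported for
completeness). Eyes of two-eye participants carry weight 1/2 so each
participant contributes total weight 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nnet
from .nnet import autograd as ag
from .prep import StandardizationStats

VARIANTS = ("base", "mag", "reg")

_COND_FIELDS = {
    "base": ("age", "sex", "ssi"),
    "mag": ("age", "sex", "ssi", "disc_area", "al", "se"),
    "reg": ("age", "sex", "ssi", "disc_area", "al", "se"),
}


@dataclass
class CVAEHyperParams:
    n_points: int = 128
    latent_vp: int = 8           # d2
    latent_nfl: int = 16         # d1
    channels: tuple = (16, 32, 64)
    kernel: int = 5
    fc_width: int = 64
    dropout: float = 0.5
    decoder_dropout: bool = False  # dropout in decoder FC stems too
    learning_rate: float = 1e-3
    adam_decay: float = 1e-3     # optimizer decay
    l2: float = 0.02             # L2 regularization factor (decoupled decay)
    kl_beta: float = 1.0
    # diagnostic switch: sever the VP-sampling -> NFLT-decoder coupling
    # (the decoder then sees zeros in place of z2)
    ablate_vp_coupling: bool = False
    batch_size: int = 32
    max_epochs: int = 120
    patience: int = 25
    val_fraction: float = 0.10   # participant-grouped internal validation


def make_conditions(eye, variant, stats: StandardizationStats, rcnn=None):
    """Standardized condition vector for one (already measured-scale) eye.

    For the REG variant the AL/SE entries come from the rCNN's estimate,
    standardized with the *measured* AL/SE training statistics.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "reg":
        if rcnn is None:
            raise ValueError("REG variant requires an rcnn model")
        est = rcnn.predict(eye)
        vals = [stats.scalar(eye, "age"), stats.scalar(eye, "sex"),
                stats.scalar(eye, "ssi"), stats.scalar(eye, "disc_area"),
                stats.scalar_value(est.al_hat, "al"),
                stats.scalar_value(est.se_hat, "se")]
        return np.array(vals)
    return np.array([stats.scalar(eye, f) for f in _COND_FIELDS[variant]])


def condition_dim(variant):
    return len(_COND_FIELDS[variant])


# ---------------------------------------------------------------------------
# latent helpers

@dataclass
class LatentParams:
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


def sample_latent(lp: LatentParams, rng) -> np.ndarray:
    """Reparameterized draw z = mu + sigma * eps, eps ~ N(0, I)."""
    eps = rng.standard_normal(lp.mu.shape)
    return lp.mu + lp.sigma * eps


def kl_divergence(lp: LatentParams) -> float:
    """KL(N(mu, diag sigma^2) || N(0, I)) = sum_j (mu_j^2 + sigma_j^2
    - 1 - ln sigma_j^2) / 2."""
    sig2 = lp.sigma ** 2
    if np.any(sig2 == 0):
        raise ValueError("sigma must be strictly positive for the KL")
    return float(0.5 * np.sum(lp.mu ** 2 + sig2 - 1.0 - np.log(sig2)))


def _kl_node(mu, log_sigma):
    """KL per eye (summed over latent dims) as an autograd node; inputs are
    (B, d) tensors with sigma parameterized via log-sigma."""
    sig2 = ag.exp(ag.mul(log_sigma, 2.0))
    per_dim = ag.mul(ag.add(ag.add(ag.pow_(mu, 2.0), sig2),
                            ag.add(ag.constant(-1.0), ag.mul(log_sigma, -2.0))), 0.5)
    return ag.sum_(per_dim, axis=1)  # (B,)


# ---------------------------------------------------------------------------
# model

class DualCVAE(nnet.Module):
    """VP-CVAE + NFLT-CVAE with the two coupling paths."""

    def __init__(self, variant: str, hp: CVAEHyperParams, seed: int = 0):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.hp = hp
        rng = np.random.default_rng(seed)
        n, ch, k = hp.n_points, hp.channels, hp.kernel
        cdim = condition_dim(variant)
        feat = ch[-1] * (n // 2 ** len(ch))  # flattened conv feature size

        self.vp_encoder = nnet.ConvEncoder1d(1, ch, k, rng)
        self.vp_enc_fc = nnet.Dense(feat + cdim, hp.fc_width, rng)
        self.vp_mu = nnet.Dense(hp.fc_width, hp.latent_vp, rng)
        self.vp_logsig = nnet.Dense(hp.fc_width, hp.latent_vp, rng)
        self.vp_decoder = nnet.ConvDecoder1d(hp.latent_vp + cdim, n, ch[::-1], k,
                                             rng, fc_width=hp.fc_width)

        self.nfl_encoder = nnet.ConvEncoder1d(1, ch, k, rng)
        self.nfl_enc_fc = nnet.Dense(feat + cdim + feat, hp.fc_width, rng)
        self.nfl_mu = nnet.Dense(hp.fc_width, hp.latent_nfl, rng)
        self.nfl_logsig = nnet.Dense(hp.fc_width, hp.latent_nfl, rng)
        # Z2 and the conditions drive the nonlinear decoder stem; Z1 enters
        # through a linear additive head, so the latent-mean shortcut
        # (decoding at Z1 = 0) equals the expectation of decodes over
        # z1 ~ N(0, I) exactly rather than approximately.
        self.nfl_decoder = nnet.ConvDecoder1d(
            hp.latent_vp + cdim, n, ch[::-1], k, rng, fc_width=hp.fc_width)
        self.nfl_z1_head = nnet.Dense(hp.latent_nfl, n, rng)
        self.nfl_z1_head.W.data *= 0.1  # start the noise channel quiet

        self.dropout = nnet.Dropout(hp.dropout)

    # -- forward pieces --------------------------------------------------
    def encode_vp(self, x_vp, cond, rng=None, training=False):
        h_vp = self.vp_encoder(x_vp)                       # (B, feat)
        h = ag.concat([h_vp, cond], axis=1)
        h = ag.leaky_relu(self.vp_enc_fc(h), 0.1)
        h = self.dropout(h, rng=rng, training=training)
        return self.vp_mu(h), self.vp_logsig(h), h_vp

    def encode_nfl(self, x_nfl, cond, h_vp, rng=None, training=False):
        h_nfl = self.nfl_encoder(x_nfl)
        h = ag.concat([h_nfl, cond, h_vp], axis=1)
        h = ag.leaky_relu(self.nfl_enc_fc(h), 0.1)
        h = self.dropout(h, rng=rng, training=training)
        return self.nfl_mu(h), self.nfl_logsig(h)

    def forward(self, x_nfl, x_vp, cond_arr, rng, training=True):
        """Full training-stage pass on a batch.

        x_nfl: (B, N) standardized profiles; x_vp: (B, N) binary;
        cond_arr: (B, cdim). Returns a dict of autograd nodes.
        """
        B = x_nfl.shape[0]
        xv = ag.constant(x_vp.reshape(B, -1, 1))
        xn = ag.constant(x_nfl.reshape(B, -1, 1))
        cond = ag.constant(cond_arr)

        dec_drop = self.dropout if self.hp.decoder_dropout else None
        mu2, logsig2, h_vp = self.encode_vp(xv, cond, rng, training)
        eps2 = rng.standard_normal(mu2.shape) if training else np.zeros(mu2.shape)
        z2 = ag.add(mu2, ag.mul(ag.exp(logsig2), ag.constant(eps2)))
        vp_logits = self.vp_decoder(ag.concat([z2, cond], axis=1),
                                    rng=rng, training=training, dropout=dec_drop)

        mu1, logsig1 = self.encode_nfl(xn, cond, h_vp, rng, training)
        eps1 = rng.standard_normal(mu1.shape) if training else np.zeros(mu1.shape)
        z1 = ag.add(mu1, ag.mul(ag.exp(logsig1), ag.constant(eps1)))
        z2_dec = (ag.constant(np.zeros(z2.shape)) if self.hp.ablate_vp_coupling
                  else z2)
        nfl_recon = ag.add(
            self.nfl_decoder(ag.concat([z2_dec, cond], axis=1),
                             rng=rng, training=training, dropout=dec_drop),
            self.nfl_z1_head(z1))

        return {"nfl_recon": nfl_recon, "vp_logits": vp_logits,
                "mu1": mu1, "logsig1": logsig1, "mu2": mu2, "logsig2": logsig2}

    def decode_nfl(self, z1_arr, z2, cond):
        """Generation-stage decode; z2/cond may be autograd nodes or arrays."""
        z1 = ag.constant(z1_arr)
        if not isinstance(z2, ag.Tensor):
            z2 = ag.constant(z2)
        if not isinstance(cond, ag.Tensor):
            cond = ag.constant(cond)
        stem = self.nfl_decoder(ag.concat([z2, cond], axis=1), training=False)
        return ag.add(stem, self.nfl_z1_head(z1))


def compute_loss(outputs, x_nfl, x_vp, weights, variant,
                 al_se_residuals=None, kl_beta=1.0):
    """Composite weighted loss; returns (total_node, components dict).

    Per-eye reconstruction terms are *summed* over the profile's points
    (squared error for the thickness profile, cross-entropy for the
    vessel profile), matching the evidence-lower-bound scaling in which
    the reconstruction log-likelihood sums over output dimensions and
    the KL sums over latent dimensions. Averaging over points instead
    would make reconstruction so cheap relative to the KL that the
    vessel latent collapses to the prior and the generated baseline
    loses its peak alignment. Everything is combined as the weighted
    mean over the batch (weights 1/2 for eyes of two-eye participants).
    For REG, the frozen rCNN's standardized AL/SE squared residuals are
    added as constants.

    Logged components report the summed values (the actual loss terms)
    plus per-point means (`mse_nflt_mean`, `bce_vp_mean`) for
    readability.
    """
    w = np.asarray(weights, dtype=float)
    n_points = x_nfl.shape[1]
    wmean = lambda node: ag.div(ag.sum_(ag.mul(node, ag.constant(w))),
                                ag.constant(w.sum()))

    err = ag.sub(outputs["nfl_recon"], ag.constant(x_nfl))
    mse_nfl = wmean(ag.sum_(ag.pow_(err, 2.0), axis=1))
    bce_vp = wmean(ag.sum_(ag.bce_with_logits(outputs["vp_logits"], x_vp), axis=1))
    kl_vp = wmean(_kl_node(outputs["mu2"], outputs["logsig2"]))
    kl_nfl = wmean(_kl_node(outputs["mu1"], outputs["logsig1"]))

    total = ag.add(ag.add(mse_nfl, bce_vp),
                   ag.mul(ag.add(kl_vp, kl_nfl), kl_beta))
    comps = {"mse_nflt": float(mse_nfl.data), "bce_vp": float(bce_vp.data),
             "kl_vp": float(kl_vp.data), "kl_nfl": float(kl_nfl.data),
             "mse_nflt_mean": float(mse_nfl.data) / n_points,
             "bce_vp_mean": float(bce_vp.data) / n_points}
    if variant == "reg":
        if al_se_residuals is None:
            raise ValueError("REG loss needs al/se residuals")
        r_al, r_se = al_se_residuals
        mse_al = float(np.sum(w * np.asarray(r_al) ** 2) / w.sum())
        mse_se = float(np.sum(w * np.asarray(r_se) ** 2) / w.sum())
        total = ag.add(total, ag.constant(mse_al + mse_se))
        comps["mse_al"], comps["mse_se"] = mse_al, mse_se
    else:
        comps["mse_al"] = comps["mse_se"] = 0.0
    comps["total"] = float(total.data)
    return total, comps


# ---------------------------------------------------------------------------
# training

def participant_weights(eyes):
    """Per-eye sample weights: 1/2 when the participant contributes two
    eyes, 1 otherwise (each participant totals 1)."""
    counts = {}
    for e in eyes:
        counts[e.participant_id] = counts.get(e.participant_id, 0) + 1
    return np.array([1.0 / counts[e.participant_id] for e in eyes])


def grouped_validation_split(eyes, val_fraction, rng):
    """Participant-grouped internal-validation split (indices)."""
    pids = sorted({e.participant_id for e in eyes})
    if len(pids) < 10:
        raise ValueError("too_small_for_internal_validation")
    pids = list(pids)
    rng.shuffle(pids)
    n_val = max(1, int(round(val_fraction * len(pids))))
    val_pids = set(pids[:n_val])
    val_idx = [i for i, e in enumerate(eyes) if e.participant_id in val_pids]
    train_idx = [i for i, e in enumerate(eyes) if e.participant_id not in val_pids]
    return np.array(train_idx), np.array(val_idx)


@dataclass
class TrainLog:
    rows: list = field(default_factory=list)  # dicts: epoch, split, components

    def append(self, epoch, split, comps):
        row = {"epoch": epoch, "split": split}
        row.update(comps)
        self.rows.append(row)

    def to_csv(self, path):
        import pandas as pd
        pd.DataFrame(self.rows).to_csv(path, index=False)

    def series(self, split="val", key="total"):
        return [r[key] for r in self.rows if r["split"] == split]


def _batch_arrays(eyes, variant, stats, rcnn):
    """Eyes are measured-scale (filtered + vessel-normalized); z-scoring
    happens here with the frozen training stats."""
    x_nfl = np.stack([stats.profile(e.nflt_profile) for e in eyes])
    x_vp = np.stack([e.vp_profile for e in eyes]).astype(float)
    cond = np.stack([make_conditions(e, variant, stats, rcnn) for e in eyes])
    w = participant_weights(eyes)
    res = None
    if variant == "reg":
        # standardized residuals of the frozen rCNN against measured AL/SE
        r_al = cond[:, 4] - np.array([stats.scalar(e, "al") for e in eyes])
        r_se = cond[:, 5] - np.array([stats.scalar(e, "se") for e in eyes])
        res = (r_al, r_se)
    return x_nfl, x_vp, cond, w, res


def train_model(train_eyes, variant, hp: CVAEHyperParams = None, seed=0,
                stats: StandardizationStats = None, rcnn=None, verbose=False):
    """Train a DualCVAE on prepped, standardized eyes.

    Model selection is the best-internal-validation-loss checkpoint over
    epochs, with the validation split grouped by participant. Fully
    deterministic for fixed (eyes, hp, seed).
    Returns (model, TrainLog).
    """
    hp = hp or CVAEHyperParams()
    if stats is None:
        raise ValueError("training requires the fitted StandardizationStats")
    if variant == "reg" and rcnn is None:
        raise ValueError("REG variant requires a trained rcnn")
    rng = np.random.default_rng(seed)
    model = DualCVAE(variant, hp, seed=int(rng.integers(2 ** 31)))
    model.stats = stats

    tr_idx, va_idx = grouped_validation_split(train_eyes, hp.val_fraction, rng)
    tr = [train_eyes[i] for i in tr_idx]
    va = [train_eyes[i] for i in va_idx]
    xn, xv, cond, w, res = _batch_arrays(tr, variant, stats, rcnn)
    xn_v, xv_v, cond_v, w_v, res_v = _batch_arrays(va, variant, stats, rcnn)

    opt = nnet.Adam(model.parameters(), lr=hp.learning_rate,
                    decay=hp.adam_decay, l2=hp.l2)
    log = TrainLog()
    best = (np.inf, None, -1)
    n = len(tr)
    for epoch in range(1, hp.max_epochs + 1):
        order = rng.permutation(n)
        ep_comps = []
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            out = model.forward(xn[idx], xv[idx], cond[idx], rng, training=True)
            rb = None if res is None else (res[0][idx], res[1][idx])
            total, comps = compute_loss(out, xn[idx], xv[idx], w[idx], variant,
                                        al_se_residuals=rb, kl_beta=hp.kl_beta)
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_comps.append(comps)
        mean_comps = {k: float(np.mean([c[k] for c in ep_comps]))
                      for k in ep_comps[0]}
        log.append(epoch, "train", mean_comps)

        out = model.forward(xn_v, xv_v, cond_v, rng, training=False)
        _, vcomps = compute_loss(out, xn_v, xv_v, w_v, variant,
                                 al_se_residuals=res_v, kl_beta=hp.kl_beta)
        log.append(epoch, "val", vcomps)
        if verbose:
            print(f"epoch {epoch:3d} train {mean_comps['total']:.4f} "
                  f"val {vcomps['total']:.4f}")
        if vcomps["total"] < best[0]:
            best = (vcomps["total"],
                    [a.copy() for a in model.state_arrays()], epoch)
        elif epoch - best[2] >= hp.patience:
            break
    model.load_state_arrays(best[1])
    model.best_epoch = best[2]
    return model, log


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: DualCVAE, path, config_hash=""):
    meta = {"variant": model.variant, "hp": asdict(model.hp),
            "stats": model.stats.to_dict(), "config_hash": config_hash}
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        arrays = [f[f"p{i}"] for i in range(len(f.files) - 1)]
    hp = CVAEHyperParams(**{**meta["hp"],
                            "channels": tuple(meta["hp"]["channels"])})
    model = DualCVAE(meta["variant"], hp, seed=0)
    model.load_state_arrays(arrays)
    model.stats = StandardizationStats.from_dict(meta["stats"])
    model.config_hash = meta.get("config_hash", "")
    return model
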