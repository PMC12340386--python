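"""Regression CNN estimating axial length and spherical equivalent.

Inputs are the two polar annulus maps around the disc center (diameters
2-4 mm): the binary vascular-pattern map and the RPE elevation map
(never the ILM surface, which glaucoma deforms), plus the demographic
scalars. The per-eye mean elevation is removed from the RPE map before
the network sees it, so estimates depend on surface *curvature* — the
magnification signal — and are exactly invariant to constant elevation
offsets.

Architecture: the two maps are stacked radius-wise into channels, three
circularly padded conv blocks run along the angular axis, global average
pooling over angle, then demographics are concatenated and a small FC
head emits (AL, SE) in standardized units. Trained with MSE_AL + MSE_SE
under the same Adam/dropout/decay regime as the CVAEs; the rCNN is
trained first and frozen, then its predictions condition the REG CVAE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nnet
from .nnet import autograd as ag
from .cvae import participant_weights, grouped_validation_split, TrainLog
from .prep import StandardizationStats

AL_WINDOW_MM = (20.0, 32.0)  # physiological clamp on inverse-standardized AL

_DEMO_FEATURES = ("age", "sex", "ssi", "disc_area")


@dataclass
class MagnificationEstimate:
    al_hat: float            # mm
    se_hat: float            # diopters
    provenance: str = "rcnn"  # "measured" | "rcnn"
    clamped: bool = False


@dataclass
class RCNNHyperParams:
    map_shape: tuple = (16, 64)
    channels: tuple = (16, 32, 64)
    kernel: int = 5
    fc_width: int = 32
    dropout: float = 0.5
    learning_rate: float = 1e-3
    adam_decay: float = 1e-3
    l2: float = 0.02
    batch_size: int = 32
    max_epochs: int = 120
    patience: int = 20
    val_fraction: float = 0.10


class MagnificationRCNN(nnet.Module):
    def __init__(self, hp: RCNNHyperParams, seed=0):
        self.hp = hp
        rng = np.random.default_rng(seed)
        n_r, n_a = hp.map_shape
        c_in = 2 * n_r  # vp + rpe maps, radii stacked as channels
        self.blocks = []
        prev = c_in
        for c in hp.channels:
            self.blocks.append(nnet.Conv1dCirc(prev, c, kernel=hp.kernel,
                                               stride=2, rng=rng))
            prev = c
        self.fc1 = nnet.Dense(hp.channels[-1] + len(_DEMO_FEATURES),
                              hp.fc_width, rng)
        self.head = nnet.Dense(hp.fc_width, 2, rng)
        self.dropout = nnet.Dropout(hp.dropout)
        self.stats: StandardizationStats | None = None

    @staticmethod
    def _map_input(eye, hp):
        if eye.vp_map is None or eye.rpe_map is None:
            raise ValueError("eye has no annulus maps")
        if eye.vp_map.shape != tuple(hp.map_shape):
            raise ValueError(f"map grid mismatch: expected {tuple(hp.map_shape)}, "
                             f"received {eye.vp_map.shape}")
        rpe = eye.rpe_map - eye.rpe_map.mean()  # remove per-eye mean elevation
        rpe = rpe / 10.0                        # bring um-scale curvature to O(1)
        return np.concatenate([eye.vp_map.astype(float), rpe], axis=0).T  # (A, 2R)

    def forward(self, x_maps, demo, rng=None, training=False):
        """x_maps: (B, A, 2R) channels-last; demo: (B, 4) standardized."""
        h = ag.constant(x_maps)
        for blk in self.blocks:
            h = ag.leaky_relu(blk(h), 0.1)
        h = ag.mean(h, axis=1)                  # global average pool over angle
        h = ag.concat([h, ag.constant(demo)], axis=1)
        h = ag.leaky_relu(self.fc1(h), 0.1)
        h = self.dropout(h, rng=rng, training=training)
        return self.head(h)                     # (B, 2): standardized (AL, SE)

    def predict(self, eye) -> MagnificationEstimate:
        """Measurement-scale estimate for one eye, AL clamped to the
        physiological window."""
        if self.stats is None:
            raise ValueError("model not trained (no stats attached)")
        x = self._map_input(eye, self.hp)[None]
        demo = np.array([[self.stats.scalar(eye, f) for f in _DEMO_FEATURES]])
        out = self.forward(x, demo, training=False).data[0]
        al = out[0] * self.stats.scalar_sd["al"] + self.stats.scalar_mean["al"]
        se = out[1] * self.stats.scalar_sd["se"] + self.stats.scalar_mean["se"]
        clamped = not AL_WINDOW_MM[0] <= al <= AL_WINDOW_MM[1]
        al = float(np.clip(al, *AL_WINDOW_MM))
        return MagnificationEstimate(al_hat=al, se_hat=float(se),
                                     provenance="rcnn", clamped=clamped)


class IdentityMagnification:
    """Oracle stub passing through the measured AL/SE (test double; makes
    the REG variant condition-identical to MAG)."""

    def predict(self, eye):
        return MagnificationEstimate(al_hat=float(eye.al), se_hat=float(eye.se),
                                     provenance="measured")


def rcnn_loss(predictions, targets, weights=None):
    """MSE_AL + MSE_SE on standardized values; returns (total, components).

    Accepts plain arrays (B, 2); weighted mean over eyes.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=float)
    sq = (p - t) ** 2
    mse_al = float(np.sum(w * sq[:, 0]) / w.sum())
    mse_se = float(np.sum(w * sq[:, 1]) / w.sum())
    return mse_al + mse_se, {"mse_al": mse_al, "mse_se": mse_se}


def _loss_node(pred, targets, weights):
    w = np.asarray(weights, dtype=float)
    sq = ag.pow_(ag.sub(pred, ag.constant(targets)), 2.0)
    per_eye = ag.sum_(sq, axis=1)  # AL + SE squared residuals
    return ag.div(ag.sum_(ag.mul(per_eye, ag.constant(w))), ag.constant(w.sum()))


def train_rcnn(train_eyes, hp: RCNNHyperParams = None, seed=0,
               stats: StandardizationStats = None, verbose=False):
    """Train on measured AL/SE; same regime as the CVAE training
    (participant-grouped 10% internal validation, best-checkpoint
    selection, per-eye weight halving, deterministic under seed)."""
    hp = hp or RCNNHyperParams()
    if stats is None:
        raise ValueError("training requires the fitted StandardizationStats")
    rng = np.random.default_rng(seed)
    model = MagnificationRCNN(hp, seed=int(rng.integers(2 ** 31)))
    model.stats = stats

    tr_idx, va_idx = grouped_validation_split(train_eyes, hp.val_fraction, rng)
    tr = [train_eyes[i] for i in tr_idx]
    va = [train_eyes[i] for i in va_idx]

    def arrays(eyes):
        x = np.stack([model._map_input(e, hp) for e in eyes])
        demo = np.stack([[stats.scalar(e, f) for f in _DEMO_FEATURES]
                         for e in eyes])
        t = np.stack([[stats.scalar(e, "al"), stats.scalar(e, "se")]
                      for e in eyes])
        return x, demo, t, participant_weights(eyes)

    x, demo, t, w = arrays(tr)
    x_v, demo_v, t_v, w_v = arrays(va)
    opt = nnet.Adam(model.parameters(), lr=hp.learning_rate,
                    decay=hp.adam_decay, l2=hp.l2)
    log = TrainLog()
    best = (np.inf, None, -1)
    n = len(tr)
    for epoch in range(1, hp.max_epochs + 1):
        order = rng.permutation(n)
        ep = []
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            pred = model.forward(x[idx], demo[idx], rng=rng, training=True)
            loss = _loss_node(pred, t[idx], w[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(float(loss.data))
        _, comps = rcnn_loss(model.forward(x, demo, training=False).data, t, w)
        comps["total"] = float(np.mean(ep))
        log.append(epoch, "train", comps)
        vtotal, vcomps = rcnn_loss(model.forward(x_v, demo_v, training=False).data,
                                   t_v, w_v)
        vcomps["total"] = vtotal
        log.append(epoch, "val", vcomps)
        if verbose:
            print(f"epoch {epoch:3d} train {comps['total']:.4f} val {vtotal:.4f}")
        if vtotal < best[0]:
            best = (vtotal, [a.copy() for a in model.state_arrays()], epoch)
        elif epoch - best[2] >= hp.patience:
            break
    model.load_state_arrays(best[1])
    model.best_epoch = best[2]
    return model, log


def predict_magnification(eye, rcnn_model) -> MagnificationEstimate:
    return rcnn_model.predict(eye)


def save_rcnn_checkpoint(model: MagnificationRCNN, path, config_hash=""):
    meta = {"hp": asdict(model.hp), "stats": model.stats.to_dict(),
            "config_hash": config_hash}
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_rcnn_checkpoint(path):
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        arrays = [f[f"p{i}"] for i in range(len(f.files) - 1)]
    hp = RCNNHyperParams(**{**meta["hp"],
                            "map_shape": tuple(meta["hp"]["map_shape"]),
                            "channels": tuple(meta["hp"]["channels"])})
    model = MagnificationRCNN(hp, seed=0)
    model.load_state_arrays(arrays)
    model.stats = StandardizationStats.from_dict(meta["stats"])
    return model
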