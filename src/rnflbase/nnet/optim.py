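"""Adam optimizer with decoupled weight decay.

The training recipe uses Adam at learning rate 1e-3 with optimizer decay
1e-3 and an L2 regularisation factor of 0.02. Both regularisers act as
decoupled weight decay on the update (the L2 factor is scaled by the
learning rate, as common deep-learning toolboxes do), so the effective
per-step shrinkage is lr * (decay + l2). Bias vectors are not decayed.
"""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 decay=1e-3, l2=0.02):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = decay + l2
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if p.data.ndim > 1 and self.wd > 0.0:  # decay weights, not biases
                p.data *= 1.0 - self.lr * self.wd
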