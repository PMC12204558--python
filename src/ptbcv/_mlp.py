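"""A compact NumPy multilayer perceptron for binary outcomes.

Architecture: input -> dense(l1) -> batch norm -> Leaky ReLU -> dropout(p1)
-> dense(l2) -> batch norm -> Leaky ReLU -> dropout(p2) -> dense(1) ->
sigmoid, trained with Adam on the binary cross-entropy (with-logits) loss
and L2 weight decay on the dense weights.  Hyperparameters (l1, l2, p1, p2,
learning rate, weight decay, batch size) are searched by successive halving
with a configurable reduction factor: a batch of sampled configurations is
trained for a small epoch budget, the top 1/eta survive to an eta-fold
larger budget, and so on up to the epoch cap; the winner (highest
validation AUROC, lower validation loss as tie-break) is refitted on the
full training data.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

_LEAKY_SLOPE = 0.01
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class MLPHyperparams:
    l1: int
    l2: int
    p1: float
    p2: float
    lr: float
    weight_decay: float
    batch_size: int


def sample_hyperparams(rng: np.random.Generator) -> MLPHyperparams:
    """Draw one configuration from the default search ranges."""
    return MLPHyperparams(
        l1=int(2 ** rng.uniform(4, 8)),            # 16..256, log-uniform
        l2=int(2 ** rng.uniform(4, 8)),
        p1=float(rng.uniform(0.0, 0.5)),
        p2=float(rng.uniform(0.0, 0.5)),
        lr=float(10 ** rng.uniform(-4, -2)),
        weight_decay=float(10 ** rng.uniform(-6, -2)),
        batch_size=int(rng.choice([16, 32, 64])),
    )


class TwoHiddenLayerMLP:
    """The network itself; holds parameters, Adam state and BN statistics."""

    def __init__(self, n_in: int, hp: MLPHyperparams, seed: int):
        self.hp = hp
        self.rng = np.random.default_rng(seed)
        r = self.rng
        def he(n_a, n_b):
            return r.standard_normal((n_a, n_b)) * np.sqrt(2.0 / n_a)
        self.params = {
            "W1": he(n_in, hp.l1), "b1": np.zeros(hp.l1),
            "g1": np.ones(hp.l1), "be1": np.zeros(hp.l1),
            "W2": he(hp.l1, hp.l2), "b2": np.zeros(hp.l2),
            "g2": np.ones(hp.l2), "be2": np.zeros(hp.l2),
            "W3": he(hp.l2, 1), "b3": np.zeros(1),
        }
        self.running = {
            "m1": np.zeros(hp.l1), "v1": np.ones(hp.l1),
            "m2": np.zeros(hp.l2), "v2": np.ones(hp.l2),
        }
        self.adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.adam_t = 0
        self.epochs_trained = 0

    # -- forward -----------------------------------------------------------

    def _bn_forward(self, z, layer, train):
        g = self.params[f"g{layer}"]
        be = self.params[f"be{layer}"]
        if train:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            run_m, run_v = self.running[f"m{layer}"], self.running[f"v{layer}"]
            run_m *= _BN_MOMENTUM
            run_m += (1 - _BN_MOMENTUM) * mu
            run_v *= _BN_MOMENTUM
            run_v += (1 - _BN_MOMENTUM) * var
        else:
            mu, var = self.running[f"m{layer}"], self.running[f"v{layer}"]
        xhat = (z - mu) / np.sqrt(var + _BN_EPS)
        return g * xhat + be, (xhat, var)

    def forward(self, X, train=False):
        cache = {"X": X}
        p = self.params
        z1 = X @ p["W1"] + p["b1"]
        bn1, cache["bn1"] = self._bn_forward(z1, 1, train)
        a1 = np.where(bn1 > 0, bn1, _LEAKY_SLOPE * bn1)
        cache["bn1_out"] = bn1
        if train and self.hp.p1 > 0:
            mask1 = (self.rng.random(a1.shape) >= self.hp.p1) / (1 - self.hp.p1)
            a1 = a1 * mask1
            cache["mask1"] = mask1
        cache["a1"] = a1
        z2 = a1 @ p["W2"] + p["b2"]
        bn2, cache["bn2"] = self._bn_forward(z2, 2, train)
        a2 = np.where(bn2 > 0, bn2, _LEAKY_SLOPE * bn2)
        cache["bn2_out"] = bn2
        if train and self.hp.p2 > 0:
            mask2 = (self.rng.random(a2.shape) >= self.hp.p2) / (1 - self.hp.p2)
            a2 = a2 * mask2
            cache["mask2"] = mask2
        cache["a2"] = a2
        logits = (a2 @ p["W3"] + p["b3"]).ravel()
        return logits, cache

    # -- backward ----------------------------------------------------------

    @staticmethod
    def _bn_backward(dout, g, bn_cache):
        xhat, var = bn_cache
        m = dout.shape[0]
        dg = (dout * xhat).sum(axis=0)
        dbe = dout.sum(axis=0)
        dxhat = dout * g
        dz = (1.0 / m) / np.sqrt(var + _BN_EPS) * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return dz, dg, dbe

    def gradients(self, X, y):
        p = self.params
        logits, c = self.forward(X, train=True)
        n = len(y)
        dlogit = (expit(logits) - y)[:, None] / n
        grads = {}
        grads["W3"] = c["a2"].T @ dlogit
        grads["b3"] = dlogit.sum(axis=0)
        da2 = dlogit @ p["W3"].T
        if "mask2" in c:
            da2 = da2 * c["mask2"]
        dbn2 = da2 * np.where(c["bn2_out"] > 0, 1.0, _LEAKY_SLOPE)
        dz2, grads["g2"], grads["be2"] = self._bn_backward(dbn2, p["g2"], c["bn2"])
        grads["W2"] = c["a1"].T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        da1 = dz2 @ p["W2"].T
        if "mask1" in c:
            da1 = da1 * c["mask1"]
        dbn1 = da1 * np.where(c["bn1_out"] > 0, 1.0, _LEAKY_SLOPE)
        dz1, grads["g1"], grads["be1"] = self._bn_backward(dbn1, p["g1"], c["bn1"])
        grads["W1"] = c["X"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        for k in ("W1", "W2", "W3"):
            grads[k] = grads[k] + self.hp.weight_decay * p[k]
        loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
        return grads, loss

    def _adam_step(self, grads):
        self.adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.adam_m[k] = b1 * self.adam_m[k] + (1 - b1) * g
            self.adam_v[k] = b2 * self.adam_v[k] + (1 - b2) * g**2
            mhat = self.adam_m[k] / (1 - b1**self.adam_t)
            vhat = self.adam_v[k] / (1 - b2**self.adam_t)
            self.params[k] -= self.hp.lr * mhat / (np.sqrt(vhat) + eps)

    # -- training ----------------------------------------------------------

    def train_epochs(self, X, y, n_epochs):
        n = len(y)
        bs = min(self.hp.batch_size, n)
        for _ in range(n_epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                if len(idx) < 2:
                    continue  # batch norm needs at least two rows
                grads, _ = self.gradients(X[idx], y[idx])
                self._adam_step(grads)
            self.epochs_trained += 1

    def predict_proba(self, X):
        logits, _ = self.forward(X, train=False)
        return expit(logits)


# ---------------------------------------------------------------------------
# successive-halving search


def _val_metrics(net, Xv, yv):
    logits, _ = net.forward(Xv, train=False)
    from scipy.stats import rankdata

    loss = float(np.mean(np.logaddexp(0.0, logits) - yv * logits))
    ranks = rankdata(logits, method="average")
    n_pos = int((yv == 1).sum())
    n_neg = len(yv) - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.5, loss
    auroc = (ranks[yv == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auroc), loss


def tune_and_fit(
    X: np.ndarray,
    y: np.ndarray,
    search_budget: int = 20,
    max_epochs: int = 250,
    reduction_factor: int = 4,
    seed: int = 0,
    val_fraction: float = 0.2,
):
    """Successive-halving search, then refit the winner on all rows.

    Returns (net, hyperparams, best_val_auroc).
    """
    if search_budget < 1:
        raise ValueError("search_budget must be >= 1")
    if reduction_factor < 2:
        raise ValueError("reduction_factor must be >= 2")
    ss = np.random.SeedSequence(seed)
    rng_cfg, rng_split, *net_seeds = ss.spawn(2 + search_budget + 1)
    rng = np.random.default_rng(rng_cfg)
    configs = [sample_hyperparams(rng) for _ in range(search_budget)]

    # stratified holdout for the search
    split_rng = np.random.default_rng(rng_split)
    pos = split_rng.permutation(np.flatnonzero(y == 1))
    neg = split_rng.permutation(np.flatnonzero(y == 0))
    n_vp = max(1, int(round(val_fraction * len(pos))))
    n_vn = max(1, int(round(val_fraction * len(neg))))
    val_idx = np.concatenate([pos[:n_vp], neg[:n_vn]])
    tr_idx = np.concatenate([pos[n_vp:], neg[n_vn:]])
    Xt, yt, Xv, yv = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    n_rungs = 0
    while reduction_factor ** (n_rungs + 1) <= search_budget:
        n_rungs += 1
    epoch_steps = [max(1, max_epochs // reduction_factor ** (n_rungs - i))
                   for i in range(n_rungs + 1)]

    nets = [TwoHiddenLayerMLP(X.shape[1], hp, seed=int(s.generate_state(1)[0] % (2**31)))
            for hp, s in zip(configs, net_seeds)]
    alive = list(range(len(nets)))
    results = {}
    for rung, target_epochs in enumerate(epoch_steps):
        for i in alive:
            extra = min(target_epochs, max_epochs) - nets[i].epochs_trained
            if extra > 0:
                nets[i].train_epochs(Xt, yt, extra)
            results[i] = _val_metrics(nets[i], Xv, yv)
        if rung < len(epoch_steps) - 1:
            alive = sorted(alive, key=lambda i: (-results[i][0], results[i][1], i))
            alive = alive[: max(1, len(alive) // reduction_factor)]
    winner = min(alive, key=lambda i: (-results[i][0], results[i][1], i))
    best_auroc = results[winner][0]

    final = TwoHiddenLayerMLP(
        X.shape[1], configs[winner],
        seed=int(net_seeds[-1].generate_state(1)[0] % (2**31)),
    )
    final.train_epochs(X, y, max_epochs)
    return final, configs[winner], best_auroc
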