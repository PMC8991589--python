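"""A small feed-forward network for PRS extraction, in plain NumPy.

Architecture: SNP dosages -> ``n_hidden_layers`` dense layers of width
``round(sqrt(n_snps)) + 2`` with leaky-ReLU and (inverted) dropout -> a
linear bottleneck -> the bottleneck concatenated with covariates
(age, pc1, pc2) -> a single sigmoid output.  Trained full-batch with Adam on
the sigmoid cross-entropy.  The panel sizes involved (tens of SNPs, a few
thousand samples) make hand-written forward/backward passes both fast and
exactly reproducible from a seed.
"""

from __future__ import annotations

import numpy as np


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class MLP:
    """Genotype pathway + covariate output head.

    Parameters are plain arrays so the model serializes to JSON trivially.
    """

    def __init__(
        self,
        n_snps: int,
        n_cov: int,
        n_hidden_layers: int,
        hidden_width: int,
        bottleneck_dim: int,
        leaky_slope: float,
        seed: int,
    ):
        rng = np.random.default_rng(seed)
        self.leaky_slope = leaky_slope
        dims = [n_snps] + [hidden_width] * n_hidden_layers
        self.Ws = [_glorot(rng, dims[i], dims[i + 1]) for i in range(n_hidden_layers)]
        self.bs = [np.zeros(dims[i + 1]) for i in range(n_hidden_layers)]
        self.Wb = _glorot(rng, dims[-1], bottleneck_dim)
        self.bb = np.zeros(bottleneck_dim)
        self.v = _glorot(rng, bottleneck_dim + n_cov, 1)[:, 0]
        self.c = 0.0
        self.n_cov = n_cov
        self.bottleneck_dim = bottleneck_dim

    # -- forward -----------------------------------------------------------
    def bottleneck(self, X: np.ndarray) -> np.ndarray:
        h = X
        for W, b in zip(self.Ws, self.bs):
            h = leaky_relu(h @ W + b, self.leaky_slope)
        return h @ self.Wb + self.bb

    def logit(self, X: np.ndarray, C: np.ndarray) -> np.ndarray:
        z = self.bottleneck(X)
        return np.concatenate([z, C], axis=1) @ self.v + self.c

    def genotype_score(self, X: np.ndarray) -> np.ndarray:
        """Genotype-pathway contribution to the pre-sigmoid logit (bottleneck
        activations times their output weights, plus the output bias)."""
        z = self.bottleneck(X)
        return z @ self.v[: self.bottleneck_dim] + self.c

    # -- training ----------------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return self.Ws + self.bs + [self.Wb, self.bb, self.v, np.array([self.c])]

    def _set_c(self, arr: np.ndarray) -> None:
        self.c = float(arr[0])

    def train(
        self,
        X: np.ndarray,
        C: np.ndarray,
        y: np.ndarray,
        n_epochs: int,
        learning_rate: float,
        dropout_rate: float,
        seed: int,
        batch_size: int = 32,
    ) -> list[float]:
        """Mini-batch Adam on sigmoid cross-entropy; returns per-epoch mean
        loss.  ``batch_size <= 0`` trains full-batch."""
        rng = np.random.default_rng(seed)
        n = len(y)
        if batch_size <= 0 or batch_size > n:
            batch_size = n
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self.params()
        ms = [np.zeros_like(p) for p in params]
        vs = [np.zeros_like(p) for p in params]
        losses = []
        t_ = 0
        for epoch in range(1, n_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                Xb, Cb, yb = X[idx], C[idx], y[idx]
                nb = len(idx)

                # forward with (inverted) dropout
                acts = [Xb]
                masks = []
                h = Xb
                for W, b in zip(self.Ws, self.bs):
                    pre = h @ W + b
                    h = leaky_relu(pre, self.leaky_slope)
                    if dropout_rate > 0:
                        keep = rng.random(h.shape) >= dropout_rate
                        h = h * keep / (1.0 - dropout_rate)
                        masks.append(keep)
                    else:
                        masks.append(None)
                    acts.append(h)
                z = h @ self.Wb + self.bb
                u = np.concatenate([z, Cb], axis=1)
                logit = u @ self.v + self.c
                p = 1.0 / (1.0 + np.exp(-logit))
                loss = -np.mean(yb * np.log(p + 1e-12) + (1 - yb) * np.log(1 - p + 1e-12))
                if not np.isfinite(loss):
                    raise FloatingPointError(f"NaN loss at epoch {epoch}")
                epoch_loss += loss * nb

                # backward
                dlogit = (p - yb) / nb
                gv = u.T @ dlogit
                gc = np.array([dlogit.sum()])
                du = np.outer(dlogit, self.v)
                dz = du[:, : self.bottleneck_dim]
                gWb = acts[-1].T @ dz
                gbb = dz.sum(axis=0)
                dh = dz @ self.Wb.T
                gWs: list[np.ndarray] = [None] * len(self.Ws)
                gbs: list[np.ndarray] = [None] * len(self.bs)
                for li in range(len(self.Ws) - 1, -1, -1):
                    if masks[li] is not None:
                        dh = dh * masks[li] / (1.0 - dropout_rate)
                    a_prev = acts[li]
                    pre = a_prev @ self.Ws[li] + self.bs[li]
                    dpre = dh * np.where(pre > 0, 1.0, self.leaky_slope)
                    gWs[li] = a_prev.T @ dpre
                    gbs[li] = dpre.sum(axis=0)
                    dh = dpre @ self.Ws[li].T

                grads = gWs + gbs + [gWb, gbb, gv, gc]
                t_ += 1
                for i, (pmt, gr) in enumerate(zip(params, grads)):
                    ms[i] = b1 * ms[i] + (1 - b1) * gr
                    vs[i] = b2 * vs[i] + (1 - b2) * gr * gr
                    mhat = ms[i] / (1 - b1**t_)
                    vhat = vs[i] / (1 - b2**t_)
                    pmt -= learning_rate * mhat / (np.sqrt(vhat) + eps)
                self._set_c(params[-1])
            losses.append(float(epoch_loss / n))
        return losses

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "leaky_slope": self.leaky_slope,
            "n_cov": self.n_cov,
            "bottleneck_dim": self.bottleneck_dim,
            "Ws": [w.tolist() for w in self.Ws],
            "bs": [b.tolist() for b in self.bs],
            "Wb": self.Wb.tolist(),
            "bb": self.bb.tolist(),
            "v": self.v.tolist(),
            "c": self.c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        obj = cls.__new__(cls)
        obj.leaky_slope = d["leaky_slope"]
        obj.n_cov = d["n_cov"]
        obj.bottleneck_dim = d["bottleneck_dim"]
        obj.Ws = [np.array(w) for w in d["Ws"]]
        obj.bs = [np.array(b) for b in d["bs"]]
        obj.Wb = np.array(d["Wb"])
        obj.bb = np.array(d["bb"])
        obj.v = np.array(d["v"])
        obj.c = float(d["c"])
        return obj
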