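"""A small tabular variational autoencoder on standardized columns.

Encoder and decoder are tanh MLPs (defaults 32-16 hidden units, 8 latent
dimensions). Training minimizes per-sample squared reconstruction error plus
``kl_weight`` times the KL divergence of the Gaussian posterior from the
standard-normal prior, with Adam. The implementation is plain numpy with
manual gradients: the network is tiny and the matrices involved are small, so
no autodiff framework is needed, and the whole state (weights plus the
standardization constants) serializes to a plain dict.

Sampling draws z ~ N(0, I), decodes, and de-standardizes back to the original
column scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite or fails to decrease."""


@dataclass
class VaeSpec:
    latent_dim: int = 8
    hidden_dims: tuple = (32, 16)
    epochs: int = 200
    batch_size: int = 32
    kl_weight: float = 1.0
    learning_rate: float = 2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")


def _xavier(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (n_in + n_out))
    return rng.normal(0.0, scale, size=(n_in, n_out))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class TabularVAE:
    """VAE over the standardized continuous columns (features + target)."""

    def __init__(self, n_inputs: int, spec: VaeSpec | None = None):
        self.spec = spec or VaeSpec()
        self.n_inputs = n_inputs
        self.mu_: np.ndarray = np.zeros(n_inputs)       # column means
        self.sd_: np.ndarray = np.ones(n_inputs)        # column sds
        self.loss_history_: list[float] = []
        rng = np.random.default_rng(self.spec.seed)
        dims = [n_inputs, *self.spec.hidden_dims]
        # encoder trunk
        self.We = [_xavier(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
        self.be = [np.zeros(d) for d in dims[1:]]
        h_last = dims[-1]
        z = self.spec.latent_dim
        self.Wmu, self.bmu = _xavier(rng, h_last, z), np.zeros(z)
        self.Wlv, self.blv = _xavier(rng, h_last, z), np.zeros(z)
        # decoder trunk (mirror)
        ddims = [z, *reversed(self.spec.hidden_dims)]
        self.Wd = [_xavier(rng, ddims[i], ddims[i + 1]) for i in range(len(ddims) - 1)]
        self.bd = [np.zeros(d) for d in ddims[1:]]
        self.Wo, self.bo = _xavier(rng, ddims[-1], n_inputs), np.zeros(n_inputs)

    # ------------------------------------------------------------ forward
    def _params(self) -> list[np.ndarray]:
        return [*self.We, *self.be, self.Wmu, self.bmu, self.Wlv, self.blv,
                *self.Wd, *self.bd, self.Wo, self.bo]

    def _encode(self, x: np.ndarray):
        acts = [x]
        h = x
        for W, b in zip(self.We, self.be):
            h = np.tanh(h @ W + b)
            acts.append(h)
        return h @ self.Wmu + self.bmu, h @ self.Wlv + self.blv, acts

    def _decode(self, z: np.ndarray):
        acts = [z]
        h = z
        for W, b in zip(self.Wd, self.bd):
            h = np.tanh(h @ W + b)
            acts.append(h)
        return h @ self.Wo + self.bo, acts

    # ------------------------------------------------------------- training
    def fit(self, X: np.ndarray) -> "TabularVAE":
        """Standardize ``X`` and train; records per-epoch mean loss.

        Raises :class:`TrainingDivergenceError` if the loss goes non-finite or
        the final epoch fails to improve on the first (for >= 2 epochs).
        """
        X = np.asarray(X, dtype=float)
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 1e-12, sd, 1.0)
        Z = (X - self.mu_) / self.sd_
        spec = self.spec
        rng = np.random.default_rng(spec.seed + 1)
        opt = _Adam(self._params(), spec.learning_rate)
        n = len(Z)
        for _epoch in range(spec.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, spec.batch_size):
                xb = Z[order[start:start + spec.batch_size]]
                loss = self._train_step(xb, rng, opt)
                epoch_loss += loss
                n_batches += 1
            epoch_loss /= max(n_batches, 1)
            if not np.isfinite(epoch_loss):
                raise TrainingDivergenceError(f"non-finite loss at epoch {_epoch + 1}")
            self.loss_history_.append(epoch_loss)
        if len(self.loss_history_) >= 2 and not (
            self.loss_history_[-1] < self.loss_history_[0]
        ):
            raise TrainingDivergenceError("final-epoch loss did not improve on epoch 1")
        return self

    def _train_step(self, x: np.ndarray, rng: np.random.Generator, opt: _Adam) -> float:
        B = len(x)
        klw = self.spec.kl_weight
        mu, lv, eacts = self._encode(x)
        lv = np.clip(lv, -10.0, 10.0)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * lv)
        z = mu + eps * std
        xhat, dacts = self._decode(z)

        recon = ((xhat - x) ** 2).sum(axis=1)
        kl = -0.5 * (1 + lv - mu**2 - np.exp(lv)).sum(axis=1)
        loss = float((recon + klw * kl).mean())

        # ---- backward
        dxhat = 2.0 * (xhat - x) / B
        gWo = dacts[-1].T @ dxhat
        gbo = dxhat.sum(axis=0)
        dh = dxhat @ self.Wo.T
        gWd, gbd = [], []
        for i in range(len(self.Wd) - 1, -1, -1):
            dh = dh * (1 - dacts[i + 1] ** 2)
            gWd.insert(0, dacts[i].T @ dh)
            gbd.insert(0, dh.sum(axis=0))
            dh = dh @ self.Wd[i].T
        dz = dh
        dmu = dz + klw * mu / B
        dlv = dz * eps * 0.5 * std + klw * 0.5 * (np.exp(lv) - 1.0) / B
        h_enc = eacts[-1]
        gWmu, gbmu = h_enc.T @ dmu, dmu.sum(axis=0)
        gWlv, gblv = h_enc.T @ dlv, dlv.sum(axis=0)
        dh = dmu @ self.Wmu.T + dlv @ self.Wlv.T
        gWe, gbe = [], []
        for i in range(len(self.We) - 1, -1, -1):
            dh = dh * (1 - eacts[i + 1] ** 2)
            gWe.insert(0, eacts[i].T @ dh)
            gbe.insert(0, dh.sum(axis=0))
            dh = dh @ self.We[i].T
        grads = [*gWe, *gbe, gWmu, gbmu, gWlv, gblv, *gWd, *gbd, gWo, gbo]
        opt.step(self._params(), grads)
        return loss

    # ------------------------------------------------------------- sampling
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Decode n prior draws back to the original column scales."""
        if n == 0:
            return np.empty((0, self.n_inputs))
        z = rng.standard_normal((n, self.spec.latent_dim))
        xhat, _ = self._decode(z)
        return xhat * self.sd_ + self.mu_

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mu_) / self.sd_
        mu, _, _ = self._encode(Z)
        xhat, _ = self._decode(mu)
        return xhat * self.sd_ + self.mu_

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "spec": self.spec.__dict__ | {"hidden_dims": list(self.spec.hidden_dims)},
            "n_inputs": self.n_inputs,
            "mu": self.mu_.tolist(),
            "sd": self.sd_.tolist(),
            "weights": [w.tolist() for w in self._params()],
            "loss_history": self.loss_history_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TabularVAE":
        spec_d = dict(d["spec"])
        spec_d["hidden_dims"] = tuple(spec_d["hidden_dims"])
        vae = cls(d["n_inputs"], VaeSpec(**spec_d))
        for p, w in zip(vae._params(), d["weights"]):
            p[...] = np.asarray(w, dtype=float)
        vae.mu_ = np.asarray(d["mu"], dtype=float)
        vae.sd_ = np.asarray(d["sd"], dtype=float)
        vae.loss_history_ = list(d["loss_history"])
        return vae
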