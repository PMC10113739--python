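"""Variational autoencoder over one-hot protein alignments (numpy backend).

A single-hidden-layer MLP encoder maps a flattened one-hot sequence to the
Gaussian posterior parameters (mu, sigma^2); the reparameterized code
z = mu + sigma * eps feeds a single-hidden-layer MLP decoder whose output
layer is a per-position softmax over the 23 symbols.  Training minimizes
the negative ELBO

    loss = -sum_i log p(a_i | z)  +  D_KL( N(mu, sigma^2) || N(0, I) )

(reconstruction cross-entropy summed over positions, KL summed over latent
dimensions, both averaged over the batch) with Adam, an L2 weight penalty
on the hidden-layer weight matrices, and patience-based early stopping that
restores the best-epoch parameters.  All forward/backward passes are
explicit numpy; given a seed, training is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alphabet import ALPHABET, Alphabet


class VAEError(ValueError):
    pass


@dataclass
class VAEConfig:
    """Training hyperparameters.

    hidden_units defaults to 3*L at train time when left as None.  The
    weight_penalty is an L2 penalty applied to the encoder and decoder
    hidden-layer weight matrices.  Training stops when the epoch mean loss
    has not improved for patience_epochs epochs (max_epochs is a hard cap).
    """

    latent_dim: int = 2
    hidden_units: Optional[int] = None
    activation: str = "relu"
    learning_rate: float = 1e-4
    weight_penalty: float = 1e-4
    patience_epochs: int = 10
    batch_size: int = 64
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise VAEError("latent_dim must be >= 1")
        if self.learning_rate <= 0:
            raise VAEError("learning_rate must be positive")
        if self.activation != "relu":
            raise VAEError("only the rectified-linear activation is supported")


_PARAM_NAMES = ("W1", "b1", "Wm", "bm", "Wv", "bv", "W2", "b2", "W3", "b3")


@dataclass
class VAEModel:
    """Trained (or freshly initialized) VAE with bound L and q."""

    params: dict
    config: VAEConfig
    L: int
    q: int
    alphabet: Alphabet = field(default_factory=lambda: ALPHABET, repr=False)

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One-hot (L, q) or (n, L, q) -> (mu, sigma^2), deterministic."""
        mu, logvar, _ = _encode(self.params, _flatten(x, self.L, self.q))
        var = np.exp(logvar)
        if x.ndim == 2:
            return mu[0], var[0]
        return mu, var

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Latent point(s) -> per-position categorical distributions.

        (d,) -> (L, q); (n, d) -> (n, L, q).  Rows sum to one.
        """
        z = np.asarray(z, dtype=np.float64)
        single = z.ndim == 1
        if single:
            z = z[None, :]
        if not np.isfinite(z).all():
            raise VAEError("latent coordinates must be finite")
        if z.shape[1] != self.config.latent_dim:
            raise VAEError(
                f"latent dim {z.shape[1]} != model latent_dim {self.config.latent_dim}"
            )
        p, _ = _decode(self.params, z, self.L, self.q)
        return p[0] if single else p

    def save(self, path: str | Path) -> None:
        """Weights as .npz next to a JSON sidecar with config/L/q/alphabet."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "config": asdict(self.config),
            "L": self.L,
            "q": self.q,
            "alphabet": self.alphabet.symbols,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VAEModel":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as npz:
            params = {k: npz[k] for k in npz.files}
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            params=params,
            config=VAEConfig(**sidecar["config"]),
            L=sidecar["L"],
            q=sidecar["q"],
        )


def _flatten(x: np.ndarray, L: int, q: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, ...]
    if x.shape[1:] != (L, q):
        raise VAEError(f"input shape {x.shape[1:]} != (L, q) = ({L}, {q})")
    return x.reshape(x.shape[0], L * q)


def _encode(params: dict, xf: np.ndarray):
    h_pre = xf @ params["W1"] + params["b1"]
    h = np.maximum(h_pre, 0.0)
    mu = h @ params["Wm"] + params["bm"]
    logvar = h @ params["Wv"] + params["bv"]
    return mu, logvar, (h_pre, h)


def _decode(params: dict, z: np.ndarray, L: int, q: int):
    g_pre = z @ params["W2"] + params["b2"]
    g = np.maximum(g_pre, 0.0)
    logits = (g @ params["W3"] + params["b3"]).reshape(-1, L, q)
    logits = logits - logits.max(axis=2, keepdims=True)
    expl = np.exp(logits)
    p = expl / expl.sum(axis=2, keepdims=True)
    return p, (g_pre, g, logits)


def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps, elementwise."""
    mu, sigma, eps = (np.asarray(a, dtype=np.float64) for a in (mu, sigma, eps))
    if not (mu.shape == sigma.shape == eps.shape):
        raise VAEError("mu, sigma and eps must have identical shapes")
    return mu + sigma * eps


def reconstruction_error(x: np.ndarray, probs: np.ndarray) -> float:
    """-sum_i log p(a_i): cross-entropy of the true symbols; zero iff the
    decoder puts probability one on every input symbol."""
    x = np.asarray(x, dtype=np.float64)
    p_true = (probs * x).sum(axis=-1)
    with np.errstate(divide="ignore"):
        return float(-np.sum(np.where(p_true > 0, np.log(p_true), -np.inf)))


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Closed-form KL( N(mu, sigma^2) || N(0, I) ), summed over dimensions."""
    return float(0.5 * np.sum(np.exp(logvar) + mu**2 - 1.0 - logvar))


def elbo_loss(
    x: np.ndarray, model: VAEModel, eps: Optional[np.ndarray] = None
) -> tuple[float, float, float]:
    """(total, reconstruction, kl) for one one-hot sequence.

    With eps omitted (or zero) the evaluation is deterministic: z = mu.
    """
    xf = _flatten(x, model.L, model.q)
    mu, logvar, _ = _encode(model.params, xf)
    if eps is None:
        eps = np.zeros_like(mu)
    else:
        eps = np.asarray(eps, dtype=np.float64).reshape(mu.shape)
    z = reparameterize(mu, np.exp(0.5 * logvar), eps)
    p, _ = _decode(model.params, z, model.L, model.q)
    recon = reconstruction_error(xf.reshape(p.shape), p)
    kl = kl_divergence(mu, logvar)
    return recon + kl, recon, kl


def _init_params(L: int, q: int, hidden: int, d: int, rng: np.random.Generator) -> dict:
    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    D = L * q
    return {
        "W1": glorot(D, hidden),
        "b1": np.zeros(hidden),
        "Wm": glorot(hidden, d),
        "bm": np.zeros(d),
        "Wv": glorot(hidden, d),
        "bv": np.zeros(d),
        "W2": glorot(d, hidden),
        "b2": np.zeros(hidden),
        "W3": glorot(hidden, D),
        "b3": np.zeros(D),
    }


def _batch_loss_and_grads(params: dict, xb: np.ndarray, eps: np.ndarray, L: int, q: int):
    """Mean loss over the batch and gradients for every parameter."""
    n = xb.shape[0]
    mu, logvar, (h_pre, h) = _encode(params, xb)
    sigma = np.exp(0.5 * logvar)
    z = mu + sigma * eps
    p, (g_pre, g, _) = _decode(params, z, L, q)

    x3 = xb.reshape(n, L, q)
    p_true = (p * x3).sum(axis=2)
    recon = -np.log(np.maximum(p_true, 1e-300)).sum(axis=1)
    kl = 0.5 * (np.exp(logvar) + mu**2 - 1.0 - logvar).sum(axis=1)
    loss = float((recon + kl).mean())

    # --- backward ---
    dlogits = (p - x3).reshape(n, L * q) / n
    dW3 = g.T @ dlogits
    db3 = dlogits.sum(axis=0)
    dg = dlogits @ params["W3"].T
    dg_pre = dg * (g_pre > 0)
    dW2 = z.T @ dg_pre
    db2 = dg_pre.sum(axis=0)
    dz = dg_pre @ params["W2"].T

    dmu = dz + mu / n
    dlogvar = dz * (0.5 * sigma * eps) + 0.5 * (np.exp(logvar) - 1.0) / n

    dWm = h.T @ dmu
    dbm = dmu.sum(axis=0)
    dWv = h.T @ dlogvar
    dbv = dlogvar.sum(axis=0)
    dh = dmu @ params["Wm"].T + dlogvar @ params["Wv"].T
    dh_pre = dh * (h_pre > 0)
    dW1 = xb.T @ dh_pre
    db1 = dh_pre.sum(axis=0)

    grads = {
        "W1": dW1, "b1": db1, "Wm": dWm, "bm": dbm, "Wv": dWv, "bv": dbv,
        "W2": dW2, "b2": db2, "W3": dW3, "b3": db3,
    }
    return loss, grads


def train(onehot: np.ndarray, config: VAEConfig) -> VAEModel:
    """Fit the VAE on an (n, L, q) one-hot tensor.

    Adam with the configured learning rate; L2 penalty (weight_penalty) on
    the hidden-layer weights W1 and W2; early stopping on the epoch mean
    training loss with best-epoch weights restored.  Reproducible given
    config.seed.
    """
    X = np.asarray(onehot, dtype=np.float64)
    if X.ndim != 3 or X.shape[0] < 2:
        raise VAEError("training requires an (n >= 2, L, q) one-hot tensor")
    n, L, q = X.shape
    hidden = config.hidden_units if config.hidden_units is not None else 3 * L
    d = config.latent_dim
    rng = np.random.default_rng(config.seed)
    params = _init_params(L, q, hidden, d, rng)

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    t = 0
    decayed = ("W1", "W2")

    Xf = X.reshape(n, L * q)
    best_loss = np.inf
    best_params = {k: p.copy() for k, p in params.items()}
    best_epoch = 0
    stale = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Xf[idx]
            eps = rng.standard_normal((len(idx), d))
            loss, grads = _batch_loss_and_grads(params, xb, eps, L, q)
            if not np.isfinite(loss):
                raise VAEError(f"training diverged (non-finite loss) at epoch {epoch}")
            epoch_loss += loss * len(idx)
            t += 1
            for k in _PARAM_NAMES:
                gk = grads[k]
                if k in decayed:
                    gk = gk + config.weight_penalty * params[k]
                m[k] = beta1 * m[k] + (1 - beta1) * gk
                v[k] = beta2 * v[k] + (1 - beta2) * gk * gk
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                params[k] = params[k] - config.learning_rate * mhat / (
                    np.sqrt(vhat) + adam_eps
                )
        epoch_loss /= n
        if epoch_loss < best_loss - 1e-12:
            best_loss = epoch_loss
            best_params = {k: p.copy() for k, p in params.items()}
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience_epochs:
                break

    model = VAEModel(params=best_params, config=config, L=L, q=q)
    model.params["_meta_best_loss"] = np.asarray(best_loss)
    model.params["_meta_best_epoch"] = np.asarray(best_epoch)
    return model


def argmax_sequence(z: np.ndarray, model: VAEModel) -> str:
    """Per-position most probable symbol; ties go to the lowest alphabet index."""
    p = model.decode(np.asarray(z, dtype=np.float64))
    return model.alphabet.decode(p.argmax(axis=1))


def argmax_sequences(z: np.ndarray, model: VAEModel) -> np.ndarray:
    """Batched argmax decoding: (n, d) latent points -> (n, L) index matrix."""
    p = model.decode(np.asarray(z, dtype=np.float64))
    return p.argmax(axis=2)


def sample_sequence(z: np.ndarray, model: VAEModel, rng: np.random.Generator) -> str:
    """Per-position independent categorical draw from the decoder distribution."""
    p = model.decode(np.asarray(z, dtype=np.float64))
    u = rng.random((p.shape[0], 1))
    idx = (p.cumsum(axis=1) > u).argmax(axis=1)
    return model.alphabet.decode(idx)
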