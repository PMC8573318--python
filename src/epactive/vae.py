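"""Variational autoencoder over excitability fields (NumPy implementation).

Encoder and decoder are three-layer fully connected networks with softplus
hidden activations: the encoder maps a per-node field to the mean and
log-variance of a 2-D Gaussian approximate posterior q_a(z|theta); the
decoder maps z back to a field through a sigmoid squashed to the
physiological range [0, 0.5], interpreted as the mean of a Gaussian
likelihood p_b(theta|z) with fixed variance ``decoder_var``.  The variance
is set to 0.1^2 by default — on the scale of the healthy/injured
excitability gap — so that reconstruction carries enough weight relative
to the latent KL penalty to prevent posterior collapse at desk-scale node
counts.  Training maximizes the usual evidence
lower bound (closed-form Gaussian KL + one reparameterized reconstruction
sample) with Adam.  Forward and backward passes are written directly in
NumPy; at this network size (2 x 512 hidden units) that is fast and keeps
runs bit-reproducible under a fixed seed.

Only the decoder *expectation* E[p_b(theta|z)] is used downstream as the
generative map from latent codes to fields; the decoder variance is not
modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from epactive.tissue import TrainingCorpus

THETA_SCALE = 0.5  # decoder output range [0, THETA_SCALE]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class VaeConfig:
    latent_dim: int = 2
    hidden: tuple[int, int] = (512, 512)
    decoder_var: float = 0.01  # fixed variance of the Gaussian decoder likelihood
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    val_fraction: float = 0.1
    patience: int = 10
    seed: int = 0


@dataclass
class VaeParams:
    """Trained weights: ``encoder_weights`` (alpha) and ``decoder_weights`` (beta)."""

    encoder_weights: dict[str, np.ndarray]
    decoder_weights: dict[str, np.ndarray]
    config: VaeConfig = field(default_factory=VaeConfig)
    training_curve: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.decoder_weights["W3"].shape[1]

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim


def init_params(n_nodes: int, config: VaeConfig | None = None) -> VaeParams:
    config = config or VaeConfig()
    rng = np.random.default_rng(config.seed)
    h1, h2 = config.hidden
    d = config.latent_dim

    def glorot(n_in, n_out):
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, size=(n_in, n_out))

    enc = {
        "W1": glorot(n_nodes, h1), "b1": np.zeros(h1),
        "W2": glorot(h1, h2), "b2": np.zeros(h2),
        "Wmu": glorot(h2, d), "bmu": np.zeros(d),
        "Wlv": glorot(h2, d), "blv": np.zeros(d),
    }
    dec = {
        "W1": glorot(d, h2), "b1": np.zeros(h2),
        "W2": glorot(h2, h1), "b2": np.zeros(h1),
        "W3": glorot(h1, n_nodes), "b3": np.zeros(n_nodes),
    }
    return VaeParams(encoder_weights=enc, decoder_weights=dec, config=config)


def _encode_batch(enc: dict, x: np.ndarray):
    a1 = x @ enc["W1"] + enc["b1"]
    h1 = _softplus(a1)
    a2 = h1 @ enc["W2"] + enc["b2"]
    h2 = _softplus(a2)
    mu = h2 @ enc["Wmu"] + enc["bmu"]
    lv = h2 @ enc["Wlv"] + enc["blv"]
    return mu, lv, (x, a1, h1, a2, h2)


def _decode_batch(dec: dict, z: np.ndarray):
    a1 = z @ dec["W1"] + dec["b1"]
    h1 = _softplus(a1)
    a2 = h1 @ dec["W2"] + dec["b2"]
    h2 = _softplus(a2)
    o = h2 @ dec["W3"] + dec["b3"]
    mu = THETA_SCALE * _sigmoid(o)
    return mu, (z, a1, h1, a2, h2, o)


def encode(params: VaeParams, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and log-variance of q_a(z|theta); deterministic in theta."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    mu, lv, _ = _encode_batch(params.encoder_weights, theta)
    if mu.shape[0] == 1:
        return mu[0], lv[0]
    return mu, lv


def decode_expectation(params: VaeParams, z: np.ndarray) -> np.ndarray:
    """E[p_b(theta|z)]: the decoded mean field, bounded in [0, 0.5]."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    mu, _ = _decode_batch(params.decoder_weights, z)
    return mu[0] if mu.shape[0] == 1 else mu


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Closed-form KL(N(mu, diag(exp(logvar))) || N(0, I)) per row."""
    return 0.5 * np.sum(np.exp(logvar) + mu**2 - 1.0 - logvar, axis=-1)


def elbo(
    params: VaeParams, theta: np.ndarray, rng_seed: int = 0
) -> tuple[float, dict[str, float]]:
    """One-sample evidence lower bound and its components for one field.

    Returns ``(elbo, components)`` where components hold the closed-form KL
    term and the reparameterized expected log-likelihood (including the
    Gaussian normalization constant, so the bound is a genuine
    log-likelihood bound).
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.shape[0] != params.n_nodes:
        raise ValueError("field length does not match decoder width")
    mu_z, lv_z, _ = _encode_batch(params.encoder_weights, theta[None, :])
    rng = np.random.default_rng(rng_seed)
    eps = rng.standard_normal(mu_z.shape)
    z = mu_z + np.exp(0.5 * lv_z) * eps
    mu_x, _ = _decode_batch(params.decoder_weights, z)
    kl = float(gaussian_kl(mu_z, lv_z)[0])
    n = theta.shape[0]
    s2 = params.config.decoder_var
    log_lik = float(
        -0.5 * np.sum((theta - mu_x[0]) ** 2) / s2
        - 0.5 * n * np.log(2 * np.pi * s2)
    )
    value = -kl + log_lik
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite ELBO (kl={kl}, log_lik={log_lik}): training diverged"
        )
    return value, {"kl": kl, "log_lik": log_lik}


def _adam_step(w, g, m, v, t, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    for key in w:
        m[key] = beta1 * m[key] + (1 - beta1) * g[key]
        v[key] = beta2 * v[key] + (1 - beta2) * g[key] ** 2
        mhat = m[key] / (1 - beta1**t)
        vhat = v[key] / (1 - beta2**t)
        w[key] -= lr * mhat / (np.sqrt(vhat) + eps)


def _loss_and_grads(enc: dict, dec: dict, x: np.ndarray, eps: np.ndarray,
                    decoder_var: float = 0.01):
    """Mean negative ELBO over a batch and gradients for all weights."""
    B = x.shape[0]
    mu_z, lv_z, (x_, ea1, eh1, ea2, eh2) = _encode_batch(enc, x)
    std = np.exp(0.5 * lv_z)
    z = mu_z + std * eps
    mu_x, (z_, da1, dh1, da2, dh2, do) = _decode_batch(dec, z)

    resid = (mu_x - x) / decoder_var  # d(recon)/d(mu_x)
    recon = 0.5 * np.sum((mu_x - x) ** 2) / (decoder_var * B)
    kl = np.sum(gaussian_kl(mu_z, lv_z)) / B
    loss = recon + kl

    # ---- decoder backward ----
    sig = mu_x / THETA_SCALE
    d_o = (resid * THETA_SCALE * sig * (1 - sig)) / B
    gdec = {}
    gdec["W3"] = dh2.T @ d_o
    gdec["b3"] = d_o.sum(0)
    d_h2 = d_o @ dec["W3"].T
    d_a2 = d_h2 * _sigmoid(da2)
    gdec["W2"] = dh1.T @ d_a2
    gdec["b2"] = d_a2.sum(0)
    d_h1 = d_a2 @ dec["W2"].T
    d_a1 = d_h1 * _sigmoid(da1)
    gdec["W1"] = z.T @ d_a1
    gdec["b1"] = d_a1.sum(0)
    d_z = d_a1 @ dec["W1"].T

    # ---- encoder backward (reparameterization + closed-form KL) ----
    d_mu_z = d_z + mu_z / B
    d_lv_z = d_z * (0.5 * std * eps) + 0.5 * (np.exp(lv_z) - 1.0) / B
    genc = {}
    genc["Wmu"] = eh2.T @ d_mu_z
    genc["bmu"] = d_mu_z.sum(0)
    genc["Wlv"] = eh2.T @ d_lv_z
    genc["blv"] = d_lv_z.sum(0)
    d_h2e = d_mu_z @ enc["Wmu"].T + d_lv_z @ enc["Wlv"].T
    d_a2e = d_h2e * _sigmoid(ea2)
    genc["W2"] = eh1.T @ d_a2e
    genc["b2"] = d_a2e.sum(0)
    d_h1e = d_a2e @ enc["W2"].T
    d_a1e = d_h1e * _sigmoid(ea1)
    genc["W1"] = x.T @ d_a1e
    genc["b1"] = d_a1e.sum(0)
    return loss, genc, gdec


def train_vae(corpus: TrainingCorpus, config: VaeConfig | None = None) -> VaeParams:
    """Train on the corpus with Adam; early stopping on a validation split.

    Reproducible: all randomness (init, shuffling, reparameterization noise)
    derives from ``config.seed``.
    """
    config = config or VaeConfig()
    x_all = corpus.fields
    n_total, n_nodes = x_all.shape
    params = init_params(n_nodes, config)
    enc, dec = params.encoder_weights, params.decoder_weights
    rng = np.random.default_rng(config.seed + 1)

    n_val = max(1, int(round(config.val_fraction * n_total))) if n_total > 10 else 0
    perm = rng.permutation(n_total)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx = perm
    x_train, x_val = x_all[train_idx], x_all[val_idx]

    m_enc = {k: np.zeros_like(w) for k, w in enc.items()}
    v_enc = {k: np.zeros_like(w) for k, w in enc.items()}
    m_dec = {k: np.zeros_like(w) for k, w in dec.items()}
    v_dec = {k: np.zeros_like(w) for k, w in dec.items()}

    best_val = np.inf
    best = None
    bad_epochs = 0
    t = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_train))
        for start in range(0, len(x_train), config.batch_size):
            xb = x_train[order[start : start + config.batch_size]]
            eps = rng.standard_normal((xb.shape[0], config.latent_dim))
            loss, genc, gdec = _loss_and_grads(enc, dec, xb, eps, config.decoder_var)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss diverged at step {t}")
            t += 1
            _adam_step(enc, genc, m_enc, v_enc, t, config.learning_rate)
            _adam_step(dec, gdec, m_dec, v_dec, t, config.learning_rate)
            params.training_curve.append(float(loss))
        if n_val:
            mu_z, lv_z, _ = _encode_batch(enc, x_val)
            mu_x, _ = _decode_batch(dec, mu_z)
            val = float(
                0.5 * np.sum((x_val - mu_x) ** 2) / (config.decoder_var * len(x_val))
                + np.mean(gaussian_kl(mu_z, lv_z))
            )
            if val < best_val - 1e-6:
                best_val = val
                best = (
                    {k: w.copy() for k, w in enc.items()},
                    {k: w.copy() for k, w in dec.items()},
                )
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    break
    if best is not None:
        params.encoder_weights, params.decoder_weights = best
    return params


def save_vae(path: str, params: VaeParams) -> None:
    arrays = {f"enc_{k}": w for k, w in params.encoder_weights.items()}
    arrays.update({f"dec_{k}": w for k, w in params.decoder_weights.items()})
    cfg = params.config
    arrays["config_json"] = np.frombuffer(
        json.dumps(
            {
                "latent_dim": cfg.latent_dim,
                "hidden": list(cfg.hidden),
                "decoder_var": cfg.decoder_var,
                "learning_rate": cfg.learning_rate,
                "batch_size": cfg.batch_size,
                "epochs": cfg.epochs,
                "val_fraction": cfg.val_fraction,
                "patience": cfg.patience,
                "seed": cfg.seed,
            }
        ).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **arrays)


def load_vae(path: str) -> VaeParams:
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    cfg_dict["hidden"] = tuple(cfg_dict["hidden"])
    config = VaeConfig(**cfg_dict)
    enc = {k[4:]: data[k] for k in data.files if k.startswith("enc_")}
    dec = {k[4:]: data[k] for k in data.files if k.startswith("dec_")}
    return VaeParams(encoder_weights=enc, decoder_weights=dec, config=config)
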