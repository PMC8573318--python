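"""Gaussian-process surrogate of the latent-space log-posterior.

Zero-mean GP with an anisotropic Matern 5/2 kernel

    k(zi, zj) = amplitude_sq * exp(-sqrt(5) d) (1 + sqrt(5) d + 5/3 d^2),
    d^2 = (zi - zj)^T Lambda (zi - zj),

where Lambda is diagonal with the inverse squared length scale per latent
dimension.  Labels are the log-posterior values themselves and are *not*
standardized: the exponential of the GP is interpreted downstream as a
log-normal process, so the absolute scale of the labels is meaningful.

Exact inference via Cholesky with escalating jitter; hyperparameters
(length scales, amplitude, noise variance) are refit after every new
training point by multi-start bounded L-BFGS on the log marginal
likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

log = logging.getLogger(__name__)

SIGMA_SQ_FLOOR = 1e-12  # predictive-variance clip
JITTERS = (0.0, 1e-10, 1e-8, 1e-6)

# amplitude must reach the squared scale of unnormalized log-posterior
# labels, which at realistic noise levels is very large (the labels are
# never standardized: their absolute scale feeds the log-normal process)
DEFAULT_BOUNDS = {
    "length_scale": (0.05, 10.0),
    "amplitude_sq": (1e-2, 1e14),
    "noise_var": (1e-8, 1e-1),
}


@dataclass
class GpHyperparams:
    length_scales: np.ndarray  # per-latent-dimension
    amplitude_sq: float = 1.0
    noise_var: float = 1e-6

    def __post_init__(self) -> None:
        self.length_scales = np.atleast_1d(np.asarray(self.length_scales, dtype=float))
        if np.any(self.length_scales <= 0) or self.amplitude_sq <= 0 or self.noise_var <= 0:
            raise ValueError("GP hyperparameters must be strictly positive")


@dataclass
class GpState:
    """Training pairs plus hyperparameters and a cached Cholesky solve."""

    z_train: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,)
    hyper: GpHyperparams
    _chol: tuple | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z_train = np.atleast_2d(np.asarray(self.z_train, dtype=float))
        self.labels = np.atleast_1d(np.asarray(self.labels, dtype=float))
        if self.z_train.size == 0:
            self.z_train = self.z_train.reshape(0, len(self.hyper.length_scales))
        if self.z_train.shape[0] != self.labels.shape[0]:
            raise ValueError("z_train and labels must have matching lengths")

    @property
    def n_train(self) -> int:
        return self.z_train.shape[0]

    def with_point(self, z: np.ndarray, label: float) -> "GpState":
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return GpState(
            z_train=np.vstack([self.z_train, z]) if self.n_train else z,
            labels=np.append(self.labels, label),
            hyper=self.hyper,
        )


def _scaled_sqdist(za: np.ndarray, zb: np.ndarray, ls: np.ndarray) -> np.ndarray:
    a = za / ls
    b = zb / ls
    return np.maximum(
        np.sum(a**2, 1)[:, None] + np.sum(b**2, 1)[None, :] - 2 * a @ b.T, 0.0
    )


def matern52_matrix(
    za: np.ndarray, zb: np.ndarray, hyper: GpHyperparams
) -> np.ndarray:
    d = np.sqrt(_scaled_sqdist(np.atleast_2d(za), np.atleast_2d(zb), hyper.length_scales))
    s5d = np.sqrt(5.0) * d
    return hyper.amplitude_sq * np.exp(-s5d) * (1.0 + s5d + (5.0 / 3.0) * d**2)


def matern52(zi: np.ndarray, zj: np.ndarray, hyper: GpHyperparams) -> float:
    """Anisotropic Matern 5/2 kernel value for a single pair."""
    return float(matern52_matrix(np.atleast_2d(zi), np.atleast_2d(zj), hyper)[0, 0])


def _gram_cholesky(state: GpState):
    """Cholesky of K + noise I with escalating jitter; cached on the state."""
    if state._chol is not None:
        return state._chol
    K = matern52_matrix(state.z_train, state.z_train, state.hyper)
    K[np.diag_indices_from(K)] += state.hyper.noise_var
    last_err: Exception | None = None
    for jit in JITTERS:
        try:
            L = cholesky(K + jit * np.eye(K.shape[0]), lower=True)
            if jit > 0:
                log.warning("Gram matrix required jitter %.1e", jit)
            state._chol = (L, jit)
            return state._chol
        except np.linalg.LinAlgError as err:  # pragma: no cover - rare
            last_err = err
    raise np.linalg.LinAlgError(
        f"Gram matrix not positive definite even with jitter {JITTERS[-1]}"
    ) from last_err


def gp_predict(
    state: GpState, z_query: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance at query points.

    mu = k^T K^-1 L(1:i); sigma^2 = k(z,z) - k^T K^-1 k, clipped at a small
    non-negative floor.  With no training data this is the prior predictive:
    mu = 0, sigma^2 = k(z, z).
    """
    z_query = np.atleast_2d(np.asarray(z_query, dtype=float))
    prior_var = np.full(z_query.shape[0], state.hyper.amplitude_sq)
    if state.n_train == 0:
        return np.zeros(z_query.shape[0]), prior_var
    L, _ = _gram_cholesky(state)
    k_star = matern52_matrix(state.z_train, z_query, state.hyper)  # (n, q)
    alpha = cho_solve((L, True), state.labels)
    mu = k_star.T @ alpha
    v = solve_triangular(L, k_star, lower=True)
    var = prior_var - np.sum(v**2, axis=0)
    return mu, np.maximum(var, SIGMA_SQ_FLOOR)


def log_marginal_likelihood(state: GpState) -> float:
    """GP evidence log p(L(1:i) | z_train, hyper)."""
    if state.n_train < 1:
        raise ValueError("need at least one training point")
    L, _ = _gram_cholesky(state)
    alpha = cho_solve((L, True), state.labels)
    return float(
        -0.5 * state.labels @ alpha
        - np.sum(np.log(np.diag(L)))
        - 0.5 * state.n_train * np.log(2 * np.pi)
    )


def _lml_and_grad(log_params: np.ndarray, z: np.ndarray, y: np.ndarray):
    """Negative LML and gradient wrt log(length_scales, amplitude_sq, noise_var)."""
    d = z.shape[1]
    ls = np.exp(log_params[:d])
    amp = np.exp(log_params[d])
    noise = np.exp(log_params[d + 1])
    n = z.shape[0]

    diff = (z[:, None, :] - z[None, :, :]) / ls  # (n, n, d)
    d2 = np.sum(diff**2, axis=2)
    r = np.sqrt(np.maximum(d2, 0.0))
    s5r = np.sqrt(5.0) * r
    E = np.exp(-s5r)
    K0 = E * (1.0 + s5r + (5.0 / 3.0) * d2)  # amplitude-free kernel
    K = amp * K0
    Kn = K + noise * np.eye(n)
    for jit in JITTERS:
        try:
            cf = cho_factor(Kn + jit * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            continue
    else:  # pragma: no cover
        return np.inf, np.zeros_like(log_params)
    alpha = cho_solve(cf, y)
    Kinv = cho_solve(cf, np.eye(n))
    lml = (
        -0.5 * y @ alpha
        - np.sum(np.log(np.diag(cf[0])))
        - 0.5 * n * np.log(2 * np.pi)
    )
    M = np.outer(alpha, alpha) - Kinv  # dLML/dK = 0.5 M

    grad = np.zeros_like(log_params)
    # d K / d r * chain to per-dimension log length scale
    # dK0/d(d2) = -(5/6) E (1 + s5r); d(d2)/d(log ls_k) = -2 diff_k^2
    dK_dd2 = amp * (-(5.0 / 6.0)) * E * (1.0 + s5r)
    for k_dim in range(d):
        dK = dK_dd2 * (-2.0 * diff[:, :, k_dim] ** 2)
        grad[k_dim] = 0.5 * np.sum(M * dK)
    grad[d] = 0.5 * np.sum(M * K)  # d/d log amp = K
    grad[d + 1] = 0.5 * np.trace(M) * noise
    return -lml, -grad


def optimize_hyperparams(
    state: GpState,
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> GpHyperparams:
    """Multi-start bounded quasi-Newton maximization of the evidence.

    The incumbent hyperparameters seed the first start; the returned
    setting never has lower evidence than the incumbent.  Deterministic
    given ``seed`` and the state.
    """
    if state.n_train < 2:
        return state.hyper
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    d = state.z_train.shape[1]
    lb = np.log(
        np.r_[[bounds["length_scale"][0]] * d, bounds["amplitude_sq"][0], bounds["noise_var"][0]]
    )
    ub = np.log(
        np.r_[[bounds["length_scale"][1]] * d, bounds["amplitude_sq"][1], bounds["noise_var"][1]]
    )
    rng = np.random.default_rng(seed)
    x0_incumbent = np.log(
        np.r_[state.hyper.length_scales, state.hyper.amplitude_sq, state.hyper.noise_var]
    )
    starts = [np.clip(x0_incumbent, lb, ub)]
    starts += [rng.uniform(lb, ub) for _ in range(n_starts - 1)]

    best_x, best_val = None, np.inf
    for x0 in starts:
        try:
            res = minimize(
                _lml_and_grad,
                x0,
                args=(state.z_train, state.labels),
                jac=True,
                method="L-BFGS-B",
                bounds=list(zip(lb, ub)),
                options={"maxiter": 100},
            )
        except Exception:  # pragma: no cover - optimizer hiccup
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_x = res.fun, res.x
    incumbent_val = -log_marginal_likelihood(state)
    if best_x is None or best_val > incumbent_val:
        if best_x is None:
            log.warning("hyperparameter optimization failed; keeping incumbent")
        return state.hyper
    return GpHyperparams(
        length_scales=np.exp(best_x[:d]),
        amplitude_sq=float(np.exp(best_x[d])),
        noise_var=float(np.exp(best_x[d + 1])),
    )


def save_gp(path: str, state: GpState) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("z_train", data=state.z_train)
        f.create_dataset("labels", data=state.labels)
        g = f.create_group("hyper")
        g.create_dataset("length_scales", data=state.hyper.length_scales)
        g.attrs["amplitude_sq"] = state.hyper.amplitude_sq
        g.attrs["noise_var"] = state.hyper.noise_var


def load_gp(path: str) -> GpState:
    import h5py

    with h5py.File(path, "r") as f:
        hyper = GpHyperparams(
            length_scales=f["hyper/length_scales"][:],
            amplitude_sq=float(f["hyper"].attrs["amplitude_sq"]),
            noise_var=float(f["hyper"].attrs["noise_var"]),
        )
        return GpState(z_train=f["z_train"][:], labels=f["labels"][:], hyper=hyper)
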