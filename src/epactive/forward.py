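"""Aliev-Panfilov propagation on a graph and the ECG measurement model.

The two-variable phenomenological model

    du/dt = d_iso * (-L u) - c u (u - theta) (u - 1) - u v + I_stim
    dv/dt = eps(u, v) * (-v - c u (u - theta - 1)),   eps = e0 + mu1 v / (u + mu2)

is integrated with explicit forward Euler on the weighted graph Laplacian L
of a :class:`~epactive.geometry.CardiacGeometry`.  u is the dimensionless
transmembrane potential (nominal range [0, 1]), v the recovery current,
theta the per-node excitability (high theta = inexcitable tissue).  Time is
in model units; no millisecond calibration is attempted.

ECG is the linear map Y(t) = H u(t) through a lead field, with optional
additive Gaussian noise at a prescribed SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from epactive.geometry import CardiacGeometry, LeadField


@dataclass
class APModelParams:
    """Aliev-Panfilov constants and integration settings.

    Defaults for c, e0, mu1, mu2 are the standard literature values; the
    diffusion coefficient, step size, horizon and stimulus are engineering
    choices sized for the synthetic fixture geometry.
    """

    c: float = 8.0
    e0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    d_iso: float = 4.0
    dt: float = 0.01
    t_end: float = 60.0
    stim_amplitude: float = 3.0
    stim_duration: float = 2.0
    n_store: int = 100  # stored frames after temporal subsampling

    def __post_init__(self) -> None:
        for name in ("c", "e0", "mu1", "mu2", "dt", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_iso < 0:
            raise ValueError("d_iso must be non-negative")


@dataclass
class SimulationTrace:
    u: np.ndarray  # (n_nodes, n_frames)
    v: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have identical shapes")
        dt = np.diff(self.times)
        if len(dt) and not np.all(dt > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class EcgMeasurement:
    Y: np.ndarray  # (n_leads, n_frames)
    snr_db: float | None = None
    sigma_e_sq: float | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_e_sq is not None and self.sigma_e_sq <= 0:
            raise ValueError("sigma_e_sq must be positive when set")


@njit(cache=True)
def _integrate(
    lap_data, lap_indices, lap_indptr, theta, c, e0, mu1, mu2, d_iso,
    dt, n_steps, stim_nodes, stim_amp, stim_steps, store_every, u0, v0,
):  # pragma: no cover - exercised through simulate_ap
    n = theta.shape[0]
    n_store = (n_steps - 1) // store_every + 1
    u_out = np.empty((n, n_store))
    v_out = np.empty((n, n_store))
    u = u0.copy()
    v = v0.copy()
    k = 0
    for step in range(n_steps):
        if step % store_every == 0:
            u_out[:, k] = u
            v_out[:, k] = v
            k += 1
        # Lu via CSR matvec
        du = np.zeros(n)
        for i in range(n):
            acc = 0.0
            for p in range(lap_indptr[i], lap_indptr[i + 1]):
                acc += lap_data[p] * u[lap_indices[p]]
            du[i] = -d_iso * acc
        for i in range(n):
            ui = u[i]
            vi = v[i]
            reaction = -c * ui * (ui - theta[i]) * (ui - 1.0) - ui * vi
            eps = e0 + mu1 * vi / (ui + mu2)
            dv = eps * (-vi - c * ui * (ui - theta[i] - 1.0))
            du[i] += reaction
            u[i] = ui + dt * du[i]
            v[i] = vi + dt * dv
        if step < stim_steps:
            # saturating stimulus: cannot push u beyond the AP ceiling
            for s in range(stim_nodes.shape[0]):
                if u[stim_nodes[s]] < 1.0:
                    u[stim_nodes[s]] = min(1.0, u[stim_nodes[s]] + dt * stim_amp)
        for i in range(n):
            if not (np.isfinite(u[i]) and np.isfinite(v[i])):
                return u_out[:, :k], v_out[:, :k], step
    return u_out, v_out, -1


def stability_bound(geom: CardiacGeometry, d_iso: float) -> float:
    """Largest stable forward-Euler step for the pure diffusion part."""
    if d_iso == 0:
        return np.inf
    return 2.0 / (d_iso * geom.laplacian_max_eig())


def simulate_ap(
    geom: CardiacGeometry,
    params: APModelParams,
    theta: np.ndarray,
    u0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    check_stability: bool = True,
) -> SimulationTrace:
    """Integrate the Aliev-Panfilov model; deterministic given its inputs.

    ``theta`` is the per-node excitability in [0, 0.5].  Initial state
    defaults to rest (u = v = 0) with the configured stimulus on the pacing
    nodes.  Raises if the state turns non-finite (instability) or if theta
    does not match the geometry.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.shape[0] != geom.n_nodes:
        raise ValueError(
            f"theta has {theta.shape[0]} entries for a {geom.n_nodes}-node geometry"
        )
    if np.any(theta < 0) or np.any(theta > 0.5):
        raise ValueError("theta must lie within [0, 0.5]")
    if check_stability and params.d_iso > 0:
        bound = stability_bound(geom, params.d_iso)
        if params.dt >= bound:
            raise ValueError(
                f"dt={params.dt} violates the stability bound {bound:.4g}; reduce dt"
            )
    n_steps = int(round(params.t_end / params.dt))
    store_every = max(1, n_steps // params.n_store)
    lap = geom.laplacian.tocsr().astype(np.float64)
    u0 = np.zeros(geom.n_nodes) if u0 is None else np.asarray(u0, dtype=float)
    v0 = np.zeros(geom.n_nodes) if v0 is None else np.asarray(v0, dtype=float)
    stim_nodes = geom.pacing_nodes.astype(np.int64)
    u, v, bad_step = _integrate(
        lap.data,
        lap.indices,
        lap.indptr,
        theta,
        params.c,
        params.e0,
        params.mu1,
        params.mu2,
        params.d_iso,
        params.dt,
        n_steps,
        stim_nodes,
        params.stim_amplitude,
        int(round(params.stim_duration / params.dt)),
        store_every,
        u0,
        v0,
    )
    if bad_step >= 0:
        raise FloatingPointError(
            f"non-finite state at step {bad_step} (t={bad_step * params.dt:.3g}); "
            "integration unstable - try a smaller dt"
        )
    times = np.arange(u.shape[1]) * store_every * params.dt
    return SimulationTrace(u=u, v=v, times=times)


def apply_lead_field(lf: LeadField, trace: SimulationTrace) -> EcgMeasurement:
    """Noise-free ECG: Y(t) = H u(t) at every stored frame."""
    if lf.H.shape[1] != trace.u.shape[0]:
        raise ValueError(
            f"lead field has {lf.H.shape[1]} columns but trace has "
            f"{trace.u.shape[0]} nodes"
        )
    return EcgMeasurement(Y=lf.H @ trace.u)


def save_lead_csv(path: str, meas: EcgMeasurement, lead: int,
                  times: np.ndarray | None = None) -> None:
    """Export one ECG lead as a two-column (time, value) CSV."""
    if not 0 <= lead < meas.Y.shape[0]:
        raise ValueError(f"lead {lead} out of range")
    t = np.arange(meas.Y.shape[1]) if times is None else np.asarray(times)
    np.savetxt(path, np.column_stack([t, meas.Y[lead]]), delimiter=",",
               header="time,value", comments="")


def add_noise_snr(
    meas: EcgMeasurement, snr_db: float | None, seed: int
) -> EcgMeasurement:
    """Add white Gaussian noise at the given SNR (dB); records sigma_e_sq.

    ``snr_db=None`` is the no-noise limit and returns the input unchanged
    (with a tiny sigma_e_sq floor so downstream likelihoods stay defined).
    """
    if meas.snr_db is not None:
        raise ValueError("measurement already carries noise")
    if snr_db is None:
        return EcgMeasurement(
            Y=meas.Y.copy(), snr_db=None, sigma_e_sq=1e-12, rng_seed=seed
        )
    signal_power = float(np.mean(meas.Y**2))
    if signal_power <= 0:
        raise ValueError("zero-power signal: cannot define an SNR")
    sigma_sq = signal_power / (10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=np.sqrt(sigma_sq), size=meas.Y.shape)
    return EcgMeasurement(
        Y=meas.Y + noise, snr_db=snr_db, sigma_e_sq=sigma_sq, rng_seed=seed
    )
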