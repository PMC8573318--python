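"""MCMC baselines: direct Metropolis-Hastings, delayed-acceptance (two-stage)
sampling with a GP surrogate first stage, proposal tuning, and the chain
protocol (burn-in, thinning, Geweke and Gelman-Rubin diagnostics).

The two-stage sampler follows the standard delayed-acceptance construction:
each random-walk candidate is first accepted or rejected by the MH ratio on
the cheap surrogate density q*(z) = exp(GP predictive mean); only stage-1
survivors are evaluated on the exact posterior with the correction ratio
[pi(z') q*(z) / pi(z) q*(z')], which preserves the exact stationary law.
Forward-simulation cost is therefore paid only for stage-1 survivors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from epactive.gp import GpState, gp_predict

log = logging.getLogger(__name__)


@dataclass
class McmcChain:
    samples: np.ndarray  # (n_steps + 1, d), includes the initial point
    acceptance_rate: float
    proposal_var: float
    n_forward_sims: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.acceptance_rate <= 1.0:
            raise ValueError("acceptance_rate must lie in [0, 1]")


@dataclass
class ChainDiagnostics:
    geweke_z: np.ndarray  # per dimension
    gelman_rubin: np.ndarray  # per dimension
    means: np.ndarray
    stds: np.ndarray


def mh_sample(
    log_target,
    init: np.ndarray,
    n_steps: int,
    proposal_var: float,
    seed: int = 0,
    count_evals: bool = True,
) -> McmcChain:
    """Random-walk Metropolis-Hastings with an isotropic Gaussian proposal."""
    rng = np.random.default_rng(seed)
    z = np.asarray(init, dtype=float).ravel()
    lp = float(log_target(z))
    if not np.isfinite(lp):
        raise ValueError("log_target not finite at the initial point")
    d = len(z)
    scale = np.sqrt(proposal_var)
    samples = np.empty((n_steps + 1, d))
    samples[0] = z
    n_accept = 0
    n_evals = 1
    for i in range(n_steps):
        cand = z + scale * rng.standard_normal(d)
        lp_cand = float(log_target(cand))
        n_evals += 1
        if np.log(rng.uniform()) < lp_cand - lp:
            z, lp = cand, lp_cand
            n_accept += 1
        samples[i + 1] = z
    rate = n_accept / n_steps if n_steps else 0.0
    if n_steps >= 1000 and rate == 0.0:
        warnings.warn("MH chain accepted nothing; target may be divergent")
    return McmcChain(
        samples=samples,
        acceptance_rate=rate,
        proposal_var=proposal_var,
        n_forward_sims=n_evals if count_evals else 0,
        seed=seed,
    )


def surrogate_log_density(state: GpState):
    """exp(GP mean) as an unnormalized log-density (cheap to evaluate)."""

    def logq(z):
        mu, _ = gp_predict(state, np.atleast_2d(z))
        return float(mu[0])

    return logq


def tune_proposal(
    surrogate_log_target,
    init: np.ndarray,
    target_rate: float = 0.22,
    tol: float = 0.03,
    chain_length: int = 2000,
    max_rounds: int = 30,
    seed: int = 0,
    bracket: tuple[float, float] = (1e-6, 1e2),
) -> float:
    """Bisection on log proposal variance until the surrogate-chain
    acceptance rate lands within ``target_rate`` +/- ``tol``.

    Acceptance decreases monotonically (in expectation) with the proposal
    variance on a smooth target, so bisection applies.  Consumes only
    surrogate evaluations.
    """
    lo, hi = np.log(bracket[0]), np.log(bracket[1])
    rng = np.random.default_rng(seed)

    def rate_at(log_var: float, round_idx: int) -> float:
        chain = mh_sample(
            surrogate_log_target,
            init,
            chain_length,
            float(np.exp(log_var)),
            seed=int(rng.integers(2**31 - 1)),
        )
        return chain.acceptance_rate

    best_lv, best_err = None, np.inf
    for round_idx in range(max_rounds):
        mid = 0.5 * (lo + hi)
        rate = rate_at(mid, round_idx)
        err = abs(rate - target_rate)
        if err < best_err:
            best_lv, best_err = mid, err
        if err <= tol:
            return float(np.exp(mid))
        if rate > target_rate:  # accepting too much -> larger steps
            lo = mid
        else:
            hi = mid
    warnings.warn(
        f"proposal tuning did not reach {target_rate}+/-{tol}; "
        f"returning nearest achievable (|err|={best_err:.3f})"
    )
    return float(np.exp(best_lv))


def two_stage_mh(
    exact_log_target,
    surrogate: GpState,
    init: np.ndarray,
    n_steps: int,
    proposal_var: float,
    seed: int = 0,
) -> McmcChain:
    """Delayed-acceptance MH; ``n_forward_sims`` counts stage-2 evaluations.

    Stage 1 screens each candidate by the surrogate MH ratio; survivors are
    evaluated on the exact posterior with the delayed-acceptance correction
    ratio, so the chain targets the exact posterior.
    """
    rng = np.random.default_rng(seed)
    logq = surrogate_log_density(surrogate)
    z = np.asarray(init, dtype=float).ravel()
    lp = float(exact_log_target(z))
    lq = logq(z)
    d = len(z)
    scale = np.sqrt(proposal_var)
    samples = np.empty((n_steps + 1, d))
    samples[0] = z
    n_accept = 0
    n_exact = 1
    for i in range(n_steps):
        cand = z + scale * rng.standard_normal(d)
        lq_cand = logq(cand)
        # stage 1: surrogate MH screen
        if np.log(rng.uniform()) < lq_cand - lq:
            # stage 2: exact evaluation with correction ratio
            lp_cand = float(exact_log_target(cand))
            n_exact += 1
            correction = (lp_cand - lp) - (lq_cand - lq)
            if np.log(rng.uniform()) < correction:
                z, lp, lq = cand, lp_cand, lq_cand
                n_accept += 1
        samples[i + 1] = z
    return McmcChain(
        samples=samples,
        acceptance_rate=n_accept / n_steps if n_steps else 0.0,
        proposal_var=proposal_var,
        n_forward_sims=n_exact,
        seed=seed,
    )


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> np.ndarray:
    """Geweke convergence score per dimension.

    Compares the means of the first 10% and last 50% of the chain, with
    variances estimated per segment (independence approximation on the
    thinned-scale segments).
    """
    chain = np.atleast_2d(chain)
    n = chain.shape[0]
    a = chain[: int(first * n)]
    b = chain[int((1 - last) * n) :]
    num = a.mean(0) - b.mean(0)
    den = np.sqrt(a.var(0, ddof=1) / len(a) + b.var(0, ddof=1) / len(b))
    return num / np.maximum(den, 1e-300)


def gelman_rubin(chains: list[np.ndarray]) -> np.ndarray:
    """Potential scale reduction factor per dimension (>= 1 up to noise)."""
    arr = np.stack([np.atleast_2d(c) for c in chains])  # (m, n, d)
    m, n, _ = arr.shape
    chain_means = arr.mean(axis=1)  # (m, d)
    B = n * chain_means.var(axis=0, ddof=1)
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    var_hat = (n - 1) / n * W + B / n
    return np.sqrt(var_hat / np.maximum(W, 1e-300))


def postprocess_chains(
    chains: list[McmcChain], burn_in_fraction: float = 0.2, thin: int = 2
) -> tuple[np.ndarray, ChainDiagnostics]:
    """Burn-in, thinning and pooling per the standard chain protocol.

    Each chain drops its first 20% and keeps every ``thin``-th remaining
    sample; the thinned chains are concatenated.  Diagnostics (Geweke,
    Gelman-Rubin) are computed on the post-burn-in, pre-thinning chains.
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    lengths = {c.samples.shape[0] for c in chains}
    if len(lengths) != 1:
        raise ValueError("chains must have equal length")
    post = []
    kept = []
    for c in chains:
        n = c.samples.shape[0]
        body = c.samples[int(np.ceil(burn_in_fraction * n)) :]
        post.append(body)
        kept.append(body[::thin])
    combined = np.vstack(kept)
    diags = ChainDiagnostics(
        geweke_z=np.vstack([geweke_z(b) for b in post]),
        gelman_rubin=gelman_rubin(post),
        means=combined.mean(0),
        stds=combined.std(0, ddof=1),
    )
    return combined, diags
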