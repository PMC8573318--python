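import numpy as np
import pytest

from epactive.forward import (
    APModelParams,
    EcgMeasurement,
    SimulationTrace,
    add_noise_snr,
    apply_lead_field,
    simulate_ap,
    stability_bound,
)
from epactive.geometry import CardiacGeometry, LeadField
import scipy.sparse as sp


def _single_node_geometry():
    """One isolated node (no diffusion, no pacing unless requested)."""
    return CardiacGeometry(
        node_coords=np.zeros((1, 3)),
        adjacency=sp.csr_matrix((1, 1)),
        laplacian=sp.csr_matrix((1, 1)),
        pacing_nodes=np.array([], dtype=int),
        segment_labels=np.array([1]),
    )


def _rk4_single_cell(theta, u0, v0, params, dt=1e-3, t_end=60.0):
    """Fine-step RK4 oracle for the isolated-cell Aliev-Panfilov ODE."""

    def rhs(state):
        u, v = state
        du = -params.c * u * (u - theta) * (u - 1.0) - u * v
        eps = params.e0 + params.mu1 * v / (u + params.mu2)
        dv = eps * (-v - params.c * u * (u - theta - 1.0))
        return np.array([du, dv])

    state = np.array([u0, v0])
    n = int(t_end / dt)
    traj = np.empty((n + 1, 2))
    traj[0] = state
    for i in range(n):
        k1 = rhs(state)
        k2 = rhs(state + 0.5 * dt * k1)
        k3 = rhs(state + 0.5 * dt * k2)
        k4 = rhs(state + dt * k3)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        traj[i + 1] = state
    return traj


class TestSingleCellDynamics:
    def test_rest_is_a_fixed_point(self):
        geom = _single_node_geometry()
        params = APModelParams(d_iso=0.0, stim_amplitude=0.0)
        trace = simulate_ap(geom, params, np.array([0.15]))
        assert np.all(trace.u == 0.0)
        assert np.all(trace.v == 0.0)

    def test_suprathreshold_cell_fires_full_upstroke(self):
        geom = _single_node_geometry()
        params = APModelParams(d_iso=0.0, stim_amplitude=0.0, dt=0.01)
        trace = simulate_ap(
            geom, params, np.array([0.15]), u0=np.array([0.3]), v0=np.zeros(1)
        )
        assert trace.u.max() > 0.9
        oracle = _rk4_single_cell(0.15, 0.3, 0.0, params)
        assert oracle[:, 0].max() > 0.9

    def test_inexcitable_cell_decays_monotonically(self):
        # at u < theta the cubic reaction is strictly negative, so an
        # initial 0.3 deflection with theta = 0.5 must decay without upstroke
        geom = _single_node_geometry()
        params = APModelParams(d_iso=0.0, stim_amplitude=0.0, dt=0.01)
        trace = simulate_ap(
            geom, params, np.array([0.5]), u0=np.array([0.3]), v0=np.zeros(1)
        )
        u = trace.u[0]
        assert np.all(np.diff(u) <= 1e-12)
        assert u[-1] < 0.01
        oracle = _rk4_single_cell(0.5, 0.3, 0.0, params)
        assert oracle[-1, 0] < 0.01 and oracle[:, 0].max() <= 0.3 + 1e-9

    def test_integrator_matches_rk4_oracle(self):
        geom = _single_node_geometry()
        params = APModelParams(d_iso=0.0, stim_amplitude=0.0, dt=0.005, t_end=40.0,
                               n_store=200)
        trace = simulate_ap(
            geom, params, np.array([0.15]), u0=np.array([0.3]), v0=np.zeros(1)
        )
        oracle = _rk4_single_cell(0.15, 0.3, 0.0, params, dt=1e-3, t_end=40.0)
        t_oracle = np.arange(oracle.shape[0]) * 1e-3
        u_interp = np.interp(trace.times, t_oracle, oracle[:, 0])
        rel = np.linalg.norm(trace.u[0] - u_interp) / np.linalg.norm(u_interp)
        assert rel < 1e-2


class TestTissueScaleDynamics:
    def test_healthy_tissue_fully_captures(self, geom200):
        params = APModelParams()
        trace = simulate_ap(geom200, params, np.full(200, 0.15))
        assert np.all(trace.u.max(axis=1) > 0.5)

    def test_activation_delay_monotone_in_theta(self, geom200):
        """Within the propagating regime, higher excitability threshold
        strictly delays the completion of activation; above ~0.2 the wave
        dies (scar physiology), so capture is lost rather than delayed."""
        params = APModelParams()
        last_act = []
        for th in (0.15, 0.17, 0.19):
            trace = simulate_ap(geom200, params, np.full(200, th))
            assert np.all(trace.u.max(axis=1) > 0.5), f"lost capture at {th}"
            act = [
                trace.times[np.argmax(trace.u[i] > 0.5)] for i in range(200)
            ]
            last_act.append(max(act))
        assert last_act[0] < last_act[1] < last_act[2]

    @pytest.mark.parametrize("theta_val", [0.3, 0.4])
    def test_high_theta_tissue_does_not_propagate(self, geom200, theta_val):
        params = APModelParams()
        trace = simulate_ap(geom200, params, np.full(200, theta_val))
        assert (trace.u.max(axis=1) > 0.5).mean() < 0.5

    def test_u_stays_within_physiological_bounds(self, geom200):
        params = APModelParams()
        trace = simulate_ap(geom200, params, np.full(200, 0.15))
        assert trace.u.min() >= -0.05 and trace.u.max() <= 1.05

    def test_diffusion_only_conserves_total_potential(self, geom200):
        # reaction terms switched off (c, e0, mu1 -> ~0), no stimulus:
        # sum_i u_i is conserved because the Laplacian is symmetric with
        # zero row sums
        params = APModelParams(
            c=1e-12, e0=1e-12, mu1=1e-12, d_iso=4.0, stim_amplitude=0.0,
            dt=0.01, t_end=20.0,
        )
        rng = np.random.default_rng(0)
        u0 = rng.uniform(0, 1, size=200)
        trace = simulate_ap(geom200, params, np.full(200, 0.15), u0=u0,
                            v0=np.zeros(200))
        totals = trace.u.sum(axis=0)
        assert np.allclose(totals, totals[0], rtol=1e-6)

    def test_agrees_with_quarter_step_reference(self, geom200):
        params = APModelParams(t_end=40.0)
        fine = APModelParams(dt=params.dt / 4, t_end=40.0)
        theta = np.full(200, 0.15)
        coarse_tr = simulate_ap(geom200, params, theta)
        fine_tr = simulate_ap(geom200, fine, theta)
        # align on the coarse frame times
        u_fine = np.vstack(
            [np.interp(coarse_tr.times, fine_tr.times, fine_tr.u[i]) for i in range(200)]
        )
        rel = np.linalg.norm(coarse_tr.u - u_fine) / np.linalg.norm(u_fine)
        assert rel < 1e-2

    def test_dimension_mismatch_rejected(self, geom200):
        with pytest.raises(ValueError, match="entries"):
            simulate_ap(geom200, APModelParams(), np.full(123, 0.15))

    def test_unstable_dt_rejected_upfront(self, geom200):
        bound = stability_bound(geom200, 4.0)
        with pytest.raises(ValueError, match="stability"):
            simulate_ap(geom200, APModelParams(dt=2 * bound), np.full(200, 0.15))


class TestLeadFieldApplication:
    def test_identity_lead_field_returns_u(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(size=(5, 7))
        trace = SimulationTrace(u=u, v=np.zeros_like(u), times=np.arange(7.0))
        meas = apply_lead_field(LeadField(H=np.eye(5), n_leads=5), trace)
        assert np.array_equal(meas.Y, u)

    def test_zero_input_gives_zero_output(self):
        trace = SimulationTrace(
            u=np.zeros((4, 3)), v=np.zeros((4, 3)), times=np.arange(3.0)
        )
        rng = np.random.default_rng(2)
        meas = apply_lead_field(LeadField(H=rng.normal(size=(6, 4)), n_leads=6), trace)
        assert np.all(meas.Y == 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        H = rng.normal(size=(6, 4))
        lf = LeadField(H=H, n_leads=6)
        u1, u2 = rng.normal(size=(2, 4, 5))
        a, b = 2.3, -0.7

        def ecg(u):
            return apply_lead_field(
                lf, SimulationTrace(u=u, v=np.zeros_like(u), times=np.arange(5.0))
            ).Y

        combo = ecg(a * u1 + b * u2)
        oracle = a * (H @ u1) + b * (H @ u2)
        assert np.allclose(combo, a * ecg(u1) + b * ecg(u2))
        assert np.allclose(combo, oracle)

    def test_dimension_mismatch_rejected(self):
        trace = SimulationTrace(
            u=np.zeros((4, 3)), v=np.zeros((4, 3)), times=np.arange(3.0)
        )
        with pytest.raises(ValueError, match="columns"):
            apply_lead_field(LeadField(H=np.zeros((6, 5)), n_leads=6), trace)


class TestNoiseInjection:
    def _clean(self, n=200, m=60, seed=4):
        rng = np.random.default_rng(seed)
        return EcgMeasurement(Y=rng.normal(size=(n, m)))

    def test_snr_definition_holds_empirically(self):
        clean = self._clean()
        noisy = add_noise_snr(clean, snr_db=20.0, seed=0)
        ratio = np.mean(clean.Y**2) / np.mean((noisy.Y - clean.Y) ** 2)
        assert ratio == pytest.approx(100.0, rel=0.05)
        assert noisy.sigma_e_sq == pytest.approx(np.mean(clean.Y**2) / 100.0)

    def test_reproducible_under_seed(self):
        clean = self._clean()
        a = add_noise_snr(clean, 20.0, seed=42)
        b = add_noise_snr(clean, 20.0, seed=42)
        assert np.array_equal(a.Y, b.Y)

    def test_no_noise_limit(self):
        clean = self._clean()
        out = add_noise_snr(clean, None, seed=0)
        assert np.array_equal(out.Y, clean.Y)

    def test_zero_power_signal_rejected(self):
        with pytest.raises(ValueError, match="zero-power"):
            add_noise_snr(EcgMeasurement(Y=np.zeros((3, 3))), 20.0, seed=0)

    def test_double_noising_rejected(self):
        noisy = add_noise_snr(self._clean(), 20.0, seed=0)
        with pytest.raises(ValueError, match="already"):
            add_noise_snr(noisy, 20.0, seed=1)
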