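"""Delay handling, coupling, stochastic Heun, network loop, BOLD forward."""

import numpy as np
import pytest

from neuromass.connectome import StructuralConnectome
from neuromass.local_model import SJ3DParams, initial_state, sj3d_derivative
from neuromass.simulator import (
    BALLOON_CONSTANTS,
    IntegrationDivergenceError,
    SimulationConfig,
    bold_forward,
    compute_delay_steps,
    coupling_term,
    heun_stochastic_step,
    sample_noise_stream,
    simulate_neural,
)
from neuromass.synthetic import generate_healthy_connectome


def desk_config(**kw):
    base = dict(params=SJ3DParams(n_modes=1), dt=0.05, duration_s=10.0,
                transient_discard_s=2.0, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestDelaySteps:
    def test_ten_mm_at_ten_mm_per_ms(self):
        d = compute_delay_steps(np.array([[0.0, 10.0], [10.0, 0.0]]), 10.0, 1.0)
        assert d[0, 1] == 1

    def test_zero_length_stored_as_one_step(self):
        d = compute_delay_steps(np.zeros((2, 2)), 5.0, 0.1)
        assert np.all(d == 1)

    def test_rounding_bound(self, rng):
        """delay * dt * v stays within half a step-distance of L."""
        for _ in range(20):
            v = rng.uniform(1, 100)
            dt = rng.uniform(0.01, 1.0)
            L = rng.uniform(dt * v, 160, size=(4, 4))  # above the 1-step floor
            L = (L + L.T) / 2
            d = compute_delay_steps(L, v, dt)
            assert np.all(np.abs(d * dt * v - L) <= dt * v / 2 + 1e-9)

    def test_invalid_velocity(self):
        with pytest.raises(ValueError):
            compute_delay_steps(np.zeros((2, 2)), 0.0, 0.1)


class TestCouplingTerm:
    def test_zero_g_gives_zero(self, rng):
        h = rng.standard_normal((10, 4))
        w = rng.uniform(0, 1, (4, 4))
        d = np.ones((4, 4), dtype=int)
        assert coupling_term(h, w, d, 0.0, 2, 5) == 0.0

    def test_single_edge_constant_source(self):
        h = np.full((10, 2), 3.0)
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        d = np.ones((2, 2), dtype=int)
        assert coupling_term(h, w, d, 0.7, 0, 5) == pytest.approx(0.7 * 3.0)

    def test_matches_triple_loop_oracle(self, rng):
        n = 5
        h = rng.standard_normal((30, n))
        w = rng.uniform(0, 2, (n, n))
        np.fill_diagonal(w, 0)
        d = rng.integers(1, 8, (n, n))
        for node in range(n):
            t = 20
            expected = 0.0
            for j in range(n):
                expected += w[node, j] * h[t - d[node, j], j]
            expected *= 0.9
            assert coupling_term(h, w, d, 0.9, node, t) == pytest.approx(
                expected, abs=1e-12)

    def test_insufficient_history_raises(self, rng):
        h = rng.standard_normal((3, 2))
        w = np.ones((2, 2)) - np.eye(2)
        d = np.full((2, 2), 5, dtype=int)
        with pytest.raises(RuntimeError, match="history"):
            coupling_term(h, w, d, 1.0, 0, 2)


class TestHeun:
    def test_one_step_matches_closed_form_for_linear_decay(self):
        """dx = -x: Heun gives x (1 - dt + dt^2/2)."""
        dt = 0.1
        x = np.array([2.0])
        out = heun_stochastic_step(x, lambda s: -s, dt)
        assert out[0] == pytest.approx(2.0 * (1 - dt + dt**2 / 2), abs=1e-15)

    def test_second_order_global_error(self):
        """Error against e^{-t} decays with slope ~2 in log-log."""
        errs = []
        dts = [0.1, 0.05, 0.025]
        for dt in dts:
            x = np.array([1.0])
            for _ in range(int(round(1.0 / dt))):
                x = heun_stochastic_step(x, lambda s: -s, dt)
            errs.append(abs(x[0] - np.exp(-1.0)))
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert 1.8 < slope < 2.2

    def test_noise_off_equals_deterministic(self, rng):
        x = rng.standard_normal(4)
        a = heun_stochastic_step(x, lambda s: -s, 0.05)
        b = heun_stochastic_step(x, lambda s: -s, 0.05,
                                 rng_draws=rng.standard_normal(4), noise_sd=0.0)
        np.testing.assert_array_equal(a, b)

    def test_noise_variance_scales_linearly_with_dt(self, rng):
        """Frozen dynamics: Var(x' - x) = sd^2 * dt."""
        n = 200_000
        draws = rng.standard_normal(n)
        for dt in (0.01, 0.04):
            out = heun_stochastic_step(np.zeros(n), lambda s: 0.0 * s, dt,
                                       rng_draws=draws, noise_sd=1.0)
            assert out.var() == pytest.approx(dt, rel=0.02)

    def test_divergence_guard(self):
        with pytest.raises(IntegrationDivergenceError):
            heun_stochastic_step(np.array([1.0]), lambda s: s * 1e7, 1.0)


class TestNoiseStream:
    def test_deterministic(self):
        np.testing.assert_array_equal(sample_noise_stream(1000, 3),
                                      sample_noise_stream(1000, 3))

    def test_standard_normal_moments(self):
        x = sample_noise_stream(200_000, 7)
        assert abs(x.mean()) < 4 / np.sqrt(len(x))
        assert abs(x.std(ddof=1) - 1.0) < 4 / np.sqrt(2 * len(x))


class TestNetworkLoop:
    def test_deterministic_for_fixed_seed(self, small_connectome):
        cfg = desk_config()
        a = simulate_neural(small_connectome, cfg)
        b = simulate_neural(small_connectome, cfg)
        np.testing.assert_array_equal(a, b)

    def test_one_step_matches_python_reference(self):
        """A single noiseless step of the compiled loop equals the pure
        NumPy stochastic-Heun update built from sj3d_derivative and
        coupling_term."""
        from neuromass.simulator import _integrate_network

        rng = np.random.default_rng(0)
        n, M = 3, 2
        p = SJ3DParams(n_modes=M)
        w = rng.uniform(0.1, 1.0, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        delays = rng.integers(1, 5, (n, n)).astype(np.int64)
        delays = np.maximum(delays, delays.T)
        init = initial_state(p)[:, None, :] + 0.01 * rng.standard_normal((6, n, M))
        dt, G = 0.02, 0.05
        out, final, div = _integrate_network(
            np.ascontiguousarray(w), np.ascontiguousarray(delays), G,
            p.flat(), p.ie, p.ii, p.mode_weights, dt, 1, 1,
            0.0, 0.0, np.ones(6), 0, np.ascontiguousarray(init), 1e6)
        assert div == -1
        # python reference: history = replicated initial mean field
        x0 = np.einsum("m,im->i", p.mode_weights, init[0])
        hist = np.tile(x0, (10, 1))
        state = init.copy()
        nxt = np.empty_like(state)
        for i in range(n):
            c_i = coupling_term(hist, w, delays, G, i, 9)
            f1 = sj3d_derivative(state[:, i, :], p, c_i)
            pred = state[:, i, :] + dt * f1
            f2 = sj3d_derivative(pred, p, c_i)
            nxt[:, i, :] = state[:, i, :] + dt / 2 * (f1 + f2)
        np.testing.assert_allclose(final, nxt, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            out[0], np.einsum("m,im->i", p.mode_weights, nxt[0]), rtol=1e-10)

    def test_uncoupled_network_equals_independent_single_nodes(self):
        """G = 0, no noise: each node evolves exactly like a lone node
        integrated from the same initial state."""
        n = 3
        labels = [f"r{i}" for i in range(n)]
        c = StructuralConnectome("z", labels, np.zeros((n, n)), np.zeros((n, n)))
        cfg = desk_config(G=0.0, noise_sd=0.0, duration_s=5.0,
                          transient_discard_s=0.0, enforce_ranges=False)
        rng = np.random.default_rng(8)
        init = initial_state(cfg.params)[:, None, :] + 0.05 * rng.uniform(
            -1, 1, (6, n, 1))
        full = simulate_neural(c, cfg, init_state=init)
        for i in range(n):
            single = StructuralConnectome(f"s{i}", ["only"],
                                          np.zeros((1, 1)), np.zeros((1, 1)))
            alone = simulate_neural(single, cfg, init_state=init[:, i:i + 1, :])
            np.testing.assert_allclose(full[:, i], alone[:, 0], rtol=1e-9,
                                       atol=1e-12)

    def test_uncoupled_noisy_nodes_match_single_node_statistics(self):
        c0 = generate_healthy_connectome(4, seed=2)
        c = c0.copy()
        c.weights = np.zeros((4, 4))
        c.lengths = np.zeros((4, 4))
        cfg = desk_config(G=0.0, duration_s=8.0, enforce_ranges=False)
        net = simulate_neural(c, cfg)
        single = StructuralConnectome("s", ["only"], np.zeros((1, 1)),
                                      np.zeros((1, 1)))
        lone = simulate_neural(single, cfg.replace(seed=77))
        v_net = np.var(net, axis=0, ddof=1)
        v_lone = np.var(lone, axis=0, ddof=1)[0]
        assert np.all(np.abs(v_net - v_lone) < 0.3 * v_lone)

    def test_isolated_node_receives_zero_coupling(self, rng):
        """coupling_term is identically 0 for a fully lesioned node."""
        w = rng.uniform(0.1, 1, (4, 4))
        np.fill_diagonal(w, 0)
        w[2, :] = w[:, 2] = 0.0
        h = rng.standard_normal((20, 4))
        d = np.ones((4, 4), dtype=int)
        for t in range(1, 20):
            assert coupling_term(h, w, d, 0.08, 2, t) == 0.0

    def test_divergence_reported_with_step(self, small_connectome):
        cfg = desk_config(divergence_guard=1e-3)
        with pytest.raises(IntegrationDivergenceError, match="step"):
            simulate_neural(small_connectome, cfg)

    def test_bounded_trajectories_across_k_grid(self):
        """Noise-free single-node trajectories stay bounded (|x| < 50)
        over 10 s for all K combinations on the exploration grid."""
        single = StructuralConnectome("s", ["only"], np.zeros((1, 1)),
                                      np.zeros((1, 1)))
        for k11 in (0.0, 0.5, 1.0):
            for k12 in (0.0, 0.5, 1.0):
                for k21 in (0.0, 0.5, 1.0):
                    cfg = desk_config(
                        G=0.0, noise_sd=0.0, duration_s=10.0,
                        transient_discard_s=0.0, enforce_ranges=False,
                        params=SJ3DParams(n_modes=3, K11=k11, K12=k12, K21=k21))
                    traj = simulate_neural(single, cfg)
                    assert np.max(np.abs(traj)) < 50


class TestBoldForward:
    def test_default_grid_is_4_minutes_at_tr_2(self):
        """240 s of BOLD at TR = 2 s -> 120 samples per region."""
        cfg = SimulationConfig()  # full-scale defaults
        n_samples = int((cfg.duration_s + cfg.transient_discard_s) * 1000
                        / cfg.decimate_ms)
        neural = np.zeros((n_samples, 2))
        bold = bold_forward(neural, cfg)
        assert bold.data.shape == (2, 120)
        assert bold.tr_s == 2.0

    def test_zero_input_gives_constant_baseline(self):
        cfg = desk_config()
        n_samples = int(12_000 / cfg.decimate_ms)
        bold = bold_forward(np.zeros((n_samples, 3)), cfg)
        assert np.ptp(bold.data) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("model", ["balloon", "gamma"])
    def test_impulse_response_peaks_seconds_after_impulse(self, model):
        cfg = desk_config(duration_s=30.0, transient_discard_s=0.0,
                          hemodynamic_model=model, bold_gain=1.0)
        n_samples = 30_000
        neural = np.zeros((n_samples, 1))
        neural[2000:2100, 0] = 1.0  # 100 ms impulse at t = 2 s
        bold = bold_forward(neural, cfg)
        y = bold.data[0]
        peak_t = (np.argmax(y) + 1) * cfg.tr_s
        assert 3.0 <= peak_t <= 12.0  # hemodynamic lag
        assert abs(y[-1]) < 0.25 * y.max()  # returns toward baseline

    def test_balloon_matches_ode_oracle_on_smooth_drive(self):
        """Compiled Euler balloon vs an independent scipy ODE solution."""
        from scipy.integrate import solve_ivp

        b = BALLOON_CONSTANTS
        k1, k2, k3 = 7 * b["E0"], 2.0, 2 * b["E0"] - 0.2
        T = 40.0
        drive_fn = lambda t: 0.1 * np.sin(2 * np.pi * 0.05 * t)

        def rhs(t, state):
            s, f, v, q = state
            E = 1 - (1 - b["E0"]) ** (1 / f)
            return [drive_fn(t) - b["kappa"] * s - b["gamma"] * (f - 1),
                    s,
                    (f - v ** (1 / b["alpha"])) / b["tau"],
                    (f * E / b["E0"] - v ** (1 / b["alpha"]) * q / v) / b["tau"]]

        sol = solve_ivp(rhs, (0, T), [0, 1, 1, 1], rtol=1e-9, atol=1e-11,
                        dense_output=True)
        t_grid = np.arange(0, T, 0.001)
        cfg = desk_config(duration_s=T - 2.0, transient_discard_s=2.0,
                          bold_gain=1.0)
        # the sine has zero mean over two full periods, so the internal
        # demeaning leaves the drive equal to the oracle's
        neural = drive_fn(t_grid)[:, None]
        bold = bold_forward(neural, cfg)
        idx = (2.0 + 2.0 * np.arange(1, bold.data.shape[1] + 1)) - 0.001
        s_, f_, v_, q_ = sol.sol(idx)
        y_ref = b["V0"] * (k1 * (1 - q_) + k2 * (1 - q_ / v_) + k3 * (1 - v_))
        np.testing.assert_allclose(bold.data[0], y_ref, atol=2e-4)

    def test_short_signal_rejected(self):
        cfg = desk_config()
        with pytest.raises(ValueError, match="shorter"):
            bold_forward(np.zeros((100, 2)), cfg)


class TestConfig:
    def test_range_enforcement(self):
        with pytest.raises(ValueError, match="exploration range"):
            SimulationConfig(G=0.5)
        SimulationConfig(G=0.5, enforce_ranges=False)

    def test_round_trip_serialization(self):
        cfg = desk_config(G=0.02, v=15.0)
        back = SimulationConfig.from_dict(cfg.to_dict())
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()
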