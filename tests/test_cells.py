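"""Single-neuron dynamics: thresholds, leak nonlinearity, AHP, OU noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from granulenet import cells
from conftest import rk4


@pytest.fixture
def gc_p():
    return cells.gc_params()


@pytest.fixture
def goc_p():
    return cells.goc_params()


class TestDrawCells:
    def test_exact_thresholds_without_heterogeneity(self, rng):
        goc = cells.draw_cells(cells.goc_params(v_t_sd=0.0), 5, rng)
        assert np.all(goc.v_t == -45.0)
        gc = cells.draw_cells(cells.gc_params(v_t_sd=0.0), 5, rng)
        assert np.all(gc.v_t == -49.0)

    def test_threshold_spread_matches_gaussian(self, goc_p, rng):
        state = cells.draw_cells(goc_p, 10_000, rng)
        assert state.v_t.std() == pytest.approx(2.25, rel=0.05)
        assert state.v_t.mean() == pytest.approx(-45.0, abs=0.1)

    def test_initial_state_at_rest(self, gc_p, rng):
        state = cells.draw_cells(gc_p, 3, rng)
        assert np.all(state.v == gc_p.e_l)
        assert np.all(state.z_ahp == 0) and np.all(state.x_ahp == 0)


class TestMembrane:
    def test_gc_rest_is_fixed_point(self, gc_p, rng):
        state = cells.draw_cells(gc_p, 1, rng)
        dv = cells.membrane_drift(state, gc_p)
        assert abs(dv[0]) < 1e-12

    def test_goc_drift_at_rest_small_and_depolarizing(self, goc_p, rng):
        # the EIF spike-initiation term at E_L is g_L*dT*exp((E_L-V_T)/dT)
        state = cells.draw_cells(cells.goc_params(v_t_sd=0.0), 1, rng)
        dv = cells.membrane_drift(state, goc_p)
        expected = goc_p.g_l * goc_p.delta_t * np.exp((-50.0 + 45.0) / 3.0) / goc_p.c_m
        assert dv[0] == pytest.approx(expected, rel=1e-12)
        assert 0 < dv[0] < 0.05

    def test_goc_free_trajectory_matches_rk4(self, rng):
        """10 ms of free GoC membrane evolution vs an RK4 oracle."""
        p = cells.goc_params(v_t_sd=0.0)
        state = cells.draw_cells(p, 1, rng)

        def f(t, y):
            return np.array(
                [(-p.g_l * (y[0] - p.e_l) + p.g_l * p.delta_t * np.exp((y[0] + 45) / 3)) / p.c_m]
            )

        _, ys = rk4(f, [p.e_l], 0.0, 10.0, 0.001)
        dt = 0.001
        for _ in range(int(10 / dt)):
            cells.step_membrane(state, p, 0.0, 0.0, dt)
        assert state.v[0] == pytest.approx(ys[-1, 0], abs=1e-3)

    def test_gc_first_spike_time_matches_rk4(self, rng):
        """Constant 100 pA depolarizing drive from rest; crossing time vs RK4."""
        p = cells.gc_params(v_t_sd=0.0)
        drive = -100.0  # pA, inward convention: subtracted in the equation

        def f(t, y):
            v = y[0]
            leak = p.g_l * (v - p.e_l) * np.exp(-(v - p.e_l) / p.leak_shape)
            return np.array([(-leak - drive) / p.c_m])

        dt_o = 0.001
        ts, ys = rk4(f, [p.e_l], 0.0, 50.0, dt_o)
        t_cross_oracle = ts[np.argmax(ys[:, 0] >= -49.0)]

        dt = 0.1
        state = cells.draw_cells(p, 1, rng)
        t_cross = None
        for k in range(int(50 / dt)):
            cells.step_membrane(state, p, drive, 0.0, dt)
            if state.v[0] >= -49.0:
                t_cross = (k + 1) * dt
                break
        assert t_cross is not None
        assert t_cross == pytest.approx(t_cross_oracle, abs=dt)

    def test_nonfinite_v_raises(self, gc_p, rng):
        state = cells.draw_cells(gc_p, 1, rng)
        state.v[0] = np.nan
        with pytest.raises(FloatingPointError):
            cells.step_membrane(state, gc_p, 0.0, 0.0, 0.1)


class TestSpikeHandling:
    def test_gc_plateau_and_reset_timing(self, gc_p, rng):
        state = cells.draw_cells(gc_p, 1, rng)
        cells.handle_spike(state, gc_p, 100.0, np.array([0]))
        assert state.v[0] == 40.0
        assert state.plateau_until[0] == pytest.approx(100.6)
        assert state.refract_until[0] == pytest.approx(102.6)
        cells.end_plateau(state, gc_p, np.array([0]))
        assert state.v[0] == gc_p.v_rest

    def test_goc_plateau_is_one_ms(self, goc_p, rng):
        state = cells.draw_cells(goc_p, 1, rng)
        cells.handle_spike(state, goc_p, 50.0, np.array([0]))
        assert state.plateau_until[0] == pytest.approx(51.0)

    def test_x_ahp_unit_increment_at_plateau_end(self, gc_p, rng):
        state = cells.draw_cells(gc_p, 1, rng)
        cells.handle_spike(state, gc_p, 10.0, np.array([0]))
        assert state.x_ahp[0] == 0.0
        cells.end_plateau(state, gc_p, np.array([0]))
        assert state.x_ahp[0] == 1.0


class TestAHP:
    def test_pure_z_decay_without_resource(self, gc_p, rng):
        state = cells.draw_cells(gc_p, 1, rng)
        state.z_ahp[0] = 0.8
        dt = 0.001
        for _ in range(int(gc_p.tau_ahp / dt)):
            cells.step_ahp(state, gc_p, dt)
        assert state.z_ahp[0] == pytest.approx(0.8 / np.e, rel=1e-3)

    def test_x_decay_time_constant_one_ms(self, gc_p, rng):
        state = cells.draw_cells(gc_p, 1, rng)
        state.x_ahp[0] = 1.0
        dt = 0.001
        for _ in range(int(1.0 / dt)):
            cells.step_ahp(state, gc_p, dt)
        assert state.x_ahp[0] == pytest.approx(1 / np.e, rel=1e-6)

    def test_z_transient_after_spike_matches_rk4(self, gc_p, rng):
        """Peak value and time of z after one spike vs an RK4 oracle."""
        tau = gc_p.tau_ahp

        def f(t, y):
            z, x = y
            return np.array([(1 - z) * x - z / tau, -x])

        ts, ys = rk4(f, [0.0, 1.0], 0.0, 20.0, 0.0005)
        z_peak_o = ys[:, 0].max()
        t_peak_o = ts[np.argmax(ys[:, 0])]

        state = cells.draw_cells(gc_p, 1, rng)
        state.x_ahp[0] = 1.0
        dt = 0.0005
        zs = []
        for _ in range(int(20 / dt)):
            cells.step_ahp(state, gc_p, dt)
            zs.append(state.z_ahp[0])
        zs = np.array(zs)
        assert zs.max() == pytest.approx(z_peak_o, rel=0.01)
        assert dt * (np.argmax(zs) + 1) == pytest.approx(t_peak_o, abs=0.05)

    @settings(max_examples=25, deadline=None)
    @given(
        x0=st.floats(0.0, 5.0),
        z0=st.floats(0.0, 1.0),
        dt=st.floats(0.01, 0.2),
        n=st.integers(1, 200),
    )
    def test_gating_bounds_invariant(self, x0, z0, dt, n):
        p = cells.gc_params()
        state = cells.CellState(
            v=np.array([p.e_l]),
            v_t=np.array([p.v_t_mean]),
            z_ahp=np.array([z0]),
            x_ahp=np.array([x0]),
            g_n=np.zeros(1),
            plateau_until=np.full(1, -np.inf),
            refract_until=np.full(1, -np.inf),
        )
        for _ in range(n):
            cells.step_ahp(state, p, dt)
        assert 0.0 <= state.z_ahp[0] <= 1.0
        assert state.x_ahp[0] >= 0.0


class TestOUNoise:
    def test_deterministic_decay_with_zero_sigma(self, gc_p, rng):
        noise = cells.NoiseParams(sigma_n=0.0, tau_n=1000.0)
        state = cells.draw_cells(gc_p, 1, rng)
        state.g_n[0] = 1.0
        for _ in range(100):
            cells.step_ou_noise(state, noise, 10.0, rng)
        assert state.g_n[0] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_stationary_sd_and_normality(self, gc_p):
        """Stationary SD sigma_N/sqrt(2) ~ 0.0849 nS within 3%."""
        from scipy import stats

        rng = np.random.default_rng(99)
        noise = cells.default_noise()
        state = cells.draw_cells(gc_p, 2000, rng)
        # exact discretization lets us burn in with few large steps
        for _ in range(20):
            cells.step_ou_noise(state, noise, 1000.0, rng)
        samples = []
        for _ in range(500):
            cells.step_ou_noise(state, noise, 100.0, rng)
            samples.append(state.g_n.copy())
        samples = np.concatenate(samples)
        assert samples.std() == pytest.approx(noise.sigma_n / np.sqrt(2), rel=0.03)
        assert stats.normaltest(samples[::200]).pvalue > 0.01

    def test_autocorrelation_time_is_tau_n(self, gc_p):
        rng = np.random.default_rng(7)
        noise = cells.default_noise()
        state = cells.draw_cells(gc_p, 500, rng)
        for _ in range(20):
            cells.step_ou_noise(state, noise, 1000.0, rng)
        dt = 100.0
        traj = []
        for _ in range(300):
            cells.step_ou_noise(state, noise, dt, rng)
            traj.append(state.g_n.copy())
        traj = np.asarray(traj)
        lag = int(noise.tau_n / dt)
        x0, x1 = traj[:-lag].ravel(), traj[lag:].ravel()
        rho = np.corrcoef(x0, x1)[0, 1]
        assert rho == pytest.approx(np.exp(-1.0), abs=0.05)


class TestNumerics:
    def test_spike_times_converge_when_dt_halved(self, rng):
        """Frozen input; dt 0.1 -> 0.05 moves each spike by < 0.2 ms."""
        p = cells.gc_params(v_t_sd=0.0)

        def simulate(dt):
            state = cells.draw_cells(p, 1, np.random.default_rng(0))
            spikes = []
            t = 0.0
            n = int(200 / dt)
            for k in range(n):
                t = (k + 1) * dt
                plateau = t < state.plateau_until[0] - 1e-9
                if not plateau and state.v[0] == p.v_plateau:
                    cells.end_plateau(state, p, np.array([0]))
                cells.step_ahp(state, p, dt)
                if not plateau:
                    drive = -80.0  # pA constant depolarizing
                    cells.step_membrane(state, p, drive, 0.0, dt)
                    if t >= state.refract_until[0] - 1e-9 and state.v[0] >= state.v_t[0]:
                        cells.handle_spike(state, p, t, np.array([0]))
                        spikes.append(t)
            return np.array(spikes)

        s1, s2 = simulate(0.1), simulate(0.05)
        n = min(len(s1), len(s2))
        assert n >= 3
        assert np.max(np.abs(s1[:n] - s2[:n])) < 0.2

    def test_refractoriness_enforced_under_strong_drive(self, rng):
        from granulenet import RunConfig, desk_counts, run

        cfg = RunConfig(
            scenario="fbi", counts=desk_counts(), duration_ms=500.0, seed=3,
            mf_rate_hz=50.0,
        )
        res = run(cfg)[0]
        p = cells.gc_params()
        min_gap = p.tau_dur + p.t_ref
        for t in res.spikes["gc"].trains.values():
            if len(t) > 1:
                assert np.diff(t).min() >= min_gap - 1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cells.gc_params(tau_ahp=-1.0)
        with pytest.raises(ValueError):
            cells.goc_params(v_rest=0.0)  # above threshold mean
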