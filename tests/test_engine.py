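"""Simulation loop: determinism, quiescence, recordings, numerics."""

import numpy as np
import pytest

import granulenet as gn
from granulenet import cells, synapses
from granulenet.engine import RunConfig, _Groups, desk_counts, run
from granulenet.network import Counts, Edges, FanIns, NetworkTopology
from granulenet.analysis import population_rate, power_spectrum, oscillation_frequency
from conftest import rk4


def _tiny_topology(weight=1.0, delay=1.0):
    """One MF driving one GC; one disconnected GoC to satisfy the engine."""
    counts = Counts(n_mf=1, n_gc=1, n_goc=1)
    edges = {
        "mf_gc": Edges(
            pre=np.array([0]), post=np.array([0]),
            weight=np.array([weight]), delay=np.array([delay]),
        )
    }
    return NetworkTopology(scenario="fbi", counts=counts, edges=edges,
                           weight_means={})


class TestDeterminism:
    def test_identical_seeds_identical_rasters(self):
        cfg = RunConfig(scenario="fbi", counts=desk_counts(), duration_ms=600.0, seed=11)
        a = run(cfg)[0]
        b = run(cfg)[0]
        for pop in ("gc", "goc", "mf"):
            ua, ta = a.spikes[pop].to_arrays()
            ub, tb = b.spikes[pop].to_arrays()
            assert np.array_equal(ua, ub) and np.array_equal(ta, tb)

    def test_different_seeds_differ(self):
        cfg1 = RunConfig(scenario="fbi", counts=desk_counts(), duration_ms=600.0, seed=11)
        cfg2 = RunConfig(scenario="fbi", counts=desk_counts(), duration_ms=600.0, seed=12)
        a, b = run(cfg1)[0], run(cfg2)[0]
        assert a.spikes["gc"].n_spikes != b.spikes["gc"].n_spikes

    def test_trials_use_fresh_streams_frozen_topology(self):
        cfg = RunConfig(scenario="fbi", counts=desk_counts(), duration_ms=400.0,
                        seed=5, n_trials=2)
        r1, r2 = run(cfg)
        a = r1.spikes["mf"].to_arrays()[1]
        b = r2.spikes["mf"].to_arrays()[1]
        assert len(a) != len(b) or not np.array_equal(a, b)


class TestQuiescence:
    def test_gcs_silent_without_input_or_noise(self):
        """No mossy drive, no noise: GCs stay at rest (their leak fixed point).

        GoCs with thresholds drawn more than ~2 mV below the mean are
        intrinsic pacemakers of the exponential spike-initiation current, so
        only the GC population is asserted silent.
        """
        cfg = RunConfig(scenario="fbi", counts=desk_counts(), duration_ms=500.0,
                        seed=1, mf_rate_hz=0.0, sigma_noise_ns=0.0)
        res = run(cfg)[0]
        assert res.spikes["gc"].n_spikes == 0
        assert res.spikes["mf"].n_spikes == 0

    def test_gc_voltage_stays_at_rest(self):
        """Isolated GC with no drive sits exactly at its leak reversal."""
        topo = _tiny_topology()
        cfg = RunConfig(scenario="fbi", counts=topo.counts,
                        fan_ins=FanIns(1, 1, 1, 1), duration_ms=300.0,
                        seed=1, mf_rate_hz=0.0, sigma_noise_ns=0.0,
                        record_v_gc=(0,))
        res = run(cfg, topology=topo)[0]
        assert np.allclose(res.v_traces["gc"], cells.gc_params().e_l, atol=1e-9)


class TestInlinedUpdatesMatchCellOps:
    """The engine inlines the noise/AHP updates; verify against the cells API."""

    def test_ahp_update_equivalence(self, rng):
        p = cells.gc_params()
        a = cells.draw_cells(p, 50, np.random.default_rng(1))
        a.x_ahp[:] = rng.uniform(0, 2, 50)
        a.z_ahp[:] = rng.uniform(0, 1, 50)
        b = cells.draw_cells(p, 50, np.random.default_rng(1))
        b.x_ahp[:] = a.x_ahp.copy()
        b.z_ahp[:] = a.z_ahp.copy()
        dt = 0.1
        # reference path
        cells.step_ahp(a, p, dt)
        # engine-inlined arithmetic
        z, x = b.z_ahp, b.x_ahp
        z += dt * ((1.0 - z) * x - z / p.tau_ahp)
        np.maximum(z, 0.0, out=z)
        np.minimum(z, 1.0, out=z)
        x *= np.exp(-dt / p.tau_ahpx)
        assert np.allclose(a.z_ahp, b.z_ahp, atol=1e-15)
        assert np.allclose(a.x_ahp, b.x_ahp, atol=1e-15)

    def test_ou_decay_equivalence_without_noise(self):
        p = cells.gc_params()
        noise = cells.NoiseParams(sigma_n=0.0)
        a = cells.draw_cells(p, 10, np.random.default_rng(0))
        a.g_n[:] = 0.5
        cells.step_ou_noise(a, noise, 0.1, np.random.default_rng(0))
        assert np.allclose(a.g_n, 0.5 * np.exp(-0.1 / noise.tau_n))


class TestClampRecording:
    def test_gaba_current_zero_at_its_reversal(self):
        cfg = RunConfig(scenario="fbi", counts=desk_counts(), duration_ms=300.0,
                        seed=2, record_clamp_gc=(0,), v_hold_inh=-75.0)
        res = run(cfg)[0]
        assert np.allclose(res.clamp["ipsc"], 0.0)

    def test_clamp_current_signs(self):
        """EPSC inward (negative) at -70 mV; IPSC outward (positive) at 0 mV."""
        cfg = RunConfig(scenario="fbi", counts=desk_counts(), duration_ms=800.0,
                        seed=2, record_clamp_gc=(0, 1))
        res = run(cfg)[0]
        assert res.clamp["epsc"].min() < 0 and res.clamp["epsc"].max() <= 0
        assert res.clamp["ipsc"].max() > 0 and res.clamp["ipsc"].min() >= 0

    def test_epsc_waveform_matches_receptor_oracle(self):
        """MF-evoked EPSC of one GC vs an RK4 oracle of the gating cascade."""
        dt = 0.005
        topo = _tiny_topology(weight=1.0, delay=1.0)
        cfg = RunConfig(
            scenario="fbi", counts=topo.counts,
            fan_ins=FanIns(1, 1, 1, 1),
            duration_ms=150.0, dt_ms=dt, seed=4, mf_rate_hz=25.0,
            sigma_noise_ns=0.0, record_clamp_gc=(0,),
        )
        res = run(cfg, topology=topo)[0]
        epsc = res.clamp["epsc"][0]

        mf_times = res.spikes["mf"].trains[0]
        assert len(mf_times) >= 2
        n = len(epsc)
        # event indices on the engine's grid: spike bin + one delay
        jumps = set((mf_times / dt).astype(int) + int(round(1.0 / dt)))
        rows = synapses.receptor_rows("mf_gc", stp_enabled=False)
        oracle = np.zeros(n)
        vh = cfg.v_hold_exc
        for rp, sp in rows:
            r_tr = np.zeros(n)
            state = np.array([0.0, 0.0])  # r, s

            def f(t, yv, rp=rp):
                r, s = yv
                return np.array(
                    [rp.alpha * s * (1 - r) - r / rp.tau_decay, -s / rp.tau_rise]
                )

            for k in range(n):
                if k in jumps:
                    state[1] += sp.u_base
                _, ys = rk4(f, state, 0, dt, dt)
                state = ys[-1]
                r_tr[k] = state[0]
            gate = synapses.nmda_gate(vh, rp)
            oracle += rp.g_mult * 1.0 * r_tr * gate * (vh - rp.e_syn)
        scale = np.max(np.abs(oracle))
        assert scale > 0
        assert np.max(np.abs(epsc - oracle)) / scale < 0.01


class TestNetworkDynamics:
    def test_fbi_oscillates_ffi_plus_fbi_reduces_gc_rate(self, desk_fbi_result):
        """Adding feedforward inhibition on top of feedback lowers GC rates."""
        cfg = RunConfig(scenario="ffi_fbi", counts=desk_counts(),
                        duration_ms=3000.0, seed=7)
        both = run(cfg)[0]
        fbi = desk_fbi_result
        rate_fbi = fbi.spikes["gc"].n_spikes / fbi.spikes["gc"].n_units
        rate_both = both.spikes["gc"].n_spikes / both.spikes["gc"].n_units
        assert rate_both < rate_fbi

    def test_fbi_gc_rate_spectrum_has_gamma_band_peak(self, desk_fbi_result):
        rate = population_rate(desk_fbi_result.spikes["gc"])
        of = oscillation_frequency(power_spectrum(rate), signal=rate.values)
        assert of is not None and 30.0 <= of <= 100.0

    def test_oscillation_frequency_stable_when_dt_halved(self):
        """Halving dt moves the rhythm's frequency content by < 2 Hz.

        Individual trajectories of a spiking network are chaotic, so the
        raw spectral argmax of a single trial fluctuates by several Hz
        between realizations; the gamma-band spectral centroid of the
        seed-averaged spectrum is the convergent frequency summary used
        for the numerics check.
        """
        centroids = []
        for dt in (0.1, 0.05):
            powers = []
            for seed in (3, 4, 5):
                cfg = RunConfig(scenario="fbi", counts=desk_counts(),
                                duration_ms=6000.0, seed=seed, dt_ms=dt,
                                sigma_noise_ns=0.0)
                res = run(cfg)[0]
                spec = power_spectrum(population_rate(res.spikes["gc"]))
                powers.append(spec.power)
            p = np.mean(powers, axis=0)
            mb = (spec.freqs >= 30) & (spec.freqs <= 120)
            centroids.append((spec.freqs[mb] * p[mb]).sum() / p[mb].sum())
        assert abs(centroids[0] - centroids[1]) < 2.0

    def test_raster_and_rate_are_consistent(self, desk_fbi_result):
        sd = desk_fbi_result.spikes["gc"]
        rate = population_rate(sd)
        total_from_rate = rate.values.sum() / rate.fs * sd.n_units
        assert total_from_rate == pytest.approx(sd.n_spikes, rel=1e-9)


class TestConfigValidation:
    def test_bad_scenario_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(scenario="nope")

    def test_duration_must_tile_dt(self):
        with pytest.raises(ValueError):
            RunConfig(duration_ms=100.05, dt_ms=0.1)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(weight_means={"mf_gc": -1.0})

    def test_gap_weight_default_switches(self):
        assert RunConfig(gap_junctions=False).resolved_weights()["goc_gc"] == 4.0
        assert RunConfig(gap_junctions=True).resolved_weights()["goc_gc"] == 2.5
        assert RunConfig(
            gap_junctions=True, weight_means={"goc_gc": 3.0}
        ).resolved_weights()["goc_gc"] == 3.0
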