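"""Fixed-step simulation loop coupling cells, synapses, gap junctions and
mossy-fiber drive.

The integrator advances the whole network on a uniform dt grid (forward Euler
for membranes, exponential factors for the linear synaptic decays).  Each
step: deliver delayed presynaptic spikes (short-term-plasticity event
updates), advance receptor gating, accumulate synaptic and gap currents,
advance noise and afterhyperpolarization, advance membranes, detect threshold
crossings and start spike plateaus.  All receptor channels of all projections
live in one flat state vector so the per-step work is a handful of vectorized
operations; per-postsynaptic-cell conductances are reduced with bincount.

Runs are deterministic per seed: one ``SeedSequence`` spawns a topology
stream and one stream per trial (topology frozen across trials unless
``resample_topology`` is set), so trial-to-trial variability is attributable
to input and noise alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse import _sparsetools

# raw CSR kernel; the python-level dispatch of scipy.sparse matmul costs more
# than the multiply itself at the sizes used here
_csr_matvec = _sparsetools.csr_matvec

try:  # optional fused kernel; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _gating_kernel(r, s, res, u, a_alpha, c_decay, s_decay, u_base,
                       e_rec, e_fac, any_stp):
        # floating-point operation order matches the numpy path exactly
        for i in range(r.shape[0]):
            ri = r[i]
            t1 = a_alpha[i] * s[i]
            t1 = t1 - t1 * ri
            t1 = t1 - c_decay[i] * ri
            ri = ri + t1
            if ri < 0.0:
                ri = 0.0
            elif ri > 1.0:
                ri = 1.0
            r[i] = ri
            s[i] = s[i] * s_decay[i]
            if any_stp:
                res[i] = 1.0 - (1.0 - res[i]) * e_rec[i]
                u[i] = u_base[i] + (u[i] - u_base[i]) * e_fac[i]

    @_njit(cache=True)
    def _cell_kernel(v, z, x, g_n, v_t, plateau_until, refract_until,
                     in_plateau, i_syn, i_gap, spike_idx,
                     t, dt, tau_ahp, x_decay, v_rest,
                     g_l, e_l, shape_or_dt, g_ahp, e_k, v_e, c_m, is_gc):
        """Fused AHP + plateau-end + Euler membrane + threshold detection.

        Floating-point operation order replicates the numpy reference path
        (cells.step_ahp / end_plateau / step_membrane) exactly.
        """
        n_spk = 0
        ok = True
        gdt = g_l * shape_or_dt  # GoC: g_L * delta_T (unused for GCs)
        for i in range(v.shape[0]):
            # AHP gating (multiplicative law)
            dz = (1.0 - z[i]) * x[i] - z[i] / tau_ahp
            zi = z[i] + dt * dz
            if zi < 0.0:
                zi = 0.0
            elif zi > 1.0:
                zi = 1.0
            z[i] = zi
            x[i] = x[i] * x_decay
            # plateau termination
            if in_plateau[i]:
                if t >= plateau_until[i] - 1e-9:
                    v[i] = v_rest
                    x[i] = x[i] + 1.0
                    in_plateau[i] = False
                else:
                    continue
            # membrane drift, forward Euler
            vi = v[i]
            if is_gc:
                arg = -(vi - e_l) / shape_or_dt
                if arg > 30.0:
                    arg = 30.0
                elif arg < -30.0:
                    arg = -30.0
                i_leak = g_l * (vi - e_l) * np.exp(arg)
            else:
                i_leak = g_l * (vi - e_l)
            total = -i_leak
            total = total - g_ahp * zi * (vi - e_k)
            total = total - (vi - v_e) * g_n[i]
            total = total - i_syn[i]
            total = total - i_gap[i]
            if not is_gc:
                arg = (vi - v_t[i]) / shape_or_dt
                if arg > 30.0:
                    arg = 30.0
                elif arg < -30.0:
                    arg = -30.0
                total = total + gdt * np.exp(arg)
            vi = vi + dt * (total / c_m)
            v[i] = vi
            if not np.isfinite(vi):
                ok = False
            # threshold detection outside plateau/refractory windows
            if t >= refract_until[i] - 1e-9 and vi >= v_t[i]:
                spike_idx[n_spk] = i
                n_spk += 1
        return n_spk, ok

except ImportError:  # pragma: no cover - numba is a pinned dependency
    _gating_kernel = None
    _cell_kernel = None

from . import cells as _c
from . import synapses as _s
from .network import (
    Counts,
    FanIns,
    GAP_GOC_GC_WEIGHT,
    DEFAULT_WEIGHTS,
    NetworkTopology,
    SCENARIOS,
    build_topology,
    gap_conductances,
    place_goc_grid,
)
from .stimulus import SpikeData, poisson_trains

__all__ = ["RunConfig", "SimResult", "run", "desk_counts", "full_counts"]


def full_counts() -> Counts:
    """Population sizes matching the reference network."""
    return Counts(n_mf=500, n_gc=2000, n_goc=144)


def desk_counts() -> Counts:
    """Reduced preset for sweeps: fan-ins preserved, populations scaled 1/4."""
    return Counts(n_mf=125, n_gc=500, n_goc=36)


@dataclass(frozen=True)
class RunConfig:
    """Complete description of one simulation experiment."""

    scenario: str = "fbi"
    counts: Counts = field(default_factory=full_counts)
    fan_ins: FanIns = field(default_factory=FanIns)
    weight_means: dict | None = None      # overrides of the per-projection W
    stp_goc_gc: bool = False
    stp_mf_gc: bool = False
    gap_junctions: bool = False
    gap_scale_factor: float = 1.0         # relative sweep of the gap strength
    gap_target_total_ns: float = 1.0      # calibration: mean summed G per cell
    mf_rate_hz: float = 25.0
    duration_ms: float = 10000.0
    dt_ms: float = 0.1
    n_trials: int = 1
    seed: int = 0
    resample_topology: bool = False
    v_init_jitter_mv: float = 0.0
    sigma_noise_ns: float | None = None   # None -> config-file default
    record_v_gc: tuple = ()
    record_v_goc: tuple = ()
    record_clamp_gc: tuple = ()           # GC ids for EPSC/IPSC recording
    v_hold_exc: float = -70.0             # mV, holding potential for EPSCs
    v_hold_inh: float = 0.0               # mV, holding potential for IPSCs
    ahp_form: str = "multiplicative"
    stp_order: str = "facilitate-first"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        n = self.duration_ms / self.dt_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a multiple of dt")
        if self.weight_means:
            bad = set(self.weight_means) - set(DEFAULT_WEIGHTS)
            if bad:
                raise ValueError(f"unknown weight keys {sorted(bad)}")
            if any(w < 0 for w in self.weight_means.values()):
                raise ValueError("weights must be >= 0")

    def resolved_weights(self) -> dict:
        """Projection weight means with the gap-junction default applied."""
        means = dict(DEFAULT_WEIGHTS)
        if self.gap_junctions:
            means["goc_gc"] = GAP_GOC_GC_WEIGHT
        if self.weight_means:
            means.update(self.weight_means)
        return means


@dataclass
class SimResult:
    """Output of one trial."""

    spikes: dict                      # population -> SpikeData
    config: RunConfig
    trial: int
    v_traces: dict = field(default_factory=dict)   # population -> (n_cells, n_steps)
    clamp: dict = field(default_factory=dict)      # "epsc"/"ipsc" -> (n_cells, n_steps)
    times: np.ndarray | None = None   # ms, sample times of the traces
    gap_matrix: np.ndarray | None = None

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        cfg["counts"] = asdict(self.config.counts)
        cfg["fan_ins"] = asdict(self.config.fan_ins)
        return {
            "config": cfg,
            "trial": self.trial,
            "n_spikes": {k: v.n_spikes for k, v in self.spikes.items()},
        }


class _Groups:
    """Flat receptor-channel state across all projections of a topology.

    Synapses of one projection that share the presynaptic cell and the
    (dt-grid) delay receive identical spike trains, so their gating and
    short-term-plasticity trajectories coincide exactly; state is therefore
    keyed by unique (pre, delay) pairs per receptor, and the per-synapse
    weights live in a sparse readout matrix mapping unit gating values to
    per-postsynaptic-cell conductances.
    """

    def __init__(self, topo: NetworkTopology, cfg: RunConfig, dt: float):
        from scipy import sparse

        self.groups = []           # per-group metadata
        tot = 0
        stp_flags = {"goc_gc": cfg.stp_goc_gc, "mf_gc": cfg.stp_mf_gc}
        for proj, e in topo.edges.items():
            rows = _s.receptor_rows(proj, stp_enabled=stp_flags.get(proj, False))
            dsteps = np.maximum(1, np.round(e.delay / dt).astype(np.int64))
            n_post = topo.counts.of(proj.split("_")[1])
            # unique (pre, delay) units shared by all receptors of this edge set
            keys = np.stack([e.pre, dsteps], axis=1)
            uniq, unit_of_edge = np.unique(keys, axis=0, return_inverse=True)
            n_units = len(uniq)
            for rp, sp in rows:
                m = sparse.csr_matrix(
                    (rp.g_mult * e.weight, (e.post, unit_of_edge)),
                    shape=(n_post, n_units),
                )
                m.sum_duplicates()
                self.groups.append(
                    dict(
                        proj=proj,
                        rp=rp,
                        sp=sp,
                        sl=slice(tot, tot + n_units),
                        unit_pre=uniq[:, 0],
                        unit_delay=uniq[:, 1],
                        readout=m,
                        csr=(n_post, n_units, m.indptr, m.indices, m.data),
                        target=proj.split("_")[1],
                    )
                )
                tot += n_units
        self.n = tot
        # flat state and coefficients
        self.r = np.zeros(tot)
        self.s = np.zeros(tot)
        self.res = np.ones(tot)
        self.u = np.empty(tot)
        self.s_decay = np.empty(tot)
        self.a_alpha = np.empty(tot)     # dt * alpha
        self.c_decay = np.empty(tot)     # dt / tau_decay
        self.u_base = np.empty(tot)
        self.stp_on = np.zeros(tot, dtype=bool)
        self.e_rec = np.ones(tot)
        self.e_fac = np.ones(tot)
        for g in self.groups:
            sl, rp, sp = g["sl"], g["rp"], g["sp"]
            self.s_decay[sl] = np.exp(-dt / rp.tau_rise)
            self.a_alpha[sl] = dt * rp.alpha
            self.c_decay[sl] = dt / rp.tau_decay
            self.u_base[sl] = sp.u_base
            self.u[sl] = sp.u_base
            if sp.enabled:
                self.stp_on[sl] = True
                self.e_rec[sl] = np.exp(-dt / sp.tau_rec)
                self.e_fac[sl] = np.exp(-dt / sp.tau_fac)
        self.any_stp = bool(self.stp_on.any())
        self._b1 = np.empty(tot)
        self._b2 = np.empty(tot)
        # outgoing adjacency per source population (CSR over flat unit indices)
        self.adj = {}
        for pop in ("mf", "gc", "goc"):
            idx_list, pre_list, off_list = [], [], []
            for g in self.groups:
                if g["proj"].split("_")[0] != pop:
                    continue
                flat = np.arange(g["sl"].start, g["sl"].stop, dtype=np.int64)
                idx_list.append(flat)
                pre_list.append(g["unit_pre"])
                off_list.append(g["unit_delay"])
            if not idx_list:
                continue
            flat = np.concatenate(idx_list)
            pre = np.concatenate(pre_list)
            offs = np.concatenate(off_list)
            order = np.argsort(pre, kind="stable")
            n_src = topo.counts.of(pop)
            indptr = np.searchsorted(pre[order], np.arange(n_src + 1))
            self.adj[pop] = (flat[order], offs[order], indptr)

    def deliver(self, idx: np.ndarray, order: str) -> None:
        """Apply spike events to receptor channels ``idx`` (may repeat)."""
        stp_mask = self.stp_on[idx]
        if self.any_stp and stp_mask.any():
            i = idx[stp_mask]
            ub = self.u_base[i]
            if order == "facilitate-first":
                u_new = self.u[i] + ub * (1.0 - self.u[i])
                rel = self.res[i] * u_new
            else:
                rel = self.res[i] * self.u[i]
                u_new = self.u[i] + ub * (1.0 - self.u[i])
            self.u[i] = u_new
            self.s[i] += rel
            self.res[i] -= rel
            i = idx[~stp_mask]
            np.add.at(self.s, i, self.u_base[i])
        else:
            np.add.at(self.s, idx, self.u_base[idx])

    def step(self) -> None:
        """Gating + STP relaxation for all channels (in-place, same math as
        :func:`granulenet.synapses.step_gating` / ``step_stp``)."""
        if _gating_kernel is not None:
            _gating_kernel(self.r, self.s, self.res, self.u, self.a_alpha,
                           self.c_decay, self.s_decay, self.u_base,
                           self.e_rec, self.e_fac, self.any_stp)
            return
        r, s, b1, b2 = self.r, self.s, self._b1, self._b2
        # r += dt*alpha*s*(1-r) - dt/tau_decay*r
        np.multiply(self.a_alpha, s, out=b1)
        np.multiply(b1, r, out=b2)
        np.subtract(b1, b2, out=b1)
        np.multiply(self.c_decay, r, out=b2)
        np.subtract(b1, b2, out=b1)
        np.add(r, b1, out=r)
        np.maximum(r, 0.0, out=r)
        np.minimum(r, 1.0, out=r)
        s *= self.s_decay
        if self.any_stp:
            # R <- 1 - (1-R) e_rec ; u <- U + (u-U) e_fac
            np.subtract(1.0, self.res, out=b1)
            b1 *= self.e_rec
            np.subtract(1.0, b1, out=self.res)
            np.subtract(self.u, self.u_base, out=b1)
            b1 *= self.e_fac
            np.add(self.u_base, b1, out=self.u)


def _outgoing(adj, cell_ids: np.ndarray):
    flat, offs, indptr = adj
    if len(cell_ids) == 0:
        return None, None
    segs = [slice(indptr[c], indptr[c + 1]) for c in cell_ids]
    units = np.concatenate([flat[sg] for sg in segs])
    delays = np.concatenate([offs[sg] for sg in segs])
    return units, delays


def _schedule(ring: list, k_base: int, units: np.ndarray, delays: np.ndarray) -> None:
    L = len(ring)
    order = np.argsort(delays, kind="stable")
    ds = delays[order]
    us = units[order]
    cuts = np.flatnonzero(ds[1:] != ds[:-1]) + 1
    start = 0
    for stop in list(cuts) + [len(ds)]:
        ring[(k_base + int(ds[start])) % L].append(us[start:stop])
        start = stop


def run(config: RunConfig, topology: NetworkTopology | None = None) -> list[SimResult]:
    """Simulate ``config.n_trials`` trials; returns one :class:`SimResult` each."""
    dt = config.dt_ms
    n_steps = int(round(config.duration_ms / dt))
    root = np.random.SeedSequence(config.seed)
    topo_ss, *trial_ss = root.spawn(config.n_trials + 1)
    topo_rng = np.random.default_rng(topo_ss)

    weights = config.resolved_weights()
    if topology is None:
        topology = build_topology(
            config.scenario,
            counts=config.counts,
            fan_ins=config.fan_ins,
            weight_means=weights,
            rng=topo_rng,
            dt=dt,
        )
    gap_g = None
    if config.gap_junctions:
        n_side = int(round(np.sqrt(config.counts.n_goc)))
        if n_side * n_side != config.counts.n_goc:
            raise ValueError("gap junctions require a square GoC count")
        layout = place_goc_grid(topo_rng, n_side=n_side)
        layout = gap_conductances(layout, target_cell_total=config.gap_target_total_ns)
        gap_g = config.gap_scale_factor * layout.conductance

    noise = _c.default_noise(
        **({} if config.sigma_noise_ns is None else {"sigma_n": config.sigma_noise_ns})
    )
    results = []
    for trial in range(config.n_trials):
        rng = np.random.default_rng(trial_ss[trial])
        if config.resample_topology and trial > 0:
            topology = build_topology(
                config.scenario, counts=config.counts, fan_ins=config.fan_ins,
                weight_means=weights, rng=rng, dt=dt,
            )
        results.append(
            _run_trial(config, topology, gap_g, noise, rng, n_steps, dt, trial)
        )
    return results


def _run_trial(cfg, topo, gap_g, noise, rng, n_steps, dt, trial) -> SimResult:
    counts = cfg.counts
    gc_p = _c.gc_params()
    goc_p = _c.goc_params()
    gc = _c.draw_cells(gc_p, counts.n_gc, rng, cfg.v_init_jitter_mv)
    goc = _c.draw_cells(goc_p, counts.n_goc, rng, cfg.v_init_jitter_mv)
    grp = _Groups(topo, cfg, dt)

    mf = poisson_trains(counts.n_mf, cfg.mf_rate_hz, cfg.duration_ms, rng)
    mf_units, mf_times = mf.to_arrays()
    mf_steps = np.minimum((mf_times / dt).astype(np.int64), n_steps - 1)
    order = np.argsort(mf_steps, kind="stable")
    mf_units, mf_steps = mf_units[order], mf_steps[order]
    mf_ptr = np.searchsorted(mf_steps, np.arange(n_steps + 1))

    max_d = 1
    for g in grp.groups:
        if g["unit_delay"].size:
            max_d = max(max_d, int(g["unit_delay"].max()))
    L = max_d + 2
    ring: list[list] = [[] for _ in range(L)]

    # conductance bookkeeping per group target
    gc_groups = [g for g in grp.groups if g["target"] == "gc"]
    goc_groups = [g for g in grp.groups if g["target"] == "goc"]

    # plateau state
    gc_plateau = np.zeros(counts.n_gc, dtype=bool)
    goc_plateau = np.zeros(counts.n_goc, dtype=bool)

    rec_v = {}
    if cfg.record_v_gc:
        rec_v["gc"] = np.empty((len(cfg.record_v_gc), n_steps))
    if cfg.record_v_goc:
        rec_v["goc"] = np.empty((len(cfg.record_v_goc), n_steps))
    clamp = {}
    clamp_units = []
    if cfg.record_clamp_gc:
        clamp["epsc"] = np.zeros((len(cfg.record_clamp_gc), n_steps))
        clamp["ipsc"] = np.zeros((len(cfg.record_clamp_gc), n_steps))
        for cell in cfg.record_clamp_gc:
            per_group = []
            for g in gc_groups:
                row = g["readout"].getrow(int(cell))
                flat_idx = row.indices + g["sl"].start
                is_inh = g["rp"].e_syn < -30.0
                vh = cfg.v_hold_inh if is_inh else cfg.v_hold_exc
                y_h = float(np.asarray(_s.nmda_gate(vh, g["rp"])).ravel()[0])
                per_group.append(
                    (flat_idx, row.data.copy(), y_h * (vh - g["rp"].e_syn), is_inh)
                )
            clamp_units.append(per_group)

    mf_adj = grp.adj.get("mf")
    gc_adj = grp.adj.get("gc")
    goc_adj = grp.adj.get("goc")
    gap_rowsum = gap_g.sum(axis=1) if gap_g is not None else None
    # precomputed per-step scalars for the inlined noise/AHP updates
    n_all = counts.n_gc + counts.n_goc
    ou_a = math.exp(-dt / noise.tau_n)
    ou_sd = noise.sigma_n * math.sqrt((1.0 - ou_a * ou_a) / 2.0)
    x_decay = math.exp(-dt / gc_p.tau_ahpx)  # tau_AHPx shared by both models
    use_kernel = (
        _cell_kernel is not None
        and cfg.ahp_form == "multiplicative"
        and goc_p.eif_depolarizing
    )
    gc_spk = np.empty(counts.n_gc, dtype=np.int64)
    goc_spk = np.empty(counts.n_goc, dtype=np.int64)
    gc_nogap = np.zeros(counts.n_gc)
    goc_nogap = np.zeros(counts.n_goc)

    for k in range(n_steps):
        t = (k + 1) * dt
        # 1. deliver events scheduled for this step
        slot = ring[k % L]
        if slot:
            grp.deliver(np.concatenate(slot), cfg.stp_order)
            ring[k % L] = []
        # 2. receptor gating and STP relaxation
        grp.step()
        # 3. synaptic conductances -> currents at the present V
        i_gc = np.zeros(counts.n_gc)
        for g in gc_groups:
            n_po, n_un, indptr, indices, data = g["csr"]
            cond = np.zeros(n_po)
            _csr_matvec(n_po, n_un, indptr, indices, data, grp.r[g["sl"]], cond)
            drive = cond * (gc.v - g["rp"].e_syn)
            if g["rp"].voltage_dependent:
                drive *= _s.nmda_gate(gc.v, g["rp"])
            i_gc += drive
        i_goc = np.zeros(counts.n_goc)
        for g in goc_groups:
            n_po, n_un, indptr, indices, data = g["csr"]
            cond = np.zeros(n_po)
            _csr_matvec(n_po, n_un, indptr, indices, data, grp.r[g["sl"]], cond)
            drive = cond * (goc.v - g["rp"].e_syn)
            if g["rp"].voltage_dependent:
                drive *= _s.nmda_gate(goc.v, g["rp"])
            i_goc += drive
        i_gap = 0.0
        if gap_g is not None:
            i_gap = goc.v * gap_rowsum - gap_g @ goc.v
        # 4. voltage-clamp-style recordings (synaptic current at V_hold)
        if clamp_units:
            for ci, per_group in enumerate(clamp_units):
                for flat_idx, w, factor, is_inh in per_group:
                    val = float(np.dot(w, grp.r[flat_idx])) * factor
                    clamp["ipsc" if is_inh else "epsc"][ci, k] += val
        # 5. noise and AHP (same updates as cells.step_ou_noise/step_ahp,
        # inlined with one shared noise draw; equivalence is unit-tested)
        if ou_sd > 0:
            eps = rng.standard_normal(n_all)
            gc.g_n *= ou_a
            gc.g_n += ou_sd * eps[: counts.n_gc]
            goc.g_n *= ou_a
            goc.g_n += ou_sd * eps[counts.n_gc :]
        else:
            gc.g_n *= ou_a
            goc.g_n *= ou_a
        # 6. AHP, plateau terminations, membrane integration, detection
        if use_kernel:
            gap_arr = i_gap if gap_g is not None else goc_nogap
            for state, params, plateau, i_syn, ig, adj, spk, shape in (
                (gc, gc_p, gc_plateau, i_gc, gc_nogap, gc_adj, gc_spk,
                 gc_p.leak_shape),
                (goc, goc_p, goc_plateau, i_goc, gap_arr, goc_adj, goc_spk,
                 goc_p.delta_t),
            ):
                n_spk, ok = _cell_kernel(
                    state.v, state.z_ahp, state.x_ahp, state.g_n, state.v_t,
                    state.plateau_until, state.refract_until, plateau,
                    i_syn, ig, spk, t, dt, params.tau_ahp, x_decay,
                    params.v_rest, params.g_l, params.e_l, shape,
                    params.g_ahp, params.e_k, noise.v_e, params.c_m,
                    params.model == "gc",
                )
                if not ok:
                    raise FloatingPointError(
                        "membrane potential diverged (non-finite V); reduce dt"
                    )
                if n_spk:
                    idx = spk[:n_spk].copy()
                    _c.handle_spike(state, params, t, idx)
                    plateau[idx] = True
                    if adj is not None:
                        units, delays = _outgoing(adj, idx)
                        if units is not None and units.size:
                            _schedule(ring, k + 1, units, delays)
        else:
            if cfg.ahp_form == "multiplicative":
                for state, params in ((gc, gc_p), (goc, goc_p)):
                    z, x = state.z_ahp, state.x_ahp
                    z += dt * ((1.0 - z) * x - z / params.tau_ahp)
                    np.maximum(z, 0.0, out=z)
                    np.minimum(z, 1.0, out=z)
                    x *= x_decay
            else:
                _c.step_ahp(gc, gc_p, dt, form=cfg.ahp_form)
                _c.step_ahp(goc, goc_p, dt, form=cfg.ahp_form)
            for state, params, plateau, i_syn, ig, adj, n_pop in (
                (gc, gc_p, gc_plateau, i_gc, 0.0, gc_adj, counts.n_gc),
                (goc, goc_p, goc_plateau, i_goc, i_gap, goc_adj, counts.n_goc),
            ):
                ending = plateau & (t >= state.plateau_until - 1e-9)
                if ending.any():
                    _c.end_plateau(state, params, np.nonzero(ending)[0])
                    plateau[ending] = False
                active = ~plateau
                _c.step_membrane(state, params, i_syn, ig, dt, noise, active=active)
                eligible = active & (t >= state.refract_until - 1e-9)
                spiking = eligible & (state.v >= state.v_t)
                if spiking.any():
                    idx = np.nonzero(spiking)[0]
                    _c.handle_spike(state, params, t, idx)
                    plateau[idx] = True
                    if adj is not None:
                        units, delays = _outgoing(adj, idx)
                        if units is not None and units.size:
                            _schedule(ring, k + 1, units, delays)
        # 7. mossy-fiber spikes of this step enter the delay queue
        p0, p1 = mf_ptr[k], mf_ptr[k + 1]
        if p1 > p0 and mf_adj is not None:
            units, delays = _outgoing(mf_adj, mf_units[p0:p1])
            if units is not None and units.size:
                _schedule(ring, k, units, delays)
        # 8. optional voltage traces
        if "gc" in rec_v:
            rec_v["gc"][:, k] = gc.v[list(cfg.record_v_gc)]
        if "goc" in rec_v:
            rec_v["goc"][:, k] = goc.v[list(cfg.record_v_goc)]

    def _collect(state, n_units):
        if state.spikes:
            units = np.concatenate([ids for ids, _ in state.spikes])
            times = np.concatenate(
                [np.full(len(ids), tt) for ids, tt in state.spikes]
            )
        else:
            units, times = np.empty(0, dtype=np.int64), np.empty(0)
        return SpikeData.from_arrays(units, times, cfg.duration_ms, n_units=n_units)

    spikes = {
        "gc": _collect(gc, counts.n_gc),
        "goc": _collect(goc, counts.n_goc),
        "mf": mf,
    }
    spikes["gc"].label = "gc"
    spikes["goc"].label = "goc"
    return SimResult(
        spikes=spikes,
        config=cfg,
        trial=trial,
        v_traces=rec_v,
        clamp=clamp,
        times=(np.arange(n_steps) + 1) * dt,
        gap_matrix=gap_g,
    )
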