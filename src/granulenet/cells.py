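"""Single-neuron dynamics of the granular-layer model.

Two integrate-and-fire variants are used:

* Granule cells (GCs): a nonlinear-leak integrate-and-fire neuron whose leak
  current is multiplicatively suppressed above rest,
  ``-g_L (V - E_L) exp(-(V - E_L) / 5 mV)``.
* Golgi cells (GoCs): an exponential integrate-and-fire neuron with slope
  factor ``delta_T = 3 mV`` and an additional gap-junction current.

Both carry a spike-triggered afterhyperpolarization (AHP) conductance gated
by a variable ``z_AHP`` driven by a fast-decaying resource ``x_AHP`` (unit
increment at the end of each spike plateau), and an Ornstein-Uhlenbeck
background conductance ``g_N`` modelling ongoing synaptic bombardment.

All state containers are vectorized: a :class:`CellState` holds one numpy
array entry per cell, so a "single cell" is simply a population of one.
Voltages are in mV, conductances in nS, currents in pA, times in ms.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "CellParams",
    "NoiseParams",
    "CellState",
    "gc_params",
    "goc_params",
    "default_noise",
    "load_cell_params",
    "draw_cells",
    "membrane_drift",
    "step_membrane",
    "handle_spike",
    "end_plateau",
    "step_ahp",
    "step_ou_noise",
]

#: clamp for exponent arguments, prevents overflow on wildly out-of-range V
_EXP_CLIP = 30.0


@dataclass(frozen=True)
class CellParams:
    """Membrane constants of one cell population."""

    model: str            # "gc" (nonlinear leak) or "goc" (exponential IF)
    c_m: float            # pF
    g_l: float            # nS
    e_l: float            # mV
    v_t_mean: float       # mV
    v_t_sd: float         # mV
    v_rest: float         # mV, post-plateau reset
    g_ahp: float          # nS
    e_k: float            # mV
    tau_ahp: float        # ms
    tau_dur: float        # ms, spike plateau duration
    tau_ahpx: float = 1.0  # ms, AHP resource decay
    t_ref: float = 2.0    # ms
    v_plateau: float = 40.0  # mV
    delta_t: float | None = None      # mV, EIF slope (GoC)
    leak_shape: float | None = None   # mV, nonlinear-leak scale (GC)
    # Sign convention for the GoC spike-initiation current: the standard EIF
    # form drives V upward (inward current).  The literal subtracted form is
    # available for comparison.
    eif_depolarizing: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("gc", "goc"):
            raise ValueError(f"unknown cell model {self.model!r}")
        for name in ("c_m", "g_l", "g_ahp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_ahp", "tau_ahpx", "tau_dur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")
        if self.v_rest > self.v_t_mean:
            raise ValueError("v_rest must not exceed v_t_mean")
        if self.model == "goc" and (self.delta_t is None or self.delta_t <= 0):
            raise ValueError("GoC model requires delta_t > 0")
        if self.model == "gc" and (self.leak_shape is None or self.leak_shape <= 0):
            raise ValueError("GC model requires leak_shape > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Ornstein-Uhlenbeck background conductance parameters."""

    sigma_n: float = 0.12   # nS, sets stationary SD sigma_n / sqrt(2)
    tau_n: float = 1000.0   # ms
    v_e: float = 0.0        # mV, reversal of the noise current

    def __post_init__(self) -> None:
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        if self.tau_n <= 0:
            raise ValueError("tau_n must be > 0")


@dataclass
class CellState:
    """Dynamic variables of a population, one array entry per cell."""

    v: np.ndarray                 # mV
    v_t: np.ndarray               # mV, per-cell drawn threshold
    z_ahp: np.ndarray             # gating in [0, 1]
    x_ahp: np.ndarray             # resource >= 0
    g_n: np.ndarray               # nS, OU noise conductance
    plateau_until: np.ndarray     # ms, spike plateau end time
    refract_until: np.ndarray     # ms, refractory end time
    spikes: list = field(default_factory=list)  # recorded (cell_ids, t) pairs

    @property
    def n(self) -> int:
        return self.v.shape[0]


@functools.cache
def _load_yaml() -> dict:
    text = resources.files("granulenet.data").joinpath("cell_params.yaml").read_text()
    return yaml.safe_load(text)


def load_cell_params(population: str, **overrides) -> CellParams:
    """Load a population's parameters from the versioned config file."""
    cfg = _load_yaml()
    if population not in ("gc", "goc"):
        raise ValueError(f"unknown population {population!r}")
    row = dict(cfg[population])
    common = cfg["common"]
    kwargs = dict(
        model=row["model"],
        c_m=row["c_m_pf"],
        g_l=row["g_l_ns"],
        e_l=row["e_l_mv"],
        v_t_mean=row["v_t_mean_mv"],
        v_t_sd=row["v_t_sd_mv"],
        v_rest=row["v_rest_mv"],
        g_ahp=row["g_ahp_ns"],
        e_k=row["e_k_mv"],
        tau_ahp=row["tau_ahp_ms"],
        tau_dur=row["tau_dur_ms"],
        tau_ahpx=common["tau_ahpx_ms"],
        t_ref=common["t_ref_ms"],
        v_plateau=common["v_plateau_mv"],
        delta_t=row.get("delta_t_mv"),
        leak_shape=row.get("leak_shape_mv"),
    )
    kwargs.update(overrides)
    return CellParams(**kwargs)


def gc_params(**overrides) -> CellParams:
    return load_cell_params("gc", **overrides)


def goc_params(**overrides) -> CellParams:
    return load_cell_params("goc", **overrides)


def default_noise(**overrides) -> NoiseParams:
    cfg = _load_yaml()["noise"]
    kwargs = dict(sigma_n=cfg["sigma_n_ns"], tau_n=cfg["tau_n_ms"], v_e=cfg["v_e_mv"])
    kwargs.update(overrides)
    return NoiseParams(**kwargs)


def draw_cells(
    params: CellParams,
    n: int,
    rng: np.random.Generator,
    v_init_jitter: float = 0.0,
) -> CellState:
    """Initialize a population of ``n`` cells.

    V starts at the leak reversal E_L (optionally jittered uniformly by up to
    ``v_init_jitter`` mV to desynchronize startup); thresholds are drawn per
    cell from a Gaussian; all gating variables start at zero.
    """
    v = np.full(n, params.e_l)
    if v_init_jitter:
        v = v + rng.uniform(-v_init_jitter, v_init_jitter, size=n)
    return CellState(
        v=v,
        v_t=rng.normal(params.v_t_mean, params.v_t_sd, size=n),
        z_ahp=np.zeros(n),
        x_ahp=np.zeros(n),
        g_n=np.zeros(n),
        plateau_until=np.full(n, -np.inf),
        refract_until=np.full(n, -np.inf),
    )


def membrane_drift(
    state: CellState,
    params: CellParams,
    i_syn: np.ndarray | float = 0.0,
    i_gap: np.ndarray | float = 0.0,
    noise: NoiseParams | None = None,
) -> np.ndarray:
    """dV/dt in mV/ms for every cell, given synaptic and gap currents in pA."""
    v = state.v
    if params.model == "gc":
        arg = np.clip(-(v - params.e_l) / params.leak_shape, -_EXP_CLIP, _EXP_CLIP)
        i_leak = params.g_l * (v - params.e_l) * np.exp(arg)
    else:
        i_leak = params.g_l * (v - params.e_l)
    i_ahp = params.g_ahp * state.z_ahp * (v - params.e_k)
    v_e = noise.v_e if noise is not None else 0.0
    i_noise = (v - v_e) * state.g_n
    total = -i_leak - i_ahp - i_noise - np.asarray(i_syn) - np.asarray(i_gap)
    if params.model == "goc":
        arg = np.clip((v - state.v_t) / params.delta_t, -_EXP_CLIP, _EXP_CLIP)
        i_spike = params.g_l * params.delta_t * np.exp(arg)
        total = total + (i_spike if params.eif_depolarizing else -i_spike)
    return total / params.c_m


def step_membrane(
    state: CellState,
    params: CellParams,
    i_syn: np.ndarray | float,
    i_gap: np.ndarray | float,
    dt: float,
    noise: NoiseParams | None = None,
    active: np.ndarray | None = None,
) -> CellState:
    """Advance V by one forward-Euler step.

    ``active`` masks cells currently integrating (outside a spike plateau);
    plateau cells keep V clamped.  Raises on non-finite V, which signals
    numerical instability (dt too large).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    dv = dt * membrane_drift(state, params, i_syn, i_gap, noise)
    if active is not None:
        dv *= active  # zero the update of plateau-clamped cells
    state.v += dv
    if not np.isfinite(state.v.sum()):
        raise FloatingPointError(
            "membrane potential diverged (non-finite V); reduce dt"
        )
    return state


def handle_spike(
    state: CellState,
    params: CellParams,
    t: float,
    idx: np.ndarray,
) -> CellState:
    """Register threshold crossings of cells ``idx`` at time ``t``.

    V is clamped to the plateau value for ``tau_dur``; the reset, the unit
    increment of x_AHP and the refractory window start at the plateau end
    (see :func:`end_plateau`).
    """
    if len(idx) == 0:
        return state
    state.v[idx] = params.v_plateau
    state.plateau_until[idx] = t + params.tau_dur
    state.refract_until[idx] = t + params.tau_dur + params.t_ref
    state.spikes.append((np.asarray(idx, dtype=np.int64), t))
    return state


def end_plateau(state: CellState, params: CellParams, idx: np.ndarray) -> CellState:
    """Terminate the spike plateau: reset V and add the AHP resource unit."""
    if len(idx) == 0:
        return state
    state.v[idx] = params.v_rest
    state.x_ahp[idx] += 1.0
    return state


def step_ahp(
    state: CellState,
    params: CellParams,
    dt: float,
    form: str = "multiplicative",
    x_floor: float = 1e-6,
) -> CellState:
    """Advance the AHP gating pair (z, x) by one Euler step.

    The default ``multiplicative`` activation law reads
    ``dz/dt = (1 - z) * x / (1 ms) - z / tau_AHP``; the ``literal`` form
    ``dz/dt = (1 - z) / max(x, x_floor) - z / tau_AHP`` is provided for
    comparison (it is singular as x -> 0 and needs the floor).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    z, x = state.z_ahp, state.x_ahp
    if form == "multiplicative":
        dz = (1.0 - z) * x - z / params.tau_ahp
    elif form == "literal":
        dz = (1.0 - z) / np.maximum(x, x_floor) - z / params.tau_ahp
    else:
        raise ValueError(f"unknown AHP form {form!r}")
    dz *= dt
    z += dz
    np.maximum(z, 0.0, out=z)
    np.minimum(z, 1.0, out=z)
    x *= math.exp(-dt / params.tau_ahpx)
    return state


def step_ou_noise(
    state: CellState,
    noise: NoiseParams,
    dt: float,
    rng: np.random.Generator,
) -> CellState:
    """Advance g_N with the exact OU discretization.

    The process ``tau_N dg = -g dt + sigma_N sqrt(tau_N) dW`` has stationary
    SD ``sigma_N / sqrt(2)``; the exact update preserves it for any dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = math.exp(-dt / noise.tau_n)
    sd = noise.sigma_n * math.sqrt((1.0 - a * a) / 2.0)
    g = state.g_n
    g *= a
    if sd > 0:
        g += sd * rng.standard_normal(state.n)
    return state
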