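"""Conductance-based synapse kinetics and Tsodyks-Markram short-term plasticity.

Each receptor channel follows a two-variable gating cascade

    s' = -s / tau_rise + R u * sum_k delta(t - t_spk)
    r' = -r / tau_decay + alpha * s * (1 - r)

and contributes a current ``I = g r Y(V) (V - E_syn)`` where the
voltage-dependent factor Y applies to NMDA receptors only.  Release is scaled
by the short-term-plasticity pair (R, u): depression depletes the resource R,
facilitation transiently raises the utilization u above its baseline U.  With
plasticity disabled the pair is frozen at (1, U), so each presynaptic spike
increments s by exactly U.

State containers are vectorized over synapses (one array entry per synapse);
the same functions serve a single synapse as an array of length one.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ReceptorParams",
    "STPParams",
    "SynapseState",
    "load_synapse_params",
    "receptor_rows",
    "make_synapses",
    "step_gating",
    "on_presynaptic_spike",
    "step_stp",
    "synaptic_current",
    "nmda_gate",
    "sample_delay",
]


@dataclass(frozen=True)
class ReceptorParams:
    """Kinetics of one receptor channel of a projection."""

    name: str
    g_mult: float          # multiplies the projection weight mean W (nS)
    alpha: float           # 1/ms
    tau_rise: float        # ms
    tau_decay: float       # ms
    e_syn: float           # mV
    voltage_dependent: bool = False   # NMDA Mg-block-like factor
    nmda_half: float = 84.0           # mV
    nmda_slope: float = 38.0          # mV

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("tau_rise and tau_decay must be > 0")
        if self.g_mult < 0:
            raise ValueError("g_mult must be >= 0")


@dataclass(frozen=True)
class STPParams:
    """Short-term-plasticity parameters of one receptor channel."""

    u_base: float                    # baseline release fraction U in (0, 1]
    tau_rec: float | None = None     # ms, resource recovery
    tau_fac: float | None = None     # ms, utilization relaxation
    enabled: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.u_base <= 1.0:
            raise ValueError("U must be in (0, 1]")
        if self.enabled and (self.tau_rec is None or self.tau_fac is None):
            raise ValueError("enabled STP requires tau_rec and tau_fac")


@dataclass
class SynapseState:
    """Dynamic variables of a homogeneous group of synapses."""

    r: np.ndarray        # gating in [0, 1]
    s: np.ndarray        # auxiliary rise variable >= 0
    res: np.ndarray      # STP resource R in [0, 1]
    u: np.ndarray        # STP utilization in [0, 1]
    weight: np.ndarray   # nS (already includes the receptor g_mult)
    delay: np.ndarray    # ms

    @property
    def n(self) -> int:
        return self.r.shape[0]


@functools.cache
def _load_yaml() -> dict:
    text = resources.files("granulenet.data").joinpath("synapse_params.yaml").read_text()
    return yaml.safe_load(text)


def load_synapse_params() -> dict:
    """Raw contents of the versioned synapse parameter file."""
    return _load_yaml()


def receptor_rows(
    projection: str,
    stp_enabled: bool = False,
    reversals: dict | None = None,
) -> list[tuple[ReceptorParams, STPParams]]:
    """Receptor/STP parameter pairs for one projection.

    ``stp_enabled`` turns dynamic (R, u) updates on for rows that carry
    recovery/facilitation time constants; rows without them are always static.
    """
    cfg = _load_yaml()
    if projection not in cfg["projections"]:
        raise ValueError(f"unknown projection {projection!r}")
    rev = dict(cfg["reversals"])
    if reversals:
        rev.update(reversals)
    out = []
    for row in cfg["projections"][projection]:
        rp = ReceptorParams(
            name=row["name"],
            g_mult=row["g_mult"],
            alpha=row["alpha"],
            tau_rise=row["tau_rise"],
            tau_decay=row["tau_decay"],
            e_syn=rev[f"{row['receptor']}_mv"],
            voltage_dependent=row["receptor"] == "nmda",
            nmda_half=cfg["nmda_half_mv"],
            nmda_slope=cfg["nmda_slope_mv"],
        )
        has_taus = row["tau_rec"] is not None and row["tau_fac"] is not None
        sp = STPParams(
            u_base=row["U"],
            tau_rec=row["tau_rec"],
            tau_fac=row["tau_fac"],
            enabled=stp_enabled and has_taus,
        )
        out.append((rp, sp))
    return out


def make_synapses(
    weight: np.ndarray,
    delay: np.ndarray,
    stp: STPParams,
) -> SynapseState:
    """Fresh state for a group of synapses at rest: r = s = 0, R = 1, u = U."""
    n = len(weight)
    return SynapseState(
        r=np.zeros(n),
        s=np.zeros(n),
        res=np.ones(n),
        u=np.full(n, stp.u_base),
        weight=np.asarray(weight, dtype=float),
        delay=np.asarray(delay, dtype=float),
    )


def step_gating(syn: SynapseState, rp: ReceptorParams, dt: float) -> SynapseState:
    """Advance (r, s) by one step.

    r integrates ``alpha * s * (1 - r) - r / tau_decay`` with forward Euler;
    the linear decay of s is applied exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    r, s = syn.r, syn.s
    syn.r = np.clip(r + dt * (rp.alpha * s * (1.0 - r) - r / rp.tau_decay), 0.0, 1.0)
    syn.s = s * np.exp(-dt / rp.tau_rise)
    return syn


def on_presynaptic_spike(
    syn: SynapseState,
    stp: STPParams,
    idx: np.ndarray | None = None,
    order: str = "facilitate-first",
) -> SynapseState:
    """Apply one presynaptic spike to synapses ``idx`` (all if None).

    With STP enabled, the event updates follow the Tsodyks-Markram
    convention: facilitate u, release the fraction R*u into s, deplete R.
    The alternative ``release-first`` order is available for sensitivity
    checks.  With STP disabled, (R, u) stay frozen at (1, U) and each spike
    adds exactly U to s; simultaneous deliveries accumulate.
    """
    sl = slice(None) if idx is None else idx
    if not stp.enabled:
        if idx is None:
            syn.s += stp.u_base
        else:
            np.add.at(syn.s, idx, stp.u_base)
        return syn
    if order == "facilitate-first":
        u_new = syn.u[sl] + stp.u_base * (1.0 - syn.u[sl])
        release = syn.res[sl] * u_new
    elif order == "release-first":
        release = syn.res[sl] * syn.u[sl]
        u_new = syn.u[sl] + stp.u_base * (1.0 - syn.u[sl])
    else:
        raise ValueError(f"unknown event order {order!r}")
    syn.u[sl] = u_new
    syn.s[sl] = syn.s[sl] + release
    syn.res[sl] = syn.res[sl] - release
    return syn


def step_stp(syn: SynapseState, stp: STPParams, dt: float) -> SynapseState:
    """Relax R toward 1 (tau_rec) and u toward U (tau_fac), exactly."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not stp.enabled:
        return syn
    syn.res = 1.0 - (1.0 - syn.res) * np.exp(-dt / stp.tau_rec)
    syn.u = stp.u_base + (syn.u - stp.u_base) * np.exp(-dt / stp.tau_fac)
    return syn


def nmda_gate(v: np.ndarray | float, rp: ReceptorParams) -> np.ndarray | float:
    """Voltage-dependent scaling Y(V); identically 1 for non-NMDA receptors."""
    if not rp.voltage_dependent:
        return np.ones_like(np.asarray(v, dtype=float))
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - rp.nmda_half) / rp.nmda_slope))


def synaptic_current(
    syn: SynapseState,
    rp: ReceptorParams,
    v: np.ndarray | float,
) -> np.ndarray:
    """Per-synapse current ``weight * r * Y(V) * (V - E_syn)`` in pA."""
    return syn.weight * syn.r * nmda_gate(v, rp) * (np.asarray(v, dtype=float) - rp.e_syn)


def sample_delay(
    projection: str,
    rng: np.random.Generator,
    n: int = 1,
    mean: float = 1.0,
    sd: float = 0.2,
    dt: float = 0.1,
) -> np.ndarray:
    """Transmission delays in ms, rounded to the dt grid.

    All projections use Gaussian delays (1 +/- 0.2 ms) except GoC->GC, which
    transmits without delay.
    """
    if projection == "goc_gc":
        return np.zeros(n)
    d = rng.normal(mean, sd, size=n)
    d = np.maximum(dt, d)
    return np.round(d / dt) * dt
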