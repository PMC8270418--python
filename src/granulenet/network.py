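"""Network construction: wiring scenarios, random fan-in connectivity, and the
GoC gap-junction layout.

Three inhibition scenarios are supported, named for the pathway through which
Golgi-cell (GoC) inhibition reaches granule cells (GCs):

* ``ffi``  - feedforward only: MF->GoC->GC (no GC->GoC feedback).
* ``fbi``  - feedback only:    MF->GC->GoC->GC (no direct MF->GoC drive).
* ``ffi_fbi`` - both loops present.

Chemical connectivity is random with fixed fan-in (each GC: 4 MFs + 10 GoCs;
each GoC: 10 MFs + 50 GCs, where the projection exists).  Gap junctions
between GoCs live on a jittered 2D grid: each cell is a disk of random radius
and process density, and the coupling conductance is proportional to the
overlap area of the two disks times both densities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synapses import sample_delay

__all__ = [
    "PROJECTIONS",
    "SCENARIOS",
    "Counts",
    "FanIns",
    "Edges",
    "NetworkTopology",
    "GapLayout",
    "build_topology",
    "place_goc_grid",
    "gap_conductances",
    "gap_current",
    "gap_currents",
    "circle_overlap_area",
    "scatter_gc_positions",
    "save_topology",
    "load_topology",
    "save_gap_layout",
    "load_gap_layout",
]

PROJECTIONS = ("mf_gc", "mf_goc", "gc_goc", "goc_gc")

#: projections present in each wiring scenario
SCENARIOS = {
    "ffi": ("mf_gc", "mf_goc", "goc_gc"),
    "fbi": ("mf_gc", "gc_goc", "goc_gc"),
    "ffi_fbi": ("mf_gc", "mf_goc", "gc_goc", "goc_gc"),
}

#: (source, target) populations of each projection
_ENDPOINTS = {
    "mf_gc": ("mf", "gc"),
    "mf_goc": ("mf", "goc"),
    "gc_goc": ("gc", "goc"),
    "goc_gc": ("goc", "gc"),
}

DEFAULT_WEIGHTS = {"mf_gc": 3.0, "mf_goc": 3.0, "gc_goc": 3.0, "goc_gc": 4.0}
#: GoC->GC mean used when gap junctions add their own inhibition
GAP_GOC_GC_WEIGHT = 2.5


@dataclass(frozen=True)
class Counts:
    n_mf: int = 500
    n_gc: int = 2000
    n_goc: int = 144

    def of(self, pop: str) -> int:
        return {"mf": self.n_mf, "gc": self.n_gc, "goc": self.n_goc}[pop]


@dataclass(frozen=True)
class FanIns:
    gc_from_mf: int = 4
    gc_from_goc: int = 10
    goc_from_mf: int = 10
    goc_from_gc: int = 50

    def of(self, projection: str) -> int:
        return {
            "mf_gc": self.gc_from_mf,
            "goc_gc": self.gc_from_goc,
            "mf_goc": self.goc_from_mf,
            "gc_goc": self.goc_from_gc,
        }[projection]


@dataclass
class Edges:
    """Directed edge list of one projection."""

    pre: np.ndarray      # source indices
    post: np.ndarray     # target indices
    weight: np.ndarray   # nS, projection weight W per synapse
    delay: np.ndarray    # ms

    @property
    def n(self) -> int:
        return self.pre.shape[0]


@dataclass
class NetworkTopology:
    scenario: str
    counts: Counts
    edges: dict[str, Edges]
    weight_means: dict[str, float]
    seed: int | None = None


@dataclass
class GapLayout:
    positions: np.ndarray    # (n, 2) um
    radii: np.ndarray        # um
    densities: np.ndarray    # dimensionless
    conductance: np.ndarray | None = None  # (n, n) nS, symmetric, zero diagonal
    # GC somata scattered uniformly over the domain; chemical connectivity is
    # distance-independent, so these are for visualization only
    gc_positions: np.ndarray | None = None


def _sample_weights(
    mean: float,
    n: int,
    rng: np.random.Generator,
    variance_frac: float = 0.1,
) -> np.ndarray:
    """Per-synapse weights: Gaussian around the projection mean with variance
    proportional to the mean (default 0.1 * mean nS^2), truncated at 0."""
    if mean == 0:
        return np.zeros(n)
    w = rng.normal(mean, np.sqrt(variance_frac * mean), size=n)
    return np.maximum(w, 0.0)


def build_topology(
    scenario: str,
    counts: Counts = Counts(),
    fan_ins: FanIns = FanIns(),
    weight_means: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    dt: float = 0.1,
    weight_variance_frac: float = 0.1,
    seed: int | None = None,
) -> NetworkTopology:
    """Random fixed-fan-in topology for one wiring scenario.

    For every postsynaptic cell the stated number of presynaptic partners is
    sampled without replacement, so in-degree histograms are delta functions.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    means = dict(DEFAULT_WEIGHTS)
    if weight_means:
        means.update(weight_means)
    edges: dict[str, Edges] = {}
    for proj in SCENARIOS[scenario]:
        src, dst = _ENDPOINTS[proj]
        n_src, n_dst = counts.of(src), counts.of(dst)
        k = fan_ins.of(proj)
        if k > n_src:
            raise ValueError(
                f"fan-in {k} for {proj} exceeds source population size {n_src}"
            )
        pre = np.empty(n_dst * k, dtype=np.int64)
        for j in range(n_dst):
            pre[j * k:(j + 1) * k] = rng.choice(n_src, size=k, replace=False)
        post = np.repeat(np.arange(n_dst, dtype=np.int64), k)
        edges[proj] = Edges(
            pre=pre,
            post=post,
            weight=_sample_weights(means[proj], n_dst * k, rng, weight_variance_frac),
            delay=sample_delay(proj, rng, n=n_dst * k, dt=dt),
        )
    return NetworkTopology(
        scenario=scenario, counts=counts, edges=edges, weight_means=means, seed=seed
    )


def place_goc_grid(
    rng: np.random.Generator,
    n_side: int = 12,
    spacing: float = 33.0,
    jitter_frac: float = 0.25,
    radius: float = 70.0,
    scatter: float = 0.3,
) -> GapLayout:
    """GoC somata on an ``n_side x n_side`` grid with uniform positional jitter.

    Radii and process densities are drawn uniformly in ``[1-scatter,
    1+scatter]`` times their nominal values (0.7-1.3x by default).
    """
    g = np.arange(n_side) * spacing
    xx, yy = np.meshgrid(g, g, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    pos += rng.uniform(-jitter_frac * spacing, jitter_frac * spacing, size=pos.shape)
    n = n_side * n_side
    radii = radius * rng.uniform(1.0 - scatter, 1.0 + scatter, size=n)
    densities = rng.uniform(1.0 - scatter, 1.0 + scatter, size=n)
    return GapLayout(positions=pos, radii=radii, densities=densities)


def scatter_gc_positions(
    layout: GapLayout, n_gc: int, rng: np.random.Generator
) -> GapLayout:
    """Scatter GC somata uniformly over the grid domain (visualization only)."""
    lo = layout.positions.min()
    hi = layout.positions.max()
    layout.gc_positions = rng.uniform(lo, hi, size=(n_gc, 2))
    return layout


def save_gap_layout(layout: GapLayout, path: str | Path) -> None:
    """Positions/radii/densities as CSV plus a dense conductance matrix."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "x_um": layout.positions[:, 0],
            "y_um": layout.positions[:, 1],
            "radius_um": layout.radii,
            "density": layout.densities,
        }
    )
    df.to_csv(path, index=False)
    if layout.conductance is not None:
        np.savetxt(path.with_suffix(".matrix.csv"), layout.conductance,
                   delimiter=",")


def load_gap_layout(path: str | Path) -> GapLayout:
    path = Path(path)
    df = pd.read_csv(path)
    layout = GapLayout(
        positions=df[["x_um", "y_um"]].to_numpy(float),
        radii=df["radius_um"].to_numpy(float),
        densities=df["density"].to_numpy(float),
    )
    mat = path.with_suffix(".matrix.csv")
    if mat.exists():
        layout.conductance = np.loadtxt(mat, delimiter=",")
    return layout


def circle_overlap_area(d: np.ndarray, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Lens area of two overlapping disks at center distance ``d``."""
    d = np.asarray(d, dtype=float)
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), d.shape)
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), d.shape)
    rmin, rmax = np.minimum(r1, r2), np.maximum(r1, r2)
    area = np.zeros_like(d)
    contained = d <= rmax - rmin
    area[contained] = np.pi * rmin[contained] ** 2
    partial = (~contained) & (d < r1 + r2)
    if np.any(partial):
        dp, a, b = d[partial], r1[partial], r2[partial]
        # standard circular-segment decomposition
        d1 = (dp**2 + a**2 - b**2) / (2 * dp)
        d2 = dp - d1
        seg1 = a**2 * np.arccos(np.clip(d1 / a, -1, 1)) - d1 * np.sqrt(
            np.maximum(a**2 - d1**2, 0.0)
        )
        seg2 = b**2 * np.arccos(np.clip(d2 / b, -1, 1)) - d2 * np.sqrt(
            np.maximum(b**2 - d2**2, 0.0)
        )
        area[partial] = seg1 + seg2
    return area


def gap_conductances(
    layout: GapLayout,
    g_scale: float | None = None,
    target_cell_total: float = 1.0,
    rng: np.random.Generator | None = None,
) -> GapLayout:
    """Fill the symmetric gap-conductance matrix of a placed layout.

    ``G_ij = g_scale * overlap_area(i, j) * d_i * d_j`` for overlapping disk
    pairs.  When ``g_scale`` is None it is calibrated so the mean summed gap
    conductance per cell equals ``target_cell_total`` nS (default 1 nS, the
    GoC leak conductance).  With the disk-overlap layout every cell couples
    to ~30-40 partners, so calibrating the per-cell total — rather than the
    per-pair mean — keeps individual junctions weak (tens of pS, coupling
    coefficients of a few percent, as measured between Golgi cells) while
    the population-level electrical coupling stays strong enough to
    synchronize.  Absolute junctional values are not printed in the model
    description; they come from prior experimental work.
    """
    pos, radii, dens = layout.positions, layout.radii, layout.densities
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    area = circle_overlap_area(dist, radii[:, None], radii[None, :])
    raw = area * dens[:, None] * dens[None, :]
    np.fill_diagonal(raw, 0.0)
    raw = 0.5 * (raw + raw.T)
    if g_scale is None:
        mean_total = raw.sum(axis=1).mean()
        g_scale = target_cell_total / mean_total if mean_total > 0 else 0.0
    layout.conductance = g_scale * raw
    return layout


def gap_currents(v: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Gap current into every cell: ``I_i = sum_j g_ij (V_i - V_j)`` in pA."""
    return v * g.sum(axis=1) - g @ v


def gap_current(i: int, v: np.ndarray, g: np.ndarray) -> float:
    """Gap current into cell ``i`` (pA)."""
    return float(np.sum(g[i] * (v[i] - v)))


def save_topology(topo: NetworkTopology, path: str | Path) -> None:
    """Write an edge-list CSV plus a JSON header next to it."""
    path = Path(path)
    rows = []
    for proj, e in topo.edges.items():
        rows.append(
            pd.DataFrame(
                {
                    "projection": proj,
                    "pre": e.pre,
                    "post": e.post,
                    "weight_ns": e.weight,
                    "delay_ms": e.delay,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    header = {
        "scenario": topo.scenario,
        "counts": {"n_mf": topo.counts.n_mf, "n_gc": topo.counts.n_gc, "n_goc": topo.counts.n_goc},
        "weight_means": topo.weight_means,
        "seed": topo.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def load_topology(path: str | Path) -> NetworkTopology:
    path = Path(path)
    df = pd.read_csv(path)
    header = json.loads(path.with_suffix(".json").read_text())
    edges = {}
    for proj, sub in df.groupby("projection"):
        edges[proj] = Edges(
            pre=sub["pre"].to_numpy(np.int64),
            post=sub["post"].to_numpy(np.int64),
            weight=sub["weight_ns"].to_numpy(float),
            delay=sub["delay_ms"].to_numpy(float),
        )
    return NetworkTopology(
        scenario=header["scenario"],
        counts=Counts(**header["counts"]),
        edges=edges,
        weight_means=header["weight_means"],
        seed=header["seed"],
    )
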