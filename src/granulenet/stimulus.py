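"""Mossy-fiber drive: independent homogeneous Poisson spike trains.

Spike containers and the plain-text raster format (two whitespace-separated
columns: ``unit_id  time_ms``) are shared with the simulated GC/GoC output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpikeData", "poisson_trains", "save_raster", "load_raster"]


@dataclass
class SpikeData:
    """Per-unit spike times of one population."""

    trains: dict[int, np.ndarray]   # unit id -> sorted spike times (ms)
    duration: float                 # ms
    label: str = ""

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(len(t) for t in self.trains.values())

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (unit, time) arrays sorted by time."""
        if not self.trains:
            return np.empty(0, dtype=np.int64), np.empty(0)
        units = np.concatenate(
            [np.full(len(t), u, dtype=np.int64) for u, t in self.trains.items()]
        )
        times = np.concatenate(list(self.trains.values()))
        order = np.argsort(times, kind="stable")
        return units[order], times[order]

    @classmethod
    def from_arrays(
        cls, units: np.ndarray, times: np.ndarray, duration: float,
        n_units: int | None = None, label: str = "",
    ) -> "SpikeData":
        trains: dict[int, np.ndarray] = {}
        units = np.asarray(units, dtype=np.int64)
        times = np.asarray(times, dtype=float)
        order = np.lexsort((times, units))
        units, times = units[order], times[order]
        bounds = np.searchsorted(units, np.arange(0, units.max() + 2 if len(units) else 1))
        ids = range(n_units) if n_units is not None else np.unique(units)
        for u in ids:
            if len(units) and u <= units.max():
                trains[int(u)] = times[bounds[u]:bounds[u + 1]].copy()
            else:
                trains[int(u)] = np.empty(0)
        return cls(trains=trains, duration=duration, label=label)


def poisson_trains(
    n_units: int,
    rate_hz: float,
    duration_ms: float,
    rng: np.random.Generator,
    label: str = "mf",
) -> SpikeData:
    """Independent homogeneous Poisson trains (exponential inter-spike
    intervals), one per unit, over ``[0, duration_ms)``."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    trains: dict[int, np.ndarray] = {}
    if rate_hz == 0:
        for u in range(n_units):
            trains[u] = np.empty(0)
        return SpikeData(trains=trains, duration=duration_ms, label=label)
    mean_isi = 1000.0 / rate_hz
    # draw with margin, then extend the rare short train
    n_guess = int(duration_ms / mean_isi + 6 * np.sqrt(duration_ms / mean_isi) + 10)
    for u in range(n_units):
        t = np.cumsum(rng.exponential(mean_isi, size=n_guess))
        while len(t) and t[-1] < duration_ms:
            t = np.concatenate([t, t[-1] + np.cumsum(rng.exponential(mean_isi, size=n_guess))])
        trains[u] = t[t < duration_ms]
    return SpikeData(trains=trains, duration=duration_ms, label=label)


def save_raster(spikes: SpikeData, path: str | Path) -> None:
    units, times = spikes.to_arrays()
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={spikes.duration} n_units={spikes.n_units} label={spikes.label}\n")
        for u, t in zip(units, times):
            fh.write(f"{u}\t{t:.4f}\n")


def load_raster(path: str | Path) -> SpikeData:
    path = Path(path)
    duration, n_units, label = None, None, ""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        fields = dict(kv.split("=") for kv in first[1:].split())
        duration = float(fields.get("duration_ms", "nan"))
        n_units = int(fields.get("n_units", "0")) or None
        label = fields.get("label", "")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        units, times = np.empty(0, dtype=np.int64), np.empty(0)
    else:
        units, times = data[:, 0].astype(np.int64), data[:, 1]
    if duration is None or np.isnan(duration):
        duration = float(times.max()) + 1.0 if len(times) else 0.0
    return SpikeData.from_arrays(units, times, duration, n_units=n_units, label=label)
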