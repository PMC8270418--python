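"""Synthetic test signals and rasters with known ground truth.

These generators provide the analysis/CFC test surface: pure tones, white
noise, amplitude-modulated tones with a constructed phase-amplitude coupling,
and perfectly periodic or Poisson spike rasters.
"""

from __future__ import annotations

import numpy as np

from .stimulus import SpikeData, poisson_trains

__all__ = [
    "tone",
    "white_noise",
    "am_coupled",
    "periodic_raster",
    "poisson_raster",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("tone", "am_coupled", "noise", "periodic_raster", "poisson_raster")


def _times(duration_ms: float, fs: float) -> np.ndarray:
    n = int(round(duration_ms * fs / 1000.0))
    return np.arange(n) / fs  # seconds


def tone(
    freq_hz: float,
    duration_ms: float = 10000.0,
    fs: float = 500.0,
    amplitude: float = 1.0,
    offset: float = 0.0,
) -> np.ndarray:
    """Pure cosine ``offset + A cos(2 pi f t)`` sampled at fs."""
    t = _times(duration_ms, fs)
    return offset + amplitude * np.cos(2 * np.pi * freq_hz * t)


def white_noise(
    duration_ms: float = 10000.0,
    fs: float = 500.0,
    sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(duration_ms * fs / 1000.0))
    return sd * rng.standard_normal(n)


def am_coupled(
    f_phase: float = 8.0,
    f_amp: float = 80.0,
    duration_ms: float = 10000.0,
    fs: float = 500.0,
    depth: float = 0.5,
    noise_sd: float = 0.0,
    invert_modulator: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Amplitude-modulated tone with known phase-amplitude coupling.

    The fast carrier at ``f_amp`` is modulated by ``1 + depth*cos(2 pi
    f_phase t)``; the slow modulator is also added to the signal so the
    phase-band component exists.  The resulting ESC map peaks at
    (f_phase, f_amp) with positive sign.  ``invert_modulator`` flips the
    sign of the amplitude modulation only (the additive slow component is
    unchanged), producing a negative ESC of the same magnitude.
    """
    t = _times(duration_ms, fs)
    sign = -1.0 if invert_modulator else 1.0
    slow = np.cos(2 * np.pi * f_phase * t)
    carrier = np.cos(2 * np.pi * f_amp * t)
    x = slow + (1.0 + sign * depth * slow) * carrier
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        x = x + noise_sd * rng.standard_normal(len(t))
    return x


def periodic_raster(
    period_ms: float = 25.0,
    n_units: int = 100,
    duration_ms: float = 10000.0,
    jitter_ms: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SpikeData:
    """Units firing in perfect synchrony every ``period_ms`` (optional jitter)."""
    base = np.arange(period_ms, duration_ms, period_ms)
    trains = {}
    for u in range(n_units):
        t = base.copy()
        if jitter_ms > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            t = np.sort(t + rng.normal(0, jitter_ms, size=len(t)))
            t = t[(t >= 0) & (t < duration_ms)]
        trains[u] = t
    return SpikeData(trains=trains, duration=duration_ms, label="periodic")


def poisson_raster(
    rate_hz: float = 25.0,
    n_units: int = 100,
    duration_ms: float = 10000.0,
    rng: np.random.Generator | None = None,
) -> SpikeData:
    if rng is None:
        rng = np.random.default_rng(0)
    return poisson_trains(n_units, rate_hz, duration_ms, rng, label="poisson")
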