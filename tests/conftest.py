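"""Shared fixtures and independent numerical oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def rk4(f, y0, t0, t1, dt):
    """Classic fixed-step Runge-Kutta 4 integrator.

    ``f(t, y) -> dy/dt`` with y a numpy vector; returns (times, trajectory).
    Used as the independent oracle for the forward-Euler production paths.
    """
    n = int(round((t1 - t0) / dt))
    ys = np.empty((n + 1, len(np.atleast_1d(y0))))
    ys[0] = y0
    ts = t0 + dt * np.arange(n + 1)
    y = np.array(y0, dtype=float)
    for i in range(n):
        t = ts[i]
        k1 = np.asarray(f(t, y))
        k2 = np.asarray(f(t + dt / 2, y + dt / 2 * k1))
        k3 = np.asarray(f(t + dt / 2, y + dt / 2 * k2))
        k4 = np.asarray(f(t + dt, y + dt * k3))
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ys[i + 1] = y
    return ts, ys


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_fbi_result():
    """One short desk-scale feedback-inhibition run, shared across tests."""
    import granulenet as gn

    cfg = gn.RunConfig(
        scenario="fbi", counts=gn.desk_counts(), duration_ms=3000.0, seed=7
    )
    return gn.run(cfg)[0]
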