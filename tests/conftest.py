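"""Shared fixtures: small pilot-established retrieval runs and helpers."""

from dataclasses import replace

import numpy as np
import pytest

import phasemem as pm
from phasemem.dynamics import SOURCE_NET


def make_pattern_train(pattern, period_ms, t_start, t_end, n_units=None):
    """Phase-perfect periodic spike train replaying ``pattern`` at any period."""
    n_units = n_units or pattern.n_units
    times, units = [], []
    for u in range(pattern.n_units):
        t0 = pattern.phases[u] / (2 * np.pi) * period_ms
        n_lo = int(np.ceil((t_start - t0) / period_ms))
        n_hi = int(np.ceil((t_end - t0) / period_ms))
        t = t0 + period_ms * np.arange(n_lo, n_hi)
        times.append(t)
        units.append(np.full(t.size, u))
    times = np.concatenate(times)
    units = np.concatenate(units)
    order = np.argsort(times, kind="stable")
    return pm.SpikeTrain(
        times=times[order],
        units=units[order],
        sources=np.full(times.size, SOURCE_NET, dtype=np.int8),
        n_units=n_units,
        duration=t_end,
    )


@pytest.fixture(scope="session")
def toy_protocol():
    # pilot-established small-network conditions: the retrieval region shrinks
    # at N=100, so the cue must recruit 30% of the units
    return replace(pm.DESK_PROTOCOL, n_runs=1, cue_fraction=0.3)


@pytest.fixture(scope="session")
def toy_retrieval(toy_protocol):
    """N=100 single-pattern retrieval run (theta=0.5, seed=7, overlap ~0.91)."""
    patterns = pm.generate_pattern_set(1, 100, 3.0, seed=7)
    J = pm.build_connectivity(patterns)
    result, train = pm.cued_trial(patterns, 0.5, toy_protocol, seed=7, J=J)
    return {
        "patterns": patterns,
        "J": J,
        "theta": 0.5,
        "seed": 7,
        "result": result,
        "train": train,
    }
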