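"""Scoring of simulated activity against stored phase patterns.

The central statistic is the overlap order parameter

    |m^mu(t)| = | (1/N) sum_j exp(-i 2 pi t_j*/T*) exp(i phi_j^mu) |,

where ``t_j*`` is unit j's most recent spike in the window ``(t - T*, t]`` and
``T*`` estimates the period of the collective dynamics.  The overlap is 1 for
a perfect phase-aligned replay (at *any* time scale — it is invariant under
uniform compression or dilation of the spike train) and of order
``1/sqrt(N)`` for activity uncorrelated with the stored phases.

A run is classified as ``retrieval`` (persistent activity, overlap with some
stored pattern above a similarity threshold), ``spurious`` (persistent but
uncorrelated with every stored pattern) or ``silent`` (no self-sustained
activity after the transient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SOURCE_CUE, SpikeTrain
from .patterns import TWO_PI, PhasePattern

#: Overlap above which a run counts as retrieval.  The classification is
#: robust to this value because steady-state overlaps cluster near 1
#: (success) or near 1/sqrt(N) (failure).
SIMILARITY_THRESHOLD = 0.5

#: Default steady-state onset: scoring starts here unless overridden.
T_BAR_MS = 600.0


class NoPeriodError(RuntimeError):
    """Raised when no period can be estimated (silent or near-silent window)."""


@dataclass
class OverlapSeries:
    """Overlap trajectories |m^mu(t)| for every stored pattern.

    ``overlaps[k]`` corresponds to ``pattern_ids[k]`` and has one value per
    entry of ``eval_times``.  ``period_estimate`` is absent for silent runs.
    """

    eval_times: np.ndarray
    pattern_ids: list[int]
    overlaps: np.ndarray = field(repr=False)  # (n_patterns, n_times)
    period_estimate: float | None = None

    def for_pattern(self, pattern_id: int) -> np.ndarray:
        return self.overlaps[self.pattern_ids.index(pattern_id)]


@dataclass
class RetrievalResult:
    """Summary of one cued run."""

    regime: str  # "retrieval" | "spurious" | "silent"
    retrieved_pattern: int | None
    replay_frequency_hz: float | None
    spikes_per_cycle: float | None
    s_tot: int
    mean_overlaps: dict[int, float] = field(default_factory=dict)


def estimate_period(
    train: SpikeTrain,
    window: tuple[float, float],
    method: str = "median-isi",
    pattern: PhasePattern | None = None,
    t_grid: np.ndarray | None = None,
) -> float:
    """Estimate the period T* (ms) of the collective dynamics in a window.

    ``median-isi`` (default): median inter-spike interval over all units with
    at least two spikes in the window — exact for clean one-spike-per-cycle
    replay.  ``maximize-overlap``: grid search for the T* that maximises the
    overlap with ``pattern`` at the window end (default grid 5–500 ms, 1 ms
    step); usable on non-periodic trains.
    """
    t0, t1 = window
    sub = train.in_window(t0, t1)
    if method == "median-isi":
        if len(sub) < 2:
            raise NoPeriodError(f"fewer than 2 spikes in window ({t0}, {t1})")
        isis = []
        order = np.lexsort((sub.times, sub.units))
        units = sub.units[order]
        times = sub.times[order]
        same = units[1:] == units[:-1]
        isis = (times[1:] - times[:-1])[same]
        if isis.size == 0:
            raise NoPeriodError("no unit spiked twice in the window")
        return float(np.median(isis))
    if method == "maximize-overlap":
        if pattern is None:
            raise ValueError("maximize-overlap requires a pattern")
        if len(sub) == 0:
            raise NoPeriodError(f"no spikes in window ({t0}, {t1})")
        if t_grid is None:
            t_grid = np.arange(5.0, 500.0 + 0.5, 1.0)
        vals = [overlap(train, pattern, T, t1) for T in t_grid]
        return float(t_grid[int(np.argmax(vals))])
    raise ValueError(f"unknown method {method!r}")


def overlap(
    train: SpikeTrain,
    pattern: PhasePattern,
    T_star: float,
    t: float,
) -> float:
    """Overlap |m^mu(t)| in [0, 1] against one stored pattern.

    Uses each unit's most recent spike in ``(t - T_star, t]``; units without
    a spike there contribute zero, and the prefactor is always 1/N.
    """
    if not T_star > 0:
        raise ValueError("T_star must be positive")
    lo = np.searchsorted(train.times, t - T_star, side="right")
    hi = np.searchsorted(train.times, t, side="right")
    if hi == lo:
        return 0.0
    units = train.units[lo:hi]
    times = train.times[lo:hi]
    # keep the last (most recent) spike of each unit in the window
    last_idx = np.full(train.n_units, -1, dtype=np.int64)
    last_idx[units] = np.arange(units.size)  # later entries overwrite earlier
    sel = last_idx[last_idx >= 0]
    z = np.exp(1j * (pattern.phases[units[sel]] - TWO_PI * times[sel] / T_star))
    return float(np.abs(z.sum()) / train.n_units)


def overlap_series(
    train: SpikeTrain,
    patterns: list[PhasePattern],
    window: tuple[float, float],
    T_star: float | None = None,
    cadence: float | None = None,
) -> OverlapSeries:
    """Overlap trajectories for all stored patterns across a window.

    ``T_star`` defaults to the median-ISI estimate on the window (``None``
    period and empty series if the window is silent).  Evaluation cadence
    defaults to T*/2.
    """
    if T_star is None:
        try:
            T_star = estimate_period(train, window)
        except NoPeriodError:
            return OverlapSeries(
                eval_times=np.empty(0),
                pattern_ids=[p.pattern_id for p in patterns],
                overlaps=np.zeros((len(patterns), 0)),
                period_estimate=None,
            )
    if cadence is None:
        cadence = T_star / 2.0
    t0, t1 = window
    eval_times = np.arange(t0 + T_star, t1 + 1e-9, cadence)
    out = np.empty((len(patterns), eval_times.size))
    for k, p in enumerate(patterns):
        out[k] = [overlap(train, p, T_star, t) for t in eval_times]
    return OverlapSeries(
        eval_times=eval_times,
        pattern_ids=[p.pattern_id for p in patterns],
        overlaps=out,
        period_estimate=float(T_star),
    )


def replay_frequency(
    train: SpikeTrain,
    window: tuple[float, float],
    **kwargs,
) -> float:
    """Collective oscillation frequency 1000/T* (Hz) in the window."""
    return 1000.0 / estimate_period(train, window, **kwargs)


def spikes_per_cycle(
    train: SpikeTrain,
    T_star: float,
    window: tuple[float, float],
) -> float:
    """Mean spikes per collective cycle over units active in the window."""
    if not T_star > 0:
        raise ValueError("T_star must be positive")
    t0, t1 = window
    sub = train.in_window(t0, t1)
    if len(sub) == 0:
        raise NoPeriodError("no spikes in the window")
    counts = np.bincount(sub.units, minlength=train.n_units)
    active = counts[counts > 0]
    return float(active.mean() / ((t1 - t0) / T_star))


def response_size(train: SpikeTrain, t_cue_end: float) -> int:
    """Number of non-cue spikes after the cue window (the response size)."""
    mask = (train.times > t_cue_end) & (train.sources != SOURCE_CUE)
    return int(mask.sum())


def classify_regime(
    train: SpikeTrain,
    overlaps: OverlapSeries,
    t_bar: float = T_BAR_MS,
    threshold: float = SIMILARITY_THRESHOLD,
    t_cue_end: float | None = None,
) -> RetrievalResult:
    """Label a cued run as retrieval, spurious or silent.

    Silent: no network-source spikes after ``t_bar``.  Retrieval: the largest
    steady-state mean overlap (over eval times > ``t_bar``) exceeds
    ``threshold``; the maximising pattern is the retrieved one.  Spurious:
    persistent activity with all overlaps at or below ``threshold``.
    """
    if t_cue_end is None:
        cue_times = train.times[train.sources == SOURCE_CUE]
        t_cue_end = float(cue_times.max()) if cue_times.size else 0.0
    s_tot = response_size(train, t_cue_end)
    net_after = (train.times > t_bar) & (train.sources != SOURCE_CUE)
    if not net_after.any():
        return RetrievalResult(
            regime="silent",
            retrieved_pattern=None,
            replay_frequency_hz=None,
            spikes_per_cycle=None,
            s_tot=s_tot,
        )
    late = overlaps.eval_times > t_bar
    if overlaps.eval_times.size and late.any():
        means = {
            mu: float(overlaps.for_pattern(mu)[late].mean())
            for mu in overlaps.pattern_ids
        }
    else:
        means = {mu: 0.0 for mu in overlaps.pattern_ids}
    best = max(means, key=means.get) if means else None
    freq = (
        1000.0 / overlaps.period_estimate
        if overlaps.period_estimate
        else None
    )
    spc = None
    if overlaps.period_estimate:
        try:
            spc = spikes_per_cycle(
                train, overlaps.period_estimate, (t_bar, train.duration)
            )
        except NoPeriodError:
            spc = None
    if best is not None and means[best] > threshold:
        return RetrievalResult(
            regime="retrieval",
            retrieved_pattern=best,
            replay_frequency_hz=freq,
            spikes_per_cycle=spc,
            s_tot=s_tot,
            mean_overlaps=means,
        )
    return RetrievalResult(
        regime="spurious",
        retrieved_pattern=None,
        replay_frequency_hz=freq,
        spikes_per_cycle=spc,
        s_tot=s_tot,
        mean_overlaps=means,
    )
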