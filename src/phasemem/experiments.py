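"""Experiment protocols: retrieval testing, storage capacity, parameter sweeps.

The success criterion throughout is the one used for the capacity analysis:
cue the first stored pattern with ``M = N * cue_fraction`` spikes, simulate,
and average the overlap ``|m^1(t)|`` over the steady-state window
``t > t_bar`` (default 600 ms); retrieval succeeds when the average over
``n_runs`` repetitions exceeds ``success_threshold`` (default 0.5).

Storage capacity ``P_max`` is the largest number of stored patterns for which
that criterion still holds; the success/failure transition in P is sharp, so
an ascending search (with an optional bisection mode) suffices.

Seeding: repetition ``r`` of a protocol run at seed ``s`` uses the derived
seed ``derive_seed(s, ...)`` so any cell of any sweep can be reproduced
exactly in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .analysis import NoPeriodError, classify_regime, overlap_series, response_size
from .dynamics import (
    CueSpec,
    NoiseParams,
    SimulationConfig,
    SpikeTrain,
    heterogeneous_thresholds,
    run,
)
from .patterns import PhasePattern, generate_pattern_set
from .plasticity import STDPWindowParams, SynapticMatrix, build_connectivity

logger = logging.getLogger("phasemem")

_SEED_MOD = 2**31 - 1


def derive_seed(seed: int, *indices: int) -> int:
    """Deterministic child seed for one repetition/cell of a protocol."""
    h = int(seed) % _SEED_MOD
    for ix in indices:
        h = (h * 1_000_003 + int(ix) + 1) % _SEED_MOD
    return h


@dataclass(frozen=True)
class CapacityProtocol:
    """Parameters of the retrieval-success criterion.

    ``n_runs = 50`` mirrors the full-fidelity protocol; the ``desk`` preset
    (5 runs) is for interactive/desk-scale work.
    """

    n_runs: int = 50
    t_bar: float = 600.0
    success_threshold: float = 0.5
    cue_fraction: float = 0.1
    duration: float = 1000.0
    t_stim: float = 50.0
    name: str = "full"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.success_threshold < 1:
            raise ValueError("success_threshold must be in (0, 1)")
        if not 0 <= self.cue_fraction <= 1:
            raise ValueError("cue_fraction must be in [0, 1]")
        if not self.duration > self.t_bar:
            raise ValueError("duration must exceed t_bar")


#: Reduced preset for desk-scale runs (recorded in output metadata).
DESK_PROTOCOL = CapacityProtocol(n_runs=5, name="desk")


@dataclass
class SweepResult:
    """Tidy container for sweep outputs.

    ``axes`` maps axis names to grids; ``tables`` maps quantity names to
    arrays shaped like the grid (or ``(grid, ...)``).  ``metadata`` records
    protocol, seeds and scalar findings (e.g. ``theta_crit``).
    """

    axes: dict[str, np.ndarray]
    tables: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        if len(self.axes) == 1:
            (name, grid), = self.axes.items()
            data = {name: grid}
            for key, tab in self.tables.items():
                tab = np.asarray(tab)
                if tab.shape[:1] == grid.shape:
                    if tab.ndim == 1:
                        data[key] = tab
                    else:
                        for k in range(tab.shape[1]):
                            data[f"{key}_{k}"] = tab[:, k]
            return pd.DataFrame(data)
        names = list(self.axes)
        mesh = np.meshgrid(*self.axes.values(), indexing="ij")
        data = {n: m.ravel() for n, m in zip(names, mesh)}
        for key, tab in self.tables.items():
            data[key] = np.asarray(tab).ravel()
        return pd.DataFrame(data)


def cued_trial(
    patterns: list[PhasePattern],
    theta,
    protocol: CapacityProtocol,
    seed: int,
    J: SynapticMatrix | None = None,
    noise: NoiseParams | None = None,
    cue_pattern: int = 0,
    window: STDPWindowParams = STDPWindowParams(),
    dt: float = 0.1,
) -> tuple[analysis.RetrievalResult, SpikeTrain]:
    """One cued simulation plus its analysis.

    Builds ``J`` from the patterns unless one is supplied, cues
    ``patterns[cue_pattern]`` with ``M = N * cue_fraction`` spikes and scores
    the steady-state window ``(t_bar, duration)``.
    """
    N = patterns[0].n_units
    if J is None:
        J = build_connectivity(patterns, window)
    m = int(round(N * protocol.cue_fraction))
    cfg = SimulationConfig(
        n_units=N, theta=theta, duration=protocol.duration, dt=dt, seed=seed
    )
    cue = CueSpec(pattern=patterns[cue_pattern], m=m, t_stim=protocol.t_stim)
    train = run(J, cfg, cue=cue, noise=noise)
    ov = overlap_series(train, patterns, window=(protocol.t_bar, protocol.duration))
    result = classify_regime(
        train, ov, t_bar=protocol.t_bar, threshold=protocol.success_threshold
    )
    return result, train


def retrieval_success(
    patterns: list[PhasePattern],
    theta: float,
    protocol: CapacityProtocol,
    seed: int,
    J: SynapticMatrix | None = None,
    noise: NoiseParams | None = None,
) -> tuple[bool, float]:
    """Success flag and mean steady-state overlap of the cued (first) pattern.

    Runs ``n_runs`` simulations with derived seeds (they differ only through
    stochastic elements such as input noise) and averages ``|m^1|`` over the
    steady-state window of every run.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    if J is None:
        J = build_connectivity(patterns)
    mu1 = patterns[0].pattern_id
    vals = []
    for r in range(protocol.n_runs):
        result, _ = cued_trial(
            patterns, theta, protocol, derive_seed(seed, r), J=J, noise=noise
        )
        vals.append(result.mean_overlaps.get(mu1, 0.0))
        if noise is None:
            # noiseless grid dynamics is deterministic: all runs are identical
            vals = vals * protocol.n_runs
            break
    mean = float(np.mean(vals))
    return mean > protocol.success_threshold, mean


def _success_fresh_patterns(
    nu: float,
    theta: float,
    n_units: int,
    n_patterns: int,
    protocol: CapacityProtocol,
    seed: int,
) -> tuple[bool, float]:
    """Success criterion with fresh random patterns for every repetition.

    This is the operational reading of the capacity protocol: repetitions
    average over the pattern ensemble (i.i.d. patterns are exchangeable, so
    testing the cued pattern on fresh draws is statistically equivalent to
    testing every stored pattern).
    """
    vals = []
    for r in range(protocol.n_runs):
        s = derive_seed(seed, n_patterns, r)
        patterns = generate_pattern_set(n_patterns, n_units, nu, s)
        result, _ = cued_trial(patterns, theta, protocol, s)
        vals.append(result.mean_overlaps.get(1, 0.0))
    mean = float(np.mean(vals))
    return mean > protocol.success_threshold, mean


def storage_capacity(
    nu: float,
    theta: float,
    n_units: int,
    protocol: CapacityProtocol,
    seed: int,
    p_cap: int = 60,
    search: str = "ascending",
) -> int:
    """Largest P for which retrieval of the cued pattern still succeeds.

    Fresh random patterns are drawn for every (P, repetition) cell; the seed
    schedule makes the whole search reproducible.  ``search='bisection'``
    exploits the sharpness of the success/failure transition for large
    ranges; the default ascends P by 1 and stops at the first failure.
    """
    if search == "ascending":
        p_max = 0
        for P in range(1, p_cap + 1):
            ok, mean = _success_fresh_patterns(nu, theta, n_units, P, protocol, seed)
            logger.info(
                "capacity: nu=%g theta=%g N=%d P=%d -> mean |m|=%.3f (%s)",
                nu, theta, n_units, P, mean, "ok" if ok else "fail",
            )
            if not ok:
                break
            p_max = P
        return p_max
    if search == "bisection":
        lo, hi = 0, 1
        while hi <= p_cap and _success_fresh_patterns(
            nu, theta, n_units, hi, protocol, seed
        )[0]:
            lo, hi = hi, hi * 2
        hi = min(hi, p_cap + 1)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _success_fresh_patterns(nu, theta, n_units, mid, protocol, seed)[0]:
                lo = mid
            else:
                hi = mid
        return lo
    raise ValueError("search must be 'ascending' or 'bisection'")


def capacity_surface(
    theta_grid,
    nu_grid,
    n_units: int,
    protocol: CapacityProtocol,
    seed: int,
    p_cap: int = 60,
) -> SweepResult:
    """``P_max`` for every (theta, nu) cell of a grid."""
    theta_grid = np.asarray(theta_grid, dtype=float)
    nu_grid = np.asarray(nu_grid, dtype=float)
    if theta_grid.size == 0 or nu_grid.size == 0:
        raise ValueError("grids must be non-empty")
    p_max = np.zeros((theta_grid.size, nu_grid.size), dtype=int)
    for a, theta in enumerate(theta_grid):
        for b, nu in enumerate(nu_grid):
            p_max[a, b] = storage_capacity(
                nu, theta, n_units, protocol, derive_seed(seed, a, b), p_cap=p_cap
            )
    return SweepResult(
        axes={"theta": theta_grid, "nu": nu_grid},
        tables={"p_max": p_max},
        metadata={
            "n_units": n_units,
            "protocol": protocol.name,
            "n_runs": protocol.n_runs,
            "seed": seed,
            "alpha_max": float(p_max.max()) / n_units,
        },
    )


def persistence_sweep(
    theta_grid,
    nu: float,
    n_units: int,
    P: int,
    n_realisations: int,
    seed: int,
    protocol: CapacityProtocol = CapacityProtocol(),
) -> SweepResult:
    """Persistence of the response across a threshold grid.

    For every theta, the fraction of pattern realisations whose response size
    ``S_tot`` (non-cue spikes after the cue) exceeds ``n`` for
    ``n in {0, N/2, N}``.  ``theta_crit`` is the largest grid theta with
    majority-persistent activity, i.e. ``P(S_tot > N) > 0.5``; above it the
    network only ever responds with a transient.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    thresholds_n = (0, n_units // 2, n_units)
    frac = np.zeros((theta_grid.size, 3))
    s_tot = np.zeros((theta_grid.size, n_realisations), dtype=int)
    persists_late = np.zeros((theta_grid.size, n_realisations), dtype=bool)
    for r in range(n_realisations):
        s = derive_seed(seed, r)
        patterns = generate_pattern_set(P, n_units, nu, s)
        J = build_connectivity(patterns)
        for a, theta in enumerate(theta_grid):
            result, train = cued_trial(patterns, theta, protocol, s, J=J)
            cue_times = train.times[train.sources == 0]
            t_cue_end = float(cue_times.max()) if cue_times.size else 0.0
            s_tot[a, r] = response_size(train, t_cue_end)
            persists_late[a, r] = bool(
                ((train.times > protocol.t_bar) & (train.sources != 0)).any()
            )
    for a in range(theta_grid.size):
        for k, n in enumerate(thresholds_n):
            frac[a, k] = np.mean(s_tot[a] > n)
    persistent = frac[:, 2] > 0.5
    theta_crit = float(theta_grid[persistent].max()) if persistent.any() else float("nan")
    return SweepResult(
        axes={"theta": theta_grid},
        tables={
            "p_stot_gt": frac,
            "s_tot": s_tot,
            "persists_after_tbar": persists_late.mean(axis=1),
        },
        metadata={
            "n_units": n_units,
            "nu": nu,
            "P": P,
            "n_realisations": n_realisations,
            "seed": seed,
            "stot_thresholds": list(thresholds_n),
            "theta_crit": theta_crit,
        },
    )


def frequency_vs_threshold(
    theta_grid,
    nu: float,
    n_units: int,
    seed: int,
    P: int = 1,
    n_realisations: int = 1,
    protocol: CapacityProtocol = CapacityProtocol(),
) -> SweepResult:
    """Replay frequency and spikes per cycle across a threshold grid.

    Cells outside the retrieval regime are flagged (``regime`` table) and
    reported as NaN rather than errors.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    freq = np.full((theta_grid.size, n_realisations), np.nan)
    spc = np.full((theta_grid.size, n_realisations), np.nan)
    regimes = np.empty((theta_grid.size, n_realisations), dtype=object)
    for r in range(n_realisations):
        s = derive_seed(seed, r)
        patterns = generate_pattern_set(P, n_units, nu, s)
        J = build_connectivity(patterns)
        for a, theta in enumerate(theta_grid):
            result, _ = cued_trial(patterns, theta, protocol, s, J=J)
            regimes[a, r] = result.regime
            if result.regime == "retrieval":
                freq[a, r] = result.replay_frequency_hz
                spc[a, r] = result.spikes_per_cycle
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean_freq = np.nanmean(freq, axis=1)
        mean_spc = np.nanmean(spc, axis=1)
    return SweepResult(
        axes={"theta": theta_grid},
        tables={
            "replay_frequency_hz": mean_freq,
            "spikes_per_cycle": mean_spc,
            "freq_runs": freq,
            "spc_runs": spc,
            "regime": regimes,
        },
        metadata={"n_units": n_units, "nu": nu, "P": P, "seed": seed},
    )


def noise_robustness(
    sigmas,
    n_units: int = 3000,
    P: int = 2,
    nu: float = 3.0,
    theta: float = 80.0,
    seed: int = 0,
    protocol: CapacityProtocol = CapacityProtocol(),
    tau_noise: float = 10.0,
) -> SweepResult:
    """Steady-state overlap of the cued pattern under input noise levels."""
    sigmas = np.asarray(sigmas, dtype=float)
    patterns = generate_pattern_set(P, n_units, nu, seed)
    J = build_connectivity(patterns)
    overlaps = np.zeros(sigmas.size)
    regimes = np.empty(sigmas.size, dtype=object)
    for k, sigma in enumerate(sigmas):
        noise = NoiseParams(tau_noise=tau_noise, sigma_j=float(sigma))
        result, _ = cued_trial(
            patterns, theta, protocol, derive_seed(seed, k), J=J, noise=noise
        )
        overlaps[k] = result.mean_overlaps.get(1, 0.0)
        regimes[k] = result.regime
    return SweepResult(
        axes={"sigma_j": sigmas},
        tables={"overlap": overlaps, "regime": regimes},
        metadata={"n_units": n_units, "P": P, "nu": nu, "theta": theta, "seed": seed},
    )


def heterogeneity_robustness(
    zs,
    n_units: int = 3000,
    P: int = 2,
    nu: float = 3.0,
    theta: float = 80.0,
    seed: int = 0,
    protocol: CapacityProtocol = CapacityProtocol(),
) -> SweepResult:
    """Retrieval under heterogeneous per-unit thresholds.

    Reports the cued-pattern overlap and the spread of per-unit mean
    inter-spike intervals in the steady state (a single collective frequency
    means all units share the same mean ISI despite unequal thresholds).
    """
    zs = np.asarray(zs, dtype=float)
    patterns = generate_pattern_set(P, n_units, nu, seed)
    J = build_connectivity(patterns)
    overlaps = np.zeros(zs.size)
    isi_spread = np.zeros(zs.size)
    regimes = np.empty(zs.size, dtype=object)
    for k, z in enumerate(zs):
        s = derive_seed(seed, k)
        theta_i = heterogeneous_thresholds(theta, float(z), n_units, s)
        result, train = cued_trial(patterns, theta_i, protocol, s, J=J)
        overlaps[k] = result.mean_overlaps.get(1, 0.0)
        regimes[k] = result.regime
        T_star = (
            1000.0 / result.replay_frequency_hz
            if result.replay_frequency_hz
            else None
        )
        isi_spread[k] = _per_unit_isi_spread(
            train, (protocol.t_bar, protocol.duration), T_star
        )
    return SweepResult(
        axes={"z": zs},
        tables={"overlap": overlaps, "isi_spread": isi_spread, "regime": regimes},
        metadata={"n_units": n_units, "P": P, "nu": nu, "theta": theta, "seed": seed},
    )


def _per_unit_isi_spread(
    train: SpikeTrain,
    window: tuple[float, float],
    T_star: float | None = None,
) -> float:
    """Relative spread (max-min)/median of per-unit oscillation periods.

    A unit's oscillation period is its mean inter-burst interval: when
    ``T_star`` is given, spikes closer than ``T_star / 2`` are collapsed into
    one burst first, so units emitting several spikes per collective cycle
    (higher rate, same rhythm) are still scored at the collective frequency.
    """
    sub = train.in_window(*window)
    if len(sub) < 2:
        return float("nan")
    order = np.lexsort((sub.times, sub.units))
    units = sub.units[order]
    times = sub.times[order]
    means = []
    for u in np.unique(units):
        t = times[units == u]
        if T_star is not None and t.size >= 2:
            t = t[np.concatenate([[True], np.diff(t) >= T_star / 2.0])]
        if t.size >= 2:
            means.append(np.diff(t).mean())
    if len(means) < 2:
        return float("nan")
    means = np.asarray(means)
    return float((means.max() - means.min()) / np.median(means))
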