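"""Phase-coded periodic spike patterns.

A stored memory is a *phase pattern*: one firing phase per neuron relative to a
collective oscillation of frequency ``nu`` (Hz).  Unit ``j`` of pattern ``mu``
spikes once per cycle, at times

    t_j = phi_j / (2 pi nu) + n / nu,   n integer,

so all information lives in the relative phases ``phi_j`` (and in the period
``T = 1/nu`` used during storage).  Phases are drawn i.i.d. uniform on
``[0, 2 pi)``.

All times in this package are milliseconds; frequencies are accepted in Hz and
converted once at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi

# Named sub-streams so experiments can vary one source of randomness at a time.
_STREAM_IDS = {
    "patterns": 1,
    "noise": 2,
    "heterogeneity": 3,
    "cue": 4,
    "protocol": 5,
}


def stream_rng(seed: int, purpose: str, *extra: int) -> np.random.Generator:
    """Dedicated random generator for one purpose (patterns, noise, ...).

    The same ``(seed, purpose, extra)`` triple always yields the same stream,
    and distinct purposes never share a stream for any seed.
    """
    if purpose not in _STREAM_IDS:
        raise ValueError(f"unknown stream purpose {purpose!r}")
    return np.random.default_rng([int(seed), _STREAM_IDS[purpose], *map(int, extra)])


@dataclass(frozen=True)
class PhasePattern:
    """One stored memory: ``n_units`` phases plus the storing frequency.

    Attributes
    ----------
    pattern_id : int
        Index of the pattern (1-based, following the usual ``mu`` labelling).
    n_units : int
        Number of neurons ``N``.
    phases : numpy.ndarray
        Shape ``(n_units,)``, each value in ``[0, 2 pi)``.
    frequency_hz : float
        Oscillation frequency ``nu`` used during storage (period 1000/nu ms).
    """

    pattern_id: int
    n_units: int
    phases: np.ndarray = field(repr=False)
    frequency_hz: float

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", phases)
        if self.n_units < 1:
            raise ValueError("n_units must be a positive integer")
        if phases.shape != (self.n_units,):
            raise ValueError(
                f"expected {self.n_units} phases, got shape {phases.shape}"
            )
        if not np.all((phases >= 0.0) & (phases < TWO_PI)):
            raise ValueError("all phases must lie in [0, 2*pi)")
        if not self.frequency_hz > 0:
            raise ValueError("frequency_hz must be positive")

    @property
    def period_ms(self) -> float:
        """Storage period ``T = 1/nu`` in milliseconds."""
        return 1000.0 / self.frequency_hz


def generate_random_pattern(
    n_units: int,
    frequency_hz: float,
    seed: int,
    pattern_id: int = 1,
) -> PhasePattern:
    """Draw a random phase pattern with i.i.d. uniform phases on [0, 2 pi).

    The same ``(seed, pattern_id)`` pair always produces the same pattern;
    distinct pattern ids drawn from the same seed are independent.
    """
    if n_units < 1:
        raise ValueError("n_units must be a positive integer")
    if not frequency_hz > 0:
        raise ValueError("frequency_hz must be positive")
    rng = stream_rng(seed, "patterns", pattern_id)
    phases = rng.uniform(0.0, TWO_PI, size=n_units)
    # uniform() can in principle return values == 2*pi after rounding; clip open.
    phases = np.nextafter(phases, -1.0, where=phases >= TWO_PI, out=phases)
    return PhasePattern(
        pattern_id=pattern_id,
        n_units=n_units,
        phases=phases,
        frequency_hz=float(frequency_hz),
    )


def generate_pattern_set(
    n_patterns: int,
    n_units: int,
    frequency_hz: float,
    seed: int,
) -> list[PhasePattern]:
    """Generate ``n_patterns`` independent patterns with ids 1..P."""
    return [
        generate_random_pattern(n_units, frequency_hz, seed, pattern_id=mu)
        for mu in range(1, n_patterns + 1)
    ]


def pattern_spike_times(
    pattern: PhasePattern,
    unit: int,
    t_start: float,
    t_end: float,
) -> np.ndarray:
    """All spike times of ``unit`` falling in ``[t_start, t_end)``, increasing.

    One spike per period by construction: times are
    ``phi/(2 pi) * T + n * T`` for every integer ``n`` landing in the window.
    """
    if not 0 <= unit < pattern.n_units:
        raise IndexError(f"unit {unit} out of range for N={pattern.n_units}")
    if not t_start < t_end:
        raise ValueError("t_start must be smaller than t_end")
    T = pattern.period_ms
    t0 = pattern.phases[unit] / TWO_PI * T
    n_lo = int(np.ceil((t_start - t0) / T))
    n_hi = int(np.ceil((t_end - t0) / T))  # exclusive
    return t0 + T * np.arange(n_lo, n_hi, dtype=float)
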