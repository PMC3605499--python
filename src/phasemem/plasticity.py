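"""STDP learning window and construction of the synaptic matrix.

Storage is a one-shot Hebbian prescription: presenting the periodic spike
pattern ``mu`` for many cycles changes each connection by the sum of the STDP
window over all spike pairs,

    J_ij^mu = sum_n A(t_i - t_j + n T),

with ``i`` the postsynaptic and ``j`` the presynaptic unit (the window
argument is the post-minus-pre lag, so a presynaptic spike shortly *before*
the postsynaptic one potentiates the connection), and the asymmetric
exponential window

    A(tau) = a_p exp(-tau/T_p)      - a_D exp(-eta tau/T_p)     for tau > 0,
    A(tau) = a_p exp(eta tau/T_D)   - a_D exp(tau/T_D)          for tau < 0,

whose amplitudes ``a_p = gamma/(1/T_p + eta/T_D)`` and
``a_D = gamma/(eta/T_p + 1/T_D)`` make the window integrate to exactly zero.
The zero integral, together with uniformly distributed phases, balances summed
excitation against summed inhibition up to O(1/sqrt(N)).

Storing several patterns superposes their contributions:
``J_ij = sum_mu J_ij^mu``.  The diagonal is excluded (no self-connections).

The periodic pair sum is evaluated in closed form: for a phase lag reduced to
``dt in [0, T)`` each of the four exponential branches sums as a geometric
series over ``n``, so the infinite sum is exact (no truncation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .patterns import TWO_PI, PhasePattern


@dataclass(frozen=True)
class STDPWindowParams:
    """Constants of the STDP window ``A(tau)``.

    Defaults fit pair-based potentiation/depression measurements in
    hippocampal cultures: potentiation decay ``T_p = 10.2`` ms, depression
    decay ``T_D = 28.6`` ms, asymmetry ``eta = 4``, overall scale
    ``gamma = 0.42``.
    """

    T_p: float = 10.2
    T_D: float = 28.6
    eta: float = 4.0
    gamma: float = 0.42

    def __post_init__(self) -> None:
        if not (self.T_p > 0 and self.T_D > 0 and self.eta > 0):
            raise ValueError("T_p, T_D and eta must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    @property
    def a_p(self) -> float:
        """Potentiation amplitude gamma / (1/T_p + eta/T_D)."""
        return self.gamma / (1.0 / self.T_p + self.eta / self.T_D)

    @property
    def a_D(self) -> float:
        """Depression amplitude gamma / (eta/T_p + 1/T_D)."""
        return self.gamma / (self.eta / self.T_p + 1.0 / self.T_D)


def compute_amplitudes(params: STDPWindowParams) -> tuple[float, float]:
    """Return the closed-form amplitudes ``(a_p, a_D)`` of the window."""
    return params.a_p, params.a_D


def stdp_window(tau, params: STDPWindowParams = STDPWindowParams()):
    """Weight-change density ``A(tau)`` (tau in ms, pre-minus-post ordering).

    Continuous at ``tau = 0`` where both branches give ``a_p - a_D``; decays
    exponentially as ``|tau| -> inf``.  Accepts scalars or arrays.
    """
    tau = np.asarray(tau, dtype=float)
    a_p, a_D = params.a_p, params.a_D
    # clamp each branch's argument to its own half-line so the branch that
    # np.where discards cannot overflow
    tp = np.maximum(tau, 0.0)
    tn = np.minimum(tau, 0.0)
    pos = a_p * np.exp(-tp / params.T_p) - a_D * np.exp(-params.eta * tp / params.T_p)
    neg = a_p * np.exp(params.eta * tn / params.T_D) - a_D * np.exp(tn / params.T_D)
    out = np.where(tau >= 0.0, pos, neg)
    return float(out) if out.ndim == 0 else out


def periodic_weight_sum(
    delta_t,
    period_ms: float,
    params: STDPWindowParams = STDPWindowParams(),
):
    """Exact sum ``W(dt) = sum_n A(dt + n T)`` for a periodic pair of spikes.

    ``delta_t`` is the presynaptic-minus-postsynaptic spike-time lag in ms
    (any real; reduced modulo the period internally).  Each exponential branch
    is a geometric series in ``n``, summed in closed form, so the result is
    the full infinite sum to machine precision.  Vectorised over ``delta_t``.
    """
    if not period_ms > 0:
        raise ValueError("period_ms must be positive")
    dt = np.mod(np.asarray(delta_t, dtype=float), period_ms)  # in [0, T)
    T = period_ms
    a_p, a_D = params.a_p, params.a_D
    T_p, T_D, eta = params.T_p, params.T_D, params.eta
    # n >= 0 terms: positive branch of A (tau = dt + nT >= 0)
    pos = a_p * np.exp(-dt / T_p) / -np.expm1(-T / T_p) \
        - a_D * np.exp(-eta * dt / T_p) / -np.expm1(-eta * T / T_p)
    # n <= -1 terms: negative branch (tau = dt - nT < 0)
    neg = a_p * np.exp(-eta * (T - dt) / T_D) / -np.expm1(-eta * T / T_D) \
        - a_D * np.exp(-(T - dt) / T_D) / -np.expm1(-T / T_D)
    out = pos + neg
    return float(out) if out.ndim == 0 else out


def pairwise_weight(
    phase_pre: float,
    phase_post: float,
    frequency_hz: float,
    params: STDPWindowParams = STDPWindowParams(),
) -> float:
    """Learned weight contribution for one (pre, post) phase pair.

    Equals ``sum_n A((phi_post - phi_pre)/(2 pi nu) + n/nu)`` over all integer
    ``n`` (post-minus-pre lag, the usual STDP causality); invariant under
    adding multiples of ``2 pi`` to either phase.
    """
    if not frequency_hz > 0:
        raise ValueError("frequency_hz must be positive")
    T = 1000.0 / frequency_hz
    dt = np.mod(phase_post - phase_pre, TWO_PI) / TWO_PI * T
    return float(periodic_weight_sum(dt, T, params))


@dataclass
class SynapticMatrix:
    """Dense learned connectivity ``J_ij`` (row = postsynaptic unit).

    ``provenance`` records the contributing pattern ids, their storing
    frequencies and the window parameters used.
    """

    n_units: int
    weights: np.ndarray = field(repr=False)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.shape != (self.n_units, self.n_units):
            raise ValueError(
                f"weights must be ({self.n_units}, {self.n_units}), got {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(np.diagonal(w) != 0.0):
            raise ValueError("diagonal of the synaptic matrix must be zero")
        self.weights = w


def build_connectivity(
    patterns: Sequence[PhasePattern],
    params: STDPWindowParams = STDPWindowParams(),
    n_units: int | None = None,
    dtype=np.float64,
) -> SynapticMatrix:
    """Superpose the STDP contributions of all patterns into one matrix.

    All patterns must share ``n_units``.  An empty list yields the all-zero
    matrix (``n_units`` must then be given).  Deterministic in its inputs.
    """
    if len(patterns) == 0:
        if n_units is None:
            raise ValueError("n_units is required for an empty pattern list")
        return SynapticMatrix(
            n_units=n_units,
            weights=np.zeros((n_units, n_units), dtype=dtype),
            provenance={"pattern_ids": [], "window": _window_dict(params)},
        )
    N = patterns[0].n_units
    if n_units is not None and n_units != N:
        raise ValueError("n_units does not match the patterns")
    for p in patterns:
        if p.n_units != N:
            raise ValueError("all patterns must share n_units")
    J = np.zeros((N, N), dtype=np.float64)
    for p in patterns:
        T = p.period_ms
        # J_ij uses the post-minus-pre lag (phi_i - phi_j)/(2 pi nu); row i = post.
        dphi = np.mod(p.phases[:, None] - p.phases[None, :], TWO_PI)
        J += periodic_weight_sum(dphi * (T / TWO_PI), T, params)
    np.fill_diagonal(J, 0.0)
    return SynapticMatrix(
        n_units=N,
        weights=J.astype(dtype, copy=False),
        provenance={
            "pattern_ids": [p.pattern_id for p in patterns],
            "frequencies_hz": [p.frequency_hz for p in patterns],
            "window": _window_dict(params),
        },
    )


def balance_statistics(J: SynapticMatrix) -> tuple[float, float]:
    """Mean summed excitation and inhibition per unit.

    For each presynaptic unit ``j`` the summed excitation is
    ``(1/N) sum_{i: J_ij > 0} J_ij`` (and likewise the summed inhibition over
    the negative entries); both are O(1) quantities.  Returns the two averages
    over units.  For uniformly distributed phases each unit's excitation and
    inhibition cancel up to a residual of order 1/sqrt(N) (see
    :func:`balance_residual`).
    """
    w = J.weights
    N = J.n_units
    exc = float(np.where(w > 0, w, 0.0).sum(axis=0).mean()) / N
    inh = float(np.where(w < 0, w, 0.0).sum(axis=0).mean()) / N
    return exc, inh


def balance_residual(J: SynapticMatrix) -> float:
    """Typical per-unit imbalance: mean over units of |(1/N) sum_i J_ij|.

    This is the quantity that vanishes like 1/sqrt(N) for stored patterns
    with uniform random phases (each column sums ~N zero-mean terms).
    """
    col = J.weights.sum(axis=0) / J.n_units
    return float(np.abs(col).mean())


def _window_dict(params: STDPWindowParams) -> dict:
    return {
        "T_p": params.T_p,
        "T_D": params.T_D,
        "eta": params.eta,
        "gamma": params.gamma,
    }
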