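"""Spike-response (leaky integrate-and-fire) network simulation.

Each neuron integrates incoming spikes through the double-exponential kernel

    eps(t) = K * (exp(-t/tau_m) - exp(-t/tau_s)) * Heaviside(t),

normalised so its peak is 1 (K = 4 for tau_m = 10 ms, tau_s = 5 ms), and the
membrane potential is

    h_i(t) = eta_i(t) + sum_j J_ij sum_{t_hat_j > t_hat_i} eps(t - t_hat_j),

where only presynaptic (and background-noise) arrivals *after* neuron i's own
last spike count.  When ``h_i >= theta_i`` the unit fires and its potential
memory is cleared (reset to zero, all earlier arrivals discarded).  The
spiking threshold ``theta`` is measured in units of the unitary PSP peak.

Integration runs on a fixed time grid (default dt = 0.1 ms).  Because the
kernel is a difference of exponentials, the potential is tracked exactly by
two per-neuron accumulators decayed geometrically each step, so the grid only
quantises spike times, never the potential between them.  Spikes emitted at
one step reach other units from the next step onward (eps(0) = 0).

Retrieval is triggered by a *cue*: M imposed spikes whose times follow the
phases of one stored pattern, compressed into a window ``T_stim * M/N``.
Background input noise is a per-unit Poisson train of Gaussian-weighted PSPs;
threshold heterogeneity draws per-unit thresholds uniformly around the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .patterns import TWO_PI, PhasePattern, stream_rng
from .plasticity import SynapticMatrix

logger = logging.getLogger("phasemem")

SOURCE_CUE = 0
SOURCE_NET = 1
SOURCE_NAMES = {SOURCE_CUE: "cue", SOURCE_NET: "net"}
SOURCE_CODES = {"cue": SOURCE_CUE, "net": SOURCE_NET}


@dataclass(frozen=True)
class KernelParams:
    """Membrane response kernel constants (times in ms).

    ``K`` normalises the kernel peak to 1; it is derived, not free.
    """

    tau_m: float = 10.0
    tau_s: float = 5.0

    def __post_init__(self) -> None:
        if not (self.tau_m > self.tau_s > 0):
            raise ValueError("need tau_m > tau_s > 0")

    @property
    def t_peak(self) -> float:
        """Argmax of the kernel: tau_m*tau_s/(tau_m-tau_s) * ln(tau_m/tau_s)."""
        tm, ts = self.tau_m, self.tau_s
        return tm * ts / (tm - ts) * np.log(tm / ts)

    @property
    def K(self) -> float:
        tp = self.t_peak
        return 1.0 / (np.exp(-tp / self.tau_m) - np.exp(-tp / self.tau_s))


def epsilon(t_since_spike, params: KernelParams = KernelParams()):
    """Postsynaptic potential kernel; 0 for t <= 0, peak value 1."""
    t = np.asarray(t_since_spike, dtype=float)
    out = np.where(
        t > 0.0,
        params.K * (np.exp(-t / params.tau_m) - np.exp(-t / params.tau_s)),
        0.0,
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SimulationConfig:
    """Grid-simulation parameters.

    ``theta`` may be a scalar (uniform threshold) or a length-N array.
    """

    n_units: int
    theta: float | np.ndarray
    duration: float
    dt: float = 0.1
    seed: int = 0
    record_potentials: bool = False
    kernel: KernelParams = field(default_factory=KernelParams)

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        theta = np.broadcast_to(np.asarray(self.theta, dtype=float), (self.n_units,))
        if not np.all(theta > 0):
            raise ValueError("all thresholds must be positive")

    def theta_array(self) -> np.ndarray:
        return np.ascontiguousarray(
            np.broadcast_to(np.asarray(self.theta, dtype=float), (self.n_units,))
        )


@dataclass(frozen=True)
class CueSpec:
    """Cue protocol: M imposed spikes following one pattern's phases.

    ``m`` defaults to N/10.  Spike times are ``t_offset + T_stim * phi/(2 pi)``
    for the selected units; with the default lowest-phase selection and
    uniform phases the cue lasts about ``T_stim * M/N`` ms.
    """

    pattern: PhasePattern
    m: int | None = None
    t_stim: float = 50.0
    t_offset: float = 0.0
    selection: str = "lowest-phase"  # or "random"

    def __post_init__(self) -> None:
        if not self.t_stim > 0:
            raise ValueError("t_stim must be positive")
        if self.m is not None and not 0 <= self.m <= self.pattern.n_units:
            raise ValueError("need 0 <= M <= N")
        if self.selection not in ("lowest-phase", "random"):
            raise ValueError("selection must be 'lowest-phase' or 'random'")


def make_cue(
    pattern: PhasePattern,
    m: int | None = None,
    t_stim: float = 50.0,
    t_offset: float = 0.0,
    selection: str = "lowest-phase",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cue events as ``(times, units)`` sorted by time.

    Selects the M units with the smallest phases (default) or a random subset,
    and places unit i's imposed spike at ``t_offset + t_stim * phi_i/(2 pi)``.
    """
    N = pattern.n_units
    if m is None:
        m = N // 10
    if not 0 <= m <= N:
        raise ValueError(f"need 0 <= M <= N, got M={m}, N={N}")
    if m == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    if selection == "lowest-phase":
        units = np.argsort(pattern.phases, kind="stable")[:m]
    elif selection == "random":
        units = stream_rng(seed, "cue").choice(N, size=m, replace=False)
    else:
        raise ValueError("selection must be 'lowest-phase' or 'random'")
    times = t_offset + t_stim * pattern.phases[units] / TWO_PI
    order = np.argsort(times, kind="stable")
    return times[order], units[order]


@dataclass(frozen=True)
class NoiseParams:
    """Poissonian background input: per-unit trains of Gaussian-weighted PSPs.

    Inter-event intervals are exponential with per-unit mean ``mean_interval``
    (default ``tau_noise``); strengths are i.i.d. Normal(``j_bar``,
    ``sigma_j``).  Noise arrivals enter the potential through the same kernel
    as synaptic spikes and are cleared by the postsynaptic reset like any
    other arrival.
    """

    tau_noise: float = 10.0
    mean_interval: float | None = None
    j_bar: float = 0.0
    sigma_j: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_j < 0:
            raise ValueError("sigma_j must be non-negative")
        if self.mean_interval is not None and not self.mean_interval > 0:
            raise ValueError("mean_interval must be positive")
        if not self.tau_noise > 0:
            raise ValueError("tau_noise must be positive")

    @property
    def interval_ms(self) -> float:
        return self.tau_noise if self.mean_interval is None else self.mean_interval


def make_noise_events(
    params: NoiseParams,
    n_units: int,
    duration: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw all noise events for a run: ``(times, units, strengths)`` by time.

    Each unit gets an independent exponential renewal train over
    ``[0, duration)``; reproducible under ``seed``.
    """
    rng = stream_rng(seed, "noise")
    mean = params.interval_ms
    times_all, units_all = [], []
    # Draw in bulk with a safety margin, then top up the rare short tails.
    n_guess = max(8, int(duration / mean * 1.5) + 8)
    for u in range(n_units):
        t = np.cumsum(rng.exponential(mean, size=n_guess))
        while t[-1] < duration:
            t = np.concatenate([t, t[-1] + np.cumsum(rng.exponential(mean, size=n_guess))])
        t = t[t < duration]
        times_all.append(t)
        units_all.append(np.full(t.size, u, dtype=np.int64))
    times = np.concatenate(times_all) if times_all else np.empty(0)
    units = np.concatenate(units_all) if units_all else np.empty(0, dtype=np.int64)
    strengths = rng.normal(params.j_bar, params.sigma_j, size=times.size)
    order = np.argsort(times, kind="stable")
    return times[order], units[order], strengths[order]


def heterogeneous_thresholds(
    theta: float,
    z: float,
    n_units: int,
    seed: int,
) -> np.ndarray:
    """Per-unit thresholds ``theta_i = (1 + z * zeta_i) * theta``.

    ``zeta_i`` are i.i.d. uniform on [-1, 1]; ``z`` is the heterogeneity
    degree.  ``z >= 1`` would allow non-positive thresholds and is rejected.
    """
    if not theta > 0:
        raise ValueError("theta must be positive")
    if not 0 <= z < 1:
        raise ValueError("need 0 <= z < 1 so all thresholds stay positive")
    zeta = stream_rng(seed, "heterogeneity").uniform(-1.0, 1.0, size=n_units)
    return (1.0 + z * zeta) * theta


@dataclass
class SpikeTrain:
    """Time-ordered spike events from a simulation (or a sampled pattern).

    ``sources`` holds integer codes: 0 = cue (imposed), 1 = network.
    """

    times: np.ndarray
    units: np.ndarray
    sources: np.ndarray
    n_units: int
    duration: float
    potentials: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.units = np.asarray(self.units, dtype=np.int64)
        self.sources = np.asarray(self.sources, dtype=np.int8)
        if not (self.times.size == self.units.size == self.sources.size):
            raise ValueError("times, units and sources must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be non-decreasing")
        if self.times.size and (
            self.units.min() < 0 or self.units.max() >= self.n_units
        ):
            raise ValueError("unit index out of range")

    def __len__(self) -> int:
        return self.times.size

    def network_mask(self) -> np.ndarray:
        return self.sources == SOURCE_NET

    def in_window(self, t0: float, t1: float) -> "SpikeTrain":
        """Events with t0 <= t < t1 (all sources)."""
        lo, hi = np.searchsorted(self.times, [t0, t1])
        return SpikeTrain(
            self.times[lo:hi], self.units[lo:hi], self.sources[lo:hi],
            self.n_units, self.duration,
        )


@njit(cache=False)
def _simulate_kernel(
    JT,                # (N, N) float64, JT[j, i] = weight from pre j to post i
    theta,             # (N,) float64
    n_steps, dt, K, decay_m, decay_s,
    cue_steps, cue_units,                 # int64, sorted by step
    noise_steps, noise_units, noise_w,    # int64/int64/float64, sorted
    record_h,          # (n_steps, N) float64 or (0, 0)
):  # pragma: no cover - exercised through run()
    N = JT.shape[0]
    Gm = np.zeros(N)
    Gs = np.zeros(N)
    cap = 1024
    out_step = np.empty(cap, dtype=np.int64)
    out_unit = np.empty(cap, dtype=np.int64)
    out_src = np.empty(cap, dtype=np.int8)
    n_out = 0
    fired = np.zeros(N, dtype=np.bool_)
    firers = np.empty(N, dtype=np.int64)
    ci = 0
    ni = 0
    do_record = record_h.shape[0] > 0
    for t in range(n_steps):
        for i in range(N):
            Gm[i] *= decay_m
            Gs[i] *= decay_s
        # noise arrivals at this step: eps(0)=0 so they add nothing to h now
        while ni < noise_steps.size and noise_steps[ni] == t:
            u = noise_units[ni]
            w = noise_w[ni]
            Gm[u] += w
            Gs[u] += w
            ni += 1
        # threshold check on the current potential
        n_fired = 0
        for i in range(N):
            h = K * (Gm[i] - Gs[i])
            if do_record:
                record_h[t, i] = h
            if h != h:
                raise FloatingPointError("membrane potential became NaN")
            if h >= theta[i]:
                fired[i] = True
                firers[n_fired] = i
                n_fired += 1
        n_net = n_fired
        # imposed cue spikes at this step (override any endogenous spike)
        while ci < cue_steps.size and cue_steps[ci] == t:
            u = cue_units[ci]
            if not fired[u]:
                fired[u] = True
                firers[n_fired] = u
                n_fired += 1
            else:
                # already counted as network firer this step; re-tag as cue
                for k in range(n_net):
                    if firers[k] == u:
                        firers[k] = firers[n_net - 1]
                        firers[n_net - 1] = u
                        n_net -= 1
                        break
            ci += 1
        if n_fired == 0:
            continue
        # record (network firers first, then cue), grow arrays as needed
        while n_out + n_fired > cap:
            cap *= 2
            tmp_s = np.empty(cap, dtype=np.int64)
            tmp_u = np.empty(cap, dtype=np.int64)
            tmp_c = np.empty(cap, dtype=np.int8)
            tmp_s[:n_out] = out_step[:n_out]
            tmp_u[:n_out] = out_unit[:n_out]
            tmp_c[:n_out] = out_src[:n_out]
            out_step, out_unit, out_src = tmp_s, tmp_u, tmp_c
        for k in range(n_fired):
            out_step[n_out] = t
            out_unit[n_out] = firers[k]
            out_src[n_out] = 1 if k < n_net else 0
            n_out += 1
        # reset: firing clears the unit's entire arrival memory
        for k in range(n_fired):
            u = firers[k]
            Gm[u] = 0.0
            Gs[u] = 0.0
        # propagate: this step's spikes become arrivals for every unit that
        # did not itself fire now (arrivals must be strictly after the last
        # postsynaptic spike); effect starts next step since eps(0) = 0
        for k in range(n_fired):
            j = firers[k]
            row = JT[j]
            for i in range(N):
                if not fired[i]:
                    w = row[i]
                    Gm[i] += w
                    Gs[i] += w
        for k in range(n_fired):
            fired[firers[k]] = False
    return out_step[:n_out], out_unit[:n_out], out_src[:n_out]


def run(
    J: SynapticMatrix,
    config: SimulationConfig,
    cue: CueSpec | None = None,
    noise: NoiseParams | None = None,
) -> SpikeTrain:
    """Simulate the network on a fixed time grid and return all spikes.

    Cue events are imposed output spikes of the cued units: they reset the
    unit and propagate through ``J`` exactly like endogenous spikes, and are
    tagged ``cue`` in the returned train.  Identical inputs (including seed)
    give identical event lists.
    """
    if J.n_units != config.n_units:
        raise ValueError(
            f"J has N={J.n_units} but config has N={config.n_units}"
        )
    N = config.n_units
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    kp = config.kernel
    decay_m = float(np.exp(-dt / kp.tau_m))
    decay_s = float(np.exp(-dt / kp.tau_s))

    if cue is not None:
        m = cue.m if cue.m is not None else N // 10
        cue_times, cue_units = make_cue(
            cue.pattern, m, cue.t_stim, cue.t_offset, cue.selection, config.seed
        )
        cue_steps = np.round(cue_times / dt).astype(np.int64)
        keep = cue_steps < n_steps
        cue_steps, cue_units = cue_steps[keep], cue_units[keep]
        order = np.argsort(cue_steps, kind="stable")
        cue_steps, cue_units = cue_steps[order], cue_units[order]
    else:
        cue_steps = np.empty(0, dtype=np.int64)
        cue_units = np.empty(0, dtype=np.int64)

    if noise is not None and noise.interval_ms > 0:
        nt, nu, nw = make_noise_events(noise, N, config.duration, config.seed)
        noise_steps = np.round(nt / dt).astype(np.int64)
        keep = noise_steps < n_steps
        noise_steps, nu, nw = noise_steps[keep], nu[keep], nw[keep]
        order = np.argsort(noise_steps, kind="stable")
        noise_steps, noise_units, noise_w = noise_steps[order], nu[order], nw[order]
    else:
        noise_steps = np.empty(0, dtype=np.int64)
        noise_units = np.empty(0, dtype=np.int64)
        noise_w = np.empty(0)

    JT = np.ascontiguousarray(np.asarray(J.weights, dtype=np.float64).T)
    theta = config.theta_array()
    record = (
        np.zeros((n_steps, N)) if config.record_potentials else np.zeros((0, 0))
    )
    steps, units, src = _simulate_kernel(
        JT, theta, n_steps, dt, kp.K, decay_m, decay_s,
        cue_steps, cue_units, noise_steps, noise_units, noise_w, record,
    )
    train = SpikeTrain(
        times=steps.astype(float) * dt,
        units=units,
        sources=src,
        n_units=N,
        duration=config.duration,
        potentials=record if config.record_potentials else None,
    )
    logger.info(
        "run: N=%d dt=%.3g duration=%.0f ms, %d spikes (%d cue)",
        N, dt, config.duration, len(train), int((train.sources == SOURCE_CUE).sum()),
    )
    return train
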