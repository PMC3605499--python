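# Methods

## Model

The network is N all-to-all coupled leaky integrate-and-fire units in the
spike-response formulation.  Unit *i*'s membrane potential is the
kernel-filtered sum of presynaptic (and background-noise) spike arrivals
that occurred *strictly after its own last spike*:

    h_i(t) = eta_i(t) + sum_j J_ij sum_{t_hat_j > t_hat_i} eps(t - t_hat_j)
    eps(t) = K (exp(-t/tau_m) - exp(-t/tau_s)) Theta(t)

with membrane time constant `tau_m = 10 ms`, synaptic time constant
`tau_s = 5 ms`, and K = 4 chosen so the kernel peak is 1 (at
`tau_m tau_s/(tau_m - tau_s) ln(tau_m/tau_s) = 10 ln 2 ≈ 6.93 ms`).  When
`h_i >= theta_i` the unit fires and its entire arrival memory is cleared
(potential resets to zero and the inner sum restarts).  Thresholds are
therefore measured in units of the unitary PSP peak; scaling all thresholds
and all weights by the same factor leaves the spike trains unchanged (this
equivalence is tested).

There are no conduction delays, refractory periods beyond the reset, or
adaptation currents; the balance built into the connectivity (below) is what
prevents runaway synchronisation.

## Storage rule

A stored pattern is one phase per neuron, i.i.d. uniform on [0, 2 pi), plus
a storing frequency nu (one spike per neuron per cycle at
`t_j = phi_j/(2 pi nu) + n/nu`).  Presenting the periodic pattern for many
cycles under pair-based STDP accumulates, for every ordered pair, the window
sum

    J_ij^mu = sum_n A(t_i - t_j + n T),     T = 1/nu,

with the asymmetric exponential window (post-minus-pre lag; pre-before-post
potentiates)

    A(tau) = a_p e^{-tau/T_p}    - a_D e^{-eta tau/T_p}   (tau > 0)
    A(tau) = a_p e^{eta tau/T_D} - a_D e^{tau/T_D}        (tau < 0)

with `T_p = 10.2 ms`, `T_D = 28.6 ms`, `eta = 4`, `gamma = 0.42` and
amplitudes `a_p = gamma/(1/T_p + eta/T_D) ≈ 1.7655`,
`a_D = gamma/(eta/T_p + 1/T_D) ≈ 0.9833`, which make the window integrate
to exactly zero.  At `tau = 0` both branches coincide at `a_p − a_D`; that
common value is used (self-pairs never arise since the diagonal is
excluded).  Multiple patterns superpose linearly, `J_ij = sum_mu J_ij^mu`.

Two numerical choices matter here:

* **Exact periodic sum.**  For a lag reduced to `dt in [0, T)` each of the
  four exponential branches of the n-sum is a geometric series, so the full
  infinite sum is evaluated in closed form — no truncation.  Tests verify
  agreement with a brute-force sum over `n in [-1000, 1000]` to 1e-10.
* **Orientation of the pair lag.**  The window argument is the
  post-minus-pre spike lag (`t_i - t_j` for connection j -> i), the standard
  STDP causality.  With the opposite orientation the learned ring drives a
  time-reversed wave whose overlap with the stored pattern is scrambled (the
  summand becomes `e^{2 i phi_j}`), and no retrieval exists anywhere in
  parameter space; with the orientation used here the stored pattern is an
  attractor.

Because the window integrates to zero and the phases are uniform, each
unit's summed excitation `(1/N) sum_{i: J_ij>0} J_ij` and summed inhibition
(negative entries) are O(1) quantities that cancel to O(1/sqrt(N)): the
per-unit residual `|(1/N) sum_i J_ij|` measured across
N in {250, 1000, 4000} scales with a log-log slope of ≈ −0.55.  Note that
the *whole-matrix* sum normalised by N does not shrink with N (its
fluctuations are dominated by a few Fourier modes of the phase ensemble);
the balance statement is intrinsically per-neuron, and the package exposes
`balance_statistics` (per-unit means) and `balance_residual` (the 1/sqrt(N)
quantity) separately.

## Simulation scheme

Integration uses a fixed time grid, default `dt = 0.1 ms`.  Because the
kernel is a difference of exponentials, each unit's potential is tracked
*exactly* by two accumulators decayed geometrically per step; the grid
quantises spike times but never the potential between spikes.  Spikes
emitted in one step become arrivals of every other unit from the next step
on (`eps(0) = 0`, one-step transmission latency), which resolves
simultaneous threshold crossings by letting all of them fire in the same
step.  A unit at exactly `h = theta` fires.  Halving `dt` in a small-network
smoke test moves no spike by more than the coarse step.  The per-step
threshold scan and spike propagation run in a numba-compiled kernel; a
1-second simulation of N = 3000 units takes on the order of a second.

**Cue.**  Retrieval is triggered by M imposed spikes (default M = N/10)
whose times follow one stored pattern: unit i of the cued set fires at
`T_stim * phi_i/(2 pi)` with `T_stim = 50 ms`.  The cued units are those
with the smallest phases, so with uniform phases the cue occupies
`~T_stim*M/N ≈ 5 ms` — a brief, phase-ordered nudge.  (Taking the cue times
as `T_stim * phi` literally would spread them over ~314 ms, which
contradicts the few-millisecond stimulation the protocol intends; both the
division by 2 pi and the lowest-phase selection are package choices, and a
random-subset selection is available as an option.)  Cue spikes reset the
cued units and propagate through J exactly like endogenous spikes; they are
tagged `cue` in the output and excluded from response-size counts.

**Background noise.**  Input noise is a per-unit Poisson train of PSPs with
Gaussian strengths (mean `J_bar = 0`, standard deviation `sigma_J`), passed
through the same kernel and cleared by the same reset rule.  The per-unit
mean inter-event interval defaults to `tau_noise = 10 ms`.  This default is
a deliberate choice among ambiguous readings of the noise rate: a
Campbell-theorem estimate gives potential fluctuations of standard deviation
`sigma_J * sqrt(integral(eps^2)/interval) ≈ 1.15 sigma_J` at this rate,
which reproduces the observed phenomenology — spontaneous activity from
noise alone at `sigma_J = 20` with `theta = 80`, retrieval surviving
`sigma_J <= 20`, and loss of the attractor at `sigma_J = 30`.  A
network-wide rate of `1/tau_noise` (per-unit interval `N tau_noise`), the
other possible reading, makes noise three orders of magnitude too weak to
affect anything; `mean_interval` is an explicit knob so either regime can be
simulated.

**Heterogeneity.**  Per-unit thresholds `theta_i = (1 + z zeta_i) theta`
with `zeta_i` uniform on [-1, 1]; `z >= 1` is rejected (it would allow
non-positive thresholds).

## Analysis

* **Period T\*.**  Default estimator: median inter-spike interval over all
  units with >= 2 spikes in the analysis window — exact for clean
  one-spike-per-cycle replay.  Alternative: grid search for the T\* that
  maximises the overlap (default grid 5–500 ms, step 1 ms), usable on
  non-periodic trains.  On a clean N=1000 replay the two agree within 2%;
  on very small networks (N ~ 100) the replay phases are distorted enough
  that the maximising T\* can differ by ~10%, so the cross-validation test
  uses N=1000.  Neither estimator is canonical; both are exposed.
* **Overlap.**  `|m^mu(t)|` uses each unit's most recent spike in
  `(t - T*, t]`; units silent in that window contribute zero and the
  prefactor is always 1/N.  Overlaps are evaluated every T\*/2 across the
  steady-state window `[t_bar, duration]`, with `t_bar = 600 ms`.
* **Classification.**  `silent` if no network spike occurs after `t_bar`;
  otherwise `retrieval` of the pattern with the largest steady-state mean
  overlap if that mean exceeds the similarity threshold (0.5, a named
  constant — steady-state overlaps cluster near 1 or near 1/sqrt(N), so the
  classification is insensitive to it); else `spurious`.
* **Rates.**  Replay frequency is `1000/T*` (Hz); spikes per cycle is the
  mean spike count of active units divided by the number of cycles in the
  window.  Under threshold heterogeneity, per-unit oscillation periods are
  compared after collapsing spikes closer than T\*/2 into bursts, because a
  unit may emit several spikes per collective cycle (rate and frequency are
  dissociable in this model) while still following the single collective
  rhythm.

## Protocols and problem sizes

The retrieval-success criterion cues pattern 1 with M = N/10 spikes and
requires the steady-state mean overlap, averaged over repetitions, to exceed
0.5.  The full-fidelity protocol uses 50 repetitions; the desk-scale preset
(`DESK_PROTOCOL`, 5 repetitions, 1000 ms runs) is what the test suite and
the acceptance script use, with fresh random patterns per repetition for
capacity searches (i.i.d. patterns are exchangeable, so testing the cued
pattern on fresh draws is statistically equivalent to testing each stored
pattern).  Noiseless grid dynamics is deterministic, so repetitions of a
fixed configuration differ only through the pattern draw or the noise
stream.  Storage capacity ascends P by one until the criterion fails
(the transition is sharp; a bisection mode exists).  The full capacity
surface over a fine (theta, nu) grid at 50 runs per cell is cluster-scale
and is provided as a config-driven CLI (`phasemem sweep`), validated here at
reduced scale.

The acceptance script uses, per target: 5 pattern seeds and a theta grid of
step 5 (critical threshold); 7 stored frequencies with a descending
theta scan of step 20 and 2 seeds (identity-crossing frequency, locating
the capacity-optimal threshold just below each frequency's silence
transition); 3 seeds for the replay-frequency targets; and a single seeded
run for the steady-state overlaps.

Seeding is hierarchical: every repetition/cell derives a child seed from
(`seed`, indices), and the named streams (patterns, noise, heterogeneity,
cue) are independent, so any single cell of any sweep can be reproduced in
isolation.

## What the generator does and does not emulate

Synthetic patterns are exactly the model's storage ensemble — i.i.d. uniform
phases, one spike per cycle, a single stored frequency per pattern — so the
tests probe the model under its own assumptions.  Real replay data differ in
ways the generator does not emulate: place-field phases are not uniform or
independent, firing is stochastic with missed cycles, oscillation frequency
drifts, and plasticity is not a clean pair-based window.  Passing tests
therefore validate the mechanism (attractor storage and time-rescaled
selective replay), not the biological fidelity of any parameter.

## Known limitations

* Finite-size effects are strong below N ≈ 200: at N = 100 the default
  M = N/10 cue never ignites persistent replay and the test fixture uses a
  30% cue with a low threshold instead.
* The critical threshold and replay frequencies quoted by the acceptance
  script are grid-resolution limited (steps of 5 and 20 threshold units).
* Weights are dense double precision; N = 10^4 fits comfortably (0.8 GB)
  but the O(N^2) build and per-spike O(N) propagation make N much beyond
  that impractical without a sparse or blocked implementation.
* Only the frozen-connectivity dynamics mode is implemented; there is no
  online plasticity during retrieval, by design.
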