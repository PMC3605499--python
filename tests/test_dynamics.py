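"""Network simulation: kernel, cue, noise, heterogeneity, grid dynamics."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import phasemem as pm
from phasemem.dynamics import SOURCE_CUE, SOURCE_NET, KernelParams
from phasemem.patterns import TWO_PI

KP = KernelParams()


class TestEpsilonKernel:
    def test_zero_for_non_positive_times(self):
        assert pm.epsilon(0.0) == 0.0
        assert pm.epsilon(-5.0) == 0.0
        assert np.all(pm.epsilon(np.array([-3.0, -0.1, 0.0])) == 0.0)

    def test_peak_location_and_normalisation(self):
        # closed form argmax tau_m tau_s/(tau_m - tau_s) ln(tau_m/tau_s) = 10 ln 2
        assert KP.t_peak == pytest.approx(10 * np.log(2), rel=1e-12)
        assert pm.epsilon(KP.t_peak) == pytest.approx(1.0, rel=1e-12)
        assert KP.K == pytest.approx(4.0, rel=1e-12)
        # numeric maximisation agrees with the closed form
        res = minimize_scalar(lambda t: -pm.epsilon(t), bounds=(0.1, 50), method="bounded")
        assert res.x == pytest.approx(KP.t_peak, abs=1e-4)

    def test_tail_value(self):
        assert pm.epsilon(100.0) == pytest.approx(
            4 * (np.exp(-10.0) - np.exp(-20.0)), rel=1e-12
        )

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            KernelParams(tau_m=5.0, tau_s=5.0)


class TestMakeCue:
    def test_default_cue_size_is_tenth(self):
        p = pm.generate_random_pattern(3000, 3.0, seed=1)
        times, units = pm.make_cue(p)
        assert times.size == units.size == 300

    def test_empty_cue(self):
        p = pm.generate_random_pattern(10, 3.0, seed=1)
        times, units = pm.make_cue(p, m=0)
        assert times.size == 0

    def test_m_larger_than_n_rejected(self):
        p = pm.generate_random_pattern(10, 3.0, seed=1)
        with pytest.raises(ValueError):
            pm.make_cue(p, m=11)

    def test_lowest_phase_units_and_short_span(self):
        # with uniform phases the M=N/10 lowest-phase cue spans ~T_stim/10
        p = pm.generate_random_pattern(3000, 3.0, seed=2)
        times, units = pm.make_cue(p, t_stim=50.0)
        expected = np.argsort(p.phases)[:300]
        assert set(units) == set(expected)
        assert np.all(np.diff(times) >= 0)
        assert times.max() - times.min() < 7.0  # "lasts less than ~5 ms"
        np.testing.assert_allclose(times, 50.0 * p.phases[units] / TWO_PI)

    def test_random_selection_reproducible(self):
        p = pm.generate_random_pattern(100, 3.0, seed=2)
        _, u1 = pm.make_cue(p, m=20, selection="random", seed=5)
        _, u2 = pm.make_cue(p, m=20, selection="random", seed=5)
        np.testing.assert_array_equal(u1, u2)


class TestNoise:
    def test_mean_interval_matches_configuration(self):
        params = pm.NoiseParams(tau_noise=10.0)
        times, units, _ = pm.make_noise_events(params, 200, 1000.0, seed=3)
        assert times.size > 10_000
        isis = []
        for u in range(200):
            t = np.sort(times[units == u])
            isis.append(np.diff(t))
        isis = np.concatenate(isis)
        se = isis.mean() / np.sqrt(isis.size)
        assert abs(isis.mean() - 10.0) < 3 * se

    def test_reproducible_under_seed(self):
        params = pm.NoiseParams(sigma_j=5.0)
        a = pm.make_noise_events(params, 20, 500.0, seed=9)
        b = pm.make_noise_events(params, 20, 500.0, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_zero_strength_noise_is_inert(self):
        # sigma=0, J_bar=0: events exist but never drive the network
        J = pm.build_connectivity([], n_units=30)
        cfg = pm.SimulationConfig(n_units=30, theta=1.0, duration=300.0, seed=4)
        train = pm.run(J, cfg, noise=pm.NoiseParams(sigma_j=0.0, j_bar=0.0))
        assert len(train) == 0


class TestHeterogeneousThresholds:
    def test_z_zero_uniform(self):
        th = pm.heterogeneous_thresholds(80.0, 0.0, 100, seed=1)
        np.testing.assert_array_equal(th, np.full(100, 80.0))

    def test_range_and_mean(self):
        th = pm.heterogeneous_thresholds(80.0, 0.5, 3000, seed=1)
        assert th.min() >= 40.0 and th.max() <= 120.0
        se = 80.0 * 0.5 / np.sqrt(3 * 3000)  # std of uniform(-1,1) is 1/sqrt(3)
        assert abs(th.mean() - 80.0) < 3 * se

    def test_degenerate_z_rejected(self):
        with pytest.raises(ValueError):
            pm.heterogeneous_thresholds(80.0, 1.0, 10, seed=0)


class TestRun:
    def test_zero_coupling_outputs_exactly_the_cue(self):
        p = pm.generate_random_pattern(50, 3.0, seed=6)
        J = pm.build_connectivity([], n_units=50)
        cfg = pm.SimulationConfig(n_units=50, theta=1.0, duration=200.0, seed=6)
        train = pm.run(J, cfg, cue=pm.CueSpec(pattern=p, m=5))
        times, units = pm.make_cue(p, m=5)
        assert len(train) == 5
        assert np.all(train.sources == SOURCE_CUE)
        np.testing.assert_array_equal(np.sort(train.units), np.sort(units))
        np.testing.assert_allclose(train.times, np.round(times / 0.1) * 0.1, atol=1e-9)

    def test_deterministic_event_lists(self, toy_retrieval):
        cfg = pm.SimulationConfig(n_units=100, theta=0.5, duration=400.0, seed=7)
        cue = pm.CueSpec(pattern=toy_retrieval["patterns"][0], m=30)
        noise = pm.NoiseParams(sigma_j=0.3)
        a = pm.run(toy_retrieval["J"], cfg, cue=cue, noise=noise)
        b = pm.run(toy_retrieval["J"], cfg, cue=cue, noise=noise)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.units, b.units)
        np.testing.assert_array_equal(a.sources, b.sources)

    def test_dimension_mismatch_rejected(self):
        J = pm.build_connectivity([], n_units=10)
        cfg = pm.SimulationConfig(n_units=11, theta=1.0, duration=10.0)
        with pytest.raises(ValueError):
            pm.run(J, cfg)

    def test_no_unit_fires_twice_in_one_step(self, toy_retrieval):
        train = toy_retrieval["train"]
        key = train.times * 1000 + train.units  # dt=0.1 -> unique per (step, unit)
        assert np.unique(np.round(key).astype(np.int64)).size == len(train)

    def test_threshold_weight_scaling_equivalence(self, toy_retrieval):
        # scaling both J and theta by c leaves the spike train unchanged
        c = 3.7
        J = toy_retrieval["J"]
        Jc = pm.SynapticMatrix(J.n_units, J.weights * c)
        cue = pm.CueSpec(pattern=toy_retrieval["patterns"][0], m=30)
        cfg1 = pm.SimulationConfig(n_units=100, theta=0.5, duration=400.0, seed=7)
        cfg2 = pm.SimulationConfig(n_units=100, theta=0.5 * c, duration=400.0, seed=7)
        a = pm.run(J, cfg1, cue=cue)
        b = pm.run(Jc, cfg2, cue=cue)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.units, b.units)

    def test_grid_convergence_smoke(self):
        # halving dt moves no spike of a transient response by more than the
        # coarse step
        patterns = pm.generate_pattern_set(1, 100, 3.0, seed=7)
        J = pm.build_connectivity(patterns)
        cue = pm.CueSpec(pattern=patterns[0], m=10)
        trains = {}
        for dt in (0.1, 0.05):
            cfg = pm.SimulationConfig(
                n_units=100, theta=3.0, duration=400.0, dt=dt, seed=7
            )
            trains[dt] = pm.run(J, cfg, cue=cue)
        a, b = trains[0.1], trains[0.05]
        assert len(a) == len(b)
        # compare per-unit spike times: simultaneous coarse-grid events may be
        # recorded in either order
        ka = np.lexsort((a.times, a.units))
        kb = np.lexsort((b.times, b.units))
        np.testing.assert_array_equal(a.units[ka], b.units[kb])
        assert np.max(np.abs(a.times[ka] - b.times[kb])) <= 0.1 + 1e-9

    def test_cue_spikes_reset_and_propagate(self, toy_retrieval):
        # cued units are tagged cue; network activity follows from them
        train = toy_retrieval["train"]
        cue_mask = train.sources == SOURCE_CUE
        assert cue_mask.sum() == 30
        assert (train.sources == SOURCE_NET).sum() > 1000
        assert train.times[cue_mask].max() < train.times[~cue_mask].max()

    def test_record_potentials_shape(self):
        J = pm.build_connectivity([], n_units=5)
        cfg = pm.SimulationConfig(
            n_units=5, theta=1.0, duration=10.0, record_potentials=True
        )
        train = pm.run(J, cfg)
        assert train.potentials.shape == (100, 5)
        np.testing.assert_array_equal(train.potentials, 0.0)
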