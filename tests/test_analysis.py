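"""Overlap order parameter, period estimation, regime classification."""

import numpy as np
import pytest

import phasemem as pm
from phasemem.analysis import NoPeriodError
from phasemem.dynamics import SOURCE_NET
from phasemem.patterns import TWO_PI

from conftest import make_pattern_train


def random_train(n_units, period, t_end, seed):
    """One spike per unit per cycle at i.i.d. random phases (unrelated to any pattern)."""
    rng = np.random.default_rng(seed)
    p = pm.PhasePattern(1, n_units, rng.uniform(0, TWO_PI, n_units), 1000.0 / period)
    return make_pattern_train(p, period, 0.0, t_end)


class TestEstimatePeriod:
    def test_perfectly_periodic_train(self):
        p = pm.generate_random_pattern(30, 3.0, seed=1)
        train = make_pattern_train(p, 40.0, 0.0, 400.0)
        assert pm.estimate_period(train, (0.0, 400.0)) == pytest.approx(40.0)

    def test_silent_window_raises(self):
        train = pm.SpikeTrain(np.empty(0), np.empty(0, int), np.empty(0, np.int8), 10, 100.0)
        with pytest.raises(NoPeriodError):
            pm.estimate_period(train, (0.0, 100.0))

    def test_methods_agree_on_clean_replay(self):
        # N=1000 replay is clean enough for the estimators to cross-validate;
        # on the N=100 toy the replay phases are too distorted for 2% agreement
        from dataclasses import replace

        patterns = pm.generate_pattern_set(1, 1000, 3.0, seed=11)
        proto = replace(pm.DESK_PROTOCOL, n_runs=1)
        _, train = pm.cued_trial(patterns, 20.0, proto, seed=11)
        t_isi = pm.estimate_period(train, (600.0, 1000.0))
        t_max = pm.estimate_period(
            train, (600.0, 1000.0), method="maximize-overlap",
            pattern=patterns[0], t_grid=np.arange(5.0, 150.0, 0.25),
        )
        assert t_max == pytest.approx(t_isi, rel=0.02)

    def test_unknown_method(self, toy_retrieval):
        with pytest.raises(ValueError):
            pm.estimate_period(toy_retrieval["train"], (0, 100), method="fft")


class TestOverlap:
    @pytest.mark.parametrize("period", [40.0, 333.33])
    def test_perfect_replay_gives_one_at_any_time_scale(self, period):
        p = pm.generate_random_pattern(200, 3.0, seed=2)
        train = make_pattern_train(p, period, 0.0, 5 * period)
        assert pm.overlap(train, p, period, 4.5 * period) == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_pair_cancels(self):
        p = pm.PhasePattern(1, 2, np.array([0.0, np.pi]), 1.0)
        train = pm.SpikeTrain(
            np.array([100.0, 100.0]), np.array([0, 1]),
            np.full(2, SOURCE_NET, np.int8), 2, 200.0,
        )
        assert pm.overlap(train, p, 50.0, 120.0) == pytest.approx(0.0, abs=1e-12)

    def test_random_phases_scale_as_inverse_sqrt_n(self):
        # |m| against an unrelated pattern is ~1/sqrt(N)
        p = pm.generate_random_pattern(3000, 3.0, seed=3)
        vals = [
            pm.overlap(random_train(3000, 50.0, 200.0, seed=s), p, 50.0, 150.0)
            for s in range(100)
        ]
        assert 0.01 < np.mean(vals) < 0.03

    def test_time_rescaling_invariance(self, toy_retrieval):
        train = toy_retrieval["train"]
        pattern = toy_retrieval["patterns"][0]
        T = pm.estimate_period(train, (600.0, 1000.0))
        base = pm.overlap(train, pattern, T, 900.0)
        for c in (2.0, 0.5):
            scaled = pm.SpikeTrain(
                train.times * c, train.units, train.sources,
                train.n_units, train.duration * c,
            )
            assert pm.overlap(scaled, pattern, T * c, 900.0 * c) == pytest.approx(
                base, abs=1e-9
            )

    def test_bounded_in_unit_interval(self, toy_retrieval):
        train = toy_retrieval["train"]
        for pattern in toy_retrieval["patterns"]:
            for t in (650.0, 800.0, 990.0):
                m = pm.overlap(train, pattern, 37.0, t)
                assert 0.0 <= m <= 1.0

    def test_invalid_period(self, toy_retrieval):
        with pytest.raises(ValueError):
            pm.overlap(toy_retrieval["train"], toy_retrieval["patterns"][0], 0.0, 100.0)


class TestReplayFrequencyAndRate:
    def test_frequency_from_period(self):
        p = pm.generate_random_pattern(30, 3.0, seed=1)
        train = make_pattern_train(p, 40.0, 0.0, 400.0)
        assert pm.replay_frequency(train, (0.0, 400.0)) == pytest.approx(25.0)

    def test_one_spike_per_cycle(self):
        p = pm.generate_random_pattern(30, 3.0, seed=1)
        train = make_pattern_train(p, 40.0, 0.0, 400.0)
        assert pm.spikes_per_cycle(train, 40.0, (0.0, 400.0)) == pytest.approx(1.0, rel=0.05)

    def test_window_doubling_consistency(self):
        p = pm.generate_random_pattern(30, 3.0, seed=1)
        train = make_pattern_train(p, 40.0, 0.0, 800.0)
        a = pm.spikes_per_cycle(train, 40.0, (0.0, 400.0))
        b = pm.spikes_per_cycle(train, 40.0, (0.0, 800.0))
        assert b == pytest.approx(a, rel=0.05)


class TestResponseSize:
    def test_counts_exclude_cue_events(self, toy_retrieval):
        train = toy_retrieval["train"]
        cue_end = train.times[train.sources == 0].max()
        s = pm.response_size(train, cue_end)
        assert s == int(((train.times > cue_end) & (train.sources != 0)).sum())
        assert s > 0

    def test_silent_train(self):
        train = pm.SpikeTrain(np.empty(0), np.empty(0, int), np.empty(0, np.int8), 10, 100.0)
        assert pm.response_size(train, 10.0) == 0


class TestClassifyRegime:
    def test_retrieval_on_toy_run(self, toy_retrieval):
        res = toy_retrieval["result"]
        assert res.regime == "retrieval"
        assert res.retrieved_pattern == 1
        assert res.mean_overlaps[1] > 0.9
        assert res.replay_frequency_hz is not None

    def test_silent_classification(self):
        p = pm.generate_random_pattern(20, 3.0, seed=1)
        # only an early transient, nothing after t_bar
        train = pm.SpikeTrain(
            np.array([1.0, 2.0]), np.array([0, 1]), np.full(2, SOURCE_NET, np.int8),
            20, 1000.0,
        )
        ov = pm.overlap_series(train, [p], window=(600.0, 1000.0))
        res = pm.classify_regime(train, ov)
        assert res.regime == "silent"
        assert res.replay_frequency_hz is None
        assert res.retrieved_pattern is None

    def test_spurious_classification(self):
        # persistent periodic activity with phases unrelated to the pattern
        p = pm.generate_random_pattern(1000, 3.0, seed=4)
        train = random_train(1000, 50.0, 1000.0, seed=5)
        ov = pm.overlap_series(train, [p], window=(600.0, 1000.0))
        res = pm.classify_regime(train, ov)
        assert res.regime == "spurious"
        assert res.mean_overlaps[1] < 0.1
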