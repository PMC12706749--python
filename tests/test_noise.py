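"""Equivalent continuous levels, masks, break delta and intermittency ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schoolenv import (
    MinuteSeries,
    NoiseMask,
    break_delta,
    intermittency_ratio,
    l_day_school,
    leq,
    leq_wk,
    noise_summary,
)
from schoolenv.series import school_day_mask
from .conftest import brute_force_leq


def _sound(values, start="2022-06-06"):
    idx = pd.date_range(start, periods=len(values), freq="min")
    return MinuteSeries("S1", idx, np.asarray(values, float), kind="sound")


class TestLeq:
    def test_constant(self):
        assert leq([50.0, 50.0, 50.0]) == pytest.approx(50.0)

    def test_two_level_hand_value(self):
        # 10·log10((10^4 + 10^6)/2) = 57.03
        assert leq([40.0, 60.0]) == pytest.approx(57.03, abs=0.01)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(35, 90, 200)
        assert leq(vals) == pytest.approx(leq(rng.permutation(vals)), abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            leq([])

    @given(st.lists(st.floats(20, 110), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_and_bounds(self, vals):
        got = leq(vals)
        assert got == pytest.approx(brute_force_leq(vals), abs=1e-9)
        assert min(vals) - 1e-9 <= got <= max(vals) + 1e-9

    def test_adding_minute_at_current_leq_is_neutral(self):
        vals = [48.0, 55.0, 62.0, 51.0]
        cur = leq(vals)
        assert leq(vals + [cur]) == pytest.approx(cur, abs=1e-9)

    def test_large_random_batch_matches_oracle(self):
        """1000 random series against the brute-force energy-sum oracle."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            vals = rng.uniform(25, 100, rng.integers(1, 40))
            assert abs(leq(vals) - brute_force_leq(vals)) <= 1e-9


class TestMaskedLevels:
    def test_school_day_mask_is_2100_minutes(self, week_index):
        assert int(school_day_mask(week_index).sum()) == 2100  # 35 h

    def test_constant_series(self, week_index):
        s = MinuteSeries("S1", week_index, np.full(10080, 57.0), kind="sound")
        assert l_day_school(s) == pytest.approx(57.0)
        assert leq_wk(s) == pytest.approx(57.0)

    def test_break_noise_excluded(self, week_index):
        """A series loud only during breaks reads at the base level."""
        mask_all = NoiseMask()
        in_school = mask_all.included_minutes(week_index)
        non_break = mask_all.minutes(week_index)
        values = np.full(10080, 50.0)
        values[in_school & ~non_break] = 95.0
        s = MinuteSeries("S1", week_index, values, kind="sound")
        assert l_day_school(s) == pytest.approx(50.0)

    def test_leq_wk_equals_l_day_on_school_only_series(self):
        idx = pd.date_range("2022-06-06 08:00", periods=60, freq="min")
        s = MinuteSeries("S1", idx, np.random.default_rng(1).uniform(50, 60, 60), kind="sound")
        assert leq_wk(s) == pytest.approx(l_day_school(s))

    def test_weekly_spike_hand_value(self):
        # 9 min at 50 + 1 min at 80 per block of 10 → 70.04 dBA
        vals = np.tile([50.0] * 9 + [80.0], 1008)
        assert leq_wk(_sound(vals)) == pytest.approx(70.04, abs=0.01)


class TestBreakDelta:
    def test_identical_strata_give_zero(self, week_index):
        s = MinuteSeries("S1", week_index, np.full(10080, 55.0), kind="sound")
        assert break_delta(s) == pytest.approx(0.0)

    def test_constant_offset_recovered(self, week_index):
        mask_all = NoiseMask()
        in_school = mask_all.included_minutes(week_index)
        non_break = mask_all.minutes(week_index)
        values = np.full(10080, 52.0)
        values[in_school & ~non_break] += 3.0
        s = MinuteSeries("S1", week_index, values, kind="sound")
        assert break_delta(s) == pytest.approx(3.0, abs=1e-9)

    def test_generator_break_boost_recovered(self):
        """Noiseless generated week recovers the configured break boost ±0.1 dBA."""
        from schoolenv import generate_sound_minutes
        from schoolenv.series import BREAK_WINDOWS

        idx = pd.date_range("2022-06-06", periods=10080, freq="min")
        series, _ = generate_sound_minutes(
            base_leq=54.0,
            event_rate=0.0,
            event_gain=0.0,
            n_minutes=10080,
            seed=5,
            jitter_sd=0.0,
            timestamps=idx,
            break_boost=0.7,
            break_windows=BREAK_WINDOWS,
        )
        assert break_delta(series) == pytest.approx(0.7, abs=0.1)

    def test_missing_stratum_errors(self):
        idx = pd.date_range("2022-06-06 09:30", periods=30, freq="min")  # breaks only
        s = MinuteSeries("S1", idx, np.full(30, 60.0), kind="sound")
        with pytest.raises(ValueError):
            break_delta(s)


class TestIntermittencyRatio:
    def test_constant_series_is_zero(self):
        assert intermittency_ratio(_sound([55.0] * 1440)) == 0.0

    def test_single_spike_hand_value(self):
        """One day, 9 min at 50 + 1 at 80: Leq 70.04, cutoff 73.04, IR 99.1%."""
        vals = [50.0] * 9 + [80.0]
        expected = 100 * 1e8 / (9 * 1e5 + 1e8)
        got = intermittency_ratio(_sound(vals))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(99.1, abs=0.05)

    def test_bounded_zero_to_hundred(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            vals = rng.uniform(30, 95, 300)
            ir = intermittency_ratio(_sound(vals))
            assert 0.0 <= ir <= 100.0

    def test_level_shift_invariance(self):
        """A uniform dBA offset shifts cutoff and energies together."""
        rng = np.random.default_rng(4)
        vals = rng.uniform(40, 85, 1440)
        a = intermittency_ratio(_sound(vals))
        b = intermittency_ratio(_sound(vals + 12.5))
        assert a == pytest.approx(b, abs=1e-9)

    def test_monotone_in_spike_amplitude(self):
        """Growing a single event's level never lowers the IR (oracle sweep)."""
        base = np.full(600, 50.0)
        irs = []
        for spike in (60.0, 70.0, 80.0, 90.0):
            vals = base.copy()
            vals[300] = spike
            irs.append(intermittency_ratio(_sound(vals)))
        assert all(a <= b + 1e-12 for a, b in zip(irs, irs[1:]))

    def test_boundary_minute_is_not_event(self):
        """Minutes at exactly Leq_day + K do not count as events."""
        # craft: values v and one minute at exactly leq+3 → IR 0
        vals = np.full(100, 50.0)
        base_leq = 10 * np.log10(np.mean(10 ** (vals / 10)))
        s = _sound(list(vals))
        assert intermittency_ratio(s, threshold_k=0.0) == 0.0  # all equal the Leq

    def test_aggregation_switch(self):
        """Energy-weighted and arithmetic day aggregation differ on unequal days."""
        quiet = [50.0] * 9 + [80.0]
        loud = [70.0] * 10
        vals = quiet * 144 + loud * 144  # two days
        s = _sound(vals)
        e = intermittency_ratio(s, aggregate="energy")
        a = intermittency_ratio(s, aggregate="arithmetic")
        assert e != pytest.approx(a)

    def test_event_generator_dominant_events(self):
        """1 event/h at +30 dBA over a week pushes IR above 90%."""
        from schoolenv import generate_sound_minutes

        series, events = generate_sound_minutes(
            base_leq=50.0, event_rate=1.0, event_gain=30.0, n_minutes=10080, seed=2,
            jitter_sd=0.0,
        )
        # brute-force energy fraction on the generated series
        e = 10 ** (series.values / 10)
        frac = 100 * e[events].sum() / e.sum()
        assert frac > 90
        assert intermittency_ratio(series) > 90

    def test_zero_event_gain_matches_no_events(self):
        from schoolenv import generate_sound_minutes

        with_gain, _ = generate_sound_minutes(50.0, 2.0, 0.0, 1440, seed=3, jitter_sd=1.0)
        assert intermittency_ratio(with_gain) == pytest.approx(
            intermittency_ratio(_sound(with_gain.values)), abs=1e-9
        )


class TestSummary:
    def test_minutes_used_reported(self, week_index):
        s = MinuteSeries("S1", week_index, np.full(10080, 55.0), kind="sound")
        res = noise_summary(s)
        assert res.minutes_used == {"l_day_school": 2100, "leq_wk": 10080, "ir": 10080}
        assert res.ir == 0.0
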