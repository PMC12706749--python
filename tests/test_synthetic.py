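"""Synthetic study generator: determinism, self-consistency, recovery hooks."""

import numpy as np
import pandas as pd
import pytest

from schoolenv import (
    AnnoyParams,
    SimConfig,
    generate_sound_minutes,
    generate_study,
    generate_survey,
)
from schoolenv.synthetic import ConfigError, weekly_temporal_field


class TestConfig:
    def test_invalid_fields_named_in_error(self):
        with pytest.raises(ConfigError, match="n_schools"):
            SimConfig(n_schools=0).validate()
        with pytest.raises(ConfigError, match="harmattan_weeks"):
            SimConfig(weeks=4, harmattan_weeks=frozenset({9})).validate()
        with pytest.raises(ConfigError, match="minutes_per_week"):
            SimConfig(minutes_per_week=100).validate()
        with pytest.raises(ConfigError, match="noise_base_range"):
            SimConfig(noise_base_range=(60.0, 50.0)).validate()


class TestDeterminism:
    def test_identical_seed_bit_identical_bundles(self):
        cfg = SimConfig(n_schools=4, n_fixed_sites=3, weeks=2,
                        harmattan_weeks=frozenset({2}), seed=1)
        b1, t1 = generate_study(cfg)
        b2, t2 = generate_study(cfg)
        f1, f2 = b1.to_frames(), b2.to_frames()
        assert set(f1) == set(f2)
        for key in f1:
            pd.testing.assert_frame_equal(f1[key], f2[key])
        pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())

    def test_different_seed_differs(self):
        cfg1 = SimConfig(n_schools=4, n_fixed_sites=3, weeks=2,
                         harmattan_weeks=frozenset({2}), seed=1)
        cfg2 = SimConfig(n_schools=4, n_fixed_sites=3, weeks=2,
                         harmattan_weeks=frozenset({2}), seed=2)
        m1 = generate_study(cfg1)[0].to_frames()["school_minutes"]
        m2 = generate_study(cfg2)[0].to_frames()["school_minutes"]
        assert not m1["value"].equals(m2["value"])


class TestTemporalField:
    def test_mean_one_within_1e12(self):
        field = weekly_temporal_field(SimConfig(weeks=18, seed=5))
        assert np.mean(list(field.values())) == pytest.approx(1.0, abs=1e-12)

    def test_zero_amplitude_gives_flat_field(self):
        cfg = SimConfig(weeks=6, harmattan_weeks=frozenset({5, 6}),
                        temporal_field_amplitude=0.0, seed=3)
        field = weekly_temporal_field(cfg)
        assert all(v == 1.0 for v in field.values())

    def test_harmattan_weeks_elevated(self):
        cfg = SimConfig(weeks=18, seed=6)
        field = weekly_temporal_field(cfg)
        h = [field[w] for w in cfg.harmattan_weeks]
        nh = [field[w] for w in field if w not in cfg.harmattan_weeks]
        assert np.mean(h) > np.mean(nh)


class TestBundleConsistency:
    def test_deployment_minutes_complete_and_unique(self, small_study):
        bundle, _truth = small_study
        for dep in bundle.deployments.values():
            assert len(dep.continuous_pm) == 10080
            assert not dep.continuous_pm.timestamps.has_duplicates
            assert dep.continuous_pm.timestamps.is_monotonic_increasing
            assert dep.sound.timestamps.equals(dep.continuous_pm.timestamps)

    def test_filter_mass_implies_true_concentration(self, small_study):
        """Gravimetric concentration from the filter equals the biased series
        mean times the true CF (the generator is self-consistent)."""
        from schoolenv import gravimetric_concentration, qc_filter_sample

        bundle, truth = small_study
        for school, dep in bundle.deployments.items():
            if not qc_filter_sample(dep.filter_sample).valid:
                continue
            grav = gravimetric_concentration(dep.filter_sample)
            cf = truth.instrument_cf_by_season[dep.season]
            # the observed continuous mean carries monitor noise; tolerance is
            # the 1/sqrt(10080) sampling error of that noise
            assert grav == pytest.approx(dep.continuous_pm.mean() * cf, rel=0.01)

    def test_seasonal_cf_recovery(self):
        """≥30 collocations per season recover CFs 1.12 / 0.83 within ±0.02."""
        from schoolenv import run_pipeline

        cfg = SimConfig(
            n_schools=90,
            weeks=18,
            harmattan_weeks=frozenset(range(12, 19)),
            invalid_filter_rate=0.0,
            seed=77,
        )
        bundle, truth = generate_study(cfg)
        res = run_pipeline(bundle)
        assert res.seasonal_cfs["Harmattan"].n_collocations >= 30
        assert res.seasonal_cfs["non-Harmattan"].n_collocations >= 30
        assert res.seasonal_cfs["Harmattan"].value == pytest.approx(1.12, abs=0.02)
        assert res.seasonal_cfs["non-Harmattan"].value == pytest.approx(0.83, abs=0.02)


class TestSoundGenerator:
    def test_no_events_no_jitter_is_constant(self):
        series, events = generate_sound_minutes(50.0, 0.0, 20.0, 100, seed=1, jitter_sd=0.0)
        assert np.all(series.values == 50.0)
        assert not events.any()

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValueError):
            generate_sound_minutes(50.0, 1.0, 10.0, 0, seed=1)

    def test_event_minutes_recorded(self):
        series, events = generate_sound_minutes(50.0, 6.0, 25.0, 10080, seed=4, jitter_sd=0.0)
        assert np.all(series.values[events] == 75.0)
        assert np.all(series.values[~events] == 50.0)
        # ~6/h × 168 h ≈ 1008 events
        assert 800 < events.sum() < 1250


class TestSurveyGenerator:
    def test_zero_slope_flat_ha(self):
        levels = {f"S{i}": 45.0 + i for i in range(10)}
        params = AnnoyParams(intercept=0.0, slope=0.0, n_children_per_school=300)
        rs = generate_survey(levels, params, seed=2)
        from schoolenv import ha_numeric

        props = [
            ha_numeric([r for r in rs if r.school_id == s], source="road_traffic")
            for s in levels
        ]
        assert np.ptp(props) < 12  # binomial noise only (p=0.5, n=300)

    def test_steep_slope_saturates(self):
        levels = {"low": 50.0, "high": 70.0}
        params = AnnoyParams(intercept=-60 * 5.0, slope=5.0, n_children_per_school=100)
        rs = generate_survey(levels, params, seed=3)
        from schoolenv import ha_numeric

        low = ha_numeric([r for r in rs if r.school_id == "low"], source="road_traffic")
        high = ha_numeric([r for r in rs if r.school_id == "high"], source="road_traffic")
        assert low < 2 and high > 98

    def test_verbal_coupled_to_numeric(self):
        levels = {"S1": 60.0}
        rs = generate_survey(levels, AnnoyParams(n_children_per_school=50), seed=4)
        from schoolenv.synthetic import verbal_from_numeric

        assert all(r.verbal == verbal_from_numeric(r.numeric) for r in rs)

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError):
            generate_survey({"S1": 60.0}, AnnoyParams(intercept=float("nan")), seed=1)
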