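"""Synthetic campaign generator: determinism, schema, study conditions and
closure of the generate -> calibrate loop."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from thermovote import synthetic_data as sd
from thermovote.calibration import calibrate_cohort
from thermovote.outdoor_climate import attach_rmot
from thermovote.survey_pipeline import filter_samples


class TestOutdoorSeries:
    def test_deterministic_under_seed(self):
        cfg = sd.SyntheticConfig()
        a = sd.generate_outdoor_series(cfg, 5)
        b = sd.generate_outdoor_series(cfg, 5)
        pd.testing.assert_frame_equal(a, b)
        c = sd.generate_outdoor_series(cfg, 6)
        assert not a["t_min"].equals(c["t_min"])

    def test_zero_weather_noise_gives_smooth_reference(self):
        cfg = sd.SyntheticConfig(outdoor_noise_sd=0.0)
        series = sd.generate_outdoor_series(cfg, 1)
        t_ref = (series["t_min"] + series["t_max"]) / 2
        # pure seasonal sinusoid: day-to-day steps bounded by the derivative
        assert np.abs(np.diff(t_ref)).max() < 2 * np.pi * cfg.outdoor_amplitude / 365 + 1e-9

    def test_min_never_exceeds_max_and_no_gaps(self):
        series = sd.generate_outdoor_series(sd.SyntheticConfig(), 2)
        assert (series["t_min"] <= series["t_max"]).all()
        deltas = pd.to_datetime(pd.Series(series["date"])).diff().dropna()
        assert (deltas == pd.Timedelta(days=1)).all()

    def test_rmot_spans_at_least_ten_degrees(self):
        cfg = sd.SyntheticConfig()
        series = sd.generate_outdoor_series(cfg, 3)
        out = attach_rmot(series)
        rmot = out.set_index("date").loc[cfg.survey_days, "rmot"]
        assert rmot.max() - rmot.min() >= 10.0


class TestRespondents:
    def test_forced_single_cell(self):
        cfg = sd.SyntheticConfig(n_days=2, n_respondents=40,
                                 cell_counts=(("female", 65, 75, 40),))
        records, _ = sd.generate_respondents(cfg, 0)
        assert (records["gender"] == "female").all()
        assert records["age"].between(65, 75).all()

    def test_default_cell_counts(self):
        records, truth = sd.generate_respondents(sd.SyntheticConfig(), 0)
        assert len(records) == 1121
        cells = {
            ("male", 30, 40): 60, ("female", 30, 40): 50,
            ("male", 65, 75): 128, ("female", 65, 75): 224,
        }
        for (gender, lo, hi), n in cells.items():
            sel = records[(records["gender"] == gender) & records["age"].between(lo, hi)]
            assert len(sel) == n
        # remainder skew: more females than males overall
        assert (records["gender"] == "female").sum() > (records["gender"] == "male").sum()

    def test_true_rates_positive_and_age_ordered(self, default_campaign):
        truth = default_campaign.truth.merge(default_campaign.survey, on="respondent_id")
        assert (truth["true_met_wm2"] > 0).all()
        adult = truth[truth["age"].between(30, 40)]["true_met_wm2"].median()
        elderly = truth[truth["age"].between(65, 75)]["true_met_wm2"].median()
        assert adult > elderly


class TestVotes:
    def test_votes_within_scale_and_climate_in_range(self, default_campaign):
        survey = default_campaign.survey
        assert survey["tsv"].between(-3, 3).all()
        assert survey["preference"].between(-2, 2).all()
        indoor = default_campaign.indoor_daily
        assert indoor["air_temp"].between(19.5, 24.0).all()
        assert (indoor["rel_humidity"] - 0.5).abs().max() < 0.05
        assert (indoor["air_speed"] < 0.2).all()

    def test_zero_contamination_passes_filter_untouched(self, default_campaign):
        kept, log = filter_samples(default_campaign.survey)
        assert log == {}
        assert len(kept) == len(default_campaign.survey)

    def test_contamination_is_caught_by_filter(self):
        cfg = sd.SyntheticConfig(contaminated_fraction=0.10)
        camp = sd.generate_campaign(cfg, seed=2)
        kept, log = filter_samples(camp.survey)
        n_bad = round(0.10 * len(camp.survey))
        assert sum(log.values()) == n_bad
        assert len(kept) == len(camp.survey) - n_bad

    def test_noiseless_zero_beta_calibration_recovers_truth(self):
        cfg = sd.SyntheticConfig(
            n_days=5, n_respondents=150,
            cell_counts=(("male", 30, 40, 30), ("female", 65, 75, 60)),
            tsv_noise_sd=0.0, day_effect_sd=0.0,
            true_beta_rmot=0.0, true_intercept=0.0,
        )
        camp = sd.generate_campaign(cfg, seed=3)
        results, _ = calibrate_cohort(camp.survey, camp.indoor_daily)
        merged = results.merge(camp.truth, on="respondent_id")
        err = (merged["met_rate_wm2"] - merged["true_met_wm2"]).abs()
        assert err.max() < 1e-2
        assert (merged["residual"] < 1e-5).all()

    def test_clothing_couples_to_outdoor_climate(self, default_campaign):
        out = attach_rmot(default_campaign.outdoor)
        rmot = dict(zip((d.isoformat() for d in out["date"]), out["rmot"]))
        survey = default_campaign.survey
        r = np.corrcoef(survey["clothing_clo"],
                        [rmot[d] for d in survey["survey_day"]])[0, 1]
        assert r < -0.3  # lighter ensembles on warm-outdoor days


class TestCampaignAndIo:
    def test_full_determinism(self, small_config):
        a = sd.generate_campaign(small_config, seed=9)
        b = sd.generate_campaign(small_config, seed=9)
        pd.testing.assert_frame_equal(a.survey, b.survey)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_seed_changes_data_not_schema(self, small_config):
        a = sd.generate_campaign(small_config, seed=9)
        b = sd.generate_campaign(small_config, seed=10)
        assert list(a.survey.columns) == list(b.survey.columns)
        assert not a.survey["tsv"].equals(b.survey["tsv"])

    def test_emit_read_round_trip(self, small_config, tmp_path):
        camp = sd.generate_campaign(small_config, seed=9)
        sd.emit_dataset(camp, tmp_path)
        back = sd.read_dataset(tmp_path)
        for col in ("tsv", "clothing_clo", "age"):
            assert np.array_equal(back.survey[col].to_numpy(), camp.survey[col].to_numpy())
        assert np.array_equal(back.truth["true_met_wm2"].to_numpy(),
                              camp.truth["true_met_wm2"].to_numpy())
        assert back.meta["seed"] == 9

    def test_truth_sidecar_not_part_of_survey_table(self, small_config, tmp_path):
        camp = sd.generate_campaign(small_config, seed=9)
        sd.emit_dataset(camp, tmp_path)
        survey = pd.read_csv(tmp_path / "survey.csv")
        assert "true_met_wm2" not in survey.columns

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sd.SyntheticConfig(n_days=0)
        with pytest.raises(ValueError):
            sd.SyntheticConfig(contaminated_fraction=1.5)
        with pytest.raises(ValueError):
            sd.SyntheticConfig(indoor_temp_range=(24.0, 19.5))

    def test_config_is_frozen(self, small_config):
        with pytest.raises(dataclasses.FrozenInstanceError):
            small_config.n_days = 10
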