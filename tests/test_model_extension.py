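"""Residual screening and the RMOT / preference extensions."""

import numpy as np
import pandas as pd
import pytest

from thermovote import model_extension as me


def rmot_series(n=35, seed=0):
    rng = np.random.default_rng(seed)
    return np.sort(rng.uniform(2, 18, n))


class TestScreening:
    def test_self_correlation(self):
        resid = np.array([0.1, -0.2, 0.3, 0.05, -0.4])
        report = me.screen_residual_correlations(resid, pd.DataFrame({"self": resid}))
        assert report.loc[0, "r"] == pytest.approx(1.0)
        assert bool(report.loc[0, "relevant"])

    def test_anti_correlation(self):
        resid = np.array([0.1, -0.2, 0.3, 0.05, -0.4])
        report = me.screen_residual_correlations(resid, pd.DataFrame({"neg": -resid}))
        assert report.loc[0, "r"] == pytest.approx(-1.0)
        assert bool(report.loc[0, "relevant"])  # magnitude criterion

    def test_zero_variance_candidate_skipped(self):
        resid = np.array([0.1, -0.2, 0.3])
        report = me.screen_residual_correlations(
            resid, pd.DataFrame({"const": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        )
        assert list(report["variable"]) == ["ok"]

    def test_null_false_positive_rate_at_35_days(self):
        # independent noise candidate, n = 35: |r| >= 0.3 should flag in
        # roughly a tenth of replicates
        rng = np.random.default_rng(99)
        flagged = 0
        n_rep = 500
        for _ in range(n_rep):
            resid = rng.normal(0, 1, 35)
            cand = pd.DataFrame({"noise": rng.normal(0, 1, 35)})
            report = me.screen_residual_correlations(resid, cand)
            flagged += bool(report.loc[0, "relevant"])
        assert 0.04 < flagged / n_rep < 0.13

    def test_sorted_by_magnitude(self):
        rng = np.random.default_rng(1)
        resid = rng.normal(0, 1, 35)
        cand = pd.DataFrame({
            "strong": resid + rng.normal(0, 0.3, 35),
            "weak": rng.normal(0, 1, 35),
        })
        report = me.screen_residual_correlations(resid, cand)
        assert list(report["variable"]) == ["strong", "weak"]


class TestRmotExtension:
    def test_zero_residuals_give_zero_coefficients(self):
        model = me.fit_rmot_extension(np.zeros(35), rmot_series())
        assert model.beta_rmot == pytest.approx(0.0, abs=1e-14)
        assert model.intercept_rmot == pytest.approx(0.0, abs=1e-14)

    def test_noiseless_recovery_of_injected_coefficients(self):
        rmot = rmot_series()
        resid = -0.024 * rmot + 0.264
        model = me.fit_rmot_extension(resid, rmot)
        assert model.beta_rmot == pytest.approx(-0.024, abs=1e-10)
        assert model.intercept_rmot == pytest.approx(0.264, abs=1e-10)

    def test_constant_rmot_rejected(self):
        with pytest.raises(ValueError):
            me.fit_rmot_extension(np.zeros(10), np.full(10, 11.0))

    def test_day_level_ci_coverage(self):
        # day-level noise on the injected affine truth: the 95 % slope CI
        # should cover it in about 95 % of replicates
        rng = np.random.default_rng(21)
        n_rep, cover = 200, 0
        for _ in range(n_rep):
            rmot = np.sort(rng.uniform(2, 18, 35))
            resid = -0.024 * rmot + 0.264 + rng.normal(0, 0.15, 35)
            model = me.fit_rmot_extension(resid, rmot)
            lo, hi = model.beta_rmot_ci95
            cover += lo <= -0.024 <= hi
        assert 0.89 <= cover / n_rep <= 0.99


class TestPredictStar:
    def test_cancellation_point(self):
        model = me.ExtendedModel(beta_rmot=-0.024, intercept_rmot=0.264)
        assert me.predict_pmv_star(0.0, 11.0, model) == pytest.approx(0.0, abs=1e-12)

    def test_affine_structure(self):
        model = me.ExtendedModel(beta_rmot=-0.024, intercept_rmot=0.264)
        assert me.predict_pmv_star(0.7, 0.0, model) == pytest.approx(0.964)

    def test_identity_when_unfitted(self):
        model = me.ExtendedModel()
        x = np.array([-0.4, 0.0, 0.9])
        assert np.allclose(me.predict_pmv_star(x, [5.0, 10.0, 15.0], model), x)


class TestPreferenceExtension:
    def test_zero_residuals(self):
        model = me.fit_preference_extension(np.zeros(10), np.linspace(-1, 1, 10),
                                            me.ExtendedModel())
        assert model.beta_pref == pytest.approx(0.0, abs=1e-14)
        assert model.intercept_pref == pytest.approx(0.0, abs=1e-14)

    def test_noiseless_recovery(self):
        pref = np.linspace(-1.5, 1.0, 35)
        resid = -0.742 * pref + 0.035
        model = me.fit_preference_extension(resid, pref, me.ExtendedModel())
        assert model.beta_pref == pytest.approx(-0.742, abs=1e-10)
        assert model.intercept_pref == pytest.approx(0.035, abs=1e-10)

    def test_constant_preference_rejected(self):
        with pytest.raises(ValueError):
            me.fit_preference_extension(np.zeros(10), np.zeros(10), me.ExtendedModel())


class TestPostExtension:
    def test_residuals_orthogonal_to_fitted_variable(self):
        rng = np.random.default_rng(3)
        rmot = rmot_series(seed=3)
        resid = -0.024 * rmot + 0.264 + rng.normal(0, 0.1, 35)
        model = me.fit_rmot_extension(resid, rmot)
        resid_star = resid - (model.beta_rmot * rmot + model.intercept_rmot)
        report = me.post_extension_screen(resid_star, pd.DataFrame({"rmot": rmot}))
        assert abs(report.loc[0, "r"]) < 1e-10

    def test_refit_on_corrected_residuals_is_zero(self):
        rng = np.random.default_rng(4)
        rmot = rmot_series(seed=4)
        resid = -0.03 * rmot + 0.2 + rng.normal(0, 0.1, 35)
        model = me.fit_rmot_extension(resid, rmot)
        resid_star = resid - (model.beta_rmot * rmot + model.intercept_rmot)
        refit = me.fit_rmot_extension(resid_star, rmot)
        assert refit.beta_rmot == pytest.approx(0.0, abs=1e-12)
        assert refit.intercept_rmot == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_residuals_empty_report(self):
        report = me.post_extension_screen(np.zeros(10),
                                          pd.DataFrame({"x": np.arange(10.0)}))
        assert report.empty

    def test_collinear_confound_decorrelated_with_fitted_variable(self):
        # clothing generated as a function of RMOT: correlated with the
        # raw residuals, de-correlated once RMOT is absorbed
        rng = np.random.default_rng(8)
        rmot = rmot_series(seed=8)
        clo = 0.95 - 0.012 * (rmot - rmot.mean()) + rng.normal(0, 0.02, 35)
        resid = -0.024 * rmot + 0.264 + rng.normal(0, 0.03, 35)
        pre = me.screen_residual_correlations(resid, pd.DataFrame({"clo": clo}))
        assert bool(pre.loc[0, "relevant"])
        model = me.fit_rmot_extension(resid, rmot)
        resid_star = resid - (model.beta_rmot * rmot + model.intercept_rmot)
        post = me.post_extension_screen(resid_star, pd.DataFrame({"clo": clo}))
        assert not post["relevant"].any()


def test_model_serialization_round_trip(tmp_path):
    model = me.ExtendedModel(beta_rmot=-0.024, intercept_rmot=0.264,
                             beta_pref=-0.742, intercept_pref=0.035, fitted_on=35,
                             beta_rmot_ci95=(-0.03, -0.018))
    model.screening_report = pd.DataFrame(
        [{"variable": "rmot", "r": -0.54, "p_value": 0.001, "relevant": True}]
    )
    path = tmp_path / "model.json"
    me.save_model(model, path)
    back = me.load_model(path)
    assert back.beta_rmot == model.beta_rmot
    assert back.beta_pref == model.beta_pref
    assert back.beta_rmot_ci95 == model.beta_rmot_ci95
    assert back.screening_report.loc[0, "variable"] == "rmot"
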