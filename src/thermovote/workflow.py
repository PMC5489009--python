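"""End-to-end campaign analysis: filter -> aggregate -> calibrate ->
evaluate -> extend.

Glue over the individual modules; each step remains usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import calibration, cohort_stats, model_extension, survey_pipeline
from .heat_balance import MET_WM2
from .survey_pipeline import RegressionFit

__all__ = ["CampaignAnalysis", "analyze_campaign"]


@dataclass
class CampaignAnalysis:
    """All intermediate and final products of one campaign analysis."""

    records: pd.DataFrame
    exclusion_log: dict
    daily: pd.DataFrame
    calibration_results: pd.DataFrame
    calibration_summary: dict
    fit_std: RegressionFit
    fit_met: RegressionFit
    fit_star: RegressionFit
    fit_double_star: RegressionFit | None
    extension: model_extension.ExtendedModel
    screening_pre: pd.DataFrame
    screening_post: pd.DataFrame
    group_comparisons: list = field(default_factory=list)


def analyze_campaign(
    survey: pd.DataFrame,
    indoor_daily: pd.DataFrame,
    outdoor,
    met_std_wm2: float = survey_pipeline.A_PRIORI_MET * MET_WM2,
    fit_preference: bool = True,
    compare_groups: bool = True,
) -> CampaignAnalysis:
    """Run the full analysis on one campaign's tables.

    Steps: sample filtering; per-respondent metabolic-rate calibration
    against daily mean climate; daily aggregation with the a-priori
    (``met_std_wm2``) and calibrated-median PMVs; identity regressions of
    AMV on each predictor; residual screening; RMOT extension (PMV*) and
    optional preference extension (PMV**); adult/elderly subgroup
    comparison of the calibrated rates.
    """
    records, log = survey_pipeline.filter_samples(survey)
    if records.empty:
        raise ValueError("no records survive filtering")

    cal_results, cal_summary = calibration.calibrate_cohort(records, indoor_daily)
    med_wm2 = cal_summary["median_met_wm2"]

    daily = survey_pipeline.aggregate_daily(
        records, indoor_daily, outdoor, met_std_wm2=met_std_wm2, met_cal_wm2=med_wm2
    )

    fit_std = survey_pipeline.fit_identity_regression(daily["amv"], daily["pmv_std"])
    fit_met = survey_pipeline.fit_identity_regression(daily["amv"], daily["pmv_met"])

    residuals = (daily["amv"] - daily["pmv_met"]).to_numpy()
    candidates = daily[["rmot", "mean_clo", "rel_humidity"]]
    screening_pre = model_extension.screen_residual_correlations(residuals, candidates)

    model = model_extension.fit_rmot_extension(residuals, daily["rmot"].to_numpy())
    model.screening_report = screening_pre
    daily = daily.assign(
        pmv_star=model_extension.predict_pmv_star(daily["pmv_met"], daily["rmot"], model)
    )
    fit_star = survey_pipeline.fit_identity_regression(daily["amv"], daily["pmv_star"])

    residuals_star = (daily["amv"] - daily["pmv_star"]).to_numpy()
    screening_post = model_extension.post_extension_screen(residuals_star, candidates)

    fit_double_star = None
    if fit_preference:
        model = model_extension.fit_preference_extension(
            residuals_star, daily["mean_preference"].to_numpy(), model
        )
        daily = daily.assign(
            pmv_double_star=model_extension.predict_pmv_double_star(
                daily["pmv_star"], daily["mean_preference"], model
            )
        )
        fit_double_star = survey_pipeline.fit_identity_regression(
            daily["amv"], daily["pmv_double_star"]
        )

    comparisons = []
    if compare_groups:
        comparisons = cohort_stats.compare_age_groups(cal_results, records)

    return CampaignAnalysis(
        records=records,
        exclusion_log=log,
        daily=daily,
        calibration_results=cal_results,
        calibration_summary=cal_summary,
        fit_std=fit_std,
        fit_met=fit_met,
        fit_star=fit_star,
        fit_double_star=fit_double_star,
        extension=model,
        screening_pre=screening_pre,
        screening_post=screening_post,
        group_comparisons=comparisons,
    )
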