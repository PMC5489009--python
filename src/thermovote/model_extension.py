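"""Residual screening and the outdoor-climate / preference extensions.

After calibrating the metabolic rate, day-level prediction residuals
(AMV - PMV_met) are screened for Pearson correlation with candidate
variables; |r| >= 0.3 is treated as relevant (the conventional threshold
for subjective human-response studies).  A relevant running-mean-outdoor-
temperature (RMOT) correlation is absorbed into the extended predictor

    PMV* = PMV_met + b_rmot * RMOT + c_rmot

by ordinary least squares on the residuals, and the remaining residuals
(AMV - PMV*) can be further extended with the day-mean thermal preference
vote to give PMV**.  PMV** is a diagnostic: preference is not known ahead
of time, so it has little value in a predictive model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RELEVANCE_THRESHOLD",
    "ExtendedModel",
    "screen_residual_correlations",
    "fit_rmot_extension",
    "predict_pmv_star",
    "fit_preference_extension",
    "predict_pmv_double_star",
    "post_extension_screen",
    "save_model",
    "load_model",
]

#: |Pearson r| at or above which a residual correlation is "relevant"
RELEVANCE_THRESHOLD = 0.3


@dataclass
class ExtendedModel:
    """Affine correction coefficients for the extended predictors."""

    beta_rmot: float = 0.0
    intercept_rmot: float = 0.0
    beta_pref: float = 0.0
    intercept_pref: float = 0.0
    fitted_on: int = 0
    beta_rmot_ci95: tuple[float, float] | None = None
    intercept_rmot_ci95: tuple[float, float] | None = None
    screening_report: pd.DataFrame | None = field(default=None, repr=False)


def screen_residual_correlations(
    residuals,
    candidates: pd.DataFrame,
    threshold: float = RELEVANCE_THRESHOLD,
) -> pd.DataFrame:
    """Pearson r (and two-sided p) between day-level residuals and each
    candidate column; rows sorted by |r| descending with a ``relevant``
    flag at ``|r| >= threshold``.

    Zero-variance candidates (or residuals) make r undefined and are
    skipped; with zero-variance residuals the report is empty.
    """
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) < 3:
        raise ValueError("need at least 3 days to screen correlations")
    if len(candidates) != len(residuals):
        raise ValueError("residuals and candidate table lengths differ")
    rows = []
    resid_const = np.ptp(residuals) == 0
    for name in candidates.columns:
        x = candidates[name].to_numpy(dtype=float)
        if resid_const or np.ptp(x) == 0:
            continue
        r, p = stats.pearsonr(residuals, x)
        rows.append({"variable": name, "r": float(r), "p_value": float(p),
                     "relevant": abs(r) >= threshold})
    report = pd.DataFrame(rows, columns=["variable", "r", "p_value", "relevant"])
    if not report.empty:
        report = report.reindex(
            report["r"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return report


def _ols_line(y, x):
    model = sm.OLS(np.asarray(y, float), sm.add_constant(np.asarray(x, float))).fit()
    ci = model.conf_int(alpha=0.05)
    return model, (float(ci[1, 0]), float(ci[1, 1])), (float(ci[0, 0]), float(ci[0, 1]))


def fit_rmot_extension(residuals, rmot, model: ExtendedModel | None = None) -> ExtendedModel:
    """OLS of day-level residuals (AMV - PMV_met) on RMOT.

    Stores the slope/intercept (with 95 % CIs) into a new or supplied
    :class:`ExtendedModel`."""
    rmot = np.asarray(rmot, dtype=float)
    if np.ptp(rmot) == 0:
        raise ValueError("RMOT is constant over the fitted days; slope undefined")
    fit, slope_ci, _ = _ols_line(residuals, rmot)
    out = model if model is not None else ExtendedModel()
    out.beta_rmot = float(fit.params[1])
    out.intercept_rmot = float(fit.params[0])
    out.beta_rmot_ci95 = slope_ci
    ci0 = fit.conf_int(alpha=0.05)
    out.intercept_rmot_ci95 = (float(ci0[0, 0]), float(ci0[0, 1]))
    out.fitted_on = int(fit.nobs)
    return out


def predict_pmv_star(pmv_met, rmot, model: ExtendedModel):
    """PMV* = PMV_met + b_rmot * RMOT + c_rmot."""
    return np.asarray(pmv_met, float) + model.beta_rmot * np.asarray(rmot, float) + model.intercept_rmot


def fit_preference_extension(residuals_star, preference, model: ExtendedModel) -> ExtendedModel:
    """OLS of the PMV* residuals (AMV - PMV*) on day-mean preference;
    updates ``model`` in place and returns it."""
    preference = np.asarray(preference, dtype=float)
    if np.ptp(preference) == 0:
        raise ValueError("preference is constant over the fitted days; slope undefined")
    fit, _, _ = _ols_line(residuals_star, preference)
    model.beta_pref = float(fit.params[1])
    model.intercept_pref = float(fit.params[0])
    return model


def predict_pmv_double_star(pmv_star, preference, model: ExtendedModel):
    """PMV** = PMV* + b_pref * Preference + c_pref (diagnostic predictor)."""
    return np.asarray(pmv_star, float) + model.beta_pref * np.asarray(preference, float) + model.intercept_pref


def post_extension_screen(
    residuals_star,
    candidates: pd.DataFrame,
    threshold: float = RELEVANCE_THRESHOLD,
) -> pd.DataFrame:
    """Re-screen candidates against the post-extension residuals; by
    construction the fitted variable is orthogonal to them on the training
    days, so its correlation should vanish."""
    return screen_residual_correlations(residuals_star, candidates, threshold=threshold)


def save_model(model: ExtendedModel, path) -> None:
    """Serialize coefficients + fit metadata (and screening report) to a
    structured text (JSON) file."""
    payload = asdict(model)
    report = payload.pop("screening_report")
    if model.screening_report is not None:
        payload["screening_report"] = model.screening_report.to_dict(orient="records")
    else:
        payload["screening_report"] = None
    del report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> ExtendedModel:
    with open(path) as fh:
        payload = json.load(fh)
    report = payload.pop("screening_report", None)
    model = ExtendedModel(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in payload.items()})
    if report is not None:
        model.screening_report = pd.DataFrame(report)
    return model
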