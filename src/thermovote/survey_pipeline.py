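"""Survey ingestion, filtering, clothing transcription, daily aggregation
and the identity-regression evaluation of predicted vs actual sensation.

Survey tables are plain DataFrames with one row per respondent (see
``REQUIRED_FIELDS``).  Votes are coded on the standard 7-point sensation
scale (-3 cold ... +3 hot) and the 5-point preference scale (-2 much
cooler ... +2 much warmer, warmer-positive).  All modelling is at the
survey-day level: predictions use daily mean climate, clothing and the
day's actual mean vote (AMV).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .heat_balance import MET_WM2, pmv_value
from .outdoor_climate import attach_rmot

__all__ = [
    "REQUIRED_FIELDS",
    "TSV_RANGE",
    "PREFERENCE_RANGE",
    "RegressionFit",
    "filter_samples",
    "transcribe_clothing",
    "load_garment_table",
    "aggregate_daily",
    "fit_identity_regression",
    "read_survey_csv",
    "write_survey_csv",
]

REQUIRED_FIELDS = (
    "respondent_id",
    "survey_day",
    "gender",
    "age",
    "time_in_venue",
    "tsv",
    "preference",
    "clothing_clo",
)

TSV_RANGE = (-3.0, 3.0)
PREFERENCE_RANGE = (-2.0, 2.0)

#: a-priori metabolic rate for a strolling-museum activity profile: mean of
#: standing relaxed (1.2 Met) and walking around (1.7 Met), rounded to 1.5
A_PRIORI_MET = 1.5


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of actual on predicted votes (Actual = a1 Predicted + a0)."""

    slope: float
    intercept: float
    r_squared: float
    slope_ci95: tuple[float, float]
    p_value: float
    n: int


def filter_samples(
    records: pd.DataFrame,
    min_minutes: float = 20.0,
    max_clo: float = 3.0,
):
    """Apply the sample-inclusion rules.

    Excluded are records with missing required fields, out-of-scale votes,
    negative visit duration, physically impossible clothing (> ``max_clo``)
    or a visit shorter than ``min_minutes`` (occupants not yet in thermal
    steady state with the venue).

    Returns ``(retained, exclusion_log)`` where the log maps reason ->
    count.  Records are counted once, under the first matching reason.
    """
    df = records.copy()
    log: dict[str, int] = {}

    def take(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            log[reason] = log.get(reason, 0) + n
            df = df[~mask]

    present = [c for c in REQUIRED_FIELDS if c in df.columns]
    missing_cols = [c for c in REQUIRED_FIELDS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"survey table lacks required columns: {missing_cols}")
    take(df[list(present)].isna().any(axis=1), "missing_value")
    take(~df["tsv"].between(*TSV_RANGE), "tsv_out_of_scale")
    take(~df["preference"].between(*PREFERENCE_RANGE), "preference_out_of_scale")
    take(df["time_in_venue"] < 0, "negative_duration")
    take((df["clothing_clo"] < 0) | (df["clothing_clo"] > max_clo), "implausible_clothing")
    take(df["time_in_venue"] < min_minutes, "short_visit")
    return df.reset_index(drop=True), log


def load_garment_table() -> dict[str, float]:
    """Packaged garment -> clo lookup (ensemble insulation is additive over
    worn garments).  The garment list is a representative transcription
    table; site-specific tables can be passed to
    :func:`transcribe_clothing` directly."""
    with resources.files("thermovote.data").joinpath("garments.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["garment"], df["clo"]))


def transcribe_clothing(garments, table: dict[str, float]) -> float:
    """Ensemble insulation [clo] as the sum of the selected garments'
    values.  Unknown garment codes raise, listing every offender."""
    unknown = [g for g in garments if g not in table]
    if unknown:
        raise KeyError(f"unknown garment codes: {unknown}")
    return float(sum(table[g] for g in garments))


def aggregate_daily(
    records: pd.DataFrame,
    indoor_daily: pd.DataFrame,
    outdoor_series,
    met_std_wm2: float = A_PRIORI_MET * MET_WM2,
    met_cal_wm2: float | None = None,
) -> pd.DataFrame:
    """Aggregate filtered survey records to one row per survey day.

    Parameters
    ----------
    records : filtered survey table.
    indoor_daily : DataFrame
        Daily mean indoor climate: ``survey_day, air_temp, radiant_temp,
        rel_humidity, air_speed``.
    outdoor_series : outdoor day records (for RMOT).
    met_std_wm2 : a-priori metabolic rate [W/m^2] for the standard PMV.
    met_cal_wm2 : optional calibrated (median) metabolic rate [W/m^2]; when
        given, a ``pmv_met`` column is added.

    Returns a DataFrame with AMV, mean clothing/preference, daily climate,
    ``pmv_std`` (and ``pmv_met``), and RMOT.
    """
    grouped = records.groupby("survey_day").agg(
        n_respondents=("tsv", "size"),
        amv=("tsv", "mean"),
        mean_clo=("clothing_clo", "mean"),
        mean_preference=("preference", "mean"),
    ).reset_index()

    daily = grouped.merge(indoor_daily, on="survey_day", how="left", validate="1:1")
    if daily["air_temp"].isna().any():
        missing = sorted(daily.loc[daily["air_temp"].isna(), "survey_day"].unique())
        raise ValueError(f"no indoor climate for survey days: {missing}")

    out = attach_rmot(outdoor_series)
    rmot_by_day = dict(zip(out["date"], out["rmot"]))
    days = pd.to_datetime(daily["survey_day"]).dt.date
    daily["rmot"] = [rmot_by_day.get(d, np.nan) for d in days]
    if daily["rmot"].isna().any():
        missing = sorted(daily.loc[daily["rmot"].isna(), "survey_day"].unique())
        raise ValueError(f"RMOT unavailable (missing outdoor history) for: {missing}")

    env = (daily["air_temp"], daily["radiant_temp"], daily["rel_humidity"], daily["air_speed"])
    daily["pmv_std"] = pmv_value(*env, met_std_wm2, daily["mean_clo"])
    if met_cal_wm2 is not None:
        daily["pmv_met"] = pmv_value(*env, met_cal_wm2, daily["mean_clo"])
    return daily


def fit_identity_regression(actual, predicted) -> RegressionFit:
    """OLS of actual votes on predicted votes.

    Perfect prediction corresponds to slope 1, intercept 0, R^2 = 1; the
    reported p-value is the two-sided test of zero slope and the CI is the
    95 % interval on the slope.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValueError("actual and predicted must be 1-d arrays of equal length")
    if len(actual) < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(predicted) == 0:
        raise ValueError("predictor is constant; slope undefined")
    model = sm.OLS(actual, sm.add_constant(predicted)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        p_value=float(model.pvalues[1]),
        n=int(model.nobs),
    )


def read_survey_csv(path) -> pd.DataFrame:
    """Read a survey table (comma-delimited, header row, ISO dates)."""
    df = pd.read_csv(path)
    if "survey_day" in df.columns:
        df["survey_day"] = pd.to_datetime(df["survey_day"]).dt.date.astype(str)
    return df


def write_survey_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
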