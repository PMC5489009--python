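"""Synthetic survey-campaign generator with known ground truth.

Emulates a year-spanning museum comfort campaign: weekly survey days, a
seasonal outdoor temperature series, tightly controlled indoor conditions
(operative temperature 19.5-24 degC at 50 % RH, air speed < 0.2 m/s), a
visitor cohort dominated by elderly females, and thermal sensation votes
generated from each visitor's true metabolic rate through the forward PMV
model plus an injected additive outdoor-climate (RMOT) effect:

    TSV_i = clamp[-3,3]( PMV(M_i, day env, clo_i)
                         + beta_rmot * RMOT_day + beta_0
                         + day_effect + eps_i )

The injected effect has exactly the affine form the RMOT extension removes,
so parameter recovery is a meaningful end-to-end check.  Clothing is
coupled to RMOT (warmer outdoors -> lighter ensembles), reproducing the
clothing/outdoor-climate confound seen in field data, and indoor set-points
are varied against season so that cold-outdoor days are the warm-indoor
days.  Votes are kept continuous by default so that the exact-fit
metabolic-rate calibration is well posed; integer rounding is a stress-test
switch.

Everything is deterministic under ``seed``.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .heat_balance import pmv_value
from .metabolic import Anthropometrics, one_met_equivalent_wm2, load_reference_anthropometrics
from .outdoor_climate import attach_rmot

__all__ = [
    "SyntheticConfig",
    "SyntheticCampaign",
    "generate_outdoor_series",
    "generate_respondents",
    "generate_votes",
    "generate_campaign",
    "emit_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generated campaign.

    Defaults mirror the emulated museum cohort: 35 weekly survey days,
    1,121 respondents with the four age/gender reference cells at
    60/50/128/224 (adult male / adult female / elderly male / elderly
    female) and the remainder spread over 18-80 y with a female skew;
    indoor operative temperature 19.5-24 degC at 50 % RH; a true RMOT
    effect of (-0.024 /degC, +0.264).
    """

    n_days: int = 35
    n_respondents: int = 1121
    start_date: dt.date = dt.date(2015, 2, 4)
    survey_interval_days: int = 7
    # demographic mix: (gender, age_lo, age_hi, count) for the reference
    # cells; the remainder is spread outside these bands
    cell_counts: tuple = (
        ("male", 30, 40, 60),
        ("female", 30, 40, 50),
        ("male", 65, 75, 128),
        ("female", 65, 75, 224),
    )
    remainder_female_share: float = 0.62
    remainder_age_range: tuple[float, float] = (18.0, 80.0)
    # outdoor climate: seasonal sinusoid + AR(1) day-to-day weather
    outdoor_mean: float = 10.0
    outdoor_amplitude: float = 7.5
    outdoor_phase_doy: float = 110.0
    outdoor_ar1: float = 0.7
    outdoor_noise_sd: float = 1.2
    diurnal_half_range: float = 4.0
    # indoor climate: set-points spanning the range, varied against season
    indoor_temp_range: tuple[float, float] = (19.5, 24.0)
    indoor_jitter_sd: float = 2.0
    rh: float = 0.50
    rh_jitter_sd: float = 0.005
    air_speed_range: tuple[float, float] = (0.05, 0.15)
    # true metabolic rates: 1-Met equivalent from anthropometrics times a
    # lognormal activity factor (median chosen so subgroup medians land in
    # the 80-100 W/m^2 range typical of strolling visitors)
    activity_factor_median: float = 1.8
    activity_factor_sigma: float = 0.12
    height_sd: float = 7.0
    weight_sd: float = 10.0
    # vote mechanism
    true_beta_rmot: float = -0.024
    true_intercept: float = 0.264
    tsv_noise_sd: float = 0.2
    day_effect_sd: float = 0.15
    integer_votes: bool = False
    # clothing and preference coupling
    clo_base: float = 0.95
    clo_rmot_slope: float = 0.012
    clo_noise_sd: float = 0.08
    pref_slope: float = -0.9
    pref_noise_sd: float = 0.5
    # data hygiene
    contaminated_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.n_respondents < self.n_days:
            raise ValueError("need >= 1 day and >= 1 respondent per day")
        for name in ("indoor_temp_range", "air_speed_range", "remainder_age_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got {(lo, hi)}")
        if not 0 <= self.contaminated_fraction < 1:
            raise ValueError("contaminated_fraction must be in [0, 1)")
        if not 0 <= self.remainder_female_share <= 1:
            raise ValueError("remainder_female_share must be a probability")

    @property
    def survey_days(self) -> list[dt.date]:
        step = dt.timedelta(days=self.survey_interval_days)
        return [self.start_date + i * step for i in range(self.n_days)]


@dataclass
class SyntheticCampaign:
    """A generated dataset plus its ground truth."""

    survey: pd.DataFrame
    indoor_daily: pd.DataFrame
    outdoor: pd.DataFrame
    truth: pd.DataFrame
    meta: dict = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def generate_outdoor_series(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Daily outdoor min/max from the first survey day minus 3 lead-in days
    through the last survey day: seasonal sinusoid + AR(1) noise."""
    rng = _rng(seed, 1)
    first = config.start_date - dt.timedelta(days=3)
    last = config.survey_days[-1]
    dates = pd.date_range(first, last, freq="D").date
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    seasonal = config.outdoor_mean + config.outdoor_amplitude * np.sin(
        2 * np.pi * (doy - config.outdoor_phase_doy) / 365.0
    )
    ar = np.zeros(len(dates))
    innov = rng.normal(0.0, config.outdoor_noise_sd, len(dates))
    for i in range(1, len(dates)):
        ar[i] = config.outdoor_ar1 * ar[i - 1] + innov[i]
    mean = seasonal + ar
    half = np.maximum(config.diurnal_half_range + rng.normal(0.0, 0.8, len(dates)), 1.0)
    return pd.DataFrame({"date": dates, "t_min": mean - half, "t_max": mean + half})


def _indoor_daily(config: SyntheticConfig, outdoor: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Daily mean indoor climate per survey day.  Set-points run against
    season (cold-outdoor days are the warm-indoor days), spanning the
    configured range."""
    rng = _rng(seed, 2)
    out = attach_rmot(outdoor)
    rmot_by_day = dict(zip(out["date"], out["rmot"]))
    rmot = np.array([rmot_by_day[d] for d in config.survey_days])
    lo_t, hi_t = config.indoor_temp_range
    r_lo, r_hi = rmot.min(), rmot.max()
    frac = (rmot - r_lo) / (r_hi - r_lo) if r_hi > r_lo else np.zeros_like(rmot)
    op = hi_t - (hi_t - lo_t) * frac + rng.normal(0.0, config.indoor_jitter_sd, len(rmot))
    op = np.clip(op, lo_t, hi_t)
    rh = np.clip(config.rh + rng.normal(0.0, config.rh_jitter_sd, len(rmot)), 0.3, 0.7)
    v = rng.uniform(*config.air_speed_range, len(rmot))
    return pd.DataFrame({
        "survey_day": [d.isoformat() for d in config.survey_days],
        "air_temp": op, "radiant_temp": op, "rel_humidity": rh, "air_speed": v,
    })


def _sample_anthropometrics(rng, gender: str, age: float, config: SyntheticConfig,
                            ref: pd.DataFrame) -> Anthropometrics:
    sub = ref[ref["gender"] == gender].sort_values("age_midpoint_y")
    ages = sub["age_midpoint_y"].to_numpy(float)
    h = float(np.interp(age, ages, sub["height_cm"].to_numpy(float)))
    w = float(np.interp(age, ages, sub["weight_kg"].to_numpy(float)))
    height = max(rng.normal(h, config.height_sd), 140.0)
    weight = max(rng.normal(w, config.weight_sd), 40.0)
    return Anthropometrics(weight=weight, height=height, age=age, gender=gender)


def generate_respondents(config: SyntheticConfig, seed: int):
    """Respondent skeleton (demographics, visit metadata, true metabolic
    rate) and the truth table.

    Returns ``(records, truth)``; ``records`` lacks the vote and clothing
    columns filled in by :func:`generate_votes`.
    """
    rng = _rng(seed, 3)
    ref = load_reference_anthropometrics()
    n_cells = sum(c[3] for c in config.cell_counts)
    if n_cells > config.n_respondents:
        raise ValueError("cell counts exceed total respondents")

    genders: list[str] = []
    ages: list[float] = []
    for gender, lo, hi, count in config.cell_counts:
        genders += [gender] * count
        ages += list(rng.uniform(lo, hi, count))
    bands = [(lo, hi) for _, lo, hi, _ in config.cell_counts]
    n_rest = config.n_respondents - n_cells
    a_lo, a_hi = config.remainder_age_range
    while len(ages) < config.n_respondents:
        a = rng.uniform(a_lo, a_hi)
        if any(lo <= a <= hi for lo, hi in bands):
            continue
        ages.append(a)
        genders.append("female" if rng.random() < config.remainder_female_share else "male")
    order = rng.permutation(config.n_respondents)
    genders = [genders[i] for i in order]
    ages = [ages[i] for i in order]

    # spread respondents over survey days as evenly as possible
    base, extra = divmod(config.n_respondents, config.n_days)
    day_sizes = [base + (1 if i < extra else 0) for i in range(config.n_days)]
    days = [d.isoformat() for d, k in zip(config.survey_days, day_sizes) for _ in range(k)]

    one_met = np.empty(config.n_respondents)
    weights = np.empty(config.n_respondents)
    heights = np.empty(config.n_respondents)
    for i, (g, a) in enumerate(zip(genders, ages)):
        anthro = _sample_anthropometrics(rng, g, a, config, ref)
        one_met[i] = one_met_equivalent_wm2(anthro)
        weights[i] = anthro.weight
        heights[i] = anthro.height
    factor = np.exp(rng.normal(np.log(config.activity_factor_median),
                               config.activity_factor_sigma, config.n_respondents))
    true_met = one_met * factor

    time_in_venue = np.clip(rng.lognormal(np.log(60.0), 0.4, config.n_respondents), 21.0, 300.0)

    records = pd.DataFrame({
        "respondent_id": np.arange(config.n_respondents),
        "survey_day": days,
        "gender": genders,
        "age": ages,
        "weight_kg": weights,
        "height_cm": heights,
        "time_in_venue": time_in_venue,
    })
    truth = pd.DataFrame({
        "respondent_id": records["respondent_id"],
        "true_met_wm2": true_met,
        "one_met_equivalent_wm2": one_met,
        "activity_factor": factor,
    })
    return records, truth


def generate_votes(
    records: pd.DataFrame,
    indoor_daily: pd.DataFrame,
    outdoor: pd.DataFrame,
    truth: pd.DataFrame,
    config: SyntheticConfig,
    seed: int,
) -> pd.DataFrame:
    """Complete the survey records with clothing, sensation votes and
    preference votes generated through the forward PMV model plus the
    injected RMOT effect."""
    rng = _rng(seed, 4)
    n = len(records)
    df = records.merge(indoor_daily, on="survey_day", how="left", validate="m:1")
    if df["air_temp"].isna().any():
        missing = sorted(df.loc[df["air_temp"].isna(), "survey_day"].unique())
        raise ValueError(f"indoor climate missing for survey days: {missing}")
    out = attach_rmot(outdoor)
    rmot_by_day = dict(zip((d.isoformat() for d in out["date"]), out["rmot"]))
    try:
        rmot = np.array([rmot_by_day[d] for d in df["survey_day"]])
    except KeyError as err:
        raise ValueError(f"outdoor climate missing for survey day {err}") from None
    if np.isnan(rmot).any():
        raise ValueError("outdoor series lacks the 3-day lead-in for some survey days")

    rmot_center = float(np.mean(np.unique(rmot)))
    clo = np.clip(
        config.clo_base - config.clo_rmot_slope * (rmot - rmot_center)
        + rng.normal(0.0, config.clo_noise_sd, n),
        0.3, 1.6,
    )

    true_met = records.merge(truth, on="respondent_id")["true_met_wm2"].to_numpy()
    pmv_true = pmv_value(
        df["air_temp"].to_numpy(), df["radiant_temp"].to_numpy(),
        df["rel_humidity"].to_numpy(), df["air_speed"].to_numpy(),
        true_met, clo,
    )

    day_index = {d: i for i, d in enumerate(sorted(df["survey_day"].unique()))}
    day_effect = rng.normal(0.0, config.day_effect_sd, len(day_index))
    eps = rng.normal(0.0, config.tsv_noise_sd, n)
    tsv = np.clip(
        pmv_true + config.true_beta_rmot * rmot + config.true_intercept
        + day_effect[[day_index[d] for d in df["survey_day"]]] + eps,
        -3.0, 3.0,
    )
    if config.integer_votes:
        tsv = np.clip(np.round(tsv), -3, 3)

    pref = np.clip(np.round(config.pref_slope * tsv + rng.normal(0.0, config.pref_noise_sd, n)),
                   -2, 2)

    completed = records.copy()
    completed["clothing_clo"] = clo
    completed["tsv"] = tsv
    completed["preference"] = pref

    if config.contaminated_fraction > 0:
        n_bad = int(round(config.contaminated_fraction * n))
        bad = rng.choice(n, size=n_bad, replace=False)
        kinds = ["short_visit", "missing_tsv", "tsv_out_of_scale", "implausible_clo"]
        for j, i in enumerate(bad):
            kind = kinds[j % len(kinds)]
            if kind == "short_visit":
                completed.loc[i, "time_in_venue"] = float(rng.uniform(0, 19))
            elif kind == "missing_tsv":
                completed.loc[i, "tsv"] = np.nan
            elif kind == "tsv_out_of_scale":
                completed.loc[i, "tsv"] = float(rng.choice([-5.0, 5.0]))
            else:
                completed.loc[i, "clothing_clo"] = float(rng.uniform(3.5, 5.0))
    return completed


def generate_campaign(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticCampaign:
    """End-to-end generation of one campaign dataset."""
    config = config or SyntheticConfig()
    outdoor = generate_outdoor_series(config, seed)
    indoor = _indoor_daily(config, outdoor, seed)
    records, truth = generate_respondents(config, seed)
    survey = generate_votes(records, indoor, outdoor, truth, config, seed)
    meta = {
        "seed": int(seed),
        "true_beta_rmot": config.true_beta_rmot,
        "true_intercept": config.true_intercept,
        "n_days": config.n_days,
        "n_respondents": config.n_respondents,
    }
    return SyntheticCampaign(survey=survey, indoor_daily=indoor, outdoor=outdoor,
                             truth=truth, meta=meta)


def emit_dataset(campaign: SyntheticCampaign, path) -> dict[str, Path]:
    """Write survey, indoor and outdoor tables plus the truth sidecar
    (``truth.csv`` + ``truth_meta.json``).  Analysis readers consume only
    the first three files; the sidecar exists for recovery tests."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "survey": path / "survey.csv",
        "indoor_daily": path / "indoor_daily.csv",
        "outdoor": path / "outdoor_daily.csv",
        "truth": path / "truth.csv",
        "truth_meta": path / "truth_meta.json",
    }
    # %.17g floats make the numeric round trip bit-exact
    campaign.survey.to_csv(files["survey"], index=False, float_format="%.17g")
    campaign.indoor_daily.to_csv(files["indoor_daily"], index=False, float_format="%.17g")
    campaign.outdoor.to_csv(files["outdoor"], index=False, float_format="%.17g")
    campaign.truth.to_csv(files["truth"], index=False, float_format="%.17g")
    files["truth_meta"].write_text(json.dumps(campaign.meta, indent=2))
    return files


def read_dataset(path) -> SyntheticCampaign:
    """Re-read an emitted dataset; numeric round trip is exact."""
    path = Path(path)
    read = dict(float_precision="round_trip")
    survey = pd.read_csv(path / "survey.csv", **read)
    indoor = pd.read_csv(path / "indoor_daily.csv", **read)
    outdoor = pd.read_csv(path / "outdoor_daily.csv", **read)
    outdoor["date"] = pd.to_datetime(outdoor["date"]).dt.date
    truth_file = path / "truth.csv"
    truth = pd.read_csv(truth_file, **read) if truth_file.exists() else pd.DataFrame()
    meta_file = path / "truth_meta.json"
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return SyntheticCampaign(survey=survey, indoor_daily=indoor, outdoor=outdoor,
                             truth=truth, meta=meta)
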