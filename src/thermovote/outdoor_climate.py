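"""Daily outdoor reference temperature and its running mean (RMOT).

The daily reference temperature is the arithmetic mean of a day's minimum
and maximum outdoor temperature.  The running mean outdoor temperature
(RMOT) weights the reference temperatures of the survey day and the three
preceding days

    RMOT = (T_e,i + 0.8 T_e,i-1 + 0.4 T_e,i-2 + 0.2 T_e,i-3) / 2.4

a finite-window implementation of the exponentially weighted running mean
used in adaptive thermal-comfort models.  Calendar gaps in the history are
treated as errors, never interpolated.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OutdoorDayRecord",
    "RMOT_WEIGHTS",
    "daily_reference_temp",
    "running_mean_outdoor_temp",
    "attach_rmot",
    "read_outdoor_csv",
    "write_outdoor_csv",
]

#: day-lag weights (lag 0..3); their sum, 2.4, is the divisor
RMOT_WEIGHTS = (1.0, 0.8, 0.4, 0.2)


@dataclass(frozen=True)
class OutdoorDayRecord:
    date: dt.date
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValueError(
                f"t_min ({self.t_min}) exceeds t_max ({self.t_max}) on {self.date}"
            )

    @property
    def t_ref(self) -> float:
        return daily_reference_temp(self.t_min, self.t_max)


def daily_reference_temp(t_min, t_max):
    """Mean of the daily minimum and maximum outdoor temperature [degC]."""
    t_min = np.asarray(t_min, dtype=float)
    t_max = np.asarray(t_max, dtype=float)
    if np.any(t_min > t_max):
        raise ValueError("t_min must not exceed t_max")
    return ((t_min + t_max) / 2.0)[()]


def _as_frame(series) -> pd.DataFrame:
    if isinstance(series, pd.DataFrame):
        df = series.copy()
    else:  # iterable of OutdoorDayRecord
        df = pd.DataFrame(
            [{"date": r.date, "t_min": r.t_min, "t_max": r.t_max} for r in series]
        )
    if df.empty:
        raise ValueError("empty outdoor series")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if "t_ref" not in df.columns:
        df["t_ref"] = daily_reference_temp(df["t_min"].to_numpy(), df["t_max"].to_numpy())
    return df


def running_mean_outdoor_temp(series, day) -> float:
    """RMOT [degC] for ``day`` from an outdoor series covering that day and
    the three preceding calendar days.

    ``series`` is a DataFrame with columns date/t_min/t_max (t_ref optional)
    or an iterable of :class:`OutdoorDayRecord`.  Missing days raise a
    ``ValueError`` naming the absent dates.
    """
    df = _as_frame(series)
    day = pd.Timestamp(day).date()
    by_date = dict(zip(df["date"], df["t_ref"]))
    wanted = [day - dt.timedelta(days=lag) for lag in range(4)]
    missing = [d for d in wanted if d not in by_date]
    if missing:
        raise ValueError(
            "outdoor series lacks required days: "
            + ", ".join(d.isoformat() for d in sorted(missing))
        )
    total = sum(w * by_date[d] for w, d in zip(RMOT_WEIGHTS, wanted))
    return total / sum(RMOT_WEIGHTS)


def attach_rmot(series) -> pd.DataFrame:
    """Return the series as a DataFrame with t_ref and rmot columns; rmot is
    NaN for days whose 3-day history is incomplete."""
    df = _as_frame(series).sort_values("date").reset_index(drop=True)
    rmot = np.full(len(df), np.nan)
    for i, day in enumerate(df["date"]):
        try:
            rmot[i] = running_mean_outdoor_temp(df, day)
        except ValueError:
            pass
    df["rmot"] = rmot
    return df


def read_outdoor_csv(path) -> pd.DataFrame:
    """Read a delimited outdoor series (columns date, t_min, t_max; ISO
    dates) and compute t_ref."""
    return _as_frame(pd.read_csv(path))


def write_outdoor_csv(series, path) -> None:
    """Write the series with derived t_ref and rmot columns."""
    attach_rmot(series).to_csv(path, index=False)
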