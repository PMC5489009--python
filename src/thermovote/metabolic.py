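"""Subpopulation metabolic-rate prediction from anthropometrics.

Basal metabolic rate (BMR) is predicted with the Harris-Benedict equations
as revised by Roza & Shizgal, converted from kcal/day to watts, normalised
by the DuBois body surface area and scaled from basal (~0.8 Met) to resting
(1 Met) level.  This yields the heat equivalent of a 1-Met activity for a
given subpopulation, the quantity that seeds the a-priori metabolic rate of
a comfort model.

A note on gender labels: the coefficient sets are assigned to male/female
as in the standard Roza-Shizgal revision (male: 13.397 W + 4.799 H -
5.677 A + 88.362; female: 9.247 W + 3.098 H - 4.330 A + 447.593, kcal/day).
This assignment reproduces the published worked examples (58 W/m^2 for an
81 kg / 180 cm / 20 y male, 51 W/m^2 for a 69 kg / 174 cm / 20 y female)
and the reference-table surface areas and Met rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .heat_balance import MET_WM2

__all__ = [
    "Anthropometrics",
    "MetRateEstimate",
    "KCAL_DAY_TO_W",
    "BASAL_TO_RESTING",
    "bmr_watts",
    "dubois_surface_area",
    "one_met_equivalent_wm2",
    "wm2_to_met",
    "estimate_met_rate",
    "load_reference_anthropometrics",
]

#: conversion factor kcal/day -> W as conventionally printed (2 s.f. beyond
#: the exact 4184/86400 = 0.048426); kept at 0.0484 for bit-level agreement
#: with published tables.
KCAL_DAY_TO_W = 0.0484

#: basal metabolic rate expressed in Met units (BMR ~ 0.8 Met); dividing a
#: per-area BMR by this scales it to the 1-Met (resting) equivalent.
BASAL_TO_RESTING = 0.8

# Roza-Shizgal revised Harris-Benedict coefficients, kcal/day:
# (weight kg, height cm, age y, constant)
_COEFFS = {
    "male": (13.397, 4.799, -5.677, 88.362),
    "female": (9.247, 3.098, -4.330, 447.593),
}


@dataclass(frozen=True)
class Anthropometrics:
    """Body weight [kg], height [cm], age [y] and gender."""

    weight: float
    height: float
    age: float
    gender: str

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0 kg, got {self.weight!r}")
        if self.height <= 0:
            raise ValueError(f"height must be > 0 cm, got {self.height!r}")
        if self.age < 0:
            raise ValueError(f"age must be >= 0 y, got {self.age!r}")
        if self.gender not in _COEFFS:
            raise ValueError(
                f"gender must be one of {sorted(_COEFFS)}, got {self.gender!r}"
            )


@dataclass(frozen=True)
class MetRateEstimate:
    """BMR and its per-area / Met-scaled derivatives for one person."""

    bmr_watts: float
    surface_area: float
    bmr_per_area: float
    one_met_equivalent: float
    met_units: float


def bmr_watts(anthro: Anthropometrics) -> float:
    """Basal metabolic rate [W] from the revised Harris-Benedict equation."""
    cw, ch, ca, c0 = _COEFFS[anthro.gender]
    kcal_day = cw * anthro.weight + ch * anthro.height + ca * anthro.age + c0
    return KCAL_DAY_TO_W * kcal_day


def dubois_surface_area(weight: float, height: float) -> float:
    """DuBois body surface area [m^2]: 0.007184 W^0.425 H^0.725
    (weight in kg, height in cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def one_met_equivalent_wm2(anthro: Anthropometrics) -> float:
    """Heat equivalent [W/m^2] of a 1-Met activity for this person:
    BMR per unit surface area scaled from basal (0.8 Met) to resting."""
    bsa = dubois_surface_area(anthro.weight, anthro.height)
    return bmr_watts(anthro) / bsa / BASAL_TO_RESTING


def wm2_to_met(rate: float) -> float:
    """Convert an areal metabolic rate [W/m^2] to Met (1 Met = 58.2 W/m^2)."""
    if rate <= 0:
        raise ValueError(f"rate must be > 0 W/m^2, got {rate!r}")
    return rate / MET_WM2


def estimate_met_rate(anthro: Anthropometrics) -> MetRateEstimate:
    """Full per-person estimate: BMR, surface area and Met equivalents."""
    bmr = bmr_watts(anthro)
    bsa = dubois_surface_area(anthro.weight, anthro.height)
    per_area = bmr / bsa
    one_met = per_area / BASAL_TO_RESTING
    return MetRateEstimate(
        bmr_watts=bmr,
        surface_area=bsa,
        bmr_per_area=per_area,
        one_met_equivalent=one_met,
        met_units=one_met / MET_WM2,
    )


def load_reference_anthropometrics() -> pd.DataFrame:
    """Packaged reference table: mean height/weight of Dutch adults
    (30-40 y) and elderly (65-75 y) by gender, with category-midpoint ages
    (35 y / 70 y) used wherever a single representative age is needed."""
    with resources.files("thermovote.data").joinpath("dutch_anthropometrics.csv").open() as fh:
        return pd.read_csv(fh)
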