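"""Fanger heat-balance engine: PMV, PPD and operative temperature.

The predicted mean vote (PMV) maps the whole-body heat-balance deficit of a
clothed occupant onto the 7-point thermal sensation scale (-3 cold ... +3
hot).  The model inputs are air temperature, mean radiant temperature,
relative humidity, air speed, metabolic rate, external work and clothing
insulation.  The clothing surface temperature ``t_cl`` is defined implicitly
and is solved here by damped fixed-point iteration with a bisection
fallback; all numerical kernels accept NumPy arrays so that whole cohorts
can be evaluated in one call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThermalEnvironment",
    "OccupantState",
    "PmvResult",
    "AirSpeedValidityWarning",
    "CLO_TO_M2KW",
    "MET_WM2",
    "saturation_vapor_pressure",
    "vapor_pressure",
    "clothing_area_factor",
    "solve_clothing_temperature",
    "pmv_value",
    "compute_pmv",
    "compute_ppd",
    "operative_temperature",
]

#: thermal resistance of 1 clo [m^2 K/W]
CLO_TO_M2KW = 0.155
#: heat equivalent of 1 Met [W/m^2]
MET_WM2 = 58.2

_STEFAN = 3.96e-8  # effective radiation coefficient f_cl-normalised [W/m^2 K^4]


class AirSpeedValidityWarning(UserWarning):
    """Operative temperature requested at air speeds where the simple
    air/radiant average is no longer a valid approximation."""


@dataclass(frozen=True)
class ThermalEnvironment:
    """One measurement context.

    Parameters
    ----------
    air_temp, radiant_temp : float
        Air and mean radiant temperature [degC].
    rel_humidity : float
        Relative humidity as a fraction in [0, 1].
    air_speed : float
        Air speed [m/s], >= 0.
    """

    air_temp: float
    radiant_temp: float
    rel_humidity: float
    air_speed: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_humidity <= 1.0:
            raise ValueError(
                f"rel_humidity must be a fraction in [0, 1], got {self.rel_humidity!r}"
            )
        if self.air_speed < 0:
            raise ValueError(f"air_speed must be >= 0, got {self.air_speed!r}")
        for name in ("air_temp", "radiant_temp"):
            t = getattr(self, name)
            if not -40.0 <= t <= 60.0:
                raise ValueError(f"{name}={t!r} degC outside plausible range [-40, 60]")


@dataclass(frozen=True)
class OccupantState:
    """Personal model inputs: metabolic rate M [W/m^2], external work W
    [W/m^2] (zero for sedentary/strolling occupants) and clothing
    insulation in clo (stored alongside its SI value)."""

    met_rate: float
    clothing_clo: float
    external_work: float = 0.0

    def __post_init__(self) -> None:
        if self.met_rate <= 0:
            raise ValueError(f"met_rate must be > 0, got {self.met_rate!r}")
        if self.external_work < 0:
            raise ValueError(f"external_work must be >= 0, got {self.external_work!r}")
        if self.clothing_clo < 0:
            raise ValueError(f"clothing_clo must be >= 0, got {self.clothing_clo!r}")

    @property
    def clothing_insulation(self) -> float:
        """Clothing insulation I_cl [m^2 K/W]."""
        return self.clothing_clo * CLO_TO_M2KW


@dataclass(frozen=True)
class PmvResult:
    """PMV with its PPD and solver diagnostics."""

    pmv: float
    ppd: float
    clothing_surface_temp: float
    convective_coeff: float
    clothing_area_factor: float
    converged: bool
    iterations: int


def saturation_vapor_pressure(air_temp):
    """Saturation water-vapor pressure [Pa] at ``air_temp`` [degC].

    Antoine-type form used by standard PMV implementations
    (p_sat = 1000 * exp(16.6536 - 4030.183 / (t + 235))); alternatives such
    as Magnus differ by < 1 % over the indoor-climate range.
    """
    air_temp = np.asarray(air_temp, dtype=float)
    return 1000.0 * np.exp(16.6536 - 4030.183 / (air_temp + 235.0))[()]


def vapor_pressure(air_temp, rel_humidity):
    """Partial water-vapor pressure [Pa] from relative humidity (fraction)."""
    rel_humidity = np.asarray(rel_humidity, dtype=float)
    if np.any((rel_humidity < 0) | (rel_humidity > 1)):
        raise ValueError("rel_humidity must lie in [0, 1] (fraction, not percent)")
    return (rel_humidity * saturation_vapor_pressure(air_temp))[()]


def clothing_area_factor(clothing_insulation):
    """Clothing area factor f_cl from insulation I_cl [m^2 K/W].

    f_cl = 1.00 + 1.290 I_cl for I_cl <= 0.078, else 1.05 + 0.645 I_cl;
    the canonical piecewise form, including its ~3e-4 discontinuity at the
    branch point.
    """
    icl = np.asarray(clothing_insulation, dtype=float)
    if np.any(icl < 0):
        raise ValueError("clothing insulation must be >= 0")
    return np.where(icl <= 0.078, 1.00 + 1.290 * icl, 1.05 + 0.645 * icl)[()]


def _tcl_update(t_cl, t_a, t_r, v, mw, icl, f_cl):
    """Right-hand side of the implicit t_cl equation and active h_c."""
    h_c = np.maximum(2.38 * np.abs(t_cl - t_a) ** 0.25, 12.1 * np.sqrt(v))
    rad = _STEFAN * f_cl * ((t_cl + 273.0) ** 4 - (t_r + 273.0) ** 4)
    conv = f_cl * h_c * (t_cl - t_a)
    return 35.7 - 0.028 * mw - icl * (rad + conv), h_c


def _solve_tcl_arrays(t_a, t_r, v, mw, icl, f_cl, tol=1e-5, max_iter=300):
    """Vectorised damped fixed-point solve for t_cl with bisection fallback.

    Returns (t_cl, h_c, converged, iterations) as arrays broadcast to the
    common shape.
    """
    t_a, t_r, v, mw, icl, f_cl = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t_a, t_r, v, mw, icl, f_cl))
    )
    shape = t_a.shape
    t_cl = (35.7 - 0.028 * mw + t_a) / 2.0
    lo_clip = np.minimum(t_a, t_r) - 40.0
    iterations = np.zeros(shape, dtype=int)
    active = np.ones(shape, dtype=bool)
    for _ in range(max_iter):
        new, _ = _tcl_update(t_cl, t_a, t_r, v, mw, icl, f_cl)
        # clip keeps an unstable iterate (possible at very high insulation)
        # finite; such elements stay active and fall through to bisection
        nxt = np.clip(0.5 * (t_cl + new), lo_clip, 90.0)
        delta = np.abs(nxt - t_cl)
        t_cl = np.where(active, nxt, t_cl)
        iterations = iterations + active
        active = active & ~(delta < tol)
        if not active.any():
            break
    converged = ~active
    if active.any():
        # damped iteration stalled: the residual g(t) = update(t) - t is
        # strictly decreasing in t, so bisection on a wide bracket is safe
        flat = np.nonzero(active.ravel())[0]
        tc = t_cl.ravel().copy()
        it = iterations.ravel().copy()
        ok = converged.ravel().copy()
        for i in flat:
            ta_i, tr_i, v_i = t_a.flat[i], t_r.flat[i], v.flat[i]
            mw_i, icl_i, fcl_i = mw.flat[i], icl.flat[i], f_cl.flat[i]

            def g(t):
                return _tcl_update(t, ta_i, tr_i, v_i, mw_i, icl_i, fcl_i)[0] - t

            lo, hi = min(ta_i, tr_i) - 40.0, 90.0
            if g(lo) < 0 or g(hi) > 0:  # pragma: no cover - outside model range
                ok[i] = False
                continue
            n = 0
            while hi - lo > tol / 2 and n < 200:
                mid = 0.5 * (lo + hi)
                if g(mid) > 0:
                    lo = mid
                else:
                    hi = mid
                n += 1
            tc[i] = 0.5 * (lo + hi)
            it[i] += n
            ok[i] = True
        t_cl = tc.reshape(shape)
        iterations = it.reshape(shape)
        converged = ok.reshape(shape)
    _, h_c = _tcl_update(t_cl, t_a, t_r, v, mw, icl, f_cl)
    return t_cl, h_c, converged, iterations


def solve_clothing_temperature(
    env: ThermalEnvironment,
    occ: OccupantState,
    tol: float = 1e-5,
    max_iter: int = 300,
):
    """Solve the implicit clothing-surface-temperature equation.

    t_cl = 35.7 - 0.028 (M - W)
           - I_cl [3.96e-8 f_cl ((t_cl+273)^4 - (t_r+273)^4)
                   + f_cl h_c (t_cl - t_a)]
    with h_c = max(2.38 |t_cl - t_a|^0.25, 12.1 sqrt(v)).

    Returns ``(t_cl, h_c, converged, iterations)``.  Non-convergence is
    reported through the flag, never raised.
    """
    icl = occ.clothing_insulation
    f_cl = clothing_area_factor(icl)
    t_cl, h_c, conv, its = _solve_tcl_arrays(
        env.air_temp,
        env.radiant_temp,
        env.air_speed,
        occ.met_rate - occ.external_work,
        icl,
        f_cl,
        tol=tol,
        max_iter=max_iter,
    )
    return float(t_cl), float(h_c), bool(conv), int(its)


def pmv_value(
    air_temp,
    radiant_temp,
    rel_humidity,
    air_speed,
    met_rate,
    clothing_clo,
    external_work=0.0,
    tol=1e-5,
    max_iter=300,
):
    """Vectorised PMV.  All arguments broadcast; returns an ndarray (or
    scalar) of PMV values.  This is the kernel behind both
    :func:`compute_pmv` and the cohort calibration."""
    args = np.broadcast_arrays(
        *(
            np.asarray(x, dtype=float)
            for x in (air_temp, radiant_temp, rel_humidity, air_speed, met_rate, clothing_clo, external_work)
        )
    )
    t_a, t_r, rh, v, m, clo, w = args
    icl = clo * CLO_TO_M2KW
    f_cl = clothing_area_factor(icl)
    mw = m - w
    t_cl, h_c, _, _ = _solve_tcl_arrays(t_a, t_r, v, mw, icl, f_cl, tol=tol, max_iter=max_iter)
    p_a = vapor_pressure(t_a, rh)
    load = _thermal_load(t_a, t_r, p_a, m, mw, icl, f_cl, t_cl, h_c)
    return ((0.303 * np.exp(-0.036 * m) + 0.028) * load)[()]


def _thermal_load(t_a, t_r, p_a, m, mw, icl, f_cl, t_cl, h_c):
    """Thermal load L [W/m^2]: metabolic heat minus the six standard loss
    terms (skin diffusion, sweat, respiration latent + dry, radiation,
    convection).  Sweat term floored at zero below the onset (M - W =
    58.15 W/m^2)."""
    skin_diffusion = 3.05e-3 * (5733.0 - 6.99 * mw - p_a)
    sweat = 0.42 * np.maximum(mw - 58.15, 0.0)
    resp_latent = 1.7e-5 * m * (5867.0 - p_a)
    resp_dry = 0.0014 * m * (34.0 - t_a)
    radiation = _STEFAN * f_cl * ((t_cl + 273.0) ** 4 - (t_r + 273.0) ** 4)
    convection = f_cl * h_c * (t_cl - t_a)
    return mw - skin_diffusion - sweat - resp_latent - resp_dry - radiation - convection


def compute_pmv(
    env: ThermalEnvironment,
    occ: OccupantState,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> PmvResult:
    """PMV/PPD for a single environment-occupant pair with diagnostics."""
    icl = occ.clothing_insulation
    f_cl = float(clothing_area_factor(icl))
    mw = occ.met_rate - occ.external_work
    t_cl, h_c, conv, its = _solve_tcl_arrays(
        env.air_temp, env.radiant_temp, env.air_speed, mw, icl, f_cl, tol=tol, max_iter=max_iter
    )
    p_a = vapor_pressure(env.air_temp, env.rel_humidity)
    load = _thermal_load(
        env.air_temp, env.radiant_temp, p_a, occ.met_rate, mw, icl, f_cl, t_cl, h_c
    )
    pmv = float((0.303 * np.exp(-0.036 * occ.met_rate) + 0.028) * load)
    return PmvResult(
        pmv=pmv,
        ppd=float(compute_ppd(pmv)),
        clothing_surface_temp=float(t_cl),
        convective_coeff=float(h_c),
        clothing_area_factor=f_cl,
        converged=bool(conv),
        iterations=int(its),
    )


def compute_ppd(pmv):
    """Predicted percentage dissatisfied [%].

    PPD = 100 - 95 exp(-(0.03353 PMV^4 + 0.2179 PMV^2)); even in PMV with
    minimum 5 % at PMV = 0.
    """
    pmv = np.asarray(pmv, dtype=float)
    return (100.0 - 95.0 * np.exp(-(0.03353 * pmv**4 + 0.2179 * pmv**2)))[()]


def operative_temperature(air_temp, radiant_temp, air_speed):
    """Operative temperature as the air/radiant mean [degC].

    Valid at low air speed; a :class:`AirSpeedValidityWarning` is emitted
    when ``air_speed`` >= 0.2 m/s (the approximation's validity limit).
    """
    if np.any(np.asarray(air_speed) >= 0.2):
        warnings.warn(
            "operative temperature as the air/radiant mean assumes air speed "
            "< 0.2 m/s",
            AirSpeedValidityWarning,
            stacklevel=2,
        )
    return (np.asarray(air_temp, dtype=float) + np.asarray(radiant_temp, dtype=float))[()] / 2.0
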