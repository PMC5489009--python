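# Methods

## Heat-balance model

The PMV engine implements the standard Fanger equation set.  The thermal
load is

```
L = (M−W) − 3.05·10⁻³ (5733 − 6.99(M−W) − p_a)
        − 0.42 max(M−W − 58.15, 0)
        − 1.7·10⁻⁵ M (5867 − p_a)
        − 0.0014 M (34 − t_a)
        − 3.96·10⁻⁸ f_cl ((t_cl+273)⁴ − (t_r+273)⁴)
        − f_cl h_c (t_cl − t_a)
```

with `PMV = (0.303 e^(−0.036 M) + 0.028) L` and all rates in W/m² of body
surface.  The sweat term is floored at zero below its onset
(M−W = 58.15 W/m²).  Saturation vapor pressure uses the Antoine-type form
`p_sat [Pa] = 1000 exp(16.6536 − 4030.183/(t+235))`, the form embedded in
standard PMV implementations; alternatives (Magnus, Arden Buck) differ by
under 1 % across the indoor range and are immaterial here.  The clothing
area factor is the canonical piecewise-linear form with its branch point at
I_cl = 0.078 m² K/W; the ~3·10⁻⁴ discontinuity there is retained for
fidelity to the standard formulation.

**Clothing-surface temperature.**  `t_cl` is defined implicitly and solved
by damped fixed-point iteration (`t ← (t + update(t))/2`), tolerance
10⁻⁵ °C, at most 300 iterations, with iterates clipped to
[min(t_a,t_r)−40, 90] °C.  The update residual is strictly decreasing in
`t_cl`, so any element that fails to contract (possible at very high
insulation, where the damped map's multiplier approaches −1) is finished by
bisection on a wide bracket; non-convergence is reported through a flag,
never raised mid-cohort.  The convective coefficient takes the larger of
the natural (2.38 |Δt|^0.25) and forced (12.1 √v) branches.

**Units.**  1 clo = 0.155 m² K/W; 1 Met = 58.2 W/m².  Relative humidity is
a fraction in [0, 1] throughout; passing percent-scale values raises
immediately rather than silently producing 100× vapor pressures.

## Metabolic-rate prediction

Basal metabolic rate uses the Harris–Benedict equations as revised by Roza
& Shizgal (male: 13.397 W + 4.799 H − 5.677 A + 88.362; female:
9.247 W + 3.098 H − 4.330 A + 447.593, kcal/day), converted to watts with
the conventional printed factor 0.0484 (kept rather than the exact
4184/86400 ≈ 0.048426 so that published table values reproduce at printed
precision).  Division by DuBois surface area
(0.007184 W^0.425 H^0.725) and by 0.8 (basal ≈ 0.8 Met) gives the 1-Met
heat equivalent.  The packaged Dutch reference table uses category-midpoint
ages 35 y and 70 y for the 30–40 y and 65–75 y bands; with those ages the
published per-cell values reproduce after rounding, and elderly 1-Met
equivalents come out ≈9 % below adults for both genders.

## Inverse calibration

For each respondent the calibrated rate solves `PMV(M) = TSV` with the
respondent's survey-day mean climate and own clothing.  PMV is strictly
increasing in M over the bracket (verified as a test invariant), so the
root is unique.  The scalar path uses Brent's method (xtol 10⁻¹⁰); the
cohort path is a vectorised monotone bisection on the same bracket
(resolution 10⁻⁸ W/m², ~35 halvings), which evaluates the whole cohort's
PMV per step and agrees with the scalar path to < 10⁻⁶ W/m².  Defaults:
bounds [40, 250] W/m² (generously enclosing the 70–150 W/m² bulk seen in
field calibrations), residual tolerance 10⁻⁵ on the sensation scale.
Votes unattainable within bounds return the nearest bound with
`bound_hit` set; such records are retained but flagged, and summary
medians are computed over all records by default (exclusion is a switch).
Calibration is deterministic: no random initialisation anywhere.

Because the fit is exact, any non-metabolic influence on a vote (noise,
adaptation, preference) is absorbed into the estimated rate.  Medians, not
means, summarise groups for exactly this reason, and counts outside
[70, 150] W/m² are logged as extreme.

## Day-level evaluation and extensions

All prediction is at the survey-day level: daily mean climate and clothing,
actual mean vote (AMV) as the daily TSV mean.  Prediction accuracy is the
OLS regression of actual on predicted (`Actual = a₁ Predicted + a₀`);
perfect prediction is (a₁, a₀, R²) = (1, 0, 1).

Residuals `AMV − PMV_met` are screened against candidate day-level
variables by Pearson correlation with two-sided p-values; |r| ≥ 0.3 is
flagged as relevant (the conventional threshold for subjective-response
studies; the criterion is the magnitude, so strong negative correlations
qualify).  No multiple-testing correction is applied — screening is
descriptive, and the small candidate set makes the raw p-values
interpretable.  The RMOT extension regresses the residuals on RMOT and adds
the fitted affine term to the predictor (PMV*); by the normal equations the
post-extension residuals are exactly orthogonal to RMOT on the training
days, so the post-extension screen serves as a structural check.  The
preference extension (PMV**) repeats the step with day-mean preference
votes; it is reported as a diagnostic only, since preference is not known
ahead of time in a predictive setting.  Extensions are fitted on day-level
aggregates by default (n = number of survey days); respondent-level fitting
is available but not default.

RMOT uses the four-day finite window `(T_e,i + 0.8 T_e,i−1 + 0.4 T_e,i−2 +
0.2 T_e,i−3)/2.4` on daily (min+max)/2 reference temperatures, survey day
inclusive.  Calendar gaps in the required window are an error, never
interpolated.

## Subgroup statistics

Age bands are 30–40 y and 65–75 y inclusive; respondents outside both are
excluded from the comparison only.  Even-sized groups use the
mean-of-central-pair median.  Percent differences are normalised by the
first (adult) group's median — the convention that makes (97, 87) W/m²
read as 10.3 %.  The Wilcoxon rank-sum test enumerates the permutation
null exactly (midranks, so ties are handled) for combined n ≤ 20 and uses
the tie-corrected normal approximation above that; fully tied samples
return p = 1 with a warning.  Significance is p < 0.05, two-sided.

## Synthetic campaign generator

The generator emulates a year-spanning weekly campaign and is the
package's test bed; its defaults are the study conditions, not tuning
knobs.

- **Outdoor weather**: seasonal sinusoid (mean 10 °C, amplitude 7.5 °C,
  Dutch-like phase) plus AR(1) day-to-day noise (φ = 0.7, σ = 1.2 °C),
  daily min/max at ±4 °C around the daily mean.  35 weekly survey days
  starting 2015-02-04 give an RMOT span well above 10 °C.
- **Indoor climate**: daily operative set-points span 19.5–24 °C and run
  *against* season — cold-outdoor days are the warm-indoor days.  This
  orientation is forced by the joint pattern the generator must reproduce
  (identity-regression slope > 1 together with a negative residual–RMOT
  correlation and a negative correction coefficient implies
  cov(RMOT, PMV) < 0).  An RMOT-independent set-point jitter of 2.0 °C
  (clipped to the range) reflects that real set-point schedules are not a
  deterministic function of outdoor weather; without it RMOT carries no
  information orthogonal to PMV and the extension's R² gain becomes
  unstable.  RH is 0.50 with 0.005 jitter; air speed uniform on
  0.05–0.15 m/s.
- **Cohort**: the four reference cells hold exactly 60/50/128/224
  respondents (adult/elderly × male/female), the remaining 659 spread over
  18–80 y outside those bands with a 62 % female share.  Anthropometrics
  are Gaussian around the reference-table means interpolated in age
  (SD 7 cm / 10 kg; the table provides means only, so the spreads are a
  modelling choice).
- **True metabolic rates**: each respondent's 1-Met equivalent times a
  lognormal activity factor (median 1.80, σ = 0.12).  The median was
  chosen so subgroup medians land in the 80–100 W/m² range reported for
  strolling museum visitors and the cohort median sits near 1.5 Met; a
  median factor of 1.5 would put the dominant elderly-female subgroup's
  bulk below 70 W/m², contradicting the observed calibrated-rate range.
- **Votes**: `TSV_i = clamp(PMV(M_i, day env, clo_i) + β_rmot·RMOT + β₀ +
  day_effect + ε_i)` with injected truth β = (−0.024 /°C, +0.264), day
  effect SD 0.15 and individual noise SD 0.2.  The day-effect SD was set
  against the reported day-level statistics of such campaigns
  (residual–RMOT correlation ≈ −0.5 to −0.6, identity R² well below 1);
  the individual SD keeps the calibrated-rate bulk inside 70–150 W/m²
  while leaving the subgroup contrasts detectable at the reference group
  sizes.  Votes are continuous by default so the exact-fit calibration is
  well posed; integer rounding is a stress-test switch.
- **Couplings**: clothing decreases with RMOT (0.012 clo/°C plus noise),
  reproducing the clothing–outdoor-climate confound; preference is a noisy
  decreasing function of own TSV (people feeling cold prefer warmer).
- **Determinism**: every draw derives from `default_rng([seed, stream])`;
  identical seeds give identical datasets, and the emitted CSVs round-trip
  bit-exactly (`%.17g` write, `round_trip` parse).

The injected RMOT effect has exactly the affine form the extension removes
— generator and model are conjugate by design, which is what makes
parameter recovery (CI coverage of the injected truth across seeds) a
meaningful end-to-end check rather than a tautology: the recovery still
passes through vote clamping, exact-fit calibration, median aggregation
and day-level regression.

### What the generator does not emulate

Sub-daily indoor dynamics and within-day visitor arrival patterns;
psychological adaptation beyond the affine RMOT term; clothing chosen in
response to *indoor* conditions; non-Gaussian vote noise, scale-use
habits, or cultural response styles; seasonal visitor-mix drift.  Passing
tests therefore demonstrate internal consistency of the method under its
own assumptions, not field validity on real cohorts.

## Numerical choices and degenerate inputs

- Solver tolerances: t_cl 10⁻⁵ °C (fixed point) with bisection fallback;
  calibration bracket resolution 10⁻⁸ W/m²; OLS via statsmodels.
- Zero-variance screening candidates are skipped with a log entry;
  zero-variance residuals yield an empty report (r undefined).
- Constant predictors (RMOT, preference, regression x) raise: a slope is
  undefined and silently returning 0 would corrupt downstream corrections.
- Operative temperature warns (does not fail) at air speeds ≥ 0.2 m/s,
  where the air/radiant mean stops being a valid approximation.
- Inverted outdoor min/max, missing calendar days, unknown garment codes
  and out-of-scale humidity all raise with the offending values named.

## Known limitations

- The exact-fit calibration attributes *all* residual variance to
  metabolic rate; individual estimates are therefore not physiological
  measurements and only group medians should be interpreted.
- Day-level aggregation evaluates PMV at the median rate and mean
  clothing; Jensen-gap effects of the skewed rate distribution are small
  (the synthetic CI-coverage check bounds them) but not exactly zero.
- The published reference-table cell 55.2 W/m² (adult male) recomputes to
  ≈55.5 under every age assumption tried; the package reports the computed
  value and does not force the printed one.  Similarly the elderly-female
  surface area 1.78 m² appears to be a truncation of the computed
  1.785 m².
- Indoor measurements are treated as spatially homogeneous at a single
  height; no vertical-gradient correction is applied.
- The simulation scale used by the test suite (one campaign per seed, 200
  seeds for coverage, 500 replicates for test-calibration checks) balances
  statistical resolution against runtime; all checks complete in a few
  minutes on one CPU.
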