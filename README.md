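# thermovote

Thermal-comfort survey analysis built around the Fanger heat-balance
model: forward PMV/PPD computation, per-respondent **metabolic-rate
calibration** against thermal sensation votes, subpopulation metabolic-rate
prediction from anthropometrics, and **outdoor-climate model extensions**
(PMV\*, PMV\*\*) driven by the running mean outdoor temperature (RMOT).

## Who this is for

Researchers analysing occupant comfort field surveys — campaigns where
visitors or workers report a thermal sensation vote (TSV, 7-point scale −3
cold … +3 hot) while the indoor climate (air and radiant temperature,
relative humidity, air speed) and daily outdoor temperatures are logged.
The package answers two questions such campaigns raise:

1. **What metabolic rate actually fits the votes?**  Standard tables give
   one activity-based number (e.g. 1.5 Met for strolling), but resting heat
   production varies with body size, age and gender.  Inverting the PMV
   model per respondent yields an empirical metabolic-rate distribution and
   exposes subpopulation differences (adults vs elderly, males vs
   females).
2. **Does recent outdoor weather shift indoor sensation?**  Adaptive
   comfort theory predicts it does.  Screening day-level prediction
   residuals against candidate variables and absorbing a relevant RMOT
   correlation into an affine correction quantifies the effect.

## The model

The predicted mean vote is

```
PMV = (0.303 e^(−0.036 M) + 0.028) · L(M, W, I_cl, t_a, t_r, p_a, v)
```

where the thermal load `L` [W/m²] is metabolic heat minus the six standard
loss terms (skin diffusion, sweat, latent and dry respiration, radiation,
convection), and the clothing surface temperature solves an implicit heat
balance handled by damped fixed-point iteration with a bisection fallback.
`PPD = 100 − 95·exp(−(0.03353 PMV⁴ + 0.2179 PMV²))`.

Because PMV is strictly increasing in the metabolic rate `M` over indoor
survey conditions, each respondent's vote pins down a unique calibrated
rate `M_i` with `PMV(M_i) = TSV_i` (bracketed root-finding on
[40, 250] W/m²; residuals < 10⁻⁵).

Day-level prediction residuals (actual mean vote AMV minus the PMV at the
cohort-median rate, `PMV_met`) are screened for Pearson correlations
(|r| ≥ 0.3 is "relevant") and extended affinely:

```
RMOT  = (T_e,i + 0.8 T_e,i−1 + 0.4 T_e,i−2 + 0.2 T_e,i−3) / 2.4
PMV*  = PMV_met + b_rmot · RMOT + c_rmot
PMV** = PMV*    + b_pref · Preference + c_pref     (diagnostic only)
```

Basal metabolic rate comes from the Harris–Benedict equations (Roza–Shizgal
revision), normalised by DuBois surface area and scaled from basal
(≈0.8 Met) to resting level, giving per-subpopulation 1-Met heat
equivalents (e.g. 58 W/m² for an adult male of 81 kg / 180 cm / 20 y,
51 W/m² for an adult female of 69 kg / 174 cm / 20 y).

Because real museum-style survey datasets are rarely shared, the package
includes a synthetic campaign generator (`thermovote.synthetic_data`) that
emulates the study conditions — 35 weekly survey days, 1,121 respondents
dominated by elderly females, indoor operative temperatures 19.5–24 °C at
50 % RH — with votes produced through the forward PMV model plus an
injected RMOT effect, so every analysis step can be validated against
known ground truth.

## Worked example

```sh
thermovote simulate --seed 1 --out demo/campaign
thermovote evaluate demo/campaign
```

prints

```
median_met_wm2: 89.4649
median_met_units: 1.5372
slope_pmv_std: 1.1679
r2_pmv_std: 0.9189
slope_pmv_star: 1.0234
r2_pmv_star: 0.9364
beta_rmot: -0.0182
intercept_rmot: 0.2038
adult_male vs elderly_male: medians 102.3 vs 91.1 W/m^2 (10.9 %), p = 0.00633
adult_female vs elderly_female: medians 94.7 vs 79.5 W/m^2 (16.0 %), p = 1.23e-07
```

Reading: the calibrated cohort-median metabolic rate is ≈1.54 Met (close
to the 1.5 Met a-priori table value for strolling); the identity regression
of AMV on the standard PMV has slope 1.17 (sensation underestimated toward
the extremes), which the RMOT-extended PMV\* pulls to 1.02 while raising
R²; the fitted correction (−0.018 /°C here) estimates the injected truth
(−0.024 /°C); and adults carry significantly higher calibrated rates than
elderly for both genders (Wilcoxon rank-sum).

The same steps are available as library calls:

```python
from thermovote import synthetic_data, analyze_campaign

camp = synthetic_data.generate_campaign(seed=1)
res = analyze_campaign(camp.survey, camp.indoor_daily, camp.outdoor)
print(res.calibration_summary["median_met_units"])
print(res.extension.beta_rmot, res.extension.beta_rmot_ci95)
```

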