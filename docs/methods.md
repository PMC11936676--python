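# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Dose–response and LT50 (`thermal_limits`)

Survival of an acute heat shock is Bernoulli with
logit P(survive) = β₀ + β·T (probit available via `link="probit"`).
The MLE is found by iteratively reweighted least squares with step
halving, which makes the deviance non-increasing by construction;
convergence is a relative deviance change below 1e−10 within 100
iterations (standard GLM practice). The covariance is the inverse
observed information at the optimum (observed = expected under the
canonical logit link).

LT50 = −β₀/β with the delta-method SE using gradient [−1/β, β₀/β²]; this
is the `dose.p` convention. Fieller intervals are not implemented.
Species contrasts assume independent samples: SE(Δ) = √(SE₁² + SE₂²).

Degenerate inputs are surfaced, not absorbed: a single outcome class and
complete separation (survivor and death temperatures do not overlap)
raise typed errors — separation would otherwise appear as a silently
enormous slope; |β| < 1e−6 makes the median dose unstable and `lt50`
refuses it. Observed per-temperature death fractions are reported
separately (`death_fractions`) because the "temperature at which half
died" can also be read per treatment; the regression median is the
analysis quantity.

Internally all data are ungrouped Bernoulli rows; grouped binomial input
is expanded on read (identical MLE, simpler residual bookkeeping).

## Thermal preference (`preference`)

Positions are labelled marks on a linear gradient bar; temperature at a
mark is linear interpolation between the end temperatures, with the
orientation (`cold_end_position`) explicit because the apparatus put
higher labels toward the cold end. T_PREF statistics default to
temperatures at the chosen marks (the apparatus recorded marked
intervals); continuous interpolation is available in the generator.

The Levene test is a one-way ANOVA on absolute deviations from each
group's centre; the default centre is the median (Brown–Forsythe), the
robust form and the default of the R ecosystem's `car` implementation,
with the mean-centred classic form behind a flag. The paired test is a
one-sample t on gradient-minus-control position differences (df = n−1).
The rearing-temperature ANOVA treats rearing temperature as a continuous
covariate (single-df regression F with df (1, n−2)); a categorical
variant exists. All degrees of freedom come from the supplied data —
published df are never hard-coded, since the published Levene df and t
df imply slightly different sample sizes.

## Emergence timing (`development`)

OLS of days-to-emergence on [1, temperature, type (0/1, parasitoid = 1),
temperature × type]. Temperature enters as a continuous covariate by
default: a five-level factor would carry 4 df where the published-style
decomposition carries 1. The 0/1 type contrast is chosen for
readability; sums of squares and F are invariant to the contrast choice.

The sequential (Type-I) ANOVA accumulates each term's drop in residual
sum of squares as the terms join the model in entry order; F is term MS
over residual MS. `AnovaTable.from_components` rebuilds a table (F and p
only) from printed SS/df components so a published decomposition can be
audited. Gaussian ML AIC is n·log(2πRSS/n) + n + 2(k+1), counting the
error variance as a parameter. The linear mixed model with a wasp-genus
random effect is deliberately out of scope; `lm_aic` ranks fixed-effects
models only.

## Synthetic data (`synthetic`)

All generators are pure functions of (design, seed) using
`numpy.random.default_rng`; no global RNG state.

* **Heat shock:** survival probability from the logistic with
  β₀ = −slope·LT50; defaults are the study design — temperatures
  34–44 °C in steps of 2, ~8 individuals per temperature, parasitoid
  truth LT50 37.4 °C, slope −0.25 (host 42.1 / −0.86 in the pipeline).
* **Gradient:** control positions uniform over the marks; gradient
  positions drawn so the implied temperature is Normal(T_PREF mean, sd)
  truncated to the bar range (12.5–44.5 °C) and snapped to the nearest
  mark. Truncation (not censoring or wrapping) because an insect cannot
  leave the bar; the truncation shifts the realised mean slightly above
  the nominal 20.1 °C, and tests compare against the truncated-normal
  mean computed by numeric integration. Defaults: n = 135, sd = 4.5 °C,
  6 marks; bar length and mark count are parameters because the physical
  apparatus geometry is reported inconsistently.
* **Emergence:** each of 150 leaves per daytime-maximum treatment
  (15–35 °C) yields a moth with probability 0.143, a parasitoid with
  probability 0.36, else nothing — reproducing ~14 % / 36 % / 50 %
  emergence bookkeeping at 750 leaves. Days to emergence follow a
  degree-day model days = DD/(T_eff − T0) + N(0, σ), floored at 1 day,
  where T_eff = (14·T_day + 10·10)/24 is the photoperiod-weighted mean
  of the square-wave incubator regime (14:10 L:D, 10 °C nights) — the
  simplest defensible collapse of that regime. Defaults DD/T0: host
  400 °C·d / 2 °C, parasitoid 270 °C·d / 8 °C, σ = 4.6 d. The higher
  parasitoid base temperature with the smaller thermal constant makes
  the mean curves cross near the 25–30 °C treatments: the parasitoid is
  much slower at 15 °C, indistinguishable at 25–30 °C and faster at
  35 °C, and the residual spread (σ² ≈ 21 d²) matches the scale of the
  study system. These defaults were fixed once from those pattern
  constraints.

What the generators do **not** emulate: leaf husbandry artefacts
(drying, transport stress, the unexplained half of non-emergences),
parasitoid genus structure, sex differences, dry-mass covariation, and
any behaviour of real wasps beyond a stationary preferred temperature.
Passing tests therefore show the statistical machinery is correct under
the assumed data-generating processes, not that those processes fully
describe field data.

## Microclimate (`microclimate`)

A desk-scale generator for the mid-day of each month from monthly
normals (t_min, t_max, mean wind, mean RH, cloud fraction), in local
solar time with no longitude or daylight-saving correction:

* **Solar geometry.** Cooper declination,
  cos z = sinφ sinδ + cosφ cosδ cos(15°(t−12)); polar day/night clamped.
* **Diurnal air temperature.** Parton–Logan: daytime sine from t_min at
  sunrise to t_max at solar noon + 1.5 h lag; nocturnal exponential
  decay (coefficient 2.2) from the sunset temperature, renormalised to
  reach exactly t_min at the next sunrise, so the curve is continuous at
  both junctions and attains its stated extremes once per day. The
  24-point integer-hour grid samples this curve, so the grid maximum
  slightly undershoots t_max; the shipped configuration's t_max values
  account for this.
* **Shortwave.** Beam = S₀·τ^m·cos z with τ = 0.72 and
  pressure-corrected air mass m; diffuse = 0.3·(1−τ^m)·S₀·cos z. Cloud
  fraction c removes beam (×(1−c)) and converts half the removed beam to
  diffuse. Direct + diffuse never exceeds the extraterrestrial flux.
* **Longwave.** Sky temperature from Brutsaert clear-sky emissivity
  1.24(e_a/T)^{1/7} with a (1 + 0.22c²) cloud correction.
* **Humidity and wind** are held at their monthly means (RH clipped to
  (0, 100]); no sub-daily humidity cycle.
* **Scenarios** add a uniform (or per-month) delta to air temperature
  after interpolation; sky temperature is computed from the warmed air
  so longwave forcing stays consistent with the scenario.

The shipped `data/mpg_north.yaml` is **synthetic calibrated data**, not
measured climatology: its May–July normals were tuned once so the
current-scenario hourly simulation reproduces the study site's published
maxima (June air 20.9 °C, sun-leaf 25.7 °C), and its scenario deltas
(+2.9 / +3.7 °C) are back-derived from published scenario maxima.
Absolute window/risk hours from this configuration are therefore
illustrative; ordering and zero/non-zero structure are the meaningful
outputs. Users supply real normals and downscaled deltas for real sites.

## Leaf energy budget (`leaf_energy`)

Steady-state flat-leaf balance per hour (Campbell–Norman form):
absorbed shortwave α_s·S (shade leaves receive diffuse only) plus
absorbed longwave εσ(T_sky⁴ + T_ground⁴) balances emitted longwave
2εσT_leaf⁴, sensible heat 2·c_p·g_H·(T_leaf − T_air) and latent heat
λ·g_v·(e_s(T_leaf) − e_a)/P. Both faces exchange sensible heat and
longwave; one (hypostomatous) face transpires through stomatal and
boundary-layer conductances in series. Boundary-layer conductance is the
forced-convection form 1.4·0.135·√(u/d) mol m⁻² s⁻¹ per face, floored at
0.05 for free convection in still air. Ground temperature defaults to
air temperature (no soil model); vapour pressures by Tetens; the VPD is
floored at zero (no dew deposition).

Defaults α_s = 0.5, ε = 0.97, d = 0.05 m, g_s = 0.2 mol m⁻² s⁻¹ are
standard broadleaf values and are all config-exposed so a published
parameterisation can be dropped in. The root is found by safeguarded
Newton (numerical derivative, bisection fallback) inside
[T_air − 20, T_air + 30] to |residual| < 0.01 W m⁻², max 200 iterations;
a bracket without sign change raises an error reporting both bracket
residuals. Flux closure at the returned root is asserted in tests.

The validation helper compares mean predicted sun-leaf excess with
observed sun and shade excess and applies two accuracy criteria: the
mean error must be smaller than (i) the observed sun–shade contrast and
(ii) the thermal safety margin.

No transient leaf thermal mass (steady state per hour), no
within-lamina mine microclimate, fixed (non-responsive) stomata.

## Risk metrics (`risk`)

Exceedance is strict (">") for risk and the preference window is the
closed interval [mean − sd, mean + sd], reading "exceeds" and "within"
literally; a 1e−9 guard absorbs floating-point noise at the band edges.
Daily values are the count averaged over the supplied whole days — by
default the mid-month days of May, June and July, when the adult wasps
and larval miners interact. Host exposure is sun-leaf temperature;
adult parasitoid exposure is air temperature at the reference height in
the sun (shade air is available by flag). Safety margins use the maxima
of the same series as the risk counts, so reports are internally
consistent. No behavioural thermoregulation is modelled — buffering by
flight to cooler microsites is interpretation, not computation.

One caveat discovered during verification: the window of opportunity is
*not* strictly unimodal in a uniform warming delta at hourly resolution.
The diurnal temperature distribution is bimodal (midday peak, long
nocturnal plateau), so whole blocks of night hours enter or leave the
preferred band together and the hour count wiggles as the delta grows.
The robust property — the window peaks at an interior delta and is lower
at both ends of a −5…+15 °C sweep, while risks grow monotonically — is
what the tests assert.

## Interface and reproducibility

All tables are RFC-4180 UTF-8 CSV with "." decimals and numerics at 6
significant digits (byte-stable round trips). Configs are YAML,
schema-validated with unknown keys rejected. The pipeline writes every
intermediate table, a JSON summary (with package version, seed and a
config hash that covers the scientific inputs but not the output path)
and is deterministic for identical config + seed. CLI exit codes: 0
success, 1 validation error, 2 computation failure.

Test-suite problem sizes are chosen for statistical adequacy: Monte-Carlo
calibration checks use 200–300 replicates (power and KS-uniformity
checks), the LT50 recovery check uses 1000 replicates at the field
design scale, and oracle-equivalence checks use 100 random small
datasets against scipy/statsmodels reference implementations.

## Known limitations

* Monthly-normal forcing cannot represent heat waves, synoptic
  variability or year-to-year spread; risk hours from a single mid-month
  day underestimate tail exposure.
* The LT50 protocol constants (1 h hold, ~0.5 °C min⁻¹ ramp) are fixed
  design features, not covariates; no thermal-death-time modelling.
* Sub-lethal heat effects, phenological mismatch and multi-generation
  dynamics are out of scope.
* The degree-day development model is linear in temperature above a
  base; it has no high-temperature deceleration, so extrapolation above
  the fitted range is unreliable.
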