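# Methods

This note documents the models, estimators and design choices behind
`schoolenv`, and what the synthetic-data experiments do and do not
demonstrate about real field data.

## Study design being modelled

Schools are measured for one week each on a rolling schedule (five
schools per week over 18 weeks by default), so raw weekly means
confound location with time. Two corrections make schools comparable:

1. **Instrument calibration.** The continuous optical PM₂.₅ monitor
   drifts seasonally relative to the gravimetric reference — it
   under-reads during the dusty Harmattan season and over-reads outside
   it. Each collocation yields CF = C_grav / mean(C_cont); the CF is a
   ratio of means, not a regression slope, because its defining property
   is that the corrected continuous mean equals the filter concentration
   exactly. Schools without a valid filter receive the pooled seasonal
   mean CF (all valid collocations, not leave-one-out, mirroring the use
   of two pooled seasonal factors in practice).
2. **Temporal adjustment.** A fixed network of ambient monitors defines
   the weekly factor TAF_w = (network mean in week w)/(network annual
   mean), computed over paired sites — a site missing a week leaves both
   the numerator and its annual mean out of the denominator. The
   annual equivalent is the weekly measurement **divided** by TAF_w.
   The direction is fixed by an invariant rather than convention: if a
   school tracks the city-wide temporal field, its measured week equals
   (annual mean) × TAF_w, and only division returns the annual mean.
   The school-hours metric (weekday 07:00–15:00 mean of the corrected
   continuous series) is adjusted by the same weekly TAF, so both
   full-week and school-hours PM₂.₅ are reported on the annual scale.

Per-site annual means are the mean of available weekly means, which
makes the equal-weight average of TAFs exactly 1 on a complete network.

## Noise metrics

All sound metrics operate on minute-integrated A-weighted levels.
Leq is the energy mean 10·log₁₀(mean 10^(L/10)). L_day(school)
restricts to weekday school hours minus the two break windows
(children's own play noise), 2100 minutes on a complete week; masks are
half-open `[start, end)` in local clock time.

The intermittency ratio uses local calendar days as the "site and
day-specific" base period: the day's Leq plus a 3 dBA threshold defines
the event cut-off, minutes strictly above it are events, and the day's
IR is the event share of total energy. Days are aggregated weighted by
their total energy by default; an arithmetic-mean switch is provided
because either aggregation is defensible and the difference only
matters when days carry very unequal energy. IR is invariant to a
uniform level shift (cut-off and energies shift together) and is zero
for any constant series.

The break-vs-class difference is the arithmetic mean over school days
of (break Leq − non-break school-hours Leq). Note an estimator
property, not a bug: when sound energy is dominated by sparse Poisson
events, the log of a 60-minute energy mean is biased low by Jensen's
inequality by more than the log of a 420-minute mean, so the estimated
break excess under-shoots the generating boost (≈0.4 dBA observed for a
0.7 dBA boost at the default event rate). The noiseless recovery test
confirms the estimator is exact when strata are homogeneous.

## Annoyance

HA_N counts numeric responses 8–10; HA_V the top two verbal categories;
HA_VW weights "extremely" in full and "very" by 0.4, so HA_VW ≤ HA_V
identically. The exposure–response curve pools respondents into 5 dB
bins of school L_day(school) anchored at multiples of 5 dBA at or below
the minimum level, computes the pooled HA_N per bin with binomial 95%
CIs (normal approximation; exact Clopper–Pearson when a bin has fewer
than 10 respondents), and fits an unweighted OLS quadratic to the bin
aggregates — bin aggregates rather than respondent-level data, matching
how such curves are reported. At least three non-empty bins are
required (three parameters).

## Determinant models

Pearson correlations carry Fisher-z 95% CIs and strength labels on |r|
(<0.3 weak, 0.3–0.5 moderate, >0.5 strong; the labels apply to negative
correlations through the absolute value). Stratified summaries use
linear-interpolated percentiles.

The additive models are Gaussian GAMs: linear terms for district
(reference: peri-urban districts), road distances, commercial activity
(ref: none), NDVI, SES index, surface (ref: unpaved), school type
(ref: private) and season (ref: non-Harmattan), plus penalized cubic
B-spline smoothers (df = 6) for weekly temperature, relative humidity
and rain. PM₂.₅ and BC are modelled on the natural-log scale — both are
right-skewed, and ln-scale coefficients read as approximate
proportional effects; noise is modelled in dBA untransformed. The
B-spline basis was chosen because it is the penalized-spline machinery
available in statsmodels; the smoothing weight defaults to a fixed
modest penalty with generalized cross-validation available via
`gcv=True` (GCV costs a few seconds per fit and changes coverage
results negligibly on the synthetic tables). A smoother whose input is
constant is dropped, so the model degenerates exactly to OLS — the
pure-linear limit test pins this. Percent deviance explained is
computed against the intercept-only model; smoother effective degrees
of freedom and Wald p-values are reported per term. Rank-deficient
designs raise an error naming the collinear columns.

## Synthetic city generator

The generator emulates the study conditions, with one global seed
feeding deterministic per-component substreams:

- **Temporal field:** city-wide multiplicative weekly field, log-normal
  with σ = 0.45 and Harmattan weeks elevated by 2.2σ on the log scale,
  normalized to mean one so annual equivalence is identifiable. The
  default produces weekly factors spanning roughly 0.3–3, the order of
  magnitude seen in strongly seasonal West African cities. Amplitude
  zero gives a flat field of exact ones.
- **PM chain:** school annual means uniform on 11–65 µg/m³ (the
  observed school range); the measured week's true mean is
  annual × field × a mean-one log-normal school-week deviation
  (σ = 0.08), the quantity that bounds how well any temporal adjustment
  can recover the annual mean (median |relative error| ≈ 5–6% at
  default settings, within the 10% acceptance bound). Minute values
  jitter log-normally (σ = 0.30) around the week mean; there is no
  within-week diurnal structure by default. The continuous monitor
  divides truth by the season's CF (1.12 / 0.83) and adds mean-one
  minute noise (σ = 0.10); the filter mass is exactly the realized true
  series mean times sampled volume, so the generator is self-consistent
  and CF recovery error comes only from monitor noise. About 10% of
  filters are made QC-invalid (short runtime or off-nominal flow) to
  exercise the seasonal-imputation path.
- **BC:** annual absorbance uniform on 1.7–12 ×10⁻⁵ m⁻¹, sharing the
  temporal field; filter reflectances are back-computed from the
  absorption-coefficient formula.
- **Sound:** base level uniform on 48–62 dBA per school, Gaussian
  minute jitter (2 dBA), i.i.d. Poisson event minutes (2/h) elevated by
  15 dBA — calibrated so the default IR sits near 50%, an event-driven
  but not spike-dominated soundscape — and a 0.7 dBA boost during break
  windows.
- **Annoyance:** P(numeric ≥ 8) = logistic(−10.37 + 0.15·L_day) for
  road traffic (≈14% at 57 dBA), with fixed per-source logit offsets
  (neighbors +2.2 dominating, industrial/aircraft negative); the verbal
  answer derives from the numeric one via fixed cut-points
  0–1/2–4/5–6/7/8–10 → 1–5, guaranteeing coherent HA metrics.
- **Covariates** are drawn independently of the pollution chain (no
  spatial autocorrelation), so the study-level determinant fits on
  generated bundles have low deviance explained by construction. Effect
  recovery is instead tested with `generate_determinant_table`, which
  plants known ln-scale effects (default: +0.3 for market proximity)
  plus nonlinear temperature/rain terms and Gaussian noise
  (σ = 0.2).

What passing tests therefore show: the estimators are algebraically
correct, unbiased under the generator's assumptions, and recover
planted parameters at realistic sample sizes. What they do not show:
robustness to features the generator omits — diurnal and spatially
correlated pollution structure, non-multiplicative instrument drift,
autocorrelated sound events, survey response styles in children, or
covariate confounding patterns of a real city.

## Numerical choices and edge cases

- QC boundaries are inclusive (exactly 75% runtime and exactly ±10%
  flow pass); QC is monotone in runtime and |flow − nominal|.
- Minutes at exactly Leq_day + threshold are not IR events (strict
  inequality).
- NDVI class gaps (0.1–0.2, 0.5–0.6) are assigned to the nearer
  boundary class with a warning; the 500 m road split is inclusive
  ("within"); SES median ties go to "above" so "below" is strictly
  below; the 55 dBA comparison is strict.
- Negative absorbance (post-reflectance brighter than pre) warns but
  returns the value; zero reflectance or zero sampled volume raise.
- The exposure–response quadratic is fit by `numpy.polynomial` least
  squares on bin aggregates and is exact (≤1e-6) when bin percentages
  lie on a quadratic.

## Problem sizes

The default configuration is the full study scale: 90 schools × 10 080
minutes × two instruments, ten fixed sites × 18 weeks of minutes, 1 080
surveyed children. The whole pipeline runs in seconds, the test suite
in well under a minute, and the acceptance script end to end in under a
minute on a single CPU; the model-coverage experiment uses 50
replicates of 90 schools.

## Known limitations

- The BC absorption coefficient uses the standard black-smoke formula;
  conversion to a mass concentration is out of scope.
- Annual means from partial fixed-site records are simple means of the
  available weeks; no seasonality-aware imputation.
- The GAM reports Wald-type smoother p-values conditional on the chosen
  penalty; penalized CIs can be mildly anticonservative, which is why
  the coverage experiments target nominal-minus-slack rates.
- No spatial statistics: schools and sites are exchangeable units.
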