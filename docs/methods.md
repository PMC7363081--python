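# Methods

## Scope and model structure

The package models adult reproduction of *Bactrocera dorsalis* as a
composition of temperature-response curves and Weibull age
distributions on a physiological-age axis, and exposes two daily cohort
simulators built from them.  Everything is deterministic at the cohort
level: the simulators track proportions of an emerging female cohort,
not individuals.  Individuals appear only in the synthetic-data
generator and in the Monte-Carlo oracle used by the tests.

Physiological age is accumulated as Px_i = Px_{i−1} + D(T_i)·Δt with
Δt = 1 calendar day and no sub-daily interpolation.  Three clocks run on
this rule with different rate models D: the aging clock (survival), the
pre-oviposition clock (completion), and each oviposition cohort's phase
clock.

### One-phase (current) model

Daily eggs per original female are
F(T_i)·[E(Px_i) − E(Px_{i−1})]·S(Px_i), with both E (whole-life
cumulative oviposition, three-parameter Weibull) and S (survival) on the
aging clock.  The model forces every female to begin laying when her
aging age crosses the onset parameter γ — the structural weakness the
two-phase model addresses for species with long pre-oviposition periods.

### Two-phase model

The fraction completing pre-oviposition on day i is
C_p(Px_i) − C_p(Px_{i−1}) on the pre-oviposition clock.  That fraction
enters the oviposition phase **the following day** (day i+1) as a
cohort-ledger entry carrying its own phase age.  A cohort's capacity is
F evaluated at its entry-day temperature (the temperature when
oviposition starts determines total capacity; at constant temperature
this is indistinguishable from F(T_i)).  Its daily laying fraction is
the increment of the two-parameter Weibull phase distribution on the
ODRM clock, and survival multiplies in from the aging clock counted
from emergence — there is no separate oviposition-phase mortality
clock.

### Rate-curve conventions

Development rates and counts clamp at zero outside their support:
negative eggs or backwards development are meaningless.  The
oviposition-phase rate curve (a + b·e^T + c/T² + d·e^{−T}) is the one
exception at the evaluation level: it is a purely empirical fit on
16.7–34.9 °C data whose e^{−T} term explodes at low temperature, so the
evaluator returns the raw value (and refuses T ≤ 0, where c/T² is
undefined).  The simulators therefore gate phase-clock progress to days
whose temperature lies inside the fecundity support (T_L, T_H) and
clamp any negative rate to zero — a cohort's phase age never decreases.
How this curve should extrapolate outside the observed range is not
knowable from the data; the fecundity-support gate is this package's
choice.

## Parameters

The packaged default parameter set carries the published estimates.
The biologically meaningful ones, with units:

| component | parameters | meaning |
|---|---|---|
| aging (per sex) | r0 /day, T_H °C, c °C | minimum aging rate (1/r0 = innate longevity ceiling, ≈104 d for females); temperature of ~unit daily aging; scale |
| survival (per sex) | α (Px), β | characteristic age (females 1.0921) and shape |
| fecundity | α_f eggs/°C², T_L, T_H °C | capacity curve; limits 16.32–35.25 °C bound all egg laying |
| ORM | γ, η (Px), β | whole-life laying onset age 0.1020; γ+η = 0.3515 is the 1−e⁻¹ age |
| PDRM | α_p, T_L, T_H °C, m | Briere-2 pre-oviposition rate, support 13.32–35.20 °C |
| PCDM | γ, η (Px), β | completion onset 0.4852; γ+η = 0.9382 |
| ODRM | a, b, c, d | empirical U-shaped phase rate, minimum near 19 °C |
| OORM | α (Px), β | phase laying: α = 0.2401 is the 1−e⁻¹ age |

Simulation defaults: horizon 300 days, early termination when survival
drops below 1e-6, day indexing 1-based from emergence (matching how the
pre-oviposition period is counted in the experiment).

The published three-parameter Weibull fits describe γ+η as the age at
which half the process is complete; algebraically it is the
1 − e⁻¹ ≈ 63.2% point.  The package implements the algebra and reports
the printed numbers as what they are (characteristic ages), without
"correcting" either.

## Fitting pipeline

`ReproductionModel.fit()` reduces individual records exactly the way
the laboratory data were reduced:

* **Onset rule.**  APOP is the first day with more than 5 eggs followed
  by at least one further laying day within the next 7 days; AOP runs
  from that day to the last laying day, inclusive.  The >5 threshold is
  the study's; the 7-day consistency window operationalises
  "consistently", which the study does not quantify.  Both are
  configurable.
* **Thermal-response fits** (aging, fecundity, PDRM, ODRM) use
  per-temperature means — reciprocals of mean periods for the rate
  curves — as data points, matching the degrees of freedom of the
  published fits.
* **Age-distribution fits** (survival, ORM, PCDM, OORM) use pooled
  per-individual curves: each temperature's daily proportion curve with
  days divided by that temperature's empirical mean period (longevity,
  longevity, APOP, AOP respectively).  Normalizing by empirical means —
  rather than model-predicted periods — follows the survival-model
  description; `normalize_ages` accepts an explicit reference to do
  otherwise.
* **Degree-day lines** are OLS on reciprocal means restricted to the
  windows where the rates are linear: 18.8–34.9 °C for aging,
  16.7–32.0 °C for APOP (34.9 °C excluded because the rate reverses),
  18.8–32.0 °C for AOP (16.7 °C anomalously short).  These windows
  reproduce every published F statistic's degrees of freedom.  LDT and
  TC are always derived from the freshly fitted, unrounded line:
  −b/a of the *printed rounded* coefficients does not always reproduce
  the printed LDT.

Numerical choices: nonlinear fits run trust-region least squares with
bounds keeping parameters in their valid regions
(xtol = ftol = gtol = 1e-13); initialisation is deterministic —
temperature limits 1 °C outside the observed support, Weibull scales at
the empirical 63rd percentile of the curve, shapes at 1.5, no random
restarts.  The ODRM curve is linear in its coefficients, whose design
matrix spans ~30 orders of magnitude (e^T against e^{−T}); it is solved
exactly by column-scaled linear least squares instead of iteration.
Noise-free samples of every model family are recovered to ≤1e-6
relative error (tested).

## Synthetic cohorts

`generate_cohort` inverts the normalization: at temperature T each
female draws a normalized death age from the survival Weibull
(longevity = age/A(T), ceiling to whole days, as a daily census records
it) and a normalized completion age from the completion Weibull
(completion day = age/D_p(T), ceiling; laying starts the following
day, so the recorded APOP is that first laying day — the quantity the
onset detector recovers).  A female dying before her completion day
lays nothing, mirroring the mortality-before-oviposition the two-phase
model captures.  Laying females deposit their full capacity F(T),
spread over their observed laying days by the phase-distribution
increments on the ODRM clock, renormalized over those days; fecundity
is modelled as a deterministic capacity, so the capacity itself is not
resampled.  `egg_noise="multinomial"` (default) distributes
round(F(T)) whole eggs multinomially over those weights;
`"none"` records the fractional expected counts.

Defaults mirror the study conditions: the six constant temperatures at
which eggs were laid and twenty females per temperature.  The
round-trip recovery test uses 500 females per temperature so sampling
noise does not mask systematic bias.

What the generator does *not* emulate, and what that means for the
tests: there is no individual variance in capacity (the study reports
only temperature-level SEs), no fluctuating-temperature regimes, no
male records, and no measurement error in daily counts beyond the
multinomial option.  More fundamentally, the synthetic world is
generated from the *two-phase* components, while the study's whole-life
ORM was fitted to the real data independently.  The component fits are
not mutually consistent to high precision (e.g. the aging model smooths
over the observed longevity dip at 16.7 °C), so the synthetic
whole-life egg-age distribution has a visibly different shape
(refitted β ≈ 1.7 versus 1.2) than the published ORM even though its
onset and characteristic age agree well.  Recovery of distribution
scale is therefore asserted on the 1 − e⁻¹ characteristic age
(γ+η for three-parameter fits, α for two-parameter fits) — the
parameterisation-independent quantile the study itself headlines —
rather than on η alone, whose strong trade-off with γ makes it an
unstable target.  Passing round-trip tests show the pipeline is
self-consistent under the stated census conventions; they do not show
the component models jointly describe a real population.

## Validation and problem sizes

The deterministic two-phase ledger is cross-checked against an
independent individual-based Monte-Carlo simulation (10⁵ females
sampling completion and death days; agreement within 2% of lifetime
eggs at 23.5 °C).  The temperature support of egg laying is established
by a 31-point integer sweep (10–40 °C, 300-day horizon): both
simulators lay exactly within 17–35 °C, bounded by the fecundity
limits.  Observed-versus-simulated comparison (Pearson r of cumulative
curves) is provided as the `validate` pipeline; the study's observed
daily egg series are not shipped, so the published per-temperature
correlations can only be reproduced by users supplying those series.

## Known limitations

* Published thermal constants (degree-day totals) cannot be reproduced
  exactly from the rounded printed means; slopes and thresholds can,
  and only those are asserted.
* The published claim that the two-phase model confines >10 eggs/day to
  days 4–50 (versus up to day 102 for the one-phase model) does not
  state its temperature or aggregation and could not be confirmed
  independently; the package asserts only the direction (the two-phase
  window is no longer, and onset is strictly later at 16.7 °C).
* The study's own simulation engine is undocumented; discretisation
  differences from the Δt = 1 day convention here are unknowable.
* No population-model coupling, density dependence, humidity or
  photoperiod effects, and no male dynamics beyond the aging/survival
  fits.
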