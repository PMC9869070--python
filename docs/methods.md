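# Methods

## Model structure and assumptions

The package treats silage dry matter loss as the sum of three emission
fractions, each expressed in mg CO2e per kg of silage dry matter:

1. **Direct fermentation CO2 (C_M).** Fermentation of hexose sugars to
   acetate, ethanol and minor VOC releases CO2 at fixed stoichiometric
   ratios (the molar CO2 equivalent, MCE, of each product). Acetic acid and
   ethanol are measured per sample; the 30 minor VOC are fixed at their
   literature mean concentrations and contribute a constant 1.6e3 mg CO2/kg.
   Hexoses are assumed to be 65% of fermentable sugars (pentose
   fermentation is assumed not to release CO2), so the hexose fraction
   scales the whole term. The equation's grouping is ambiguous in its
   source rendering; this package multiplies the minor-VOC constant by the
   hexose fraction too (the reading consistent with the prose and with the
   surrogate intercept to within ~29 mg/kg rather than ~290), and exposes
   the alternative grouping behind
   `ModelConstants(hexose_scales_minor_constant=False)`.

2. **Ozone-mediated CO2e of evaporated VOC (C_O).** After silo opening,
   fractions of the fermentation products evaporate (0.554 of acetic acid,
   0.991 of ethanol at ambient/60 °C conditions) and form tropospheric
   ozone in proportion to their equal benefit incremental reactivity
   (EBIR). Ozone has no published GWP, so one is derived: its radiative
   forcing increase normalized to abundance increase, relative to CO2's
   (RNRF = 681.0), amortized over its 22-day atmospheric lifetime gives
   multipliers of 681.0 × (22/365.25)/H for horizon H — 2.05 (20 y) and
   0.41 (100 y). The emission equations use 2.04 for the 20-year constant,
   matching the published equation text; 2.05 is available via
   `ModelConstants(ozone_gwp20=2.05)`. The year length (365.25 d) is a
   package choice that reproduces the published multipliers exactly.

3. **Respiration CO2 (C_R).** Whatever dry matter loss is not explained by
   glycolytic mass loss (3 g per mol pyruvate, term P), metabolic CO2 and
   volatilization is attributed to respiration of glucose and converted to
   CO2 by 6 × 44.01/180.156 = 1.46573. With oven DML the full volatile
   mass V (four analytes + 6.2e3 minor constant) is subtracted; with
   volatile-corrected DML only the minor constant is, because the analyte
   volatilization is already inside the correction. Negative C_R values are
   retained as meaningful (microbial CO2 recycling), never clamped.

Totals are exact sums: GWP_H = C_M + C_O-H + C_R. All computation is in
mg/kg DM; % DM is accepted and produced only at I/O boundaries (factor 1e4).

## Volatile-corrected dry matter loss

vcDML subtracts the volatilized mass of the four measured analytes from
oven DML using temperature-specific volatility coefficients: (0.090, 0.554,
0.991, 1.003) for lactic acid, acetic acid, ethanol and ammonia at 60 °C;
(0.375, 0.892, 0.975, 0.987) at 100 °C. The subtraction direction is not
written out in the source; it is adopted here because it reproduces the
reported ordering (corrected mean below oven mean) and admits the negative
values the literature reports for 100 °C drying. Minor VOC are *not*
subtracted in the correction — they enter only through the emission
equations. Missing ethanol or ammonia is imputed with the meta-analysis
means (1.0% and 0.2% of DM, applied on the % DM scale before unit
conversion) and flagged; missing lactic acid, acetic acid or DML is an
error. Default drying temperature is 60 °C, the majority condition in the
underlying review.

## Synthetic cohort generator

The generator emulates the meta-analysis population of laboratory corn
silage fermentation outcomes. Each metric is drawn independently in a
transformed space where the source data are approximately normal:

| metric | transform | transformed mean ± SD (% DM scale) |
|---|---|---|
| lactic acid | square root | 2.27 ± 0.48 |
| acetic acid | Box-Cox λ=0.47 | 0.44 ± 0.60 |
| ammonia | Box-Cox λ=−0.21 | −2.43 ± 1.26 |
| ethanol | Box-Cox λ=0.38 | −0.24 ± 0.89 |
| vcDML | Box-Cox λ=0.18 on x+10 | 2.95 ± 0.51 |

Draws are back-transformed to % DM and converted to mg/kg. Inverse-domain
violations (λy+1 ≤ 0; for the ethanol spec about 0.4% of draws, the normal
tail below −2.68 SD) are rejection-resampled with counts recorded; a rate
above 5% aborts generation. Resampling truncates the low tail slightly —
negligible at the observed rate, and the distributional test widens its
tolerance by the corresponding bias bound. One master seed spawns
independent per-metric substreams (`numpy` `SeedSequence`), so cohorts are
reproducible and metric draws do not interact. Default n = 1,000.

What the generator does **not** emulate: correlations between metrics (the
source publishes none; real silages surely correlate acids with DM loss),
between-study heterogeneity, measurement error structure, or commercial-
scale conditions (the population is laboratory silos, where oxygen exposure
and hence respiration are far lower). Passing tests therefore show the
pipeline reproduces the published laboratory-scale analysis, not that the
estimates transfer to bunker silos.

Back-transforming a normal draw through a convex inverse raises the raw-
scale expectation above the back-transform of the transformed mean (for
vcDML: back-transform of the mean is ≈0.66% DM while the expected draw is
≈1.15%, close to the source's raw mean 1.1%). This is a property of the
published specs, not a calibration knob.

## Monte Carlo summary and projection

Each emission term is summarized over the cohort as mean, SD, SEM = SD/√n,
a 95% interval, and a two-sided one-sample t-test against zero. The 95%
interval is the empirical 2.5/97.5 percentile interval by default (the
published intervals' slight asymmetry suggests percentiles; the source does
not say), with the normal approximation mean ± 1.96 SD selectable. A
sample SD at rounding-noise level relative to the mean flags the t-test as
degenerate (NaN) rather than reporting spurious certainty. Results are
reported in % of DM at 1 decimal in the CLI, full precision in the API.

The national projection multiplies harvested silage mass (default 130.3 Mt
as fed, US 2021) by dry matter fraction (0.32) and a GWP fraction of DM.
The incremental scenario converts a vcDML change to a GWP change through
the D_V slope (1.46573), and also reports the simplified 1:1
point-for-point figure used in the source narrative, so the ~1.47× gap
between the two readings stays visible.

## Linear surrogate derivation

With the vcDML pathway, GWP is exactly affine in (A, E, L, D_V); ammonia
influences GWP only through the D_V measurement itself. Coefficients are
obtained two independent ways: OLS (statsmodels) of full-equation GWP on
(A, E, L, N, D_V) over a cohort, and closed-form composition from the model
constants. The two agree to 1e-6 relative on any nonsingular cohort, the
fit residual is machine-level (R² = 1), the ammonia slope is numerically
zero, and the coefficients are seed-invariant. Ammonia is kept in the
design matrix so its nullity is verified rather than assumed. The published
slope set is reproduced at all printed decimals. The published intercepts
(−3626.1, −8526.1) sit ≈29.3 mg/kg above the analytic composition under
either grouping; the residual is not recoverable from the published
constants, so printed intercepts are exposed (`printed_coefficients`) and
reported but never asserted. The lactic acid molar mass, required by the
glycolysis term but never printed, is 90.08 g/mol — the value that
reproduces the published lactic slope −0.03173 exactly.

## Numerical and interface choices

- Problem sizes: all analyses run at the published scale (n = 1,000
  cohorts); the whole test suite completes in a few seconds.
- Box-Cox forward/inverse use `scipy.special.boxcox`/`inv_boxcox`; round
  trips are exact to 1e-10 across the working domain.
- Validation: metabolite concentrations must be nonnegative; vcDML and C_R
  may be negative; unknown horizons (other than 20/100 y) and drying
  temperatures (other than 60/100 °C) are errors, not silent defaults.
- Tables are comma-separated UTF-8 with mandatory headers; missing values
  are empty fields; per-row `units` may be `percent_dm` or `mg_per_kg`.
- The packaged compound table stores published per-row CDMP and ozone-GWP
  cells as `*_printed` audit columns. Several are inconsistent with the
  row's own arithmetic (heptanal's 20-year ozone cell is ~100× MRC × EBIR ×
  2.04), so derived quantities are always recomputed from molar mass, MCE,
  MRC and EBIR, while the *aggregate* constants consumed by the equations
  are the published ones (6.2e3, 1.6e3, 99.2, 0.49, 6.2e3, 1.3e3). Both
  printed and recomputed aggregates are surfaced for audit; recomputed
  values match the published ones at their printed precision.

## Known limitations

- Laboratory-scale population only; commercial-scale dry matter losses are
  several-fold larger and would need their own input distributions.
- No enteric, field or full life-cycle emissions; this is the fermentation
  stage only.
- The ozone GWP derivation is a deliberate simplification (amortized
  steady-state forcing ratio), not an atmospheric chemistry model.
- Independence between simulated metrics likely understates the variance of
  GWP relative to a correlated population.
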