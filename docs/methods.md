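# Methods

This note documents the models, numerical choices and known limitations of
`fallowcast`.  Notation: `P` precipitation (mm), `T` monthly mean
temperature (°C), `PET` potential evapotranspiration (mm), `y` yield
(kg ha⁻¹).

## Calendar and stage windows

All records are keyed to the **test year** — the calendar year of the
July–September fallow window.  Sowing follows in October of the same year
and harvest comes the next June, so growth-stage months carry a +1
calendar-year offset.  The default whole-month approximation of the
stage boundaries is

| stage | months |
|---|---|
| fallow | Jul–Sep (year Y) |
| sowing–jointing | Oct (Y) – Mar (Y+1) |
| jointing–anthesis | Apr (Y+1) |
| anthesis–maturity | May–Jun (Y+1) |

The true boundaries are ten-day periods (e.g. fallow begins in the last
ten days of June); monthly granularity is the package's canonical
resolution because the drought index and the published stage totals are
monthly, and the calendar is configuration-overridable for sites with a
different phenology.  With this keying, fallow + whole-growth
precipitation equals the July–June annual total, and the September SPEI-3
of year Y is directly the drought index of test year Y.

Accumulated temperature is Σ(monthly mean × days in month) in °C·d, with
no base-temperature threshold — the input record is monthly, and a base
would require daily data.  Missing station months are filled with the
multi-year mean of the same calendar month (or whole years dropped, by
policy); imputation is idempotent.

## SPEI-3 and year typing

Thornthwaite PET uses the standard sub-formulas: annual heat index
`H = Σ_{T>0} (T/5)^1.514` over a year's 12 months, exponent
`A = 6.75·10⁻⁷H³ − 7.71·10⁻⁵H² + 1.792·10⁻²H + 0.49239`, and
`PET = 16 (10T/H)^A` for `T > 0`, else 0.  An optional day-length
correction `(N/12)(days/30)` from latitude is available but off by
default, matching a formulation that omits it.

The climatic balance `D = P − PET` is summed over trailing 3-month
windows; for each calendar month the k-month sums across the calibration
years (default: all years supplied) are fitted with the 3-parameter
log-logistic via **unbiased probability-weighted moments**:
with `w₀, w₁, w₂` the order-0..2 PWMs,

    β = (2w₁ − w₀) / (6w₁ − w₀ − 6w₂)
    α = (w₀ − 2w₁) β / (Γ(1+1/β) Γ(1−1/β))
    γ = w₀ − α Γ(1+1/β) Γ(1−1/β)

the canonical estimator for this index.  The fit requires n ≥ 4, a
non-degenerate sample, and β̂ > 1 (the mean must exist).  Standardization
maps the exceedance probability `p = 1 − F(x)` through the
Abramowitz–Stegun rational approximation (c₀ = 2.515517, c₁ = 0.802853,
c₂ = 0.010328; d₁ = 1.432788, d₂ = 0.189269, d₃ = 0.001308), with the
sign flip at p > 0.5; probabilities at the support edge are clipped to
10⁻⁶ with a warning.  The estimator is exact in the large-sample limit
(checked against an independent log-logistic implementation); at n = 200
the origin parameter's sampling error can exceed 15% for unlucky draws,
which is sampling variance, not bias.

**Nonparametric fallback.**  Ten-year September samples that are strongly
bimodal (a tight dry cluster against a long wet tail) can push the PWM
shape estimate outside the valid domain.  When the parametric fit is
invalid for a month, the series falls back to empirical standardization by
Gringorten plotting positions passed through the same normal-quantile
approximation.  This preserves ranking and the drought/normal partition;
the parametric path remains the default and is what the property tests
exercise.

Year typing: drought iff September SPEI-3 ≤ −0.5 (inclusive), normal
otherwise.  The exact year labels of the original station record are not
asserted anywhere — they depend on the station's full daily inputs — but
the labelled drought years always have lower mean fallow rainfall than the
labelled normal years, and raising any fallow month's rain never lowers
that year's September index.

## Soil water and yield accounting

Gravimetric water content `GSW = (wet − dry)/dry × 100` (%), layer storage
`GSW/100 × ρ_b × SD × 10³` mm, profile storage the sum over fifteen 0.2 m
layers to 3 m, with contiguity checked.  Yields are standardized to 12.5%
grain moisture by dry-matter conservation,
`y_std = y_fresh (1 − mc)/(1 − 0.125)`; the conversion formula is the
grain-trade convention (the source states only the standard moisture).
Treatment summaries are unweighted means per (precipitation type ×
tillage) cell with counts; correlation screening is plain Pearson r with
two-sided t-based p-values, reported unadjusted (no multiplicity
correction is applied in this analysis tradition).

Known source discrepancy: the published treatment-summary table's SS cells
(normal 4385.94, drought 4437.41 kg ha⁻¹) disagree with the means of the
same publication's per-year SS columns (4437.41 and 4811.04) — an apparent
label swap.  The package recomputes means from per-year values and bundles
both printed tables; likewise the printed drought-DP MEAN prediction
(4984.30) does not equal the mean of its own five per-year predictions
(5024.30), and the recomputed value is what `relative_error_table`
reports.

## Detrending

Trend yield is the 3-year centered moving average of each tillage's annual
mean yield.  Endpoints use the mean of the available in-window years
(2-year windows), so the first and last years still receive a trend value
— required because both appear in the reported results.  The error term of
the three-component decomposition is absorbed into the meteorological
yield, so `y = y_t + y_c` holds exactly and `y_w = y_c/y_t` is scale-free.
A cubic least-squares polynomial (degree configurable) is fitted to each
trend series for reporting; downstream computation always uses the moving
average itself, following the stated detrending method.  The alternative
reading of "3-year linear and sliding average" as a linear-then-smoothed
hybrid is noted but not implemented.

## Factor analysis

Principal-component extraction on the correlation matrix of the 14
meteorological indices; factors with eigenvalue > 1 retained (this
retention rule is what makes PC extraction the consistent choice);
varimax rotation by SVD updates, which preserves per-variable
communalities to machine precision; per factor, the variable with the
largest absolute rotated loading is selected, ties broken by column order
and duplicates skipped so selections stay distinct.  A `top_k_per_factor`
option supports selecting more than one index per factor, since the
source text lists six selected indices against four factors.  With only
~10 year-level rows the 14×14 correlation matrix is singular; plot-level
rows (or generated long records) are the supported use, and the year-level
pipeline stage reports the factor solution without depending on it.

## The tree ensemble

`RandomForestRegressor` with N = 200 trees, m = 5 candidate features per
split, unlimited depth, minimum leaf 1, bootstrap resampling, one seed for
all randomness.  m = 5 equals the default 5-predictor pool (fallow and
sowing–jointing precipitation; storage at sowing, jointing, anthesis), so
split-level feature sampling is effectively disabled; a warning notes this
whenever m ≥ p, and the literal m = 5 is kept as the protocol default.
OOB RMSE is computed from out-of-bag predictions.  `tune_ntree` scans a
grid and picks the smallest N whose RMSE is within 2% of the grid minimum
(the curve flattens near 200 trees on the study-scale records).  Targets:
unit yield, meteorological yield, relative meteorological yield, spike
number, grains per spike; detrended targets map back to kg ha⁻¹ via
`ŷ = y_t + ŷ_c` or `ŷ = y_t(1 + ŷ_w)`.

The unit-yield target cannot extrapolate the technology trend beyond the
training years — predictions are bounded by training targets — which is
why the detrended targets are preferred for multi-year forecasting; the
package reproduces this behaviour rather than hiding it.

## Evaluation

`R² = 1 − Σ(S−O)²/Σ(O−Ō)²`, `RMSE = √(Σ(S−O)²/n)`, and
`MRE = (1/n)Σ|S−O|/S` with the *predicted* value as denominator, as the
metric is formally defined.  The per-year error tables instead divide by
the *true* value — only that convention reproduces the published per-year
error column — and MEAN rows average true and predicted values first, then
apply the same formula to the means (not the mean of the per-year errors).
Reports round to 2 decimals; full precision is kept internally.

## Synthetic data generator

The generator emulates the study conditions with recorded ground truth:

- **Weather.**  Temperature is a sinusoid around the site's 13.72 °C
  annual mean with a 13 °C continental amplitude and small monthly noise;
  sunshine totals ~2461 h yr⁻¹ with a summer peak.  Monthly precipitation
  is gamma-distributed: fallow months use shape 12 (many monsoon storm
  events → tighter relative spread) scaled by a lognormal (σ = 0.25)
  year-level monsoon strength; off-season months use shape 4.  Fallow
  means are set so the *mean* fallow share of annual precipitation hits
  the 0.6 target after drought down-scaling (factor 0.5 applied to a
  seeded half of the years).  The resulting interannual fallow
  distribution is right-skewed — a tight dry cluster and a long wet tail —
  matching the observed record's shape; symmetric alternatives produce
  L-skewness outside the log-logistic domain, i.e. unrealistic climates.
- **Storage.**  Per (year × stage × tillage), storage loads on the
  standardized fallow anomaly `w` with the target storage–yield
  correlations (sowing 0.78, wintering 0.80, jointing 0.95, anthesis 0.92,
  maturity 0.75), plus tillage recharge offsets (DP +30, SS +25, NT 0 mm)
  and residual noise filling the remaining unit variance.
- **Yield.**  `y = trend + β_w w + β_z z_joint + tillage + noise(150)`,
  where `z_joint` is the (year × tillage) jointing-storage anomaly and the
  weather-driven component splits evenly between the two drivers so each
  carries an independently recoverable signal (βs are normalized to keep
  the total weather-driven variance at 550² kg² ha⁻²).  Tillage offsets
  DP +650, SS +500, NT −350 kg ha⁻¹ reproduce the published ordering and
  the ~16% DP-over-SS drought contrast at the observed yield scale; the
  technology trend is 60 kg ha⁻¹ yr⁻¹ from a 4000 kg ha⁻¹ base.  The plot
  residual of 150 kg ha⁻¹ matches the scale implied by the published
  validation RMSE (94–154 kg ha⁻¹).  Yield components share the water
  signal with year-level plus plot-level noise, tuned weak for
  thousand-grain weight (r ≈ 0.4–0.6) and strong for spike number and
  grains per spike, as in the published correlation screen.  An optional
  late-era shock subtracts a constant from all yields from a given year
  on, emulating validation-era conditions the predictors cannot see.

What the generator does **not** emulate: spatial heterogeneity between
plots, pest/disease shocks, daily weather structure, year-to-year carryover
of soil water, or any nonlinearity in the weather–yield link.  Passing
tests therefore demonstrate that the implementation recovers known
structure under the stated conditions — not that the model would attain
the same accuracy on new field data.

## Problem sizes used in checks

Desk-scale table arithmetic runs on the bundled 10-year record.  The
signal-recovery checks use 150 generated years × 3 plots (450 rows; 120/30
chronological split): many distinct years at few replicates keeps the
year-level signal learnable, whereas few-year/many-plot layouts let
fully-grown trees memorize year identity through storage values, which
also makes out-of-bag error over-optimistic (sibling plots of the same
year are in-bag for most trees).  For the same reason, permutation
importance is computed on held-out rows, and the OOB-vs-holdout agreement
check uses exchangeable rows (no trend, one replicate per tillage).  The
trial-shaped 10 × 69 layout is retained for the 552/138 split bookkeeping
and the end-to-end pipeline.

## Known limitations

- Monthly resolution throughout; the ten-day stage boundaries are
  approximated to whole months.
- SPEI calibrated on the record itself (default): with 10 years the index
  is a within-sample ranking more than a climatological anomaly, and the
  nonparametric fallback may engage for pathological samples.
- The factor-analysis stage is descriptive at year-level sample sizes.
- Model state is kept in memory (refit from seed + data reproduces
  predictions bit-identically); no serialized model-file format is
  provided.
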