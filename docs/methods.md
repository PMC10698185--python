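# Methods

## Problem and model

The package estimates the mass of each pesticide active substance (AS)
applied annually in small regions, split across six agricultural
land-cover classes. Reported use is available only for a subset of
countries, at heterogeneous spatial resolution (country, province or
region level), for the crops each country happens to survey. The
estimation proceeds in two moves:

* **downscaling** of the reported amounts to regions, proportionally to
  dose-weighted applicable crop areas (a mass-conserving dasymetric
  apportionment), which yields a calibration dataset of (region,
  substance, class, kg) rows; and
* **regression extrapolation**: for each substance × class, a linear model
  y = β₀ + Σ βⱼxⱼ + ε of regional use on crop-group areas (ha) and
  regional climate summaries, fitted on the calibration regions of the
  reporting countries and applied to every region's total crop extents.

Two crop-extent datasets play distinct roles. Calibration uses the
*reported-coverage* extents — the share of each crop's area for which use
was actually reported — because the reported kilograms refer only to that
share. Prediction uses *total* extents. Keeping the two apart is what
allows the fitted coefficients (kg/ha at the crop-group level) to transfer
from partially covered calibration data to full landscapes.

Responses are modelled on the raw kg scale, not log-transformed: the
non-negativity semantics of the constrained model (M6) apply to raw
coefficients, and predictions must add up in kilograms. Log scales appear
only in displays and in order-of-magnitude comparison statistics.

## The model cascade and the decision policy

Six model variants are fitted per substance × class dataset:

| id | definition | role |
| --- | --- | --- |
| M1 | OLS on the applicable crop-group areas | baseline |
| M2 | M1 after bidirectional stepwise AIC on the crop terms | used only on arable land, where up to ten crop groups compete; elsewhere it would equal M1 |
| M3 | M2/M1 terms + categorical country effect | diagnostic only; flags country-specific use; never extrapolated |
| M4 | stepwise AIC addition of retained climate features, crop terms protected, at most 4 climate terms | tests whether climate adds explanatory power |
| M5 | Huber M-estimation (IRLS, tuning constant 1.345, MAD scale, coefficient-change tolerance 1e-8, max 200 iterations) | damps outlying regions |
| M6 | least squares with βⱼ ≥ 0 and β₀ = 0 | enforces physical coherence: no negative use per hectare, no use on zero area |

AIC is computed on the least-squares profile likelihood,
n·ln(RSS/n) + 2(k+1), with the RSS floored at 1e-16·Σy² so that two
numerically interpolating fits are compared by parameter count alone
(without the floor, meaningless differences between residual sums of
order 1e-20 dominate the criterion on noise-free data).

The deterministic selection policy per substance × class:

1. substances with strictly positive reported use in fewer than 4
   reporting countries are ineligible;
2. the base model is M2 on arable land, M1 otherwise; M3 is fitted only to
   set the `country_specific` flag (ΔAIC > 2 against the base);
3. M4 adds climate terms; for non-arable classes a clean M4/base
   (cross-validated NSE > 0, no negative coefficient, intercept within 10%
   of mean |y|) is accepted directly;
4. otherwise M5 is fitted and outliers are diagnosed (below); M5 is
   preferred when outliers are flagged;
5. a preferred model with any negative coefficient or an intercept beyond
   tolerance is replaced by M6 on the same features;
6. finally, a model whose cross-validated NSE is ≤ 0 (no better than
   predicting the mean) is excluded — with reason `country_specific_only`
   when the M3 diagnostic fired, `cv_fail` otherwise.

Every eligible substance × class receives exactly one decision with a
reason code (`accepted_base`, `accepted_M4`, `outliers->M5`,
`negative_coefs->M6`, `cv_fail`, `country_specific_only`, `ineligible`),
kept in a machine-readable audit structure. "Minimize the intercept" is
realized as β₀ = 0 in M6 (the physically coherent reading: zero
agricultural area implies zero application); a free non-negative intercept
is available via `intercept_mode="nonneg"`.

**Outlier diagnosis.** A region is flagged when its Cook's distance under
the M4 OLS fit exceeds 4/n (the usual screening threshold) **and** the M4
and M5 predictions for it differ by more than one robust residual sd of M4
(1.4826 × MAD of the residuals). The conjunction matters: the 4/n screen
alone flags a few percent of perfectly clean observations (and on
heavy-tailed area distributions legitimate high-leverage regions reach
Cook's distances above any absolute cutoff), while the plain residual sd
is inflated by the very outlier it should detect. Flagged regions steer
the policy toward M5; rows are never deleted.

## Predictors

* Climate: per region, five statistics (min, max, median, mean, sample sd;
  sd = 0 for a single cell; even-count medians use the midpoint) of each
  of the 24 monthly variables — 120 candidate features. Collinearity is
  removed by iterative pairwise pruning: while any pair of remaining
  features has |Pearson r| above the threshold (default 0.9, on raw
  untransformed features), the member of the worst pair with the larger
  mean absolute correlation to the remaining features is dropped (ties
  drop the later column; constant columns are dropped first with a
  warning). The procedure is deterministic given column order and
  guarantees no retained pair exceeds the threshold. Under the default
  synthetic climate geometry it retains 12 features.
* Crops: 44 crop codes pool into 16 group predictors, each group belonging
  to one land-cover class (ten arable groups, two fruit-tree, one each for
  grassland, olives, vineyards, rice). Dose weights within a group are
  uniform unless the substance profile supplies relative recommended
  doses. Together: 28 candidate predictors.

## Cross-validation and metrics

Repeated k-fold CV (default 10-fold × 100 repetitions; the in-cascade
gate uses 10-fold × 5 for speed, configurable in `CascadePolicy`)
re-fits the selected model family on k−1 folds and predicts the held-out
fold; every observation is validated exactly `repetitions` times, with
seeded shuffling. Leave-one-country-out CV probes cross-country
transferability: a country's rows are predicted by a model that saw none
of them.

Metrics: SMAPE on the [0, 2] scale (mean of 2|ŷ−y|/(|y|+|ŷ|), 0/0 terms
counted as 0); NSE = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²; NRMSE = RMSE/mean(y);
NMAE = MAE/mean(y); R² = squared Pearson correlation. NRMSE and NMAE are
normalized by the mean of the observations (range-normalization is the
common alternative); the normalizer is recorded in every report. External
comparisons use ratios of summed amounts and the median ± MAD of
log₁₀(modelled+1) − log₁₀(reported+1), with |deviation| ≤ 1 counted as
"within one order of magnitude" (boundary inclusive); the +1 kg shift
keeps zero amounts finite on the log scale.

## The synthetic data generator

The generator emulates the statistical structure of the real inputs; it
is the ground truth against which the pipeline is tested.

* **Crop areas**: log-normal per (region, crop), median 500 ha, log-sd 1.0
  — heavy-tailed like real agricultural statistics. Reported-coverage
  areas are a per-cell fraction of the total (default uniform on
  [0.7, 1.0] in the reference fixture); crops a country does not report
  on, and all crops of non-reporting countries, get zero coverage.
* **Climate**: 12 monthly mean temperatures (°C, seasonal base level) and
  12 monthly mean precipitations (mm/month, base 80). The regional level
  of month m follows a smooth sinusoidal gradient of frequency m across
  the region sequence (amplitudes 5 °C and 30 mm), shared by that month's
  temperature and precipitation; within-region cell spread (sds 1.0 °C,
  5 mm over 100 cells by default) scales with the same gradient
  (coefficient 0.6). The twelve latent gradients are mutually
  near-orthogonal, so the 120 summary features form twelve tight
  correlation blocks (within-block |r| ≈ 0.94+, cross-block ≈ 0.08) and
  pruning at 0.9 retains one feature per block.
* **True use**: kg(region, substance, crop) = dose(group) × area ×
  country multiplier × exp(Σ c_f z_f) × exp(ε), with standardized climate
  features z_f and ε ~ N(0, noise_sd²) drawn per (substance, crop,
  region). Multiplicative noise keeps use non-negative. Note that OLS on
  such data consistently estimates the mean-scale effective dose
  dose·exp(noise_sd²/2) (≈ 1.046 × dose at sd 0.3); recovery checks
  compare against that estimand.
* **Reporting**: sums of true use (computed on reported-coverage extents)
  over each country's scope — whole country, provinces (contiguous blocks
  of 2 regions), or single regions — excluding unreported crops; optional
  per-year replicates with log-normal noise.
* **Reference fixture**: 12 countries × 10 regions, 8 reporting (4 at
  country, 3 at province, 1 at region level) and 4 silent; 44 crop codes
  in 16 groups; 12 substances with fixed doses (0.35–3 kg/ha) spanning
  all six land-cover classes; one substance used in only 2 countries
  (exercising the eligibility filter); one country not reporting the
  plants-harvested-green crops; seed 42; noise- and climate-free by
  default so the truth is exactly recoverable.

What the generator does **not** emulate: spatial geometry (regions are a
sequence, not polygons), crop rotation and year-to-year dynamics,
dose heterogeneity between crops within a group, correlated reporting
errors, and the national idiosyncrasies of real surveys. Passing tests
therefore demonstrate the internal correctness and statistical behaviour
of the pipeline — conservation, recoverability, convergence, policy
determinism — not the accuracy of any real-world inventory.

## Numerical choices and problem sizes

* Rank-deficient designs drop aliased columns (QR with pivoting) with a
  warning.
* Stepwise accepts a move only if AIC improves by > 1e-10; the result's
  AIC never exceeds its starting model's.
* M6 is solved by active-set NNLS; KKT conditions are verified in tests to
  1e-6 (scaled).
* Negative extrapolated predictions (possible for intercept-bearing
  models) are clipped to zero and counted; M6 cannot produce them on
  non-negative predictors.
* Duplicate reports for the same (country, scope, substance, year) are an
  error — no precedence is guessed.
* Default problem sizes (120 regions, 100 climate cells/region, 12
  substances; convergence checks on 40–160 regions with 10 seeded
  replicates) keep the full suite around a minute while leaving every
  statistical assertion comfortably powered.

## Known limitations

* The decision policy is fully deterministic; the expert-judgement
  overrides that a human analyst might apply (variable transformations,
  weighted least squares, manual outlier removal) are out of scope.
* The authorization default for pairs absent from the table is
  *authorized* (permissive, logged): only known non-authorizations mask.
* Climate enters the generator multiplicatively but the models linearly;
  with strong climate effects the linear cascade is a first-order
  approximation, which is intentional — the models are approximations in
  reality too.
* `country_specific_only` exclusions depend on the ΔAIC > 2 margin, a
  conventional evidence threshold, not a calibrated error rate.
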