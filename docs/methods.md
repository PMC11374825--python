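# Methods

## Exposure assembly

Gestational week 1 begins on the conception date (day 0); week w covers
days 7(w−1)…7w−1 from conception for every w in −11…42, so preconception
week 0 is the 7 days immediately before conception and the 12
preconception weeks are −11…0. All date arithmetic is day-count based (no
time zones, no menstrual-dating adjustments). Follow-up ends at the *end
week*: the diagnosis week for cases, the delivery week for controls,
capped at 42. The *event day* used by period averages is the last day of
the end week, since the data are weekly-resolved.

Period averages are daily means over exact day ranges: preconception
(84 days before conception), pregnancy (conception through the event
day), trimesters 1–3 (weeks 1–13, 14–26, 27–event), and preconception-
through-event. A trimester that starts after the event day is absent; one
that straddles it is truncated at the event day.

The fixed-cohort-bias filter retains conceptions in
[cohort_start − 20 weeks, cohort_end − 42 weeks]: every gestational
length 20–42 weeks then delivers inside the observation window, so
neither unusually short nor unusually long gestations are differentially
truncated at the window edges.

Prediction levels (P1, P5, median, P95, P99, and the mean for the
mean-reference sensitivity) default to centiles of the subject-level
preconception-through-event averages; a person-week option is available.
Quantiles use linear interpolation between order statistics.

## Padding the weekly matrix

The cross-basis needs a complete −11…42 row per subject while follow-up
varies, so masked weeks must be filled. Three policies are implemented:

* `median` (default): cohort median of observed person-weeks;
* `locf`: last observed week carried forward;
* `natural`: the location's actual climate after the event.

A caveat that matters: with any *constant* fill, the count of padded
weeks is a deterministic function of the end week, and the end week is
correlated with case status by construction (diagnosis truncates
follow-up earlier for cases than delivery does for controls). A logistic
DLNM can and does exploit that direction of the design, which distorts
the fitted coefficients well beyond their nominal standard errors — in
our simulations the fitted-minus-true linear predictor correlated −0.6
with the end week and late-lag "protective" artifacts appeared. `natural`
padding removes the channel entirely (post-event weeks carry ordinary
climate, uninformative about the outcome) and is what the validation
experiments use; it requires climate coverage through week 42 for every
subject. For ingested datasets without such coverage the constant fills
remain available, and late-lag features estimated under them should be
read with this artifact in mind.

## Spline bases

Natural (restricted) cubic splines: cubic between knots, linear beyond
the boundary knots, continuous second derivatives. Construction is by
projection of a cubic B-spline basis onto the null space of the
second-derivative boundary constraints; evaluation outside the boundary
knots uses the first-order Taylor extension at the boundary, which is
exact for a natural spline. Interior knots sit at equally spaced
quantiles of the observed values (exposure dimension) or of the integer
lag grid (lag dimension); boundary knots at the observed min/max. Same
data and spec therefore always give the same knots, and specs serialise
to plain dictionaries so a fit can be reproduced bit-for-bit.

The exposure basis carries no intercept (the model has a single global
intercept). The lag basis *does* span constants: a surface component that
is constant in lag is otherwise inexpressible, and the usual DLNM
software convention includes it. `df` always counts total columns, so the
default 4 × 3 cross-basis has 12 columns either way.

## Fitting and inference

Binomial-logit likelihood, maximised by IRLS with step-halving whenever a
Newton step would decrease the log-likelihood; convergence requires score
max-norm < 1e-8 (max 100 iterations). The covariance matrix is the
inverse observed information at the optimum. Full-column-rank is checked
up front via pivoted QR and rank deficiency is reported with the
offending column names; separation is raised explicitly when fitted
probabilities collapse onto the labels or the information matrix becomes
singular. AIC = −2·loglik + 2·(number of coefficients); the df grid
search refits each (df_x, df_lag) pair, records failures, and returns the
argmin plus the full table.

Curves and cumulative ORs are linear contrasts of the cross-basis
coefficients with delta-method standard errors and Wald 95% intervals
(z = 1.96) on the log scale. At the reference exposure the contrast is
identically zero, so OR = 1 with a zero-width interval. Prediction levels
beyond the exposure boundary knots are permitted (the basis is linear
there) but flagged as extrapolation. Critical windows are maximal runs of
consecutive weeks whose CI excludes 1, split by direction; `min_run`
drops short runs (default 1 keeps everything).

Covariate coding: fixed reference levels (female, non-Caucasian,
unmarried, non-smoker, nulliparous, non-urban, high SES); conception
month and year as categorical indicators to absorb seasonality and drift
non-parametrically (a continuous-index option exists); maternal age as a
3-df natural spline, or the categorical bins ≤19 / 20–34 / ≥35 in the
corresponding sensitivity variation. Rows with unknown covariate levels
are dropped listwise with counts logged. Exposure ORs are invariant to
the reference-level choices (tested).

Early-onset models use cases diagnosed at ≤ 34 weeks with lags −11…34;
late-onset ≥ 35 weeks with lags −11…42; the other onset stratum leaves
the comparison group. Controls for each outcome are all pregnancies
without that outcome. Strata or subgroups whose fits fail (separation at
tiny case counts) are skipped with a logged warning rather than silently
reported.

## Synthetic data

The climate generator produces one daily UTCI series per location:
mean level 14.5 °C + location offset + seasonal cosine (amplitude 6 °C,
peak mid-January — a Southern Hemisphere summer) + AR(1) noise
(coefficient 0.6, innovation SD 3.5 °C, stationary initialisation).
Location offsets are N(0, 2 °C) with an 8% "hot" mixture offset by a
further +3…13 °C, giving the pooled exposure distribution a long right
tail (subject-average 99th centile well above the median) like that of a
population concentrated in a temperate region with a tropical-north
minority. Weekly means then have SD ≈ 5 °C around ≈ 14.5 °C.

The cohort generator draws conception dates uniformly over 1999–2015,
gestational lengths with ~90% mass on 37–41 weeks and small early/
post-term tails, covariates at the prevalences of the study population
(51.2% male, 78.3% Caucasian, 87.3% married, 14.7% smokers, 58.1%
multiparous, 61.9% urban, SES tertiles), and maternal age ~N(29.5, 5.5)
truncated to 15–45. Outcomes are mutually exclusive labels drawn from
per-outcome logistic models: baseline intercepts logit(0.037) for
gestational hypertension and logit(0.028) for preeclampsia, plus the
configured lag-response surface summed over the at-risk weeks (−11
through the gestational length), plus optional covariate effects (zero by
default; a confounded mode ties smoking to conception month to exercise
adjustment). Cases then receive a diagnosis week from a base distribution
truncated at their gestational length — most mass at ≥ 35 weeks, with
early-onset fractions of 7.5% (gestational hypertension) and 23%
(preeclampsia). The generating truth (surface parameters, intercepts,
covariate effects, seeds) is stored losslessly for recovery tests.

Truth surfaces: `null` (no effect); `inverted_U`, a Gaussian lag bump
(peak week 13, SD 5.5 weeks) times a linear exposure ramp scaled so the
weekly log-OR at 26 °C — a 99th-centile exposure — peaks at 0.1 (OR
1.10); `inverted_U_spline`, the same idea with a compact raised-cosine
bump (support ≈ weeks 6–20, i.e. inert after the earliest possible
diagnosis) projected onto the span of the deterministic lag spline basis,
so a DLNM using the same knot rule contains the truth exactly; and
`custom_grid` for arbitrary tabulated surfaces.

What the generator does *not* emulate: real geography (locations are
exchangeable draws, no spatial interpolation or SA1 geometry), residential
mobility, climate trends beyond the seasonal cycle, multiple gestations,
competing events such as preterm delivery induced by the exposure, or
outcome misclassification. Passing tests on this cohort therefore
demonstrate that the estimation machinery is correct and calibrated under
the stated generating process — not that the epidemiological estimates
from any real cohort are unbiased.

## Validation experiments

Two experiments, shared by the test suite and `scripts/acceptance.py`,
each use 25 replicate cohorts of 50,000 pregnancies (a size that keeps
the two runs to a few minutes while leaving per-week standard errors
around 0.01–0.03 on the log-OR scale), single-outcome prevalence 3.7%,
zero covariate effects, unadjusted fits, `natural` padding, and df (4, 4)
with the truth built inside that lag span:

* **Recovery** — inverted-U truth, curve evaluated at 26 °C vs the
  14.2 °C reference: mean truth-vs-fit RMSE of the 54-week log-OR curve,
  pointwise 95% CI coverage, and whether a detected harmful window
  overlaps weeks 8–18.
* **Null calibration** — null truth: pooled per-week rate at which the
  95% CI excludes 1 (no multiplicity correction), and the fraction of
  replicates whose all-weeks cumulative-OR CI covers 1.

Placing the truth within the fitted function class is deliberate: weekly
exposures are strongly collinear across lags (the seasonal cycle), and
under collinearity even small spline-approximation error projects into
poorly identified coefficient directions and distorts the curve far
beyond its nominal CIs. The experiments therefore measure estimation
error; approximation error for out-of-span surfaces is a separate,
design-dependent question that the df/AIC machinery addresses.

## Known limitations

* Constant-fill padding carries the end-of-follow-up artifact described
  above; `natural` padding needs post-event climate coverage.
* The delta method and Wald intervals are first-order; at very small case
  counts (early-onset strata of small cohorts) fits separate and are
  skipped rather than penalised (no Firth correction).
* No survival-time modelling: the outcome is a per-pregnancy dichotomy,
  matching the study design this package implements.
* Trimester one-bases use each period's own quantile knots, so their OR
  tables are comparable across modes but not across differently
  distributed periods at identical exposure values.
* Uncertainty in the prediction centiles themselves (estimated from the
  same cohort) is ignored, as is spatial/temporal exposure measurement
  error.
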