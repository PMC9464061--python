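# Methods

## Model

Households of a city are classified into a low-income minority (`c = 1`,
income at or below a minimum-wage cut-off) and a reference group (`c = 0`).
The counts `nⱼᶜ` over the `J` census tracts are modelled as a product of two
independent multinomials, `Mult(n¹, p¹)` × `Mult(n⁰, p⁰)`, whose MLE is the
observed tract shares `p̂ⱼᶜ = nⱼᶜ/nᶜ`. The dissimilarity index
`D = ½ Σⱼ |p̂ⱼ¹ − p̂ⱼ⁰|` is the plug-in estimator of
`D_pop = ½ Σⱼ |pⱼ¹ − pⱼ⁰|`; an equivalent conditional form weights tracts by
size and compares `P(c=1 | tract)` against the overall minority probability.
Both forms are implemented and agree to 1e-12 by construction.

Two reference-group conventions exist in the segregation literature:
minority vs. the complement (the form the index formula uses) and minority
vs. the total population. The package implements both; the default is
`complement`, because the formula's `nⱼ = nⱼ¹ + nⱼ⁰` decomposition only holds
there, and the mode used is recorded in every `SegregationResult`. The two
differ numerically, so published values should not be compared across modes.

Tracts with zero reported households are dropped with a logged warning;
tracts where only one group is present are retained (the index handles
them). Households that did not report income are assumed excluded before the
table is built.

## Bias quantification

The plug-in `D` is biased upward in finite samples. Two resampling schemes
are offered:

* **parametric** (default): Efron's bootstrap bias estimator at the fitted
  model — replicate tables drawn from the MLE multinomials,
  `bias = mean(D*) − D`, corrected index `2D − mean(D*)`, clipped to [0, 1]
  with a flag when clipping fires. The replicate standard deviation is
  reported as the bootstrap SE.
* **random_allocation**: both groups allocated by tract size
  (`pⱼ = nⱼ/n`), a no-segregation null whose mean replicate `D` is the
  unevenness expected by chance — the classical "systematic vs. random"
  reference point.

Bias is reported both in index units and as a percent of the observed `D`;
the literature's informal "below half a percent" statements do not say
which scale they mean, so both are always available. Default `B = 1000`
replications: at typical city sizes the Monte-Carlo SE of the bias is far
below the bias magnitudes of interest.

An exact oracle, `exact_expected_D`, enumerates the full product-multinomial
outcome space (rejected above 10⁶ outcomes) and anchors the bootstrap in
tests; for two tracts with one household per group per tract the exact
`E[D]` is 0.375.

Measured behaviour of the correction on synthetic cities with 10 tracts of
50 households: it removes most of the error at low true segregation
(`D_pop` 0–0.1, where the upward bias dominates) and is approximately
neutral at `D_pop` 0.3–0.5, where the bias is small relative to sampling
noise and the correction trades a small bias reduction for a little added
variance. Pooled over that ground-truth range the corrected index has
clearly smaller mean absolute error.

## Cut-off selection

Each candidate cut-off is scored by the household-weighted pooled national
minority share (not an unweighted mean of city shares) plus the per-city
distribution of `D` and its bias. The rule returns the smallest cut-off
whose pooled share lies in `[lower, upper)`; `upper = 0.5` is definitional
(above it the group is no minority), while `lower = 0.2` is this package's
operationalization of "large enough to be stable" — the literature rejects
shares of a few percent verbally without naming a threshold, so the bound is
configurable and surfaced in the CLI help. The scan never assumes `D` is
monotone in the cut-off (it is not; the tests construct a witness).

## Association models

The panel carries one row per city: IDI plus Gini (normalized mean absolute
income difference), poverty rate, GDP per capita, unemployment, and the
Social Environment Index — an equal-weight mean of z-scored education, water
access, sanitation and reverse-coded overcrowding. All covariates are
z-scored (sample SD, n−1); population enters as the natural log before
z-scoring. Model 1 regresses IDI on Gini, model 2 on the poverty rate
(a `model2_text` variant uses SEI instead, since both variants circulate for
the "second model"), model 3 on the full covariate set.

By default the outcome is z-scored as well, which makes the model-1
coefficient exactly the Pearson correlation and puts coefficients on the
per-SD scale on which they are usually reported. `standardize_outcome=False`
leaves the outcome on its stored scale; parameter-recovery tests use it
because z-scoring the outcome by its sample SD would divide the estimand by
a random factor and distort confidence-interval coverage of the generating
coefficients. Confidence intervals are t-based at 95%.

Diagnostics per fit: Breusch–Pagan/Cook–Weisberg (LM form), White's general
test, and Durbin–Watson. A city panel has no time ordering, so DW is
computed over stored row order and should be read as an order-sensitive
descriptive, reported for completeness rather than inference. Missing
covariates are handled by listwise deletion with a logged count.

## Synthetic data

The generator emulates the operational features of Brazilian census tracts
that matter for the index: near-equal tract sizes (targets jittered ±10%
uniformly, default 300 households), household income in minimum-wage units
drawn log-normal and binned at {½, 1, 2, 3} (minimum wage normalized to
1.0), and a city-level true segregation level imposed exactly.

Defaults: `sigma = 0.9` and `mu = ln 2 + 0.418·sigma`, which by construction
puts 33.8% of households at or below 2 MW and yields roughly 2.5% below
½ MW, 12% below 1 MW and 51% below 3 MW — the empirically observed pattern
of shares across cut-offs. The default poverty line of 1.5 MW implies a
head-count rate near 0.24. Regional effects shift the income scale and the
target `D_pop` upward for the "ne"/"n" tags and downward for "s"/"se".

Calibration inverts the population-index formula: minority allocation
probabilities are tilted up by `δ` on half the tracts and down on the rest,
and the reference allocation compensates so every tract keeps the same
expected size (the IBGE equal-households design). Then
`D_pop = h·δ/(1−p)` for `h` tilted tracts and minority share `p`, solved for
`δ` in closed form; infeasible targets (extreme share or tiny `J`) are
rejected with the feasible maximum. Per-city seeds derive from the global
seed as `seed + city index`, so any city regenerates in isolation.

What the generator does *not* emulate: spatial autocorrelation between
neighbouring tracts, within-city variation in tract size policy, migration
or temporal dynamics, and measurement error in reported income. Passing
tests therefore demonstrate the statistical machinery — estimation, bias
correction, selection, regression — under the multinomial allocation model,
not the geography of any real city.

`generate_panel` draws the regression outcome directly as
`idi = Z(X)β + ε` on the z-scored design (defaults `β_gini = 0.5`,
`β_poverty = 0.2`, noise SD 0.5, 152 cities), with Gini and poverty rate
computed from each city's simulated incomes so that covariate pair carries
its natural correlation.

## Numerical choices

* Probability-vector and equivalence checks at tolerance 1e-12; proportions
  in double precision throughout.
* `0·log 0 = 0` in the log-likelihood; a positive count on a
  zero-probability tract gives −∞.
* Ties in the population-quartile split and the city ranking are broken by
  stable sort on `city_id` (ranking first by Gini, then id), making both
  deterministic and permutation-invariant.
* Quartile groups are as equal as possible (152 → 38/38/38/38); one-city
  groups report SD as NaN with a degeneracy flag.
* Pipeline seeds expand from the run seed through `numpy` `SeedSequence`
  streams keyed by stage and city index; all outputs are plain text with the
  run's config hash, and reruns are byte-identical.

## Problem sizes in the test-suite

Simulation-based checks run at sizes chosen to make their Monte-Carlo error
comfortably smaller than the effects they measure: 1000 random models for
the two-form equivalence, 50,000 bootstrap replicates against the
enumeration oracle, 2000 cities (500 per ground-truth level) for the
bias-correction comparison, 500 replicate panels of 152 cities for CI
coverage and diagnostic calibration, and a 20-city end-to-end determinism
run.

## Known limitations

* The bias correction is additive and can clip at 0 for very small, very
  even cities; the clip is flagged, not hidden.
* The random-allocation baseline conditions on observed tract sizes; it is
  a null reference, not an estimator of `D_pop`.
* DW on a cross-section is order-dependent by construction.
* The feasible `D_pop` range of the two-block calibration shrinks as the
  minority share approaches 0 or 1 and for very uneven base weights; the
  error message reports the attainable maximum.
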