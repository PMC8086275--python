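# Methods

## The estimand

The infant mortality rate is the probability q(1) that a live-born
child dies before completing 12 months of age, reported per 1000 live
births.  All estimation applies to births in a reference window of the
`window_months` (default 60) months preceding the survey interview,
matching the usual "five years preceding the survey" convention for
period rates from full birth histories.

Dates are DHS century-month codes (CMC: months since January 1900).
Within-month timing is resolved by placing events at month midpoints,
so a child born in CMC `b` and interviewed in CMC `v` has attained
exactly `A = v − b` completed months and its observed lifetime covers
age months `0 … A−1`.  A recorded age at death of 12 months counts as
having survived infancy (the target interval is the half-open [0, 12)).

## Synthetic-cohort estimation

Infancy is partitioned into the four standard DHS age segments
[0,1), [1,3), [3,6), [6,12) months.  For each segment `[lo, hi)` a
conditional death probability is estimated as a weighted
deaths-over-exposure ratio

    q_a = Σ w·1{died in [lo,hi)} / Σ w·e,

where the risk set is children in the window known to have survived to
age `lo`, and the exposure `e` is 1 for children who attained the
segment's upper bound and `(A − lo)/(hi − lo)` for children interviewed
mid-segment — whether or not they died.  The rate is then
`IMR = 1000·(1 − Π_a (1 − q_a))`.

Two details are deliberate choices rather than DHS's exact variant
(which uses half-cohort weighting at the window boundaries):

* **Risk-set conditioning.**  The denominator excludes children who
  died before the segment starts.  Without it each ratio estimates the
  *unconditional* probability of dying in the segment and the product
  formula understates q(1) by roughly the sum of pairwise products of
  segment risks (≈2% relative at q(1) ≈ 0.05).
* **Fractional exposure for the partially observed.**  Counting a
  mid-segment child in the denominator only when it died (a rule
  sometimes used for simplicity) counts those deaths as a full
  person-segment and inflates q_a by a factor of about
  `(N_full + Σf)/N_full` in the late segments (≈5% for [6,12) at a
  60-month window, ≈2% on q(1) overall).  Fractional exposure makes
  the numerator and denominator expectations proportional with the
  same constant, so the ratio is unbiased whenever deaths are uniform
  over the segment's months — exactly the generator's model, and a
  good approximation for real schedules.

The package therefore recovers generating parameters in expectation,
which the test suite exploits (mean estimate over 50 replicates of
n = 20,000 within 2 Monte-Carlo SEs at q(1) ∈ {0.020, 0.0467, 0.090}).

A deliberately naive cross-check, `cohort_imr_oracle`, computes the
weighted proportion of infant deaths among children old enough to have
completed infancy by the interview.  It uses none of the component
machinery, so agreement between the two (tested at 3 combined
Monte-Carlo SEs) guards against errors in either.

**Uncertainty.**  Survey clusters are the resampling unit: the cluster
bootstrap resamples primary sampling units with replacement (default
B = 1000) and reports percentile intervals.  Per-cluster
deaths/exposure sums are the sufficient statistics, so replicates are
cheap.  Degenerate replicates (a resample with an empty segment) are
dropped.

Empty risk sets raise `UndefinedEstimateError` naming the segment —
never a silent zero.

## Disaggregation

`disaggregate` fits the same estimator within each subgroup of a
stratifier and reports the national average µ from the full sample
(not as a weighted mean of the subgroup rows — the two differ once
subgroup estimates are rounded or suppressed).  The `population`
column is the *unweighted* birth count in the window, matching how
published tables report subgroup sizes; weighted totals are kept
internally and can drive ACI shares via a flag.  Subgroups under
`min_n` births (default 200) are suppressed to NA with the reason
recorded, mirroring the treatment of small subnational samples in
published tables; the threshold is this package's documented default,
not a claim about any particular toolkit's rule.

Published tables read from CSV may state a national population that
differs slightly from the column sum (rounding and suppression make
off-by-small totals common in print); mismatches beyond ±1 raise a
warning, never an error.

## Summary measures

With subgroups ordered most-disadvantaged → most-advantaged:

* `D = μ_dis − μ_adv` and `R = μ_dis/μ_adv` compare the two *extreme*
  ordered subgroups (poorest vs richest), even if an interior subgroup
  happens to have the highest estimate; a max-vs-min comparison is a
  different measure and is intentionally not the default.
* `PAR = μ_ref − µ`, `PAF = 100·PAR/µ`.  The reference is the subgroup
  with the lowest estimate for an adverse indicator (highest for a
  favourable one) — chosen by the estimates, not by the nominal
  ordering, so a non-extreme subgroup can be the reference.
* `ACI = Σ_j p_j μ_j (2x_j − 1)` with population shares `p_j` and
  midpoint cumulative-share ranks `x_j = c_{j−1} + p_j/2`, equal to
  twice the population-weighted covariance of estimate and rank.  It
  requires a genuinely ordered dimension (not binary, not unordered).

NA subgroups make D/R/ACI undefined (raised, and collected as notes by
the batch driver) rather than silently dropped; PAR/PAF remain defined
as long as one subgroup is observed.

**Numerical choices.**  Shares and midpoint ranks are computed in
exact rational arithmetic and the ACI dot product with a correctly
rounded sum (`math.fsum`), so two properties hold bit-exactly rather
than approximately: reversing the subgroup order negates ACI, and
Σ p_j x_j = 1/2.  Under exact subgroup equality ACI returns 0.0 by
construction.

**Confidence intervals.**  The published-table route derives subgroup
standard errors from printed 95% bounds (`SE = (hi − lo)/(2·1.96)`,
a symmetric-normal reading of intervals that are in truth mildly
asymmetric) and uses: Wald for D; the delta method on log R; and for
PAR/PAF/ACI a parametric simulation (B = 2000) that redraws subgroup
estimates from `N(μ_j, SE_j)`, re-selecting the PAF reference per draw
— which widens the PAF interval relative to treating the reference as
fixed, a conservative choice.  With raw birth records, a cluster
bootstrap of the whole disaggregate-then-measure pipeline is available
for every measure.  Printed intervals from other toolkits should be
treated as qualitative comparators: their variance machinery is not
documented and is not reproduced here.

## The synthetic generator

`generate_births` emulates a simplified DHS birth-recode extract, with
defaults chosen to mirror the 2013 Yemen DHS analysis sample: 800
clusters; a 60-month birth window ending November 2013 (CMC 1367);
marginal prevalences for wealth quintiles, education, residence, sex
and the 21 regions following the published sample composition;
q(1) = 0.0467 nationally.  Mechanics:

* Births are uniform over the window; cluster labels uniform over
  clusters.
* Each child's q(1) (scalar, or a per-subgroup marginal map for one
  dimension) is split across the four age segments on the
  log-survival scale via `segment_probabilities` (exact product
  identity `1 − Π(1−q_a) = q(1)`); the default split
  (0.45, 0.20, 0.18, 0.17) front-loads the neonatal month as in
  typical DHS schedules.
* Children pass through segments sequentially (survive one to be at
  risk in the next); a death's age-month is uniform within its
  segment; deaths at ages the child had not yet lived by the
  interview are censored to "alive".
* Weights are i.i.d. gamma with mean 1 and CV `weight_dispersion`
  (default 0.2), normalised to mean 1.
* An optional Gaussian copula (`stratifier_correlation`) links the
  wealth, education and residence draws so that poor, uneducated and
  rural co-occur; the default is independence.

The generator intentionally omits several features of real surveys:
stratified two-stage sampling with oversampled small strata (weights
are noise, not design-derived), mother-level clustering of births,
age-at-death heaping, displacement of birth dates, and any trend in
mortality over the window.  Passing recovery tests therefore shows the
estimator is correct *under its stated model*, not that it reproduces
every artefact of field data.

## Problem sizes in the test suite

Recovery tests use 50 replicates of n = 20,000 births (point recovery
at three mortality levels) and 20 replicates of n = 50,000 (end-to-end
rural/urban D and R against their generating values 15.1 and 1.42,
at the survey's 73/27 residence split); distributional checks use
single draws of 50,000–200,000 births.  These sizes put Monte-Carlo
SEs well below the effects being checked while keeping the whole suite
fast.

## Known limitations

* The component method here is a clean, internally consistent variant;
  rates from tools implementing DHS's exact half-cohort rule will
  differ slightly in the last segment's handling of boundary cohorts.
* Parametric simulation CIs for PAF are wider than those of toolkits
  that condition on the observed reference subgroup.
* Only marginal (single-dimension) mortality targets are supported in
  the generator; joint subgroup-combination targets are rejected with
  a validation error.
* `PAR`/`PAF` with µ taken from a published national row inherit that
  row's rounding; summary measures recomputed from rounded published
  inputs can differ from values computed on unrounded microdata by a
  few hundredths.
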