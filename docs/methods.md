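# Methods

## The rating framework

Each shortage is rated on five elements on an ordinal 1/2/3 scale
(low/moderate/high patient impact). Ratings are deterministic functions
of raw registry attributes; where an element comprises several aspects,
the element rating is the maximum of its aspect ratings, so adding
evidence can only raise, never lower, an element (monotonicity is a
tested invariant).

* **Alternative product** — a ladder over the proposed solution:
  generic substitution (same active substance and route) → 1;
  therapeutic substitution or an unlicensed product → 2; no suitable
  therapy → 3. The ladder is configurable
  (`RaterConfig.solution_ladder`); the default places unlicensed
  products at 2, reflecting that a usable product still exists, so only
  the total absence of therapy rates 3.
* **Disease** — categorical grades mild/moderate/severe → 1/2/3; a
  disease graded at several levels depending on progression
  (`multi_class`) is treated as moderate. Numeric WHO disability
  weights w ∈ [0,1] map through cut-points: w ≤ 0.10 → 1, w > 0.30 → 3,
  else 2. The framework itself fixes no numeric cut-points, so these
  live in `RaterConfig` and are echoed into all outputs via the config
  fingerprint.
* **Susceptibility** — vulnerability: a population confined to children
  (age_max ≤ 18) or the elderly (age_min ≥ 65) → 3, one including them
  among adults → 2, adults only → 1; the 18/65-year bounds are
  configurable. Trust in the alternative: media attention or
  patient-forum reports → 3, notes on patient contact alone → 2, no
  signals → 1 (presence/absence, not intensity — intensity grading
  would need a corpus the registry does not carry).
* **Costs** — medicine-cost aspect: the ratio
  100·price_alternative/price_original is compared with the *cohort's*
  quartiles; strictly above q3 → 3, strictly below q1 → 1, otherwise 2
  (boundary values are moderate, matching the strict above/below
  reading). Quartiles use linear interpolation on the sorted sample
  (the common default of mainstream statistics software) and the method
  label is stored in `CostThresholds` for reproducibility; at least 4
  ratios are required, otherwise explicit thresholds must be supplied.
  Personnel-cost aspect: equal to the alternative-product rating — the
  harder the substitution, the more professional time it consumes.
  With missing prices the element falls through to personnel costs
  alone; a zero original price makes the ratio undefined (warned,
  treated as missing).
* **Number of patients** — an orphan indication implies few patients
  and rates 1, overriding everything else; hospital products without
  usage statistics rate 2 by default; otherwise prior-year users
  ≤ 1 000 → 1, ≥ 100 000 → 3, else 2. The count thresholds have no
  published values; the defaults (1 000 / 100 000 users per year,
  roughly "niche product" vs. "population-scale product" in a country
  of 17 M) are explicit in `RaterConfig`.

## Aggregation and ECHO rollup

The overall score is the product of the five ratings (1–243). The
score support is the 21-value set {2^a·3^b : a+b ≤ 5}; the package
checks itself against direct enumeration of all 3⁵ combinations. An
additive variant (range 5–15) is available as a labelled sensitivity
option, default off, because multiplication better separates shortages
rating high on several elements.

The elements trace to ECHO outcomes by the max rule: economic =
max(costs, n_patients); clinical = max(disease, alternative-primary,
vulnerability); humanistic = max(alternative-secondary, trust). When a
profile carries only combined element ratings (e.g. an externally rated
registry), the combined rating stands in for each aspect slot. This
"aspect fallback" is an upper bound and can overstate the humanistic
outcome in particular; profiles rated by the package always carry
vulnerability/trust and cost-aspect detail, so the fallback then only
affects the alternative-product aspects.

Classification flags: direct impact = high on alternative product or
disease; indirect = high on costs, susceptibility or number of
patients; "unforgiving" = high on ≥ k elements (default k = 2).

## Episode logic

Eligibility requires ≥ 14 days of unavailability, counted inclusive of
both start and end dates; shorter gaps are expected to be absorbed by
stock in the supply chain. Ongoing episodes (no end date) are retained
— impact is rated at the start of a shortage, so an unresolved episode
is rateable. Episodes of the same product separated by at most 30 days
are one shortage (a gap of exactly 30 merges; 31 starts a new one);
merging is idempotent. When the registry carries a `product_type`
column, products without a regular marketing authorisation (parallel
imports, homeopathic/herbal, unregistered preparations) are dropped
with a logged count.

## Cohort statistics

* Sample size: Cochran's n₀ = z²p(1−p)/e² with the exact normal
  quantile (1.959964 at 95%, not 1.96) and finite-population correction
  n = n₀/(1+(n₀−1)/N), rounded up. The exact quantile matters: it
  reproduces 319 for N = 1844 where 1.96 would round differently.
* Representativeness: chi-square goodness-of-fit of sample counts
  against population proportions (the sample is a subset of the
  population, so an independence test on overlapping groups is not
  well-posed); categories with expected counts < 5 are flagged, zero
  expected counts are an error to be pooled by the caller.
* Stratified comparison: Kruskal–Wallis omnibus plus pairwise Dunn
  tests (rank z statistics with tie correction), p-adjustment
  Bonferroni by default with Holm and none as options, label always
  recorded. When every score is identical the rank statistic is
  degenerate and the limiting values (H = 0, p = 1) are returned.
* All quantiles (score medians/IQRs, cost thresholds) use one
  interpolation method for internal consistency.

## Synthetic cohorts

The generator emulates the published structure of the Dutch 2012–2015
registry: marginal composition per start year, route, first-level ATC
class and originator status (the published population counts are the
defaults), and element-rating distributions close to the published
shares — alternative product (39/60/1)%, disease (33/38/29)%,
susceptibility (79/16/5)%, number of patients (25/60/15)%; only the
shares quoted in the text are pinned, the remainders were split once as
an approximate calibration. Raw attributes are constructed to invert
to the sampled ratings through the raters, so rating recovery is exact
by construction whenever generator and rater share a `RaterConfig` — a
tested contract, including at quartile boundaries, because cost
thresholds are recomputed from the same cohort.

The costs element is the exception: its medicine-cost aspect is
cohort-relative, so its ground truth is derived from the sampled
prices through the same ratio/quartile code path the rater uses rather
than sampled from a target distribution. Cost ratios are log-normal
with median 100% (σ = 0.5) and 20% of records have missing prices; with
strict quartile cuts this lands the high-cost share near 20%.

What the generator does **not** emulate: dependence between variables
(attributes are sampled independently — no published joint distribution
exists; `joint_hook` accepts a user-supplied dependence structure),
shortage causes, market dynamics, duration structure beyond the
eligibility threshold, or within-year seasonality. Passing tests on
synthetic cohorts therefore demonstrate the pipeline's correctness
contracts (recovery, closure, convergence of marginals), not that real
cohorts will reproduce any particular published percentage: real
registries have correlated attributes (e.g. parenteral ↔ hospital) that
shift joint statistics such as the ECHO shares and stratified medians.

## Problem sizes and numerical choices

Convergence tests use n = 10⁴ synthetic records with 3-binomial-SE
tolerances; randomized invariant checks use 10⁴ profiles; end-to-end
CLI closure uses the study-sized n = 324. All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
outputs. Ratings and scores are exact integer arithmetic; the only
floating-point comparisons are the strict quartile cuts, which both
generator and rater evaluate on identical floats (shared ratio helper),
avoiding boundary flips.

## Known limitations

* The full per-element rating examples of the original framework are
  not public; the solution ladder and the disability-weight, age and
  user-count cut-points are this package's own defaults and may differ
  from the original raters' judgement in edge cases. All are
  configurable and fingerprinted into outputs.
* Published chi-square p-values for the original sample cannot be
  reproduced exactly (the original software's exact procedure is not
  recoverable); this package's goodness-of-fit gives p ≈ 0.22 on the
  year variable versus a published 0.207.
* The confidential cohort's own percentages (29% disease-high, 20%
  costs-high, median 8, …) are not reproducible and are not targets;
  the synthetic defaults approximate them only marginally.
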