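# Methods

## The estimation problem

`heritmap` estimates narrow-sense heritability (h²) of binary health
outcomes from pairs of relatives identified in population registers,
without zygosity information. The design exploits two facts:

1. Opposite-sex twin pairs are necessarily dizygotic (DZ), while
   same-sex pairs are a mixture of monozygotic (MZ) and DZ pairs.
2. Under Weinberg's rule a DZ pair is same-sex with probability 1/2, so
   the MZ fraction of all twin pairs is identifiable from the
   opposite-sex count alone:

       p(MZ) = 1 − 2·N_OS / N_all,     p = P(MZ | SS) = p(MZ) / (N_SS / N_all).

With classical Falconer logic, h² = 2(r_MZ − r_DZ). Replacing the
zygosity contrast with the same-sex/opposite-sex contrast and accounting
for the mixture weight gives the zygosity-free estimator

       h² = (2/p) · (r_SS − r_OS),

where r_SS and r_OS are liability-scale phenotypic correlations of the
same-sex and opposite-sex (reference) groups. In the sibling design the
reference group additionally contains every non-twin full-sibling pair
regardless of sex, since full siblings share on average the same 50% of
segregating variation as DZ twins.

## Variance-component model

Observed-scale correlations come from a linear mixed model on the 0/1
outcome (a linear probability model — the liability correction is
applied afterwards, not through a link function):

       y = Xβ + u_pair + u_onlySS + e,

with fixed effects sex and birth year, a random intercept `u_pair`
shared by both members of every pair, and a random intercept `u_onlySS`
shared only within same-sex twin pairs (each remaining individual
carries an independent level, so the component contributes variance
everywhere but covariance only inside same-sex pairs). Then

       V_SS = V_pair + V_onlySS,  V_OS = V_pair,
       V_total = V_pair + V_onlySS + V_e,
       r_SS = V_SS / V_total,     r_OS = V_OS / V_total.

### REML on 2×2 blocks

Every random-effect group has exactly two members, so the marginal
covariance is block diagonal with 2×2 blocks. Rotating each pair into
within-pair *sum* and *difference* coordinates diagonalises every block;
with variance ratios a = V_pair/V_e, b = V_onlySS/V_e, the four
homoscedastic classes are

| class | variance / V_e |
|---|---|
| same-sex differences | 1 |
| same-sex sums | 1 + 2a + 2b |
| reference differences | 1 + b |
| reference sums | 1 + 2a + b |

The restricted likelihood then depends on the data only through
per-class cross-products of the rotated design and outcome, so one
O(n) pass yields sufficient statistics from which each criterion
evaluation is O(1). The residual variance is profiled out analytically;
the two ratios are optimized by a bounded Nelder–Mead simplex with the
nonnegativity constraints enforced as box bounds (components estimated
at the boundary are reported as exactly 0). The full-data fit runs the
simplex to `xatol = 1e-10` from two starting points (method-of-moments
and a small interior point); bootstrap replicates use a single
moment start and `xatol = 1e-4`, which resolves the optimum three to
four orders of magnitude below bootstrap noise. A dense-matrix
grid-plus-simplex optimizer over the explicit 2×2-block covariance
serves as an independent oracle in the test suite and agrees with the
production path to 1e-6 on the variance ratios.

Fixed-effect "age" is implemented as the individual's birth year
(attained age at end of follow-up is collinear with follow-up length in
an ever/never design); birth year is centred and scaled only for
conditioning, which leaves the fit invariant.

## Observed to liability scale

A binary trait with prevalence K is modelled as a standard-normal
liability exceeding T = Φ⁻¹(1−K). Writing i = φ(T)/K for the mean
liability of affected individuals, the within-pair covariance `cov` of
the 0/1 indicators fixes the recurrence risk in co-members of affected
individuals, q = K + cov/K, with group threshold T_g = Φ⁻¹(1−q). The
liability-scale correlation uses the classical Reich et al. (1972)
conversion

       r = (T − T_g·√(1 − (T² − T_g²)(1 − T/i))) / (i + T_g²(i − T)).

This transform is strictly increasing in `cov`, maps 0 to 0 for every
K ∈ (0,1), and on exact bivariate-normal quadrant probabilities
round-trips ρ ∈ [0.1, 0.8] × K ∈ [0.01, 0.2] within 0.009 (the error
grows with ρ and with 1/K; it is an approximation, not an identity).
Two printed-formula variants that circulate — a plus sign in the
recurrence argument, and the square root applied to the whole threshold
difference — are retained behind `variant="printed"` for audit; both
break monotonicity and the round-trip, so the Reich form is the
default. The covariance entering the transform is the raw observed-scale
V_SS (or V_OS), not a normalised correlation, consistent with its
definition as the within-pair covariance.

### Known bias of the estimator

The same-sex group mixes MZ and DZ pairs *on the observed scale* before
the nonlinear liability conversion, whereas the estimand mixes
correlations on the liability scale. The convexity gap inflates r_SS
slightly; at h² = 0.5, c² = 0.2, K = 0.1, p(MZ) = 0.28 the infinite-data
value of the full pipeline is 0.547 rather than 0.500. This is a
property of the method (any implementation of this design shares it),
grows with the MZ–DZ correlation gap and with rarity of the trait, and
is small relative to sampling noise at realistic cohort sizes. The
parameter-recovery tests therefore check agreement within bootstrap
error rather than asserting exact unbiasedness.

## Cohort construction rules

* **Twin pairs**: children of the same mother *and* father (unordered
  parent-couple key; half-siblings never match) born within one calendar
  day of each other at an identical birthplace; one pair per couple, the
  earliest born.
* **Non-twin sibling pairs**: same parent couple, birth gap in
  [334 days, 1461 days] (11 months to 4 years, fixed calendar
  arithmetic); the closest-gap pair per couple, ties broken by earliest
  first-born then person id. Twin-pair members are never reused.
* **Follow-up** ends at the first member-level death or emigration in
  the pair, or the study end (31 Dec 2021).
* **Birth cohorts**: the 1955 cohort keeps pairs with both members born
  1955–2021 and alive on 1 Jan 1977 (diagnoses before 1977 are
  unobservable — left truncation); the 1977 cohort keeps pairs with both
  members born 1977–2021, followed from birth.
* **Code mapping**: ICD-8 → ICD-10 → phecode through user-supplied map
  files; events propagate to every dotted-decimal ancestor (751.11 →
  751.1 → 751). Unmapped codes are counted and logged, never fatal.
* **Phenotype filters**: prevalence ≥ 0.5%; ≥ 400 cases (twin-cohort
  analyses only); ≥ 5 concordant pairs in each analysis group; case sex
  ratio ≤ 5, with sex-ratio exclusions dragging out all hierarchical
  ancestors (an apparently balanced parent code may merely aggregate
  imbalanced children). The exclusion ledger records the first failing
  rule per phecode, and eligible ∪ excluded partitions the input.
* **Onset**: a phenotype is early-onset if ≥ 10% of its cases have a
  first event at age ≤ 18. The denominator is cases (not the population
  at risk); the computed fraction is reported alongside the label so the
  reading is auditable.
* The sex ratio is computed over case individuals, not pairs.

## Uncertainty and multiple testing

* **Bootstrap**: pairs are resampled with replacement, stratified by
  analysis group (preserving group sizes and hence the mixture weight
  p, which is a cohort-level constant); the full pipeline, including
  the replicate's own prevalence, is re-run per replicate. Default 500
  replicates; SE is the replicate SD; the reported CI is the 2.5/97.5
  percentile interval, with the normal-approximation interval emitted
  for audit. Resampling is canonicalised by (group, pair id), making
  results invariant to row order, and is deterministic under a fixed
  seed.
* **Testing**: two-tailed z-test of h²/SE; Benjamini–Hochberg step-up
  q-values with the family defined as all phecodes estimated in one
  (cohort × design) run; "non-zero heritability" means q < 0.05.
  Negative raw estimates are reported as-is; only the truncated
  `h2_report` is clamped to [0, 1].
* **Aggregation**: inverse-variance-weighted means (weights 1/SE²) per
  functional domain with normal CIs; cross-cohort / cross-design /
  external comparisons by weighted least squares of y on x with weights
  1/(SE_x² + SE_y²), optionally excluding phenotypes whose case sex
  ratios differ between sets by more than a configurable
  ratio-of-ratios (default 1.5), since differential sex imbalance
  biases the same-sex/opposite-sex contrast.

## Synthetic registry

The generator emulates the family structure and observation process the
pipeline assumes, with known ground truth:

* Each of `n_families` contributes a twin pair (probability
  `twin_fraction`, default 0.06 — the twin share of analyzable pairs in
  a national sibling cohort) or a non-twin sibling pair. Twin pairs are
  MZ with probability `p_mz` (default 0.28, the Weinberg-implied MZ
  fraction of a national 1977–2021 twin cohort). MZ pairs share one
  Bernoulli(1/2) sex draw; DZ twins and siblings draw sexes i.i.d. —
  exactly Weinberg's rule, with no sex-ratio-at-birth adjustment.
* Liabilities are l = g + c + e with Var(g) = h², genetic correlation 1
  (MZ) or 0.5 (DZ and siblings), Var(c) = c²_twin or c²_sib shared
  within the pair, and independent e topping up to unit variance. A
  person is affected iff l + sex_effect·1[male] > Φ⁻¹(1−K). The paper
  trail for c²_sib is thin in this literature; it is a free simulation
  knob (c²_sib ≤ c²_twin), which is exactly what makes the
  twin-vs-sibling inflation experiments expressible.
* Ages at onset are log-normal (mean 30, SD 15 years by default);
  deaths and emigrations are independent constant hazards (default
  0.002/year each — order of magnitude for a young Northern-European
  cohort); a diagnosis is recorded only if onset falls between the
  registry start (default 1977) and the individual's censoring date.
  Left-truncation experiments (1955- vs 1977-style cohorts) fall out of
  moving `registry_start_year`.
* Determinism: one `numpy` generator seeded from `SimulationParams.seed`
  drives everything; identical parameters give byte-identical TSVs.

What it deliberately does not model: realistic demography, assortative
mating, dominance or epistasis, age-varying hazards, diagnostic
misclassification, and sex-ratio-at-birth deviations. Passing recovery
tests therefore show the estimator is faithful to its own model, not
that real registry data satisfy that model.

## Test-problem sizes

Validation experiments use sizes chosen to make Monte-Carlo error small
relative to the effects being checked: parameter recovery on 200,000
twin pairs (point estimate within 3 bootstrap SEs of truth, 500
bootstrap replicates); twin-vs-sibling inflation direction over 20
replicates of 20,000 families; liability round-trips at 10⁷ simulated
pairs per (ρ, K); REML-vs-oracle agreement on 50 instances of ≤ 200
pairs; bootstrap calibration over 500 repetitions of a 3,000-pair
experiment at 200 replicates each (h² = 0.5, c² = 0, K = 0.3, a setting
where the mixing bias above is a small fraction of the sampling SD, so
coverage of the generative truth is interpretable).

## Degenerate inputs and numerical conventions

* Constant outcomes, empty analysis groups, zero total variance and
  covariances incompatible with the prevalence (recurrence argument
  outside (0,1)) raise errors naming the offending quantity; pipeline
  drivers convert them to per-phecode error rows rather than aborting a
  run.
* Variance ratios are capped at 200 (far outside any plausible binary
  outcome) to bound the simplex; ratios below 10× the simplex tolerance
  snap to exactly 0.
* Bootstrap replicates that fail (e.g. a resample with no concordant
  pairs) are dropped; more than 20% failures aborts with a census of
  failure messages.
* All output tables are plain TSV; manifests record SHA-256 hashes of
  inputs and outputs so stages chain verifiably.
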