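# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Event model and conventions

Units (signals/gestures vs actions) are half-open intervals
`[onset, offset)` in seconds from interaction start, so overlap
arithmetic is exact and a unit ending exactly when another begins does
not overlap it.  Interactions are strictly dyadic; units are ordered by
onset with ties broken by offset, then actor id.  Interchange is plain
TSV; readers validate every row, name the offending column or row in
errors, and (by default) warn rather than fail on ids missing from a
roster, since field datasets routinely contain visitors and
part-identified individuals.  `strict=True` upgrades those warnings to
errors.

### Inter-rater agreement

Two annotation tiers are compared by greedily linking segments in order
of decreasing temporal overlap (each segment links at most once).  A
linked pair counts as agreement only if the overlap covers ≥ 60% of
*both* segments' durations and the labels are identical.  The published
tooling convention for this style of check states only "at least 60%
overlap"; the bidirectional reading is the stricter, symmetric one and
is the default (`bidirectional=False` gives the one-sided variant).
Unlinked segments and under-overlapping links enter an explicit
"unmatched" category of the confusion matrix, so missed annotations
penalise Cohen's κ rather than being dropped.  Empty tiers yield an
explicit no-data result (`kappa=None`), never NaN.

## Turn transitions

A turn transition is a unit by one interactant followed by a unit of
the other (role reversal) whose onset is within `window` (default 30 s)
of the first unit's offset.  Signed timing is
`timing = offset₁ − onset₂`: negative = gap (overlap avoidance),
positive = overlap.  A timing of exactly zero counts as *not*
overlapping — simultaneity is treated as the limit of avoidance.

The pairing rule is greedy-earliest.  Scanning units in temporal order,
each unit's candidate response is the earliest-onset unit by the other
interactant starting no earlier than it that has not already been
claimed as a response.  Each unit is first element of at most one
transition and second element of at most one; a unit whose candidate
fails the window rule yields no transition and becomes a "no response"
row of the unit-level model.  The window constrains only the *gap*:
overlapping responses always qualify.  Mutual grooming appears as
overlapping action units and simply yields positive-timing
action–action transitions; there is no special-casing.  The rule is
verified exactly against an exhaustive brute-force oracle on random
logs in the test suite.

## Dominance

Aggression outcomes and submissive-signal records are pooled into one
winner-by-loser count matrix; the producer of a pant-grunt or pant-bark
is recorded as subordinate to its recipient, the standard chimpanzee
ethology reading.

* **David's scores.**  `P_ij = w_ij / n_ij` (0 for unobserved dyads);
  the chance-corrected variant `D_ij = P_ij − (P_ij − 0.5)/(n_ij + 1)`
  is the default.  `DS = w + w₂ − l − l₂`,
  `normDS = (DS + n(n−1)/2)/n`.  Unobserved dyads contribute zero to
  all sums.  Note that because DS is quadratic in the dyadic index, the
  Pij and Dij variants are *not* guaranteed to rank identically even
  when every dyad is observed equally often (the map between the
  indices is affine, the score is not); they agree on clearly separated
  hierarchies.
* **Steepness** is the absolute OLS slope of descending normDS against
  rank position 1..n; a perfectly despotic, fully observed hierarchy
  has normDS spacing 1 per rank step and hence steepness 1.  The
  permutation test reallocates each dyad's outcomes as fair coin flips
  while keeping its interaction count, and reports the right-tail
  probability with the usual (g+1)/(N+1) correction.
* **Linearity h′** is the expected Landau
  `h = 12/(n³−n) · Σ(Vᵢ − (n−1)/2)²` after randomly directing every
  tied or unknown dyad (estimated over seeded randomizations; exact
  when none exist).  The p-value compares h′ against matrices whose
  every dyad is directed at random.
* **I&SI ranking** minimises lexicographically the number of
  inconsistencies (pairs where the lower-ranked individual holds the
  winning record) and their summed rank distance.  Groups of ≤ 8 are
  solved exactly by enumeration; larger groups use seeded
  pairwise-swap local search with random restarts from the normDS
  order.  Ties between optimal orders break by descending normDS, then
  id, so results are reproducible.

## Sociality (DSI)

The index is implemented literally as the two-fraction sum

    DSI = G_AB/(G_AB + G_A + G_B) + P_AB/(P_AB + P_A + P_B)

with bout/scan *counts* (not durations), a zero-denominator term
contributing 0, and `G_A` meaning "grooming bouts of A not involving
B" (the alternative reading — grooming while B is absent from the
party — would need party composition data the event model does not
carry).  This raw form is deliberately not the rate-normalised average
used by some composite sociality indices; it is bounded by 2, symmetric
in the dyad, scale-invariant in the counts, and monotone in the joint
terms.

## The four models

All models share the covariate structure: initiator/recipient age and
ordinal rank, dyadic DSI (all z-scored over the pooled model data,
sample-sd denominator), binary relatedness, and community as a control,
with random intercepts for initiator, recipient, dyad and interaction.
The six age/rank interaction terms are the four age × rank
cross-products plus age × age and rank × rank; the list is switchable
since other subsets of the six pairwise products are defensible.

1. **Unit-level response** (Bernoulli): one row per produced unit;
   outcome = the unit received a qualifying response.
2. **Transition counts** (Poisson): one row per interaction with
   `log(duration)` as exposure offset; duration must be positive.
3. **Transition types**: the four type indicators fitted jointly as
   Bernoulli responses sharing the grouping labels (block-separable
   likelihood, one parameter block per type).  Since exactly one type
   holds per transition, a single 4-class categorical likelihood
   (first alphabetical level as reference) is available via
   `family="categorical"`.
4. **Timings** (Gaussian): response is the signed-log transform
   `sign(t)·log1p(|t|)` — a plain log is undefined for the negative
   (gap) timings, and this odd, monotone, invertible transform
   compresses tails symmetrically.  Transition type enters through
   sum-to-zero contrasts (effects are deviations from the grand mean)
   plus type × covariate interactions.

**Priors** (centralised in `PRIORS_DEFAULT`) are weakly informative:
Normal(0, 1) on standardized slopes, Normal(0, 2.5) on intercepts,
half-Normal(0, 1) on group-level standard deviations, half-Normal(0,
2.5) on the Gaussian residual scale.  On z-scored covariates a unit
slope is already a large effect, so these regularise without driving
estimates.

**Sampling.**  Posteriors are sampled by the package's adaptive HMC
(`turntaking._hmc`): analytic gradients for all families, non-centered
random effects, dual-averaging step-size adaptation (target acceptance
0.8), a diagonal mass matrix estimated from a warmup variance window,
jittered trajectory lengths, and divergence flagging for proposals with
energy error > 1000.  The full profile is 4 chains × 4000 iterations
with 1000 warmup each (12 000 retained draws); the reduced profile
(2 × 1000, 500 warmup) is the default for tests and CLI smoke runs and
is *not* intended for inference — with only 1000 retained draws the
ESS > 1000 criterion is unattainable by construction and R-hat can
exceed 1.05 on weakly identified variance components, which the result
then flags.

**Summaries** are the posterior median, MAD scaled by 1.4826,
equal-tailed 89% credible interval (5.5%/94.5% quantiles; an HDI is a
straightforward extension but equal tails are the default), and the
probability of direction pd = 100·max(P(θ>0), P(θ<0)).  An effect is
flagged as supported when its 89% CrI excludes zero.  Diagnostics
(R-hat, bulk/tail ESS via arviz, divergence count) are attached to
every fit; non-convergence flags the result rather than hiding it.

## Synthetic-data generator

The generator emulates the statistical structure the models assume, at
configurable scale:

* ages uniform on [13, 56] years (adolescent and older males);
* a latent linear hierarchy whose win-probability scale is calibrated
  by root-finding so the *expected* agonistic matrix has the requested
  steepness (default 0.18, an egalitarian setting); agonistic outcomes
  are binomial per dyad with Poisson interaction counts (default mean
  2/dyad, sparse as in field data);
* exponential latent dyadic bonds driving Poisson grooming-bout counts
  and proximity-scan membership, so realized DSI is informative about
  the bond;
* unit streams in which every produced unit draws a partner response
  with probability `logistic(β·x + u_interaction)` on the z-scored
  covariates (default β mirror the magnitudes of plausible age/rank
  effects, intercept −0.6 ≈ a 35% response rate); response modality
  follows the type mixture conditioned on the first unit's modality,
  and signed latencies are lognormal magnitudes with per-type overlap
  probabilities, truncated at the 30 s window.

Two calibrations keep the generated data consistent with its own
configuration.  First, because a response's modality becomes the next
pair's first modality, a naive chain would skew the realized
transition-type mixture; the modality distribution of *restart* units
is solved from the stationarity equation so the realized pair mixture
matches the configured weights.  Second, after a non-response the
stream resumes beyond the pairing window, so the extraction rule
attributes exactly the generated responses — generated and extracted
transitions coincide by construction.

A single seed drives all streams through numpy seed-sequence spawning;
identical configs are bit-reproducible.

**What passing tests show — and don't.**  Recovery and calibration on
this generator demonstrate that the estimators and sampler are correct
*under the assumed data-generating process*.  Real grooming data
violate several of its simplifications: covariates are not exchanged
through a clean logistic link, latencies are not stationary lognormals,
bonds and ranks drift over a field season, observation is biased toward
visible dyads, and DSI distributions can be much more compressed than
the exponential-bond default produces.  End-to-end coefficient recovery
is also mildly attenuated by design: the pipeline re-standardizes
covariates over realized data rows and replaces the latent bond with
the realized DSI, so sign recovery and CrI coverage, not point
equality, are the meaningful checks.

## Problem sizes in the shipped experiments

The acceptance script simulates a two-community study (27 + 15 males,
190 + 121 interactions, ≈ 6300 units) and runs the reduced-profile
unit-level model on it; sampler calibration uses 20 replicates of
n = 2000 Bernoulli observations in 100 groups.  These sizes give
stable Monte-Carlo behaviour for the quantities reported while keeping
a full run in the minutes range on one CPU.

## Known limitations

* The HMC sampler is static-trajectory (jittered) rather than NUTS;
  it is adequate for these log-concave-ish hierarchical posteriors but
  less robust on pathological geometries.
* h′ is estimated by randomization (its defining expectation), not the
  closed-form correction; with the default 10 000 randomizations the
  Monte-Carlo error is ≈ 0.002.
* The I&SI local search above n = 8 is a heuristic; optimality is
  guaranteed only for the exact regime (tests cross-check n ≤ 7
  against exhaustive enumeration).
* Model 3's joint-binary parameterisation ignores the one-hot
  constraint between the four indicators (each block is a marginal
  model); the categorical family respects it.
* Phase marks (starting/grooming/ending) are carried by the event
  model but not used by any estimator.
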