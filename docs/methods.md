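# Methods

## The valuation problem

The ASCOT-Carer instrument describes the long-term-care-related quality of
life of an informal carer by one level (1 = ideal state … 4 = high needs)
in each of 7 domains. A summary score that simply adds level numbers treats
all domains and all level steps as equally important; preference weights
replace that assumption with empirically elicited values. This package
implements the full valuation chain used for profile-case best–worst
scaling (BWS) studies of the instrument: experimental design, (synthetic)
choice data, a scale-adjusted multinomial logit (S-MNL), and rescaling into
a 0–1 scoring tariff. The package ships the published Austrian estimates
(`ascot_bws.reference`) both as the simulator's default generating values
and as a ready-to-use weight source.

## Experimental design

The choice sets come from an orthogonal main-effects plan. Treating the 7
domains plus one blocking factor as 8 four-level factors, the full
factorial (4^8) is reduced to a 32-run orthogonal array of strength 2,
OA(32, 8, 4, 2): every column shows each symbol 8 times and every ordered
symbol pair appears exactly twice in every column pair, so main effects are
estimated without two-factor confounding.

Construction: the 32-run two-level Hadamard-derived array has 31 columns
indexed by the nonzero vectors of GF(2)^5. A "closed triple" {a, b, a⊕b}
is a line of PG(4, 2); collapsing the (a, b) bits of a line into one
four-level symbol gives a balanced four-level column, and two such columns
are strength-2 orthogonal exactly when their lines are disjoint (their
spans intersect trivially). A seeded backtracking search over the 155 lines
finds 8 pairwise disjoint lines (a partial spread; up to 9 exist, so the
search always succeeds quickly). `verify_design` re-checks every
constructed or loaded array by exhaustive counting — 16 symbol pairs × 28
column pairs — never by sampling, and a pre-verified fixture array ships
with the package so the pipeline does not depend on the search.

The 8th column is the blocking factor: its symbols partition the 32
scenarios into 4 blocks of 8 tasks, and each respondent answers one block.
Because the blocking column is strength-2 orthogonal to every domain
column, each domain shows every level exactly twice within every block, so
all 28 domain-levels are identified from any single block. Design symbols
map to levels as level = symbol + 1 (recorded in the design file header).
Display order is randomised once per respondent (constant across their 8
tasks); per-task randomisation would also be valid but the per-respondent
reading matches how positioning effects are defined here.

## Choice model

Each task elicits four sequential picks — best, worst, second best, second
worst — over a shrinking available set (7, 6, 5, 4 items). The likelihood
is the exploded product of stage-level multinomial logits. For respondent
r (scale λ_r), item i (utility β_i) at display position p:

* best-type stages: P(i) ∝ exp(λ_r (β_i + δ_p))
* worst-type stages: P(i) ∝ exp(−λ_r β_i)

Positioning effects δ enter best-type stages only (worst-type positioning
effects were found negligible in this design tradition and are excluded
from the model); positions are the original display positions even after
items are removed. Stage utilities are computed with max-subtraction so
|λβ| up to ~700 cannot overflow.

Identification. Utilities are relative: the item with the lowest perceived
utility (space and time to be yourself, level 4) is pinned to 0, and
levels 1–2 of feeling supported and encouraged share one coefficient
(respondents value them indistinguishably). δ_1 = 0. Scale is relative:
λ = 1 for the reference group (understood the tasks, under 35, completion
time below the first quartile); respondents in several groups multiply the
group factors (a product-composition assumption). Multiplying all β, δ by
c and dividing all λ by c leaves the likelihood unchanged, which is
exactly why the reference-group normalisation is needed; the free
parameterisation (26 β + 6 δ + 3 log λ = 35) makes the optimum unique.

Estimation maximises the total log-likelihood with L-BFGS-B on the mean
per-stage objective, using the analytic score (verified against finite
differences at 1e−6). Convergence requires the max-norm of the mean
per-stage gradient below 1e−5 within 500 iterations; anything else is
flagged, never silently accepted. λ are optimised on the log scale to
enforce positivity. A level never shown in the data raises an
identification error naming the level; fewer than 2 respondents is an
error.

Inference uses the cluster-robust sandwich A⁻¹BA⁻¹: A is the observed
information (central finite differences of the analytic gradient, step
1e−5·(1+|x|), symmetrised), B the sum over respondents of outer products
of per-respondent score sums — the respondent is the cluster because each
contributes 32 dependent choices. Coefficient-vs-zero p-values are
two-sided; pairwise level comparisons report one-sided normal tails (the
convention of the published valuation tables); an aliased pair (the joint
coefficient) returns difference 0, z = 0, p = 0.5 and is flagged.

## Synthetic data generator

The generator emulates the structure of the Austrian valuation survey; its
defaults are the study conditions, not tuning knobs:

* n = 1001 respondents, uniformly assigned to the 4 blocks; 8 tasks × 4
  picks = 32 choices each.
* Age 35+ share 0.737 (the surveyed shares of the 35–54 and 55+ quota
  groups). Task understanding is a single binary flag merging "not at all"
  and "only sometimes"; its prevalence is not reported for the original
  sample, so the default 0.15 was chosen once as a plausible online-panel
  value and documented here as an emulation choice.
* Completion times are log-normal (σ = 0.5) truncated below at the
  4.5-minute speeder threshold, with location solved so the first quartile
  of the truncated distribution sits at 7 minutes — the Q1 threshold that
  defines the "slow completer" scale group. A configurable speeder share
  (default 0.05) is planted uniformly on [1.5, 4.4] minutes purely to
  exercise the cleaning filter.
* True parameters default to the published Austrian estimates (β, δ, λ of
  `ascot_bws.reference`).

Stage picks are drawn by Gumbel-max sampling over the stage utilities,
which is exactly multinomial-logit sampling at the probabilities of
`choice_probability`; the test suite confirms this distributionally
(softmax frequencies, and a chi-square goodness-of-fit of full pick
sequences against the exploded model probabilities on a 4-domain reduced
instrument, where the 24 ordered sequences can be enumerated).

What the generator does **not** emulate: item non-response, attrition,
learning/fatigue over tasks, real response-time dynamics, or any deviation
of human behaviour from the S-MNL (lexicographic choice, attribute
non-attendance). Passing recovery tests therefore demonstrates correctness
of the estimation machinery under the model, not robustness to
misspecification. The original study also filtered speeders during
collection and continued sampling to the target n; the package applies the
same 4.5-minute rule post hoc instead, which is the testable equivalent
(n after cleaning is ~0.95 × 1001 at the default speeder share).

## Post-processing

Group-specific coefficient vectors (e.g. by education or income strata
when the sample under-represents them) can be combined entrywise with
population proportions (which must sum to 1 within the grouping variable);
linearity preserves the identification constraints. Rescaling to weights
uses the per-domain min–max map with a shared denominator,
w[d][l] = (β[d][l] − min_l β[d]) / Σ_d (max_l − min_l). This is the unique
per-domain-affine map for which the best possible state scores exactly 1,
the worst exactly 0, and every domain's minimum level carries weight 0.
It preserves within-domain orderings; across domains, near-tied utilities
can change order on the weight scale because each domain subtracts its own
minimum — rankings of items are therefore defined on the utility scale.
Scoring a full response profile sums its 7 weights and is monotone in
every domain.

## Numerical and testing choices

* Tolerances: probability conservation of the exploded likelihood is
  checked by exhaustive enumeration (840 sequences for 7 items) to 1e−10;
  the vectorised likelihood is checked against a pure-Python double-loop
  reference to 1e−10.
* Parameter-recovery checks run 20 seeded replicates at n = 1001 (the
  study's sample size); each replicate simulates, cleans and refits in a
  few seconds. Pooled 95%-CI coverage, within-domain ordering and headline
  point recovery are evaluated across those replicates.
* Degenerate inputs are hard errors: empty choice sets, unknown stages,
  chosen items not removed from later stages, non-positive scales,
  unobserved levels, constant utilities in rescaling.
* Ties in item ranking are broken by instrument order and flagged.

## Known limitations

* The top two Austrian utilities (occupation L1 at 3.53, space-and-time L1
  at 3.50) differ by less than their estimation error at n ≈ 1000: the
  sampling sd of the estimated difference is ~0.04, so *which* of the two
  ranks first is not reliably recoverable from a single survey of this
  size — by the package's own replicate analysis the top item matches in
  only ~70–85% of simulated surveys, while the bottom item and the top
  *pair* are recovered essentially always. Rank statements about near-tied
  items should be read accordingly.
* Taste heterogeneity is only supported through the group-reweighting
  step; there is no mixed-logit or latent-class estimation.
* No anchoring to QALY/dead = 0 scales; weights are relative 0–1 tariffs.
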