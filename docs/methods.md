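# Methods

This note records the model, the default parameters, the synthetic-data
design and the numerical choices behind `dentmatch`, including the places
where the design was genuinely open and what was decided.

## The state model

A dentition is a vector of 32 FDI positions (18…11, 21…28, 48…41, 31…38),
each in one of six treatment states. State change over time is constrained
by a directed graph encoding monotone treatment escalation:

```
NATURAL → PROSTHESIS, NATURAL → ROOT_CANAL, NATURAL → MISSING
PROSTHESIS → ROOT_CANAL, PROSTHESIS → MISSING
ROOT_CANAL → MISSING
MISSING ↔ PONTIC ↔ IMPLANT ↔ MISSING   (all six directed edges)
```

`NATURAL` has in-degree 0: no treatment is ever undone. The
{MISSING, PONTIC, IMPLANT} cluster is pairwise interconvertible at
distance 1. Two arrowheads are not uniquely determined by the escalation
principle and were decided here: `PROSTHESIS → ROOT_CANAL` is included
(a restored tooth can later need endodontic treatment; the reverse is
excluded because re-restoration maps to the same `PROSTHESIS` state), and
the cluster edges are all direct rather than routed through `MISSING`.
Both choices are configurable: the graph is an injected parameter
everywhere and serializes to/from JSON, so an alternative ontology is a
config change, not a code change.

## Similarity scoring

Per position: 0 points for agreement; `unit_step_score × d` points for a
change at shortest-path distance `d`, capped at `max_position_score`; the
full `discrepancy_penalty` when the PM state is unreachable from the AM
state. Defaults: `unit_step_score = 3`, cap and penalty both 10. The unit
step of 3 keeps the longest finite escalation (2 steps → 6 points) strictly
below the discrepancy level, preserving the intent that impossible
transitions dominate possible ones. The exact per-pair point table is not
canonical; only the constraints (0 for agreement, cap 10, penalty 10) are
fixed, so the unit step is exposed in `ScoringParams`.

Two situations draw the penalty under one rule: a transition with no
directed path (e.g. `IMPLANT → NATURAL`) and a "position unavailable in
the past" conflict — both are the UNREACHABLE branch. Candidates are never
removed for low similarity; the score only penalizes.

The similarity is `1 − total/normalization_constant` with the constant
defaulting to `32 × max_position_score = 320`, chosen so the worst case
(a discrepancy at every position) is exactly 0 and identity exactly 1.

## Matching and evaluation

Competition ranking: tied similarities share the lowest rank of their
block; the next distinct score's rank skips by the block size. Among tied
candidates the list order is ascending id, for reproducibility; the rank
value, not the list order, carries meaning.

The top-*p*% candidate group contains the candidates with rank ≤
`ceil(p·N)`. Because tied candidates share a rank, a tie block straddling
the boundary enters whole — the CG may exceed its nominal size. This
favors recall and is deterministic. Consequence (measured, not incidental):
under a pure-noise null with heavily tied discrete scores, the expected
hit rate is `E[|CG|]/N`, slightly *above* `p`; with continuous scores it
is exactly `ceil(p·N)/N`. The test suite checks both statements.

The primary success rate is the hit rate: the percentage of queries whose
true AM record lies in the CG. The literal per-query ratio
`100 × rank / |CG|` is also computed (`rank_ratio`) as a secondary
diagnostic only — the two readings of "success" differ, and the hit rate
is the one consistent with a probability interpretation. Evaluation is
closed-set by default (every query's true record is in the database);
open-set queries are allowed in `rank_candidates` and simply have no
correct rank.

## Interval analysis

For thresholds at every multiple of 100 days in (min interval, max
interval], the dummy `X = 1[interval ≥ t]` (equality goes to the long
group, consistent with the final "≥ cutoff" split) defines a one-regressor
OLS fit, solved in closed form as the two group means: `b0 = mean(Y|X=0)`,
`b1 = mean(Y|X=1) − b0`. A span of 1 to 7,732 days yields exactly 77
regressions. Thresholds with an empty dummy group are recorded as NaN and
excluded from the trend scan (with the threshold grid defined on the open
interval above the minimum, this does not occur in practice, but the
guard is kept for injected threshold lists).

The cut-off is the midpoint of the 100-day section between the two
consecutive defined thresholds with the largest absolute first difference
of `b1`; ties resolve to the earliest section. "Most rapid change" could
also be read as the largest second difference; that criterion is available
behind `trend="second_difference"` but the first difference is the direct
reading and the default. Days convert to years by 365.25 with half-up
rounding to one decimal (6,450 days → 17.7 years; 365 vs 365.25 does not
change that figure).

The group comparison is the pooled-variance two-sample Student *t*-test
(`scipy.stats.ttest_ind`, `equal_var=True`); Welch is available behind a
flag. Zero-variance degenerate inputs yield a NaN statistic, reported as
such rather than raised.

**A caution on the trend criterion.** The first-difference rule is not
robust to thresholds whose dummy=1 group is tiny: near the maximum
observed interval, `b1` is the mean of a handful of pairs and its
replicate-to-replicate swing can exceed any genuine change-point signal
by an order of magnitude. On cohorts whose interval law has a thin upper
tail — including this package's own default cohorts — the selected section
therefore tends to sit among the last few thresholds. Such thresholds are
deliberately kept (only empty groups are excluded), matching the method's
definition; users should read the selected section together with the
`n1` column of the sweep.

## Synthetic cohorts

The generator emulates a paired AM/PM cohort of 20–49-year-old adults:

- **Cohort size and sex.** Defaults: 1,029 individuals (so 2,058
  records), 54.8% women.
- **Imaging intervals.** Target moments 2,197.5 ± 1,934.7 days on
  [1, 7732]. No truncated normal on that support can realize those
  moments after truncation (its maximum sd at that mean is ≈ 1,860, and
  naively plugging the targets in as pre-truncation parameters realizes
  2,659 ± 1,559). The sampler therefore solves, once per configuration, a
  moment-matched mixture of a truncated exponential and a uniform over the
  support (defaults solve to weight 0.806 on the exponential, scale 1,941
  days), which reproduces the target mean and sd essentially exactly;
  low-dispersion configurations where the mixture has no solution fall
  back to a moment-solved truncated normal. The family is a modeling
  choice — many short recall intervals plus a diffuse long tail — not an
  estimate of the source population's shape.
- **Baseline dentitions.** Positions i.i.d. from a per-state prior
  (default: 80% natural, 12% prosthesis, 4% root canal, 2% missing, 1%
  pontic, 1% implant — a plausible mix for this age band). The i.i.d.
  structure is a known simplification: real treatment clusters within
  individuals, producing many low-information (near-all-natural)
  dentitions that are mutually confusable. Synthetic dentitions are
  therefore *more* distinctive than real ones, and default-condition
  success rates sit near 100%. Passing tests at the defaults show the
  machinery is correct, not that real-world success rates would be high;
  tests of discrimination behavior (hazard monotonicity, sex gap) use
  elevated-drift stress conditions stated in the tests themselves.
- **Forward simulation.** Each position evolves independently as a
  discrete-time Markov chain with one step per started 100-day period
  (the same unit as the interval analysis), moving along edge (a, b) with
  the configured per-step hazard. Default hazards are small
  (e.g. `NATURAL → PROSTHESIS` 0.003/step ≈ 1%/tooth-year) and escalation
  out of `NATURAL` dominates. Because steps follow graph edges, a
  generated PM state is always reachable from its AM state, so true pairs
  never incur the discrepancy penalty unless noise is on.
- **Sex effect.** All hazards are multiplied by 0.5 for women — a
  synthetic device giving the sex-stratified evaluation a detectable
  analog (slower drift → easier identification), not a biological claim.
- **Detector noise** (off by default). Each position is corrupted with
  probability 1 − recall of its category (defaults: natural 0.996,
  prosthesis 0.843, root canal 0.892, implant 0.981; missing and pontic
  have no measured category and default to 1.0), replaced by a uniformly
  drawn confusable state (natural ↔ prosthesis being the canonical hard
  call; a missed root-canal trace reads as natural or restored; a missed
  implant as a pontic). Noise applies to the query (PM) side by default,
  the AM database being the clean constructed one; `noise_on_am` corrupts
  both.
- **Determinism.** All randomness flows through one
  `numpy.random.Generator` seeded from the config; identical seeds give
  byte-identical cohort files and pipeline artifacts.

## Change-point validation design

`make_step_dataset` generates (interval, similarity) pairs with a planted
step for validating the sweep: mean similarity drops by `effect` at
`step_at_days`, with i.i.d. Gaussian noise. Its interval law is an
*identifiability design*, not a population model: intervals are uniform on
`[step − 1.5·unit, step + 4.5·unit)`. The bounded, dense support keeps
every threshold bin populated by ~n/6 pairs, excluding the tiny-tail-group
noise described above, and the asymmetry (more mass above the step than
below) makes the coefficient jump at the threshold *leaving* the
change-point strictly larger than the jump *entering* it, so the section
whose lower edge is the true change-point is the unique deterministic
argmax. Under this design, a −0.05 step at 3,000 days with noise sd 0.05
and 1,000 pairs is localized to the correct 100-day section in ≈ 96–98% of
replicates; with full-range interval laws the same step is essentially
unrecoverable by the first-difference rule (the tail groups dominate),
which is why the validation fixes the design rather than the rule.

## Problem sizes used in the test suite

Unit and property tests run on 6-state exhaustive enumerations, 32-position
dentitions, and cohorts of 8–300 individuals; the end-to-end determinism
check and the acceptance script use the full 1,029-individual scale. The
statistical checks use 1,000-query null baselines, 50-replicate
change-point recovery, and 200-replicate *t*-test power runs.

## Known limitations

- No per-tooth weighting, no restoration sub-typing (inlay vs direct
  filling), no pathologic states (caries, periodontal lesions), no
  deciduous or supernumerary teeth — out of scope by design.
- The similarity normalization constant (320) and the unit step (3) are
  conventions; only the constraints (identity = 1, all-discrepancy = 0,
  penalty dominates) are fixed.
- The synthetic generator reproduces the *structure* the pipeline assumes
  (directional drift, interval distribution, sex strata, detector noise),
  not the treatment-prevalence correlations of any real population; see
  the baseline-dentition caveat above.
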