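# Methods

## Choice model

A rater's decision about a message is a Bernoulli draw whose success
(correct classification) probability is logistic in two quantities: the
rater's difficulty `d` with that message and the running rating signal `r`
accumulated by earlier raters,

    Prob(correct) = 1 / (1 + d/(1−d) · e^(−s·r)).

The odds of an incorrect decision are `d/(1−d) · e^(−s·r)`: at `r = 0` the
model reduces to independent accuracy `1 − d`, and each unit of signal
shifts the log-odds by `s`. Difficulty is alignment-specific,
`d_align = d̄ − b·v/2` and `d_mis = d̄ + b·v/2` with veracity `v = ±1`, so
the bias magnitude `b` is exactly the gap `|d_align − d_mis|` and `d̄` their
mean. The signal seen by rater `i` is the mean ±1-coded correctness of
raters `1..i−1` (0 for the first rater). Assumptions worth keeping in mind:
all raters of the same alignment class share one difficulty, everyone
shares one susceptibility, and ratings are binary.

Numerical conventions: difficulties of exactly 0 or 1 return the limiting
probabilities 1 and 0 (the odds form is continuous there); correctness is
coded ±1 internally because the signal's stated range [−1, 1] forces it,
while the experiment-facing tables store the raw true/false choice and the
correctness bit separately (subjects see true/false counts, which are the
correctness tallies reflected through the veracity sign — the two
parameterisations are isomorphic).

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `d̄`  | population-mean difficulty | 0.45 | probability of an incorrect independent decision |
| `b`  | bias activation (aligned/misaligned difficulty gap) | 0.2 | probability difference |
| `s`  | susceptibility to the rating signal | 2.35 | log-odds per unit signal |
| `N`  | raters per group | 50 | — |

The defaults are the reference parameter set used throughout the theory
analysis; at these values an independent rater is right 55% of the time and
an aligned rater faces difficulty 0.35 (true message) or 0.55 (false
message).

## Scenarios and ensembles

Three idealised orders: segregated (all aligned first — a message spreading
through its friendly cluster), integrated (strict alternation — a
well-mixed network), independent (alternation, signal hidden, i.e. `s`
forced to 0). Ensembles simulate all runs position-by-position in one
vectorised pass; the Monte-Carlo standard error of the ensemble mean is the
standard deviation of run-level fraction-correct divided by √runs, because
runs are iid while decisions within a run are not.

**Starting side of alternating scenarios.** At realistic susceptibilities
the first rater's difficulty materially steers the cascade — with the
reference parameters a fixed aligned-first alternation yields ≈0.648
fraction correct when the first rater is the low-difficulty type but ≈0.540
when the first rater is the high-difficulty type, a gap that does not
vanish with N. A well-mixed network gives no side systematic priority, so
the alternating scenarios flip the whole alignment pattern per run with
probability 1/2 by default (deterministic starts are available via
`start_aligned`). This makes the integrated advantage over independence
hold for both veracity signs (≈0.595 vs 0.55), as the scenario is meant to
capture. The segregated scenario is aligned-first by definition.

## Synthetic experiment generator

`generate_experiment` emulates a bipartisan rating study: 80 groups of 50
subjects (25 liberal + 25 conservative) in four conditions — segregated
liberal-first, segregated conservative-first, integrated, independent (20
groups each) — each subject sequentially rating the same balanced catalog
of 20 messages (5 per veracity × lean cell) as true or false, 80,000
decisions in total. Decisions are generated per group × message by the
choice model, with each rater's alignment derived from ideology vs message
lean; segregated groups are rated by the stated ideology first for every
message (so cross-lean messages run misaligned-first), integrated and
independent groups alternate ideologies starting with a liberal (the
concrete ideologies plus the lean-balanced catalog balance the starting
alignment across messages, which is why the generator keeps a
deterministic alternation while the abstract simulator randomizes its
start). The independent condition forces `s = 0` and displays no counts.
Default message parameters are `d̄ = 0.45`, `b = 0.2` for every message
and `s = 2.35` — the reference conditions.

What the generator does *not* emulate: subject-level heterogeneity in
ability or susceptibility (available as an explicit per-message parameter
law, but off by default), cross-message learning within a subject,
recruitment batching, dropout, response times, or coarse heuristic use of
the displayed counts. Passing tests therefore demonstrate that the
*pipeline* recovers the properties of this generative process, not that
human crowds behave like the model; real group-level variance can be
smaller (weaker social influence) or larger (shared subject quality within
groups) than the model produces.

## Analysis pipeline

* **Difficulty estimation** uses only the independent condition, where
  decisions are exchangeable: `d̄_hat` is the fraction of incorrect
  decisions per message and `d_align_hat` the same fraction among aligned
  raters. Difficulty is the probability of an *incorrect* decision
  throughout (an occasionally seen "fraction of correct decisions" phrasing
  for the same quantity is an elision of the complement).
* **Message scoping:** every hypothesis requires `d̄_hat < 0.5` (the
  average rater must beat chance, otherwise any broadcast backfires
  regardless of composition). The aligned-first-helps tests (H2/H4) add
  true messages with `d_align_hat < 0.5`; the backfiring tests (H3/H5) add
  false messages with `d_align_hat > 0.5`. Ties at exactly 0.5 are
  excluded (strict inequalities).
* **Randomization tests** operate on group-level fractions of correct
  decisions — the group is the randomization unit. The observed ATE is the
  difference in arm means (reported in percentage points); the null
  distribution relabels arms over the pooled fractions preserving sizes.
  Monte-Carlo p-values use the add-one convention
  `p = (1 + #{|ATE*| ≥ |ATE|})/(1 + n_perm)`, which keeps p strictly
  positive; small problems are enumerated exhaustively (exact
  count/total). The ≥ comparison uses a relative tolerance so p-values are
  invariant to affine rescaling of the fractions. Condition comparisons
  are run lean-by-lean (homogeneous message samples, 20 vs 20 groups) plus
  a pooled comparison in which each segregated group is summarised on its
  first-ideology-aligned messages; per-group summaries are fixed unit-level
  outcomes, so label permutation remains a valid test of the sharp null.
* **Position trends** (H4/H5) are logistic regressions of correctness on
  sequence position per stratum (subject ideology × alignment × veracity
  class, within aligned-first segregated sequences), with group-clustered
  robust standard errors. This approximates a multilevel random-effects
  model; exact random-effects replication is out of scope. All-correct or
  all-incorrect strata and separated fits are flagged and their estimates
  suppressed rather than reported.
* **Bootstrap:** difficulty estimates are resampled nonparametrically
  within message over independent-condition decisions; percentile
  intervals are reported together with the share of resamples on which a
  message's scope classification (`d̄ < 0.5`, `d_align > 0.5`) flips —
  messages near a threshold are the ones whose hypothesis membership is
  fragile.

## Problem sizes and test design

Monte-Carlo checks use 10,000-run ensembles (the standard replication
count for the theory analysis; MC standard errors ≈ 0.0007–0.0035 at
N = 50). Exact-enumeration equivalence is checked at N ∈ {2, 4, 6}, where
all 2^N correctness paths can be enumerated. Estimator recovery and
bootstrap coverage use independent-condition experiments with 200–500
decisions per message, 200 bootstrap resamples and 100 replicates;
type-I-error calibration uses 200 null experiments of 40 groups at 1,000
permutations; the end-to-end pipeline check runs 20 replicate experiments
at full design scale with 10,000 permutations. Statistical assertions use
3-standard-error bands (≈99.7% per-assertion confidence) with fixed seeds.

## Known limitations

* The end-to-end pipeline check is power-limited by the model itself: at
  the reference parameters cascades are strongly bimodal (per-message
  group-fraction SD ≈ 0.34), so group fractions over 5–20 messages carry
  SD ≈ 0.08–0.15 and the 20-vs-20 group permutation test has ≈50–65% power
  per hypothesis at the ≈4–7 percentage-point effects involved. Effect
  *signs* reproduce in ≈97% of replicates; joint sign-plus-significance
  across H1–H3 reproduces in well under half.
* Scenario orders are ideal types, not network topologies; there is no
  continuous-time diffusion, no non-binary rating, and no per-individual
  heterogeneity within an alignment class.
* The permutation p-value convention and the randomization unit
  (group-level) are design choices; decision-level permutation would
  answer a different question.
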