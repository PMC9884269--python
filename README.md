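# crowdrate

Sequential crowd veracity ratings — model, simulation and randomization
inference.

Real-time "community ratings" let the recipients of an online message tag
it as true or false, so that poor early crowd reception can temper belief in
misinformation before professional fact-checking catches up. Whether that
works depends on *who rates first*: online networks are ideologically
homophilous, so a partisan message is often rated first by the people most
inclined to believe it. `crowdrate` is a toolkit for studying this problem.
It is aimed at computational social scientists who want to simulate
sequential rating cascades in bipartisan crowds, generate synthetic rating
experiments with a known generative process, and analyse them with
group-level randomization tests.

## The model

Raters `i = 1..N` sequentially classify a message with veracity `v` (+1
true, −1 false) as true or false. The probability of a *correct* decision
is logistic in the rater's difficulty `d_i` and the running rating signal
`r_i`:

```
Prob(C_i = 1) = ( 1 + d_i/(1 − d_i) · exp(−s · r_i) )^(−1)
```

* `d_i` is the probability of misclassifying the message when deciding
  independently. It takes the value `d_align = d̄ − b·v/2` for raters whose
  ideology matches the message's lean and `d_mis = d̄ + b·v/2` otherwise,
  where `d̄` is the population-mean difficulty and `b ∈ [0,1]` is the bias
  the message activates: congenial content is easier to accept and harder
  to reject.
* `r_i` is the mean of the previous raters' correctness coded ±1 (0 for the
  first rater), and `s ≥ 0` scales how strongly it shifts the log-odds.
  `s = 0` is the independence benchmark, where accuracy is exactly `1 − d̄`.

Three idealised rating orders stand in for network structure: *segregated*
(all aligned raters first), *integrated* (strict alternation) and
*independent* (alternation with the signal hidden). With `d̄ < 0.5` the
broadcast signal triggers a positive feedback loop in integrated groups;
in segregated groups it amplifies whatever the biased early raters decide —
helpful for true messages (`d_align < 0.5`), *backfiring* for false ones
(`d_align > 0.5`).

The package contains:

* `crowdrate.model_core` — the choice model (difficulties, rating signal,
  logistic propensity);
* `crowdrate.simulator` — vectorised Monte-Carlo ensembles and difficulty
  sweeps over the three scenarios;
* `crowdrate.synthetic_experiment` — a generator that emulates an
  80-group bipartisan rating experiment (4 conditions × 20 groups × 50
  subjects × 20 messages, 80,000 decisions) with the model as the
  generative process;
* `crowdrate.analysis` — difficulty estimation from the independent
  condition, hypothesis-scoped message selection, group-level permutation
  tests, moving-average position profiles, cluster-robust logistic position
  trends, and a bootstrap for difficulty-estimate uncertainty;
* `crowdrate.cli` — `crowdrate simulate-theory | generate-data | analyze |
  reproduce-tables`.

## Worked example

```python
import numpy as np
from crowdrate import (ExperimentConfig, MessageSpec, ModelParams,
                       estimate_difficulty, generate_experiment,
                       run_ensemble, run_hypothesis_analysis)

rng = np.random.default_rng(1)
params = ModelParams(susceptibility=2.35, group_size=50)
false_msg = MessageSpec("demo", veracity=-1, lean="liberal",
                        mean_difficulty=0.45, bias=0.2)
for scenario in ("independent", "integrated", "segregated"):
    s = run_ensemble(params, false_msg, scenario, n_runs=10_000, rng=rng)
    print(scenario, round(s.fraction_correct, 3))
```

prints (values vary within Monte-Carlo error ±0.01):

```
independent 0.55
integrated 0.594
segregated 0.479
```

Independent raters are correct 55% of the time (`1 − d̄`); broadcasting the
rating in a well-mixed group lifts accuracy to ~0.60, while the same false
message rated aligned-first *backfires* to ~0.48 — worse than no rating
display at all. The full experimental pipeline:

```python
decisions = generate_experiment(ExperimentConfig(seed=7))   # 80,000 rows
report = run_hypothesis_analysis(decisions, "H3",
                                 n_permutations=10_000, seed=3)
for t in report["tests"]:
    print(t.label, round(t.ate, 1), round(t.p_value, 3))
```

```
H3_liberal -5.9 0.085
H3_conservative -4.3 0.289
H3_all -5.1 0.165
```

i.e. groups that rated false congenial messages aligned-first classified
them ~5 percentage points less accurately than independent groups, with a
two-sided permutation p-value per comparison (group-level cascade variance
makes individual replicates noisy; see `docs/methods.md` on power).

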