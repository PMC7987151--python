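# crowdsolve

Tools for studying **nominal-group aggregation of crowdsourced reasoning
answers**: when does pooling independent workers' answers by plurality vote
help, and when does it systematically amplify a shared cognitive bias?

The package is aimed at researchers in collective judgement / psychometrics
and at practitioners running crowdsourcing ("crowdsolving") pipelines who
want to quantify the effect of group size and of pre-screening workers.

## The problem and the model

A pool of workers answers a 30-item reasoning challenge split into four
subtests: a 4-item Cognitive Reflection Test (CRT), a 9-item Raven's
Standard Progressive Matrices short form (RSPM), a 9-item
heuristics-and-biases test (HBT) and an 8-item syllogistic reasoning test
(SRT, half of whose items cross believability with logical validity and
index *belief bias*). A *nominal group* of size *n* is a random sample of
workers, drawn without replacement, whose answer to each item is the option
with the most votes (relative majority); ties are broken uniformly at
random.

The generalized Condorcet Jury Theorem governs what aggregation does: with
*k* options and each voter more likely to choose the correct option than any
single wrong one, the plurality's probability of being correct increases
with *n*; but when an intuitively appealing *lure* option is modal in the
pool, the same mechanism drives the group answer toward the wrong option as
*n* grows — bias amplification. Screening workers by CRT performance
(pass = at least 2 of 4 correct; 3 of 4 as a stringent variant) reshapes the
pool's response distribution and can flip amplification into mitigation.

The package provides:

- `synthetic_pool` — a calibrated generator of worker pools: a shared latent
  reasoning trait θ ~ N(0,1), per-item correct probability
  `expit(a_i·θ + b_i)`, and errors split between the item's lure (weight
  λ_i) and the remaining distractors. Difficulties `b_i` are calibrated by
  Gauss–Hermite quadrature + root finding so marginal accuracies hit
  specified targets.
- `scoring` — 0/1 scoring, subtest totals (SRT split by congruence),
  percent-correct, CRT screening, and per-item response distributions.
- `group_aggregation` — the resampling procedure: accuracy-vs-group-size
  curves over B replicates (default 1000) per size (default 1..25), and
  Cohen's *d* between replicate score distributions at two sizes.
- `condorcet` — exact plurality-winner probabilities (with 1/t tie credit)
  for iid voters (multinomial) and for finite-pool sampling without
  replacement (multivariate hypergeometric), the analytic oracle of the
  simulation.
- `inferential_stats` — descriptives, Spearman correlations, Welch *t* with
  Satterthwaite df and CI, per-item 2×2 χ² (passed/failed × correct/
  incorrect), and hierarchical OLS blocks with ΔR²/ΔF.
- `cli_io` / a `crowdsolve` CLI — CSV/JSON/YAML formats, free-text answer
  normalisation, and a reproducible end-to-end pipeline.

## Worked example

```python
from crowdsolve import (
    PoolSpec, GroupConfig, sample_pool, default_item_bank,
    score_responses, screen_by_crt, accuracy_curves, max_gain_effect_size,
)

bank = default_item_bank()
pool = sample_pool(PoolSpec(n_workers=95, seed=0))   # workers x items labels
scores = score_responses(pool, bank)
screen = screen_by_crt(scores, threshold=2)
print(f"passed {len(screen.passed)} of 95")

ids = [it.item_id for it in bank if it.scale == "SRT_incongruent"]
cfg = GroupConfig(sizes=tuple(range(1, 26)), replicates=1000, seed=0)
for label, workers in [("all", None), ("passed", list(screen.passed))]:
    curve = accuracy_curves(pool, bank, ids, cfg, workers=workers)
    eff = max_gain_effect_size(curve, n_low=1, n_high=25)
    print(f"{label:7s} mean score {eff.mean_low:.2f} -> {eff.mean_high:.2f} "
          f"(d = {eff.d:+.2f}, {eff.direction})")
```

Output:

```
passed 32 of 95
all     mean score 1.46 -> 0.52 (d = -0.77, loss)
passed  mean score 2.76 -> 3.75 (d = +0.99, gain)
```

Read: on the four belief-bias syllogisms, unscreened nominal groups of 25
score *worse* than individuals (the lure is modal in the full pool, so
plurality voting amplifies the bias, d = −0.77), while groups drawn from the
CRT-screened subpool improve with size (d = +0.99) — screening flips
amplification into mitigation.

The same analysis end to end, with all artifacts written to `out/`:

```bash
crowdsolve run-all --seed 0 --out out
```

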