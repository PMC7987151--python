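# Methods

This note documents the models and procedures implemented in `crowdsolve`,
the choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Nominal-group aggregation

A nominal group of size *n* is drawn uniformly without replacement from the
worker pool. The group's answer to an item is the option with the strictly
largest vote count; a *t*-way tie is broken uniformly at random. A group
answers every item of a test, its test score is the number of items answered
correctly, and the procedure is repeated B times (default 1000) for each
size n in 1..25. Item-level accuracies (fraction of replicates correct) and
the B replicate test scores come from the same replicates, so the mean
replicate score equals the sum of item accuracies at each n.

Groups are re-drawn independently across sizes and replicates (no nesting):
each (n, replicate) pair is a fresh draw. The maximal group-size effect is
summarised by Cohen's d between the replicate score distributions at two
sizes (default 1 and 25), pooled-SD variant,
d = (m_high − m_low) / s_pooled with
s_pooled = sqrt(((B−1)s_high² + (B−1)s_low²) / (2B−2)). The sign is kept:
negative d means larger groups scored worse (bias amplification).

**Reproducibility.** All randomness derives from a single master seed via
`numpy` `SeedSequence`-style keyed streams: group draws for size n use the
stream `[seed, 11, n]`; tie-breaks for item i at size n use
`[seed, 13, n, crc32(item_id)]`, indexed by replicate. Tie-break streams are
keyed by item id rather than by iteration order, so curves are bit-identical
regardless of the order in which items are processed, and identical
configurations give identical output files.

## Exact plurality-winner probabilities

The simulation's estimand has a closed form. For one item with k options,
the probability that a designated option wins the plurality (counting a
1/t share for t-way ties — exactly what random tie-breaking estimates) is
computed by summing over vote-count vectors:

- **multinomial backend** (iid voters with probability vector p): sum over
  compositions of n into k parts with multinomial weights; above 2×10⁶
  compositions a dynamic program is used instead (condition on the
  designated option's count c, convolve the other options' generating terms
  p_j^{c_j}/c_j! under the cap c_j ≤ c, tracking how many hit c exactly);
  a guard raises above 10⁸ compositions.
- **hypergeometric backend** (n votes drawn without replacement from fixed
  pool counts): sum over bounded compositions with multivariate-
  hypergeometric weights. This is the exact finite-pool counterpart of
  nominal-group sampling and is the oracle the simulation is tested against.

Both backends partition unity when every option is treated as the
designated one in turn (checked to 1e-10), and the hypergeometric backend
converges to the multinomial one as the pool grows at fixed n.

Tie handling is "random tie-break credit" (1/t), not "tie = failure", so
simulation and analytics estimate the same quantity.

## The synthetic pool

Real response data live in an external repository; the generator reproduces
the *statistical structure* the analyses depend on, not the data:

- one latent reasoning trait θ ~ N(0,1) per worker;
- P(correct on item i | θ) = expit(a_i·θ + b_i), a two-parameter logistic
  item response curve with discrimination a_i ≥ 0;
- an incorrect answer lands on the item's lure with probability λ_i,
  otherwise uniformly on the remaining distractors (items with two options
  have λ_i ≡ 1 — the single wrong option *is* the lure).

This is the simplest generative structure that yields (i) positive
cross-subtest correlations through the shared trait, (ii) heterogeneous
item difficulty, and (iii) items whose modal pool answer is wrong, which
happens exactly when λ_i(1−p_i) exceeds both p_i and every other-distractor
mass.

**Calibration.** Marginal accuracies E_θ[expit(a_iθ + b_i)] are evaluated
with a 61-node Gauss–Hermite rule (error far below every tolerance used)
and b_i is solved by bracketed root finding (Brent) to reproduce target
rates to ~1e-12; the stated calibration contract is 1e-6. Default per-item
targets sum to the study-scale subtest anchors: CRT 1.27/4, RSPM 4.76/9,
HBT 3.63/9, SRT-incongruent 1.45/4, SRT-congruent 3.66/4. Within a subtest
the per-item spread is a design choice (published anchors are subtest-level
means): RSPM difficulty increases through the set; the HBT spans accuracies
0.18–0.62 so item-level curves range from steep improvement to marked
amplification.

**Lure placement.** The full-pool modal answer is incorrect on exactly
three HBT items — sample-size accounting (strongly), covariation detection
(most strongly) and methodological reasoning (weakly) — and on all four
incongruent SRT items; every other item is correct-modal. Denominator
neglect is configured nearly even with the correct option slightly ahead,
regression-to-the-mean with low accuracy but errors spread over four
distractors.

**Discrimination.** Defaults are per subtest: CRT 1.3, RSPM 1.0, HBT 0.65,
SRT-congruent 0.8, SRT-incongruent 2.2 (all overridable per item). These
were calibrated once, at N = 10,000, against the cross-subtest rank
correlation targets (CRT–HBT ≈ .44, CRT–SRT-incongruent ≈ .56) and the
screening pass rate (≈ 35/95 at threshold 2): a uniform a_i = 1 cannot
reproduce the published ordering (CRT correlates more strongly with the
belief-bias items than with the HBT), which requires the belief-bias items
to load hardest on the trait. The high SRT-incongruent discrimination is
also what makes CRT screening flip those items from lure-modal to
correct-modal — the mechanism behind the mitigation result.

**Demographics.** Age (≈ N(48.6, 15.4²), clipped to 18–90), a female
indicator (47%) and a tertiary-education indicator (42%) are generated
independently of the trait, matching the pool's marginals; the regression
layer needs them as covariates. Real demographic–performance correlations,
platform effects, inattention, and item-level multidimensionality are *not*
modelled — so passing tests show that the pipeline and the aggregation
mathematics are correct under the stated generative assumptions, not that
any particular real-world pool behaves this way.

**CRT answers** are generated directly as canonical labels
(`correct`/`lure`/`other`); parsing of free-text numeric answers ("5
cents", "$0.05", "5c") is confined to the I/O layer, which normalises text
(trim, lowercase, strip currency and unit tokens, parse the number) and
matches against the answer key's accepted-value sets — numerically for
numbers, literally for strings. Unparseable entries are kept verbatim and
simply score 0.

## Scoring and screening

Answers score 1 if equal to the keyed correct option, else 0; missing
answers score 0 (denominators stay fixed) and are logged rather than
excluded. Percent-correct (100·total/n_items) is never rounded internally.
Screening partitions the pool at CRT ≥ threshold (default 2 of 4; 3 is the
stringent variant, which shrinks the passed pool and therefore caps the
attainable group sizes — the pipeline clips the size grid to the pool).

## Inference layer

- Descriptives: mean, sample SD (n−1), median per subtest.
- Correlations: Spearman's rho with average ranks (the "non-parametric"
  choice; Pearson available via flag), p from the large-sample
  approximation.
- Welch t from summary statistics or raw samples, Welch–Satterthwaite df,
  95% CI from the t quantile at that df. From the published 2-decimal
  summaries of the screening contrast this gives t = 16.87, df = 57.6,
  CI [1.89, 2.41]; a df computed from unrounded SDs differs in the first
  decimal, which is within the input-rounding envelope.
- Per-item 2×2 χ² (passed/failed × correct/incorrect), df = 1, no
  continuity correction by default (selectable); a zero marginal is flagged
  degenerate rather than raising. No multiple-testing adjustment is applied
  across items by default; a Holm helper is provided.
- Hierarchical regression: nested OLS blocks (demographics; + estimated
  IQ; + CRT pass indicator) on z-scored variables, so coefficients are
  standardised βs; block improvement is tested with
  ΔF = (ΔR²/Δk) / ((1−R²_full)/(n−k_full−1)). Rank deficiency raises an
  error naming the collinear columns.
- Estimated IQ is a declared stand-in: 100 + 15·(RSPM − pool mean)/pool SD.
  The published short-form-to-full-scale conversion is not reproduced;
  because the mapping is affine, standardised regression results are
  unaffected by the choice.

## Numerical and testing choices

- Quadrature: 61-node probabilists' Gauss–Hermite; root finding: Brent on
  b ∈ [−50, 50], xtol 1e-12.
- Enumeration guard: 10⁸ compositions; multinomial DP fallback engages at
  2×10⁶.
- The simulation-vs-oracle agreement test runs a 20-worker pool, all 30
  items, n ∈ {1,3,5,7}, B = 20,000 — 120 simultaneous comparisons. The
  family bound is Bonferroni-calibrated (max |z| ≤ 3.94 at familywise 1%)
  with at most two individual 3-SE excursions and median |z| ≤ 1.2; a
  systematic bias of half a standard error would fail all three. Simulation
  unbiasedness was verified directly (mean deviation across 30 independent
  simulation seeds: −0.0004 ± 0.0005).
- Directional tests (amplification unscreened vs mitigation screened) run
  on the default pool (N = 95, seed 0, B = 1000, sizes 1..25). At study
  scale the screened-pool pattern is a property of the generating process,
  not of every realisation: an N = 95 draw occasionally yields a passed
  subpool in which an SRT item stays lure-modal, exactly as a real pool of
  that size might.
- Problem sizes used by the test suite and the acceptance script (N = 95
  and N = 10,000 pools, B = 1000 curves, B = 20,000 oracle comparison) keep
  a full run within a few seconds on one CPU.

## Known limitations

- Single latent trait: all cross-subtest structure is unidimensional;
  method variance, speededness and inattention are absent.
- HBT option counts per construct are plausible stand-ins (the published
  materials are external); so are the CRT accepted-answer sets.
- No deliberation, confidence weighting, or correlated voting: groups are
  strictly nominal, matching the aggregation model, not interacting crowds.
- The exact backends scale as bounded compositions of n into k parts —
  comfortable at k ≤ 9, n ≤ 101, but not intended for large-k ballots.
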