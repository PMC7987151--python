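"""Nominal-group aggregation: plurality voting over resampled groups.

The core procedure: for each group size ``n``, repeatedly (``B`` replicates,
default 1000) draw a nominal group of ``n`` workers from the pool uniformly
without replacement, answer every item of a test by relative majority
(plurality) with uniform random tie-breaking, score the group's answer
vector, and summarise accuracy per item and per test across replicates.

Group draws for size ``n`` come from a dedicated RNG stream derived from the
master seed and ``n``; tie-breaks come from per-(size, item) streams indexed
by replicate, so results do not depend on the order in which items are
iterated.  Identical configuration therefore yields bit-identical curves.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .items import ItemSpec

__all__ = [
    "GroupConfig",
    "AccuracyCurve",
    "EffectSizeReport",
    "sample_nominal_group",
    "plurality_vote",
    "accuracy_curves",
    "max_gain_effect_size",
    "cohens_d",
]

# namespace constants separating the RNG streams derived from the master seed
_NS_GROUPS = 11
_NS_TIES = 13


@dataclass(frozen=True)
class GroupConfig:
    """Configuration of the resampling procedure."""

    sizes: tuple[int, ...] = tuple(range(1, 26))
    replicates: int = 1000
    seed: int = 0
    pool: str = "all"  # "all" | "passed" | "failed" — bookkeeping label

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(n < 1 for n in self.sizes):
            raise ValueError("group sizes must be >= 1")


@dataclass(frozen=True)
class AccuracyCurve:
    """Per-size accuracy estimates from one resampling run.

    ``item_accuracy``: DataFrame indexed by group size, one column per item,
    each cell the fraction of replicates in which that item's group answer
    was correct.  ``scores``: per size, the B replicate overall test scores
    (number of items the group answered correctly).  Item accuracies and
    scores come from the same replicates: ``item_accuracy.loc[n].sum() ==
    scores[n].mean()``.
    """

    test: str
    item_accuracy: pd.DataFrame
    scores: Mapping[int, np.ndarray]
    replicates: int
    seed: int
    pool: str = "all"
    pool_size: int = 0

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(int(n) for n in self.item_accuracy.index)

    @property
    def n_items(self) -> int:
        return self.item_accuracy.shape[1]

    def overall(self) -> pd.Series:
        """Mean replicate test score per group size."""
        return pd.Series(
            {n: float(np.mean(s)) for n, s in self.scores.items()},
            name="mean_score",
        )


@dataclass(frozen=True)
class EffectSizeReport:
    """Cohen's d between replicate score distributions at two group sizes."""

    n_low: int
    n_high: int
    d: float
    direction: str  # "gain" | "loss" | "none" | "degenerate"
    mean_low: float = 0.0
    mean_high: float = 0.0


def sample_nominal_group(
    pool: Sequence[str], n: int, rng: np.random.Generator
) -> list:
    """Draw one nominal group: n distinct workers, uniformly, no replacement."""
    pool = list(pool)
    if n < 1:
        raise ValueError("group size must be >= 1")
    if n > len(pool):
        raise ValueError(
            f"group size {n} exceeds the available pool of {len(pool)} workers"
        )
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def plurality_vote(counts: Mapping, rng: np.random.Generator):
    """Group answer by relative majority; ties broken uniformly at random."""
    if not counts:
        raise ValueError("empty vote counts")
    total = sum(counts.values())
    if total < 1 or any(c < 0 for c in counts.values()):
        raise ValueError("vote counts must be non-negative with total >= 1")
    top = max(counts.values())
    tied = [opt for opt, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def _stable_item_key(item_id: str) -> int:
    return zlib.crc32(item_id.encode("utf-8")) & 0x7FFFFFFF


def _sample_groups_matrix(
    m: int, n: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B independent groups of n from m workers, without replacement (B x n)."""
    # rank of iid uniforms = a uniform random permutation per row
    return np.argsort(rng.random((B, m)), axis=1)[:, :n]


def accuracy_curves(
    responses: pd.DataFrame,
    key: Sequence[ItemSpec],
    item_ids: Sequence[str],
    config: GroupConfig,
    workers: Sequence[str] | None = None,
    test: str = "custom",
) -> AccuracyCurve:
    """Estimate item- and test-level accuracy across group sizes.

    For each size in ``config.sizes`` and each of ``config.replicates``
    replicates, one group is drawn and answers *all* items of the test, so
    the replicate's overall score is the sum of its item scores.
    """
    keyed = {it.item_id: it for it in key}
    items = []
    for iid in item_ids:
        if iid not in keyed:
            raise KeyError(f"unknown item {iid!r}")
        items.append(keyed[iid])
    if not items:
        raise ValueError("empty item set")

    pool_ids = list(workers) if workers is not None else list(responses.index)
    m = len(pool_ids)
    for n in config.sizes:
        if n > m:
            raise ValueError(
                f"group size {n} exceeds the available pool of {m} workers"
            )

    sub = responses.loc[pool_ids]
    # integer-code each item's responses over (options + stray labels)
    coded: dict[str, tuple[np.ndarray, int, int]] = {}
    for it in items:
        col = sub[it.item_id]
        labels = list(it.options) + sorted(
            set(col.dropna().unique()) - set(it.options)
        )
        lut = {lab: j for j, lab in enumerate(labels)}
        missing_code = len(labels)  # missing answers are never correct
        codes = np.array(
            [missing_code if pd.isna(v) else lut[v] for v in col], dtype=np.int64
        )
        coded[it.item_id] = (codes, missing_code + 1, lut[it.correct])

    B = config.replicates
    item_acc = np.zeros((len(config.sizes), len(items)))
    scores: dict[int, np.ndarray] = {}
    for si, n in enumerate(config.sizes):
        rng_groups = np.random.default_rng([config.seed, _NS_GROUPS, n])
        groups = _sample_groups_matrix(m, n, B, rng_groups)
        score = np.zeros(B, dtype=np.int64)
        for ii, it in enumerate(items):
            codes, n_codes, correct_code = coded[it.item_id]
            votes = codes[groups]  # B x n
            counts = np.zeros((B, n_codes), dtype=np.int64)
            for j in range(n_codes):
                counts[:, j] = (votes == j).sum(axis=1)
            top = counts.max(axis=1)
            at_max = counts == top[:, None]
            t = at_max.sum(axis=1)
            rng_tie = np.random.default_rng(
                [config.seed, _NS_TIES, n, _stable_item_key(it.item_id)]
            )
            pick = np.floor(rng_tie.random(B) * t).astype(np.int64)
            # choose the pick-th tied option per replicate
            order = np.cumsum(at_max, axis=1) - 1
            chosen = np.argmax(
                at_max & (order == pick[:, None]), axis=1
            )
            correct = chosen == correct_code
            item_acc[si, ii] = correct.mean()
            score += correct
        scores[int(n)] = score

    item_accuracy = pd.DataFrame(
        item_acc,
        index=pd.Index(list(config.sizes), name="n"),
        columns=[it.item_id for it in items],
    )
    return AccuracyCurve(
        test=test,
        item_accuracy=item_accuracy,
        scores=scores,
        replicates=B,
        seed=config.seed,
        pool=config.pool,
        pool_size=m,
    )


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD Cohen's d, (mean(y) - mean(x)) / s_pooled, sign preserved."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per sample")
    sx2, sy2 = np.var(x, ddof=1), np.var(y, ddof=1)
    sp = np.sqrt(((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2))
    diff = float(np.mean(y) - np.mean(x))
    if sp == 0.0:
        if diff == 0.0:
            return 0.0
        raise ValueError("degenerate: zero pooled SD with unequal means")
    return diff / float(sp)


def max_gain_effect_size(
    curve: AccuracyCurve, n_low: int = 1, n_high: int = 25
) -> EffectSizeReport:
    """Cohen's d between replicate test scores at two group sizes.

    Positive d means a performance gain with group size; negative means
    aggregation amplified bias (the larger groups scored lower).
    """
    for n in (n_low, n_high):
        if n not in curve.scores:
            raise KeyError(f"size {n} not present in the curve")
    lo = np.asarray(curve.scores[n_low], dtype=float)
    hi = np.asarray(curve.scores[n_high], dtype=float)
    try:
        d = cohens_d(lo, hi)
    except ValueError as exc:
        if "degenerate" in str(exc):
            return EffectSizeReport(
                n_low=n_low,
                n_high=n_high,
                d=float("nan"),
                direction="degenerate",
                mean_low=float(lo.mean()),
                mean_high=float(hi.mean()),
            )
        raise
    direction = "gain" if d > 0 else ("loss" if d < 0 else "none")
    return EffectSizeReport(
        n_low=n_low,
        n_high=n_high,
        d=d,
        direction=direction,
        mean_low=float(lo.mean()),
        mean_high=float(hi.mean()),
    )
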