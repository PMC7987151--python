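"""Scoring, subtest totals, CRT screening, and response distributions.

Responses are scored 1 for a correct answer and 0 for anything else
(including a missing answer — denominators stay fixed), and summed within
subtest; SRT totals are split by congruence because only the incongruent
items index belief bias.  Percent-correct is ``100 * total / n_items``.

Screening partitions the pool by the CRT total: a worker "passes" with at
least ``threshold`` of the 4 CRT items correct (default 2; 3 is the
stringent variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .items import SCALE_COLUMNS, ItemSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMatrix",
    "ScreenResult",
    "PluralityDistribution",
    "score_responses",
    "percent_correct",
    "screen_by_crt",
    "response_distribution",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Binary worker x item scores plus derived per-worker subtest totals.

    ``scores``: DataFrame of 0/1 ints (workers x items).
    ``totals``: DataFrame of per-worker totals over the five scales
    (CRT 0-4, RSPM 0-9, HBT 0-9, SRT_congruent 0-4, SRT_incongruent 0-4).
    """

    scores: pd.DataFrame
    totals: pd.DataFrame
    items: tuple[ItemSpec, ...]

    @property
    def worker_ids(self) -> list[str]:
        return list(self.scores.index)

    def n_items(self, scale: str) -> int:
        return sum(1 for it in self.items if it.scale == scale)


@dataclass(frozen=True)
class ScreenResult:
    """Partition of the pool into CRT 'passed' and 'failed' workers."""

    threshold: int
    passed: tuple[str, ...]
    failed: tuple[str, ...]

    @property
    def pass_fraction(self) -> float:
        n = len(self.passed) + len(self.failed)
        return len(self.passed) / n


@dataclass(frozen=True)
class PluralityDistribution:
    """Empirical per-option response probabilities for one item in a pool.

    ``counts`` are retained because the finite-pool (hypergeometric)
    plurality oracle needs integer counts, not just frequencies.
    """

    item_id: str
    options: tuple[str, ...]
    counts: tuple[int, ...]
    n_pool: int

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_pool

    def __post_init__(self) -> None:
        if self.n_pool <= 0:
            raise ValueError("empty pool")
        if sum(self.counts) != self.n_pool:
            raise ValueError("counts do not sum to the pool size")


def score_responses(
    responses: pd.DataFrame, key: Sequence[ItemSpec]
) -> ScoreMatrix:
    """Score a response matrix against an answer key.

    A cell scores 1 iff the response equals the item's correct option label
    (free-text normalisation for open-numeric items happens at load time,
    see :mod:`crowdsolve.cli_io`).  Missing responses score 0 and are
    logged.  Every response column must resolve to a keyed item.
    """
    keyed = {it.item_id: it for it in key}
    unknown = [c for c in responses.columns if c not in keyed]
    if unknown:
        raise KeyError(f"response columns not in the answer key: {unknown}")
    if responses.index.has_duplicates:
        dupes = responses.index[responses.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate worker ids: {dupes}")

    n_missing = int(responses.isna().sum().sum())
    if n_missing:
        logger.info("scoring %d missing responses as 0", n_missing)

    items = tuple(keyed[c] for c in responses.columns)
    correct_row = pd.Series(
        {it.item_id: it.correct for it in items}, dtype=object
    )
    scores = (
        responses.eq(correct_row, axis=1).fillna(False).astype(int)
    )

    totals = pd.DataFrame(index=responses.index)
    for scale in SCALE_COLUMNS:
        cols = [it.item_id for it in items if it.scale == scale]
        totals[scale] = scores[cols].sum(axis=1) if cols else 0
    return ScoreMatrix(scores=scores, totals=totals, items=items)


def percent_correct(total: float, n_items: int) -> float:
    """Percentage score, ``100 * total / n_items``, unrounded."""
    if n_items <= 0:
        raise ValueError("n_items must be positive")
    if not 0 <= total <= n_items:
        raise ValueError(f"total {total} outside [0, {n_items}]")
    return 100.0 * total / n_items


def screen_by_crt(scores: ScoreMatrix, threshold: int = 2) -> ScreenResult:
    """Partition workers by CRT total at the given pass threshold."""
    if not 0 <= threshold <= 5:
        raise ValueError("threshold must be in 0..5")
    crt = scores.totals["CRT"]
    passed = tuple(crt.index[crt >= threshold])
    failed = tuple(crt.index[crt < threshold])
    return ScreenResult(threshold=threshold, passed=passed, failed=failed)


def response_distribution(
    responses: pd.DataFrame,
    item: ItemSpec,
    subset: Iterable[str] | None = None,
    collapse_unique: bool = False,
) -> PluralityDistribution:
    """Empirical option frequencies for one item within a worker subset.

    With ``collapse_unique=True``, options chosen by exactly one worker are
    pooled into an ``"other"`` display category (the figure-style variant);
    voting and the exact oracles always use the non-collapsed counts.
    Responses outside the item's option list (e.g. unnormalised free text)
    are tallied as their own categories so the distribution still sums to 1.
    """
    col = responses[item.item_id]
    if subset is not None:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("empty worker subset")
        col = col.loc[subset]
    if len(col) == 0:
        raise ValueError("empty worker subset")

    observed = col.dropna()
    counts = observed.value_counts()
    # fixed option order first, then any stray labels in sorted order
    labels = list(item.options) + sorted(
        set(counts.index) - set(item.options)
    )
    tallies = [int(counts.get(lab, 0)) for lab in labels]
    n_missing = len(col) - len(observed)
    if n_missing:
        labels.append("<missing>")
        tallies.append(int(n_missing))

    if collapse_unique:
        kept_labels, kept = [], []
        n_other = 0
        for lab, c in zip(labels, tallies):
            if c == 1:
                n_other += 1
            else:
                kept_labels.append(lab)
                kept.append(c)
        if n_other:
            kept_labels.append("other")
            kept.append(n_other)
        labels, tallies = kept_labels, kept

    return PluralityDistribution(
        item_id=item.item_id,
        options=tuple(labels),
        counts=tuple(tallies),
        n_pool=int(len(col)),
    )
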