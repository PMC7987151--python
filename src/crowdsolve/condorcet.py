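"""Exact plurality-winner probabilities (generalised Condorcet machinery).

For a group of ``n`` voters over ``k`` options, the group answer is the
option with the strictly largest vote count; ties among ``t`` maxima are
broken uniformly at random.  The quantity computed throughout is therefore

    P(win) = P(strict max) + sum_t (1/t) * P(tied among t maxima),

the *tie-credit* form, which is exactly what a simulation with random
tie-breaking estimates.

Two voting models are supported:

* **multinomial** — iid voters, each voting per a probability vector ``p``
  (the classical jury-theorem setting: if the correct option's probability
  exceeds every other option's, the win probability increases with ``n``
  and tends to 1; reversed if a wrong option is favoured);
* **hypergeometric** — ``n`` votes drawn without replacement from a finite
  pool with fixed per-option counts, the exact counterpart of nominal-group
  sampling from a worker pool.

Both are computed by summing over vote-count vectors (bounded compositions
of ``n``) with exact multinomial / multivariate-hypergeometric weights; a
guard raises above 1e8 compositions, and the multinomial backend then falls
back to a dynamic program over per-option count caps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .scoring import PluralityDistribution

__all__ = [
    "CondorcetCurve",
    "plurality_prob_multinomial",
    "plurality_prob_hypergeometric",
    "cjt_curve",
]

_MAX_COMPOSITIONS = 10**8


@dataclass(frozen=True)
class CondorcetCurve:
    """Exact win probability of one option across group sizes."""

    backend: str  # "multinomial" | "hypergeometric"
    sizes: tuple[int, ...]
    values: tuple[float, ...]
    correct_index: int
    direction: str  # "toward_correct" | "toward_wrong:<label/index>" | "mixed"


def _compositions(n: int, bounds: Sequence[int]) -> Iterator[tuple[int, ...]]:
    """All integer vectors c with 0 <= c_j <= bounds[j] and sum(c) = n."""
    k = len(bounds)

    def rec(j: int, remaining: int, prefix: list[int]):
        if j == k - 1:
            if remaining <= bounds[j]:
                yield tuple(prefix + [remaining])
            return
        tail_cap = sum(bounds[j + 1:])
        lo = max(0, remaining - tail_cap)
        hi = min(bounds[j], remaining)
        for c in range(lo, hi + 1):
            yield from rec(j + 1, remaining - c, prefix + [c])

    yield from rec(0, n, [])


def _n_compositions(n: int, k: int) -> int:
    return math.comb(n + k - 1, k - 1)


def _tie_credit(counts: Sequence[int], correct_index: int) -> float:
    m = max(counts)
    if counts[correct_index] != m:
        return 0.0
    return 1.0 / sum(1 for c in counts if c == m)


def _validate_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValueError("p must be a 1-d probability vector")
    if (p < 0).any():
        raise ValueError("p has negative entries")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError(f"p sums to {p.sum()!r}, not 1")
    return p


def plurality_prob_multinomial(
    p: Sequence[float],
    correct_index: int,
    n: int,
    method: str = "auto",
) -> float:
    """Exact P(designated option wins the plurality) with n iid voters.

    ``method``: "enumerate" sums over all count compositions, "dp" uses the
    dynamic program (conditioning on the designated option's count and
    convolving the others under a per-option cap), "auto" enumerates when
    feasible and otherwise switches to the DP.
    """
    p = _validate_p(p)
    if not 0 <= correct_index < len(p):
        raise IndexError("correct_index out of range")
    if n < 1:
        raise ValueError("n must be >= 1")
    k = len(p)
    if method == "auto":
        method = "enumerate" if _n_compositions(n, k) <= 2_000_000 else "dp"
    if method == "enumerate":
        if _n_compositions(n, k) > _MAX_COMPOSITIONS:
            raise ValueError(
                "composition count exceeds the 1e8 guard; use method='dp'"
            )
        return _multinomial_enumerate(p, correct_index, n)
    if method == "dp":
        return _multinomial_dp(p, correct_index, n)
    raise ValueError(f"unknown method {method!r}")


def _multinomial_enumerate(p: np.ndarray, correct_index: int, n: int) -> float:
    k = len(p)
    logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
    lg_n = math.lgamma(n + 1)
    total = 0.0
    for counts in _compositions(n, [n] * k):
        credit = _tie_credit(counts, correct_index)
        if credit == 0.0:
            continue
        logw = lg_n
        ok = True
        for c, lp in zip(counts, logp):
            if c == 0:
                continue
            if lp == -np.inf:
                ok = False
                break
            logw += c * lp - math.lgamma(c + 1)
        if ok:
            total += credit * math.exp(logw)
    return total


def _multinomial_dp(p: np.ndarray, correct_index: int, n: int) -> float:
    """DP form: condition on the designated option's count c, then convolve
    the remaining options' exponential-generating terms p_j^c_j / c_j! under
    the cap c_j <= c, tracking how many hit c exactly (tie multiplicity)."""
    others = [p[j] for j in range(len(p)) if j != correct_index]
    pc = p[correct_index]
    total = 0.0
    for c in range(n + 1):
        r = n - c
        if r > c * len(others):  # others cannot all stay <= c
            continue
        # f[v][t] = sum over assignments of v votes to processed options,
        # each <= c, t of them exactly c, of prod p_j^c_j / c_j!
        f = np.zeros((r + 1, len(others) + 1))
        f[0][0] = 1.0
        for q in others:
            g = np.zeros_like(f)
            powq = [q**cj / math.factorial(cj) for cj in range(min(c, r) + 1)]
            for v in range(r + 1):
                for t in range(len(others) + 1):
                    base = f[v][t]
                    if base == 0.0:
                        continue
                    for cj in range(min(c, r - v) + 1):
                        g[v + cj][t + (1 if cj == c and c > 0 else 0)] += (
                            base * powq[cj]
                        )
            f = g
        if pc == 0.0 and c > 0:
            continue
        lead = (pc**c / math.factorial(c)) if c > 0 else 1.0
        contrib = sum(f[r][t] / (1 + t) for t in range(len(others) + 1))
        total += lead * contrib
    return total * math.factorial(n)


def plurality_prob_hypergeometric(
    pool_counts: Sequence[int],
    correct_index: int,
    n: int,
) -> float:
    """Exact P(designated option wins) when n votes are drawn without
    replacement from a finite pool with the given per-option counts."""
    counts = [int(c) for c in pool_counts]
    if any(c < 0 for c in counts):
        raise ValueError("pool counts must be non-negative")
    total_pool = sum(counts)
    if total_pool < 1:
        raise ValueError("empty pool")
    if not 0 <= correct_index < len(counts):
        raise IndexError("correct_index out of range")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > total_pool:
        raise ValueError(
            f"group size {n} exceeds the pool size {total_pool}"
        )
    if _n_compositions(n, len(counts)) > _MAX_COMPOSITIONS:
        raise ValueError("composition count exceeds the 1e8 guard")
    denom = float(math.comb(total_pool, n))
    total = 0.0
    for draw in _compositions(n, counts):
        credit = _tie_credit(draw, correct_index)
        if credit == 0.0:
            continue
        w = 1.0
        for m, c in zip(counts, draw):
            w *= math.comb(m, c)
        total += credit * w / denom
    return total


def cjt_curve(
    distribution: PluralityDistribution | Sequence[float] | Sequence[int],
    correct_index: int,
    sizes: Sequence[int],
    backend: str = "hypergeometric",
) -> CondorcetCurve:
    """Win-probability curve of the designated option across group sizes.

    Accepts a :class:`PluralityDistribution` (uses its integer counts for
    the hypergeometric backend or its frequencies for the multinomial one),
    a probability vector (multinomial) or raw counts (hypergeometric).
    The ``direction`` flag reports where aggregation pushes the group
    answer: toward the correct option (it is the unique pool mode), toward
    a specific wrong option (a unique incorrect mode), or "mixed" (tied
    modes).
    """
    if isinstance(distribution, PluralityDistribution):
        weights = (
            list(distribution.counts)
            if backend == "hypergeometric"
            else distribution.p
        )
        labels: Sequence = distribution.options
    else:
        weights = list(distribution)
        labels = list(range(len(weights)))

    if backend == "multinomial":
        p = _validate_p(np.asarray(weights, dtype=float))
        values = tuple(
            plurality_prob_multinomial(p, correct_index, n) for n in sizes
        )
        ref = p
    elif backend == "hypergeometric":
        values = tuple(
            plurality_prob_hypergeometric(weights, correct_index, n)
            for n in sizes
        )
        ref = np.asarray(weights, dtype=float)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    m = ref.max()
    modes = np.flatnonzero(ref == m)
    if len(modes) == 1 and modes[0] == correct_index:
        direction = "toward_correct"
    elif len(modes) == 1:
        direction = f"toward_wrong:{labels[modes[0]]}"
    else:
        direction = "mixed"

    return CondorcetCurve(
        backend=backend,
        sizes=tuple(int(n) for n in sizes),
        values=values,
        correct_index=int(correct_index),
        direction=direction,
    )
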