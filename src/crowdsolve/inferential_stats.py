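"""Descriptive and inferential layer: summaries, correlations, Welch t,
per-item chi-square screening contrasts, and hierarchical regression.

These are the classical analyses run on the individual-level scores before
any aggregation: per-subtest descriptives, nonparametric (Spearman)
correlations between subtests, a Welch two-sample t comparing CRT-passed and
CRT-failed workers, 2x2 chi-square tests of correct/incorrect by screening
status for each item, and nested OLS blocks (demographics, then estimated
IQ, then the CRT pass indicator) with block-wise delta-R-squared and
delta-F.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .items import SCALE_COLUMNS, ItemSpec
from .scoring import ScoreMatrix, ScreenResult

__all__ = [
    "WelchResult",
    "ChiSquareResult",
    "RegressionBlockResult",
    "summarize",
    "spearman_corr",
    "welch_t",
    "welch_t_samples",
    "chisq_pass_fail",
    "hierarchical_regression",
    "estimate_iq",
    "holm_adjust",
]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    mean_diff: float


@dataclass(frozen=True)
class ChiSquareResult:
    item_id: str
    chi2: float
    df: int
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False  # a zero marginal: p undefined


@dataclass(frozen=True)
class RegressionBlockResult:
    block: int
    predictors: tuple[str, ...]
    beta: dict
    t_values: dict
    p_values: dict
    r_squared: float
    adj_r_squared: float
    delta_r_squared: float
    delta_f: float
    delta_f_df: tuple[int, int]
    delta_f_p: float


def summarize(
    scores: ScoreMatrix, subset: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-subtest mean, sample SD (n-1), median and n for a worker subset."""
    totals = scores.totals
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("empty worker subset")
        totals = totals.loc[subset]
    if totals.empty:
        raise ValueError("empty worker subset")
    rows = {}
    for scale in SCALE_COLUMNS:
        col = totals[scale]
        rows[scale] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            "median": float(col.median()),
            "n": int(len(col)),
            "n_items": scores.n_items(scale),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def spearman_corr(x, y, method: str = "spearman") -> tuple[float, float]:
    """Rank (or, with method="pearson", product-moment) correlation and p.

    Spearman uses average ranks for ties; the p-value is the usual
    large-sample t approximation.  Constant input is flagged as undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def welch_t(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> WelchResult:
    """Welch two-sample t from summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), Welch–Satterthwaite df, and a
    95% CI for the mean difference using the t quantile at that df.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 == 0 and s2 == 0:
        raise ValueError("degenerate: both SDs are zero")
    v1, v2 = s1**2 / n1, s2**2 / n2
    se = np.sqrt(v1 + v2)
    t = (m1 - m2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    tq = sps.t.ppf(0.975, df)
    diff = m1 - m2
    return WelchResult(
        t=float(t),
        df=float(df),
        p=float(p),
        ci_low=float(diff - tq * se),
        ci_high=float(diff + tq * se),
        mean_diff=float(diff),
    )


def welch_t_samples(x, y) -> WelchResult:
    """Welch t from raw samples; identical to the summary-statistic path."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t(
        float(np.mean(x)), float(np.std(x, ddof=1)), len(x),
        float(np.mean(y)), float(np.std(y, ddof=1)), len(y),
    )


def chisq_pass_fail(
    item: ItemSpec,
    responses: pd.DataFrame,
    screen: ScreenResult,
    correction: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 table passed/failed x correct/incorrect.

    No continuity correction by default.  A zero marginal (e.g. nobody
    answered the item correctly) makes the test degenerate; the result is
    flagged and p set to NaN.
    """
    if not screen.passed or not screen.failed:
        raise ValueError("both screening groups must be non-empty")
    col = responses[item.item_id]
    table = []
    for group in (screen.passed, screen.failed):
        sub = col.loc[list(group)]
        n_correct = int((sub == item.correct).sum())
        table.append((n_correct, len(sub) - n_correct))
    tab = np.asarray(table, dtype=float)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return ChiSquareResult(
            item_id=item.item_id,
            chi2=float("nan"),
            df=1,
            p=float("nan"),
            table=(tuple(map(int, table[0])), tuple(map(int, table[1]))),
            degenerate=True,
        )
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=correction)
    return ChiSquareResult(
        item_id=item.item_id,
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        table=(tuple(map(int, table[0])), tuple(map(int, table[1]))),
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = np.std(col, ddof=1)
    if sd == 0:
        raise ValueError("constant column cannot be standardised")
    return (col - np.mean(col)) / sd


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    blocks: Sequence[Sequence[str]],
) -> list[RegressionBlockResult]:
    """Nested OLS blocks with standardised coefficients and delta-F tests.

    Each block adds predictors to the previous model.  Coefficients are
    standardised (all variables z-scored, ddof=1); their t and p values
    equal those of the raw fit.  Block improvement is tested with
    delta-F = (dR2/dk) / ((1 - R2_full)/(n - k_full - 1)).
    """
    n = len(data)
    cum: list[str] = []
    results: list[RegressionBlockResult] = []
    prev_r2 = 0.0
    for bi, block in enumerate(blocks, start=1):
        cum = cum + [c for c in block if c not in cum]
        if n <= len(cum) + 1:
            raise ValueError("not enough rows for the predictor count")
        X_raw = data[cum].to_numpy(dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), X_raw])) < len(cum) + 1:
            # name the offending columns: those whose removal restores rank
            collinear = []
            for j, name in enumerate(cum):
                reduced = np.delete(X_raw, j, axis=1)
                full_rank = np.linalg.matrix_rank(
                    np.column_stack([np.ones(n), reduced])
                )
                if full_rank == np.linalg.matrix_rank(
                    np.column_stack([np.ones(n), X_raw])
                ):
                    collinear.append(name)
            raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
        y = _zscore(data[outcome].to_numpy(dtype=float))
        Xz = np.column_stack([_zscore(X_raw[:, j]) for j in range(X_raw.shape[1])])
        model = sm.OLS(y, sm.add_constant(Xz)).fit()
        r2 = float(model.rsquared)
        k_full = len(cum)
        dk = len([c for c in block])
        d_r2 = r2 - prev_r2
        df2 = n - k_full - 1
        if r2 >= 1.0 - 1e-15:
            delta_f = float("inf") if d_r2 > 1e-15 else 0.0
            delta_f_p = 0.0 if d_r2 > 1e-15 else 1.0
        else:
            delta_f = (d_r2 / dk) / ((1.0 - r2) / df2)
            delta_f_p = float(sps.f.sf(delta_f, dk, df2))
        results.append(
            RegressionBlockResult(
                block=bi,
                predictors=tuple(cum),
                beta={c: float(model.params[j + 1]) for j, c in enumerate(cum)},
                t_values={c: float(model.tvalues[j + 1]) for j, c in enumerate(cum)},
                p_values={c: float(model.pvalues[j + 1]) for j, c in enumerate(cum)},
                r_squared=r2,
                adj_r_squared=float(model.rsquared_adj),
                delta_r_squared=float(d_r2),
                delta_f=float(delta_f),
                delta_f_df=(dk, df2),
                delta_f_p=delta_f_p,
            )
        )
        prev_r2 = r2
    return results


def estimate_iq(rspm_total, reference) -> np.ndarray | float:
    """Map RSPM short-form totals onto an IQ-like scale.

    A stand-in linear mapping, 100 + 15 * (score - pool mean) / pool SD:
    the published short-form-to-full-scale conversion is not reproduced
    here, and any affine mapping leaves standardised regression results
    unchanged.  ``reference`` is the pool of RSPM totals defining the
    anchor mean and SD.
    """
    ref = np.asarray(reference, dtype=float)
    sd = np.std(ref, ddof=1)
    if sd == 0:
        raise ValueError("reference pool has zero SD")
    score = np.asarray(rspm_total, dtype=float)
    out = 100.0 + 15.0 * (score - ref.mean()) / sd
    return float(out) if out.ndim == 0 else out
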