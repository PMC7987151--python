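"""Synthetic worker pools for the crowdsolving reasoning challenge.

Real worker data live on an external repository; this module generates
pools with the same statistical structure so that every downstream stage
(scoring, screening, nominal-group aggregation, inference) is fully testable
offline.  The generative model is deliberately minimal:

* each worker ``w`` has a single latent reasoning trait
  ``theta_w ~ Normal(0, 1)``;
* the probability of answering item ``i`` correctly is a two-parameter
  logistic, ``P(correct | theta) = expit(a_i * theta + b_i)``, with
  discrimination ``a_i >= 0`` and difficulty offset ``b_i``;
* an incorrect answer lands on the item's lure option with probability
  ``lambda_i`` and otherwise uniformly on the remaining distractors.

This is the simplest structure that reproduces the three features the
downstream analyses depend on: positive cross-subtest correlations through
the shared trait, heterogeneous item difficulty, and items whose *modal*
pool answer is incorrect (the lure commands a relative majority whenever
``lambda_i * (1 - p_i) > p_i``).

Default marginal accuracies are calibrated so that the expected subtest
totals match the study-scale anchors (CRT 1.27/4, RSPM 4.76/9, HBT 3.63/9,
SRT-incongruent 1.45/4, SRT-congruent 3.66/4); calibration adjusts each
``b_i`` by root finding on the trait-marginalised correct probability,
evaluated with 61-node Gauss–Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .items import ItemSpec, SUBTESTS

__all__ = [
    "TraitModelParams",
    "PoolSpec",
    "default_item_bank",
    "default_target_rates",
    "default_params",
    "marginal_correct_rate",
    "calibrate_difficulties",
    "sample_pool",
    "sample_demographics",
    "params_to_yaml",
    "params_from_yaml",
]

# 61-node probabilists' Gauss-Hermite rule for E_theta[f(theta)], theta ~ N(0,1)
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class TraitModelParams:
    """Per-item parameters of the latent-trait response model.

    ``a`` (discrimination, >= 0), ``b`` (difficulty offset) and
    ``lure_weight`` (share of incorrect-response mass on the lure option,
    in [0, 1]) are mappings keyed by item id.  The trait distribution is
    fixed to standard normal.
    """

    a: Mapping[str, float]
    b: Mapping[str, float]
    lure_weight: Mapping[str, float]

    def __post_init__(self) -> None:
        for item_id, val in self.a.items():
            if val < 0:
                raise ValueError(f"item {item_id!r}: discrimination a < 0")
        for item_id, val in self.lure_weight.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"item {item_id!r}: lure weight outside [0, 1]")

    def validate_against(self, bank: Sequence[ItemSpec]) -> None:
        """Check that the parameters cover the bank and respect its structure."""
        bank_ids = {it.item_id for it in bank}
        for name, mapping in (("a", self.a), ("b", self.b),
                              ("lure_weight", self.lure_weight)):
            for item_id in mapping:
                if item_id not in bank_ids:
                    raise KeyError(
                        f"parameter {name!r} references unknown item {item_id!r}"
                    )
        for it in bank:
            for name, mapping in (("a", self.a), ("b", self.b),
                                  ("lure_weight", self.lure_weight)):
                if it.item_id not in mapping:
                    raise KeyError(f"item {it.item_id!r} missing from {name!r}")
            # a 2-option item has a single incorrect option: all of the
            # incorrect mass is the lure by construction
            if it.n_options == 2 and self.lure_weight[it.item_id] != 1.0:
                raise ValueError(
                    f"item {it.item_id!r}: 2-option items require lure weight 1"
                )
            if it.lure is None and len(it.options) > 2:
                # without a designated lure, incorrect mass must be uniform
                if self.lure_weight[it.item_id] not in (0.0,):
                    raise ValueError(
                        f"item {it.item_id!r}: nonzero lure weight but no lure"
                    )


@dataclass(frozen=True)
class PoolSpec:
    """Specification of a synthetic worker pool."""

    n_workers: int = 95
    items: Sequence[ItemSpec] = field(default_factory=lambda: default_item_bank())
    params: TraitModelParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        counts = {s: 0 for s in SUBTESTS}
        for it in self.items:
            counts[it.subtest] += 1

    def resolved_params(self) -> TraitModelParams:
        params = self.params if self.params is not None else default_params(self.items)
        params.validate_against(self.items)
        return params


def marginal_correct_rate(a: float, b: float) -> float:
    """Trait-marginalised probability of a correct answer.

    ``E_theta[expit(a * theta + b)]`` for ``theta ~ N(0, 1)``, by 61-node
    Gauss-Hermite quadrature (exact enough that calibration error is
    dominated by the root-finder tolerance, not the quadrature).
    """
    return float(np.dot(_GH_WEIGHTS, expit(a * _GH_NODES + b)))


def calibrate_difficulties(
    params: TraitModelParams,
    target_rates: Mapping[str, float],
) -> TraitModelParams:
    """Adjust difficulty offsets so marginal correct rates hit targets.

    For each item in ``target_rates``, solves ``marginal_correct_rate(a_i, b)
    = target`` for ``b`` by bracketed one-dimensional root finding; ``a`` and
    lure weights are untouched.  Targets must lie strictly in (0, 1).
    """
    new_b = dict(params.b)
    for item_id, target in target_rates.items():
        if not 0.0 < target < 1.0:
            raise ValueError(
                f"item {item_id!r}: target rate {target} outside (0, 1)"
            )
        if item_id not in params.a:
            raise KeyError(f"target references unknown item {item_id!r}")
        a = params.a[item_id]
        try:
            root = brentq(
                lambda b: marginal_correct_rate(a, b) - target,
                -50.0,
                50.0,
                xtol=1e-12,
                rtol=8.9e-16,
            )
        except ValueError as exc:  # pragma: no cover - requires absurd target
            raise RuntimeError(
                f"calibration did not converge for item {item_id!r}"
            ) from exc
        new_b[item_id] = float(root)
    return replace(params, b=new_b)


# ---------------------------------------------------------------------------
# Default item bank
# ---------------------------------------------------------------------------

# (item_id, k options, target marginal accuracy, lure weight, discrimination)
# CRT: open-numeric, represented categorically; high lure weight because the
# intuitive wrong answer dominates errors.
_CRT_DESIGN = [
    ("crt_bat_ball", 0.25, 0.85, 1.3),
    ("crt_lily_pads", 0.30, 0.85, 1.3),
    ("crt_widgets", 0.33, 0.85, 1.3),
    ("crt_students", 0.39, 0.85, 1.3),
]

# Accepted free-text forms for the open-numeric CRT stand-in items.
_CRT_ACCEPTED = {
    "crt_bat_ball": {
        "correct": (0.05, "5 cents", "5c"),
        "lure": (0.10, "10 cents", "10c"),
    },
    "crt_lily_pads": {
        "correct": (47, "47 days"),
        "lure": (24, "24 days"),
    },
    "crt_widgets": {
        "correct": (5, "5 minutes", "5 min"),
        "lure": (100, "100 minutes", "100 min"),
    },
    "crt_students": {
        "correct": (29, "29 students"),
        "lure": (30, "30 students"),
    },
}

# RSPM: 8-option matrices, difficulty increasing through the set, modest lure
# pull so the correct option stays modal on every item.
_RSPM_TARGETS = [0.85, 0.78, 0.70, 0.62, 0.53, 0.45, 0.36, 0.28, 0.19]

# HBT: one item per rational-thinking construct.  Items flagged lure-modal
# (sample size accounting, covariation detection, and more weakly
# methodological reasoning) get a low accuracy and a high lure weight so the
# full-pool modal answer is the lure; on every other item the correct option
# is modal.
_HBT_DESIGN = [
    # (construct, k, target, lure_weight)
    ("methodological_reasoning", 4, 0.32, 0.75),
    ("sample_size_accounting", 3, 0.26, 0.90),
    ("probability_matching", 3, 0.48, 0.40),
    ("covariation_detection", 4, 0.18, 0.95),
    ("regression_to_mean", 5, 0.36, 0.25),
    ("probabilistic_reasoning", 4, 0.52, 0.40),
    ("gamblers_fallacy", 3, 0.62, 0.50),
    ("causal_base_rate", 4, 0.52, 0.50),
    ("denominator_neglect", 3, 0.37, 0.55),
]

# SRT: binary valid/invalid judgements.  Incongruent (belief-bias) items are
# all below 0.5 accuracy, hence all lure-modal in the full pool; congruent
# items are easy.  Incongruent items carry the highest discrimination: belief
# bias is what the latent reflection trait most strongly protects against,
# which is also what lets a CRT-screened subpool flip their modal answer.
_SRT_DESIGN = [
    ("srt_congruent_1", True, "valid", 0.90, 0.8),
    ("srt_congruent_2", True, "invalid", 0.91, 0.8),
    ("srt_congruent_3", True, "valid", 0.92, 0.8),
    ("srt_congruent_4", True, "invalid", 0.93, 0.8),
    ("srt_incongruent_1", False, "invalid", 0.30, 2.2),
    ("srt_incongruent_2", False, "valid", 0.34, 2.2),
    ("srt_incongruent_3", False, "invalid", 0.39, 2.2),
    ("srt_incongruent_4", False, "valid", 0.42, 2.2),
]

_OPTION_LETTERS = "ABCDEFGH"


def default_item_bank() -> list[ItemSpec]:
    """The default 30-item bank: 4 CRT, 9 RSPM, 9 HBT, 8 SRT (4+4).

    Item texts are copyrighted; items here are structural stand-ins keyed by
    construct name, with option counts and lure placement chosen to mirror
    the published response structure.
    """
    bank: list[ItemSpec] = []
    for item_id, _, _, _ in _CRT_DESIGN:
        bank.append(
            ItemSpec(
                item_id=item_id,
                subtest="CRT",
                options=("correct", "lure", "other"),
                correct="correct",
                lure="lure",
                accepted_answers=_CRT_ACCEPTED[item_id],
            )
        )
    for i, _ in enumerate(_RSPM_TARGETS, start=1):
        options = tuple(_OPTION_LETTERS)
        bank.append(
            ItemSpec(
                item_id=f"rspm_{i}",
                subtest="RSPM",
                options=options,
                # vary correct/lure placement across items
                correct=options[(i - 1) % 8],
                lure=options[i % 8],
            )
        )
    for construct, k, _, _ in _HBT_DESIGN:
        options = tuple(_OPTION_LETTERS[:k])
        bank.append(
            ItemSpec(
                item_id=f"hbt_{construct}",
                subtest="HBT",
                options=options,
                correct=options[0],
                lure=options[1],
            )
        )
    for item_id, congruent, correct, _, _ in _SRT_DESIGN:
        options = ("valid", "invalid")
        bank.append(
            ItemSpec(
                item_id=item_id,
                subtest="SRT",
                options=options,
                correct=correct,
                lure=options[0] if correct == options[1] else options[1],
                congruent=congruent,
            )
        )
    return bank


def default_target_rates() -> dict[str, float]:
    """Per-item marginal accuracies the default pool is calibrated to.

    Chosen so expected subtest totals match the study-scale anchors:
    CRT 1.27/4, RSPM 4.76/9, HBT 3.63/9, SRT-incongruent 1.45/4,
    SRT-congruent 3.66/4.
    """
    rates: dict[str, float] = {}
    for item_id, target, _, _ in _CRT_DESIGN:
        rates[item_id] = target
    for i, target in enumerate(_RSPM_TARGETS, start=1):
        rates[f"rspm_{i}"] = target
    for construct, _, target, _ in _HBT_DESIGN:
        rates[f"hbt_{construct}"] = target
    for item_id, _, _, target, _ in _SRT_DESIGN:
        rates[item_id] = target
    return rates


def _raw_default_params() -> TraitModelParams:
    a: dict[str, float] = {}
    lw: dict[str, float] = {}
    for item_id, _, lam, disc in _CRT_DESIGN:
        a[item_id] = disc
        lw[item_id] = lam
    for i in range(1, 10):
        a[f"rspm_{i}"] = 1.0
        lw[f"rspm_{i}"] = 0.2
    for construct, _, _, lam in _HBT_DESIGN:
        a[f"hbt_{construct}"] = 0.65
        lw[f"hbt_{construct}"] = lam
    for item_id, _, _, _, disc in _SRT_DESIGN:
        a[item_id] = disc
        lw[item_id] = 1.0
    b = {item_id: 0.0 for item_id in a}
    return TraitModelParams(a=a, b=b, lure_weight=lw)


def default_params(bank: Sequence[ItemSpec] | None = None) -> TraitModelParams:
    """Default trait-model parameters, difficulty-calibrated to the targets."""
    params = calibrate_difficulties(_raw_default_params(), default_target_rates())
    if bank is not None:
        params.validate_against(bank)
    return params


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_pool(spec: PoolSpec) -> pd.DataFrame:
    """Draw one synthetic worker pool as a response matrix.

    Returns a workers x items DataFrame of chosen option labels (the
    ResponseMatrix): index are worker ids, columns item ids, in bank order.
    Bit-reproducible given ``spec.seed``.
    """
    params = spec.resolved_params()
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_workers
    theta = rng.standard_normal(n)

    width = max(3, len(str(n)))
    worker_ids = [f"w{i:0{width}d}" for i in range(1, n + 1)]

    data: dict[str, np.ndarray] = {}
    for it in spec.items:
        a = params.a[it.item_id]
        b = params.b[it.item_id]
        lam = params.lure_weight[it.item_id]
        p_correct = expit(a * theta + b)
        u = rng.random(n)
        v = rng.random(n)
        w = rng.random(n)

        correct = u < p_correct
        answers = np.empty(n, dtype=object)
        answers[correct] = it.correct
        wrong = ~correct
        if it.lure is not None:
            to_lure = wrong & (v < lam)
            answers[to_lure] = it.lure
            rest = wrong & ~to_lure
        else:
            rest = wrong
        distractors = it.distractors
        if rest.any():
            if len(distractors) == 0:
                # no non-lure distractor exists; all incorrect mass is lure
                answers[rest] = it.lure
            else:
                idx = np.floor(w[rest] * len(distractors)).astype(int)
                idx = np.clip(idx, 0, len(distractors) - 1)
                answers[rest] = np.asarray(distractors, dtype=object)[idx]
        data[it.item_id] = answers

    return pd.DataFrame(data, index=pd.Index(worker_ids, name="worker_id"))


def sample_demographics(n_workers: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic worker covariates for the regression layer.

    Age, gender and tertiary-education indicators with marginals matching
    the study pool (mean age ~48.6, SD ~15.4; 47% female; 42% with a
    completed university degree), drawn independently of the reasoning
    trait.  Index aligns with :func:`sample_pool` worker ids.
    """
    rng = np.random.default_rng([seed, 1])
    age = np.clip(np.round(rng.normal(48.61, 15.41, n_workers)), 18, 90)
    female = (rng.random(n_workers) < 0.47).astype(int)
    tertiary = (rng.random(n_workers) < 0.42).astype(int)
    width = max(3, len(str(n_workers)))
    worker_ids = [f"w{i:0{width}d}" for i in range(1, n_workers + 1)]
    return pd.DataFrame(
        {"age": age, "female": female, "tertiary_education": tertiary},
        index=pd.Index(worker_ids, name="worker_id"),
    )


# ---------------------------------------------------------------------------
# Parameter (de)serialisation
# ---------------------------------------------------------------------------


def params_to_yaml(params: TraitModelParams, path) -> None:
    doc = {
        "a": {k: float(v) for k, v in params.a.items()},
        "b": {k: float(v) for k, v in params.b.items()},
        "lure_weight": {k: float(v) for k, v in params.lure_weight.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def params_from_yaml(path) -> TraitModelParams:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return TraitModelParams(
        a=doc["a"], b=doc["b"], lure_weight=doc["lure_weight"]
    )
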