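"""Test items and answer keys.

An :class:`ItemSpec` describes one question of the 30-item reasoning
challenge: which subtest it belongs to (CRT, RSPM, HBT or SRT), its response
options, the correct option, and — where an intuitively appealing wrong
answer exists — the *lure* option that can become modal in an unscreened
worker pool.  SRT items additionally carry a congruence flag: incongruent
items cross the believability of the conclusion with its logical validity
and index belief bias.

CRT items are open-ended numeric questions.  They are represented here with
the canonical categorical labels ``correct`` / ``lure`` / ``other`` plus an
``accepted_answers`` mapping used by :mod:`crowdsolve.cli_io` to normalise
free-text answers onto those labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

SUBTESTS = ("CRT", "RSPM", "HBT", "SRT")

#: Subtest totals used throughout: SRT is split by congruence.
SCALE_COLUMNS = ("CRT", "RSPM", "HBT", "SRT_congruent", "SRT_incongruent")


@dataclass(frozen=True)
class ItemSpec:
    """One test item of the reasoning challenge.

    Parameters
    ----------
    item_id:
        Unique identifier, e.g. ``"hbt_covariation_detection"``.
    subtest:
        One of ``CRT``, ``RSPM``, ``HBT``, ``SRT``.
    options:
        Ordered option labels.  For open-numeric CRT items these are the
        canonical categorical labels.
    correct:
        The correct option label (must be in ``options``).
    lure:
        The intuitively appealing incorrect option, if the item has one.
    congruent:
        SRT only — ``True`` for congruent items (believability agrees with
        logical validity), ``False`` for incongruent (belief-bias) items.
    accepted_answers:
        Open-numeric items only — maps an option label to the set of raw
        answers (numbers or literal strings) that count as that label.
    """

    item_id: str
    subtest: str
    options: tuple[str, ...]
    correct: str
    lure: str | None = None
    congruent: bool | None = None
    accepted_answers: Mapping[str, tuple] | None = field(default=None, hash=False)

    def __post_init__(self) -> None:
        if self.subtest not in SUBTESTS:
            raise ValueError(
                f"item {self.item_id!r}: unknown subtest {self.subtest!r}"
            )
        if len(self.options) < 2:
            raise ValueError(f"item {self.item_id!r}: needs at least 2 options")
        if len(set(self.options)) != len(self.options):
            raise ValueError(f"item {self.item_id!r}: duplicate option labels")
        if self.correct not in self.options:
            raise ValueError(
                f"item {self.item_id!r}: correct option {self.correct!r} "
                "not among options"
            )
        if self.lure is not None:
            if self.lure not in self.options:
                raise ValueError(
                    f"item {self.item_id!r}: lure {self.lure!r} not among options"
                )
            if self.lure == self.correct:
                raise ValueError(
                    f"item {self.item_id!r}: lure equals the correct option"
                )
        if (self.congruent is not None) != (self.subtest == "SRT"):
            raise ValueError(
                f"item {self.item_id!r}: congruent flag is set iff subtest is SRT"
            )

    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def distractors(self) -> tuple[str, ...]:
        """Incorrect options other than the lure."""
        return tuple(
            o for o in self.options if o != self.correct and o != self.lure
        )

    @property
    def scale(self) -> str:
        """Scoring scale the item counts toward (SRT split by congruence)."""
        if self.subtest != "SRT":
            return self.subtest
        return "SRT_congruent" if self.congruent else "SRT_incongruent"


def item_by_id(bank: Sequence[ItemSpec], item_id: str) -> ItemSpec:
    for item in bank:
        if item.item_id == item_id:
            return item
    raise KeyError(f"unknown item {item_id!r}")


def items_to_json(bank: Sequence[ItemSpec], path) -> None:
    """Write an answer key / item bank as JSON."""
    records = []
    for it in bank:
        rec: dict = {
            "item_id": it.item_id,
            "subtest": it.subtest,
            "options": list(it.options),
            "correct": it.correct,
        }
        if it.lure is not None:
            rec["lure"] = it.lure
        if it.congruent is not None:
            rec["congruent"] = it.congruent
        if it.accepted_answers is not None:
            rec["accepted_answers"] = {
                k: list(v) for k, v in it.accepted_answers.items()
            }
        records.append(rec)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=2)
        fh.write("\n")


def items_from_json(path) -> list[ItemSpec]:
    """Read an answer key / item bank written by :func:`items_to_json`."""
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    bank = []
    for rec in records:
        accepted = rec.get("accepted_answers")
        bank.append(
            ItemSpec(
                item_id=rec["item_id"],
                subtest=rec["subtest"],
                options=tuple(rec["options"]),
                correct=rec["correct"],
                lure=rec.get("lure"),
                congruent=rec.get("congruent"),
                accepted_answers=(
                    {k: tuple(v) for k, v in accepted.items()}
                    if accepted is not None
                    else None
                ),
            )
        )
    return bank
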