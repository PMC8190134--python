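"""Questionnaire-based fall-risk labelling.

A participant answers three items: whether they fell in the last six months,
how many times, and whether they fear falling.  A :class:`RiskRule` is a
decision table over (fall-count band, fear) cells; the default rule is
monotone (more falls, or adding fear, never lowers the risk) and labels
high risk for two or more falls, or one fall combined with fear of falling.
The exact published cell assignments are not recoverable, so the rule is a
first-class configurable object rather than a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from gaitfall.errors import ParameterError

HIGH, LOW = 1, 0

#: fall-count bands: 0 falls, exactly 1 fall, 2+ falls
BANDS = (0, 1, 2)


@dataclass(frozen=True)
class FallQuestionnaire:
    fell_6mo: bool
    n_falls_6mo: int
    fear_of_falling: bool

    def __post_init__(self) -> None:
        if self.n_falls_6mo < 0:
            raise ParameterError("n_falls_6mo must be non-negative")
        if self.fell_6mo != (self.n_falls_6mo > 0):
            raise ParameterError("fell_6mo must equal (n_falls_6mo > 0)")


@dataclass(frozen=True)
class RiskRule:
    """Decision table: ``cells[(band, fear)] -> HIGH | LOW`` over the six
    (band, fear) combinations, band = min(n_falls, 2)."""

    cells: dict[tuple[int, bool], int]

    def __post_init__(self) -> None:
        expected = {(b, f) for b in BANDS for f in (False, True)}
        if set(self.cells) != expected:
            raise ParameterError("rule must define all six (band, fear) cells")
        if not all(v in (HIGH, LOW) for v in self.cells.values()):
            raise ParameterError("rule cells must map to HIGH (1) or LOW (0)")

    def label(self, band: int, fear: bool) -> int:
        return self.cells[(band, fear)]

    def cells_for(self, label: int) -> list[tuple[int, bool]]:
        return sorted(k for k, v in self.cells.items() if v == label)


def default_rule() -> RiskRule:
    """High risk for >=2 falls, or exactly 1 fall with fear of falling."""
    return RiskRule({
        (0, False): LOW, (0, True): LOW,
        (1, False): LOW, (1, True): HIGH,
        (2, False): HIGH, (2, True): HIGH,
    })


def classify_fall_risk(q: FallQuestionnaire, rule: RiskRule | None = None) -> int:
    """Label a questionnaire: returns 1 (high risk) or 0 (low risk)."""
    rule = rule if rule is not None else default_rule()
    band = min(q.n_falls_6mo, 2)
    return rule.label(band, q.fear_of_falling)


def _dominating_pairs() -> Iterator[tuple[tuple[int, bool], tuple[int, bool]]]:
    """All ordered cell pairs (a, b) with a <= b componentwise, a != b."""
    cells = [(b, f) for b in BANDS for f in (False, True)]
    for a in cells:
        for b in cells:
            if a != b and a[0] <= b[0] and a[1] <= b[1]:
                yield a, b


def validate_rule(rule: RiskRule) -> list[tuple[tuple[int, bool], tuple[int, bool]]]:
    """Exhaustively check monotonicity; returns the list of violating cell
    pairs ((lower cell, higher cell) with label high -> low). Empty = ok."""
    return [(a, b) for a, b in _dominating_pairs()
            if rule.label(*a) == HIGH and rule.label(*b) == LOW]


def sample_questionnaire(label: int, rule: RiskRule,
                         rng: np.random.Generator) -> FallQuestionnaire:
    """Draw a questionnaire that ``classify_fall_risk`` maps back to ``label``,
    uniformly over the decision-table cells carrying that label."""
    cells = rule.cells_for(label)
    if not cells:
        raise ParameterError(f"rule has no cell with label {label}")
    band, fear = cells[rng.integers(len(cells))]
    n_falls = int(band) if band < 2 else int(rng.integers(2, 5))
    return FallQuestionnaire(fell_6mo=n_falls > 0, n_falls_6mo=n_falls,
                             fear_of_falling=bool(fear))


def rule_to_dict(rule: RiskRule) -> dict:
    """Serializable form: {'cells': [{'band':, 'fear':, 'label':}, ...]}."""
    return {"cells": [{"band": b, "fear": f, "label": v}
                      for (b, f), v in sorted(rule.cells.items())]}


def rule_from_dict(data: dict) -> RiskRule:
    cells = {(int(c["band"]), bool(c["fear"])): int(c["label"])
             for c in data["cells"]}
    return RiskRule(cells)
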