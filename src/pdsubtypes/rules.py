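"""Conjunctive subtype rules: (feature, <=/>, threshold) conditions ANDed together.

A subtype rule is the path of a decision-tree leaf read back from the root:
every condition must hold for a patient to belong to the subtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordinal labels of the 0-4 MDS-UPDRS rating scale, used for display.
ORDINAL_LABELS = ("Normal", "Slight", "Mild", "Moderate", "Severe")

LE = "<="
GT = ">"


@dataclass(frozen=True)
class RuleCondition:
    """One atomic condition, e.g. ``NP3GAIT <= 1.5``."""

    feature: str
    operator: str  # "<=" or ">"
    threshold: float

    def __post_init__(self) -> None:
        if self.operator not in (LE, GT):
            raise ValueError(f"operator must be '<=' or '>', got {self.operator!r}")

    def evaluate(self, values: np.ndarray | pd.Series) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.operator == LE:
            return values <= self.threshold
        return values > self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.operator} {self.threshold:g}"


@dataclass
class SubtypeRule:
    """A candidate subtype: a conjunction of conditions plus bookkeeping.

    Attributes
    ----------
    rule_id : int
        Stable identifier (leaf id in the source tree).
    conditions : list of RuleCondition
        Simplified path conditions: at most one lower and one upper bound
        per feature.
    depth : int
        Raw root-to-leaf path length (before simplification).
    member_ids : frozenset
        Unique training patients in the leaf.
    unique_counts : tuple (n_early, n_late)
        Class composition of the members, counted over unique patients.
    gini : float
        Gini impurity of ``unique_counts``.
    category : str
        ``"early"``, ``"late"`` or ``"mixed"``.
    name : str
        Display name: ``E``/``L``/``M`` prefix plus ordinal, e.g. ``"L2"``.
    """

    rule_id: int
    conditions: list[RuleCondition]
    depth: int = 0
    member_ids: frozenset = frozenset()
    unique_counts: tuple[int, int] = (0, 0)
    gini: float = 0.0
    category: str = ""
    name: str = ""

    def matches(self, frame: pd.DataFrame) -> np.ndarray:
        """Boolean mask of rows satisfying every condition."""
        mask = np.ones(len(frame), dtype=bool)
        for cond in self.conditions:
            if cond.feature not in frame.columns:
                raise KeyError(
                    f"rule {self.name or self.rule_id} references feature "
                    f"{cond.feature!r} absent from the cohort"
                )
            values = frame[cond.feature]
            mask &= cond.evaluate(values)
        return mask

    def describe(self, ordinal_features: set[str] | None = None) -> str:
        """Human-readable one-liner; ordinal thresholds get scale labels."""
        parts = []
        for cond in self.conditions:
            text = str(cond)
            if ordinal_features and cond.feature in ordinal_features:
                level = int(np.floor(cond.threshold))
                if 0 <= level < len(ORDINAL_LABELS):
                    text += f" ({ORDINAL_LABELS[level]})"
            parts.append(text)
        return " AND ".join(parts) if parts else "(all patients)"


def apply_rule(rule: SubtypeRule, cohort_frame: pd.DataFrame) -> list:
    """Patient ids of rows satisfying all of the rule's conditions.

    An empty condition list matches every patient; contradictory conditions
    match none. Raises ``KeyError`` naming any feature the cohort lacks.
    """
    mask = rule.matches(cohort_frame)
    return cohort_frame.loc[mask, "patient_id"].tolist()


def simplify_conditions(conditions: list[RuleCondition]) -> list[RuleCondition]:
    """Keep only the tightest upper (``<=``) and lower (``>``) bound per feature.

    Order of first appearance of each feature is preserved.
    """
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    order: list[str] = []
    for cond in conditions:
        if cond.feature not in order:
            order.append(cond.feature)
        if cond.operator == LE:
            prev = upper.get(cond.feature)
            upper[cond.feature] = cond.threshold if prev is None else min(prev, cond.threshold)
        else:
            prev = lower.get(cond.feature)
            lower[cond.feature] = cond.threshold if prev is None else max(prev, cond.threshold)
    out: list[RuleCondition] = []
    for feat in order:
        if feat in lower:
            out.append(RuleCondition(feat, GT, lower[feat]))
        if feat in upper:
            out.append(RuleCondition(feat, LE, upper[feat]))
    return out
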