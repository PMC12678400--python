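"""Leaf-to-subtype extraction and the three-stage filtering criteria.

Each leaf of the fitted onset tree is a candidate subtype: the conjunction
of conditions along its root-to-leaf path. Candidates are categorized by
their unique-patient class composition (Gini impurity <= 0.4 means skewed
toward one onset class, > 0.4 mixed) and then filtered:

* Criterion 1 (size): at least 10 unique training patients; on oversampled
  rows this scales to ceil(n_major / n_minor * 10) for minority-class leaves.
* Criterion 2 (external match): rule matches at least 5% of the external
  cohort's same-onset class (the whole cohort for mixed candidates).
* Criterion 3 (precision, early/late only): external precision above the
  class prior of the external cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EOPD, LOPD
from .rules import RuleCondition, SubtypeRule, apply_rule, simplify_conditions
from .tree import OnsetTreeClassifier, gini_impurity

CATEGORY_GINI_CUTOFF = 0.4
CATEGORY_PREFIX = {"early": "E", "late": "L", "mixed": "M"}


def categorize_subtype(unique_counts: tuple[int, int]) -> str:
    """``early``/``late`` when sufficiently skewed (Gini <= 0.4), else ``mixed``.

    An exact tie has Gini 0.5 and therefore lands in ``mixed`` (no majority).
    """
    n_early, n_late = unique_counts
    if gini_impurity(unique_counts) > CATEGORY_GINI_CUTOFF:
        return "mixed"
    return "late" if n_late > n_early else "early"


def extract_candidate_subtypes(model: OnsetTreeClassifier, train: pd.DataFrame,
                               label_col: str = "onset_label") -> list[SubtypeRule]:
    """One conjunction-of-conditions rule per leaf of a fitted tree.

    Path conditions are simplified to the tightest lower/upper bound per
    feature; members and class counts are computed over *unique* training
    patients (oversampling duplicates collapse). Names are assigned after
    categorization, numbered in left-to-right leaf order within each
    category (E1, E2, ..., L1, ..., M1, ...).
    """
    features = list(model.feature_names_in_)
    leaf_of_row = model.apply(train[features])
    rules: list[SubtypeRule] = []
    for leaf in model.leaves_:  # preorder build = left-to-right leaf order
        raw_path = model.decision_path_conditions(leaf.node_id)
        conditions = simplify_conditions(
            [RuleCondition(f, op, t) for f, op, t in raw_path])
        members = train.loc[leaf_of_row == leaf.node_id]
        unique = members.drop_duplicates("patient_id")
        counts = (int((unique[label_col] == EOPD).sum()),
                  int((unique[label_col] == LOPD).sum()))
        rule = SubtypeRule(
            rule_id=leaf.node_id,
            conditions=conditions,
            depth=len(raw_path),
            member_ids=frozenset(unique["patient_id"]),
            unique_counts=counts,
            gini=gini_impurity(counts) if sum(counts) else 0.0,
            category=categorize_subtype(counts) if sum(counts) else "mixed",
        )
        rules.append(rule)
    numbering = {"early": 0, "late": 0, "mixed": 0}
    for rule in rules:
        numbering[rule.category] += 1
        rule.name = f"{CATEGORY_PREFIX[rule.category]}{numbering[rule.category]}"
    return rules


# ------------------------------------------------------------- criterion 1

def criteria1_size(rule: SubtypeRule, min_unique: int = 10) -> dict:
    """Pass iff the rule holds at least ``min_unique`` unique patients."""
    n = len(rule.member_ids)
    return {"n_unique": n, "threshold": min_unique, "pass": n >= min_unique}


def oversampled_min_leaf(n_major: int, n_minor: int, base: int = 10
                         ) -> tuple[float, int]:
    """Row-count leaf threshold equivalent to ``base`` unique minority patients.

    After oversampling, every minority patient appears n_major/n_minor times
    in expectation, so ``base`` unique patients correspond to
    ``n_major / n_minor * base`` rows. Returns the real value and its
    ceiling (the enforced row threshold).
    """
    if n_minor <= 0:
        raise ValueError("n_minor must be positive")
    exact = n_major / n_minor * base
    return exact, math.ceil(exact)


# ------------------------------------------------------------- criterion 2

def criteria2_threshold(category: str, n_eopd: int, n_lopd: int,
                        fraction: float = 0.05) -> int:
    """Minimum external matches: ceil(fraction x relevant class size)."""
    size = {"early": n_eopd, "late": n_lopd, "mixed": n_eopd + n_lopd}[category]
    return math.ceil(fraction * size)


def criteria2_from_counts(category: str, matches: int, n_eopd: int, n_lopd: int,
                          fraction: float = 0.05) -> dict:
    threshold = criteria2_threshold(category, n_eopd, n_lopd, fraction)
    return {"matches": matches, "threshold": threshold,
            "pass": matches >= threshold}


def criteria2_external(rule: SubtypeRule, external: pd.DataFrame,
                       fraction: float = 0.05,
                       label_col: str = "onset_label") -> dict:
    """Match the rule against a labeled external cohort and test criterion 2.

    Early (late) candidates count matches among external EOPD (LOPD)
    patients only; mixed candidates count matches in the full cohort.
    """
    if len(external) == 0:
        raise ValueError("external cohort is empty")
    matched = rule.matches(external)
    labels = external[label_col].to_numpy()
    tp_early = int((matched & (labels == EOPD)).sum())
    tp_late = int((matched & (labels == LOPD)).sum())
    n_eopd = int((labels == EOPD).sum())
    n_lopd = int((labels == LOPD).sum())
    matches = {"early": tp_early, "late": tp_late,
               "mixed": tp_early + tp_late}[rule.category]
    out = criteria2_from_counts(rule.category, matches, n_eopd, n_lopd, fraction)
    out.update({"eopd_matches": tp_early, "lopd_matches": tp_late,
                "n_eopd": n_eopd, "n_lopd": n_lopd})
    return out


# ------------------------------------------------------------- criterion 3

def subtype_precision(tp: int, fp: int) -> float:
    """Own-class external matches over all external matches."""
    if tp + fp == 0:
        raise ZeroDivisionError("no external matches")
    return tp / (tp + fp)


def criteria3(category: str, tp: int, fp: int, n_eopd: int, n_lopd: int) -> dict:
    """Precision above the external class prior; mixed candidates are exempt."""
    if category == "mixed":
        return {"applicable": False, "pass": True,
                "precision": None, "threshold": None}
    own = n_eopd if category == "early" else n_lopd
    threshold = own / (n_eopd + n_lopd)
    if tp + fp == 0:
        return {"applicable": True, "pass": False, "precision": 0.0,
                "threshold": threshold, "reason": "no external matches"}
    precision = subtype_precision(tp, fp)
    return {"applicable": True, "pass": precision > threshold,
            "precision": precision, "threshold": threshold}


# ------------------------------------------------------------ the pipeline

@dataclass
class FilterReport:
    """Per-rule criteria outcomes plus the surviving final subtypes."""

    rows: list[dict] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    def match_table(self) -> pd.DataFrame:
        """External-match summary: per-candidate true/false positive counts
        and percentages against the relevant external class sizes."""
        records = []
        for row in self.rows:
            rec = {"subtype": row["name"], "category": row["category"],
                   "tree_depth": row.get("depth"),
                   "true_positive": row["tp"], "overall_positives": row["n_own"],
                   "true_positive_pct": round(100 * row["tp"] / row["n_own"], 1)}
            if row["category"] != "mixed":
                rec["false_positive"] = row["fp"]
                rec["overall_negatives"] = row["n_other"]
                rec["false_positive_pct"] = round(100 * row["fp"] / row["n_other"], 1)
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def precision_table(self) -> pd.DataFrame:
        """Precision filtering summary for the early/late survivors of
        criterion 2."""
        records = []
        for row in self.rows:
            c3 = row["criteria3"]
            if not c3.get("applicable") or not row["criteria2"]["pass"]:
                continue
            records.append({
                "subtype": row["name"],
                "eopd_matches": row["eopd_matches"],
                "lopd_matches": row["lopd_matches"],
                "precision": round(c3["precision"], 3) if c3["precision"] is not None else None,
                "precision_threshold": round(c3["threshold"], 3),
                "pass": c3["pass"],
            })
        return pd.DataFrame.from_records(records)


def _assemble_row(name: str, category: str, depth: int | None,
                  n_unique: int | None, c1: dict,
                  eopd_matches: int, lopd_matches: int,
                  n_eopd: int, n_lopd: int, fraction: float) -> dict:
    if category == "early":
        tp, fp, n_own, n_other = eopd_matches, lopd_matches, n_eopd, n_lopd
    elif category == "late":
        tp, fp, n_own, n_other = lopd_matches, eopd_matches, n_lopd, n_eopd
    else:
        tp, fp = eopd_matches + lopd_matches, 0
        n_own, n_other = n_eopd + n_lopd, 0
    c2 = criteria2_from_counts(category, tp, n_eopd, n_lopd, fraction)
    c3 = criteria3(category, tp, fp, n_eopd, n_lopd)
    final = c1["pass"] and c2["pass"] and c3["pass"]
    return {"name": name, "category": category, "depth": depth,
            "n_unique": n_unique, "eopd_matches": eopd_matches,
            "lopd_matches": lopd_matches, "tp": tp, "fp": fp,
            "n_own": n_own, "n_other": n_other,
            "criteria1": c1, "criteria2": c2, "criteria3": c3, "pass": final}


def run_filter_pipeline(rules: list[SubtypeRule], external: pd.DataFrame,
                        min_unique: int = 10, fraction: float = 0.05,
                        label_col: str = "onset_label") -> FilterReport:
    """Apply criteria 1-3 to every candidate against a labeled external cohort."""
    if len(external) == 0:
        raise ValueError("external cohort is empty")
    labels = external[label_col].to_numpy()
    n_eopd = int((labels == EOPD).sum())
    n_lopd = int((labels == LOPD).sum())
    report = FilterReport()
    for rule in rules:
        c1 = criteria1_size(rule, min_unique)
        matched = rule.matches(external)
        tp_early = int((matched & (labels == EOPD)).sum())
        tp_late = int((matched & (labels == LOPD)).sum())
        row = _assemble_row(rule.name, rule.category, rule.depth,
                            len(rule.member_ids), c1, tp_early, tp_late,
                            n_eopd, n_lopd, fraction)
        report.rows.append(row)
    report.survivors = [r["name"] for r in report.rows if r["pass"]]
    return report


def filter_from_counts(records: list[dict], n_eopd: int, n_lopd: int,
                       fraction: float = 0.05) -> FilterReport:
    """Replay criteria 2-3 from per-candidate external match counts.

    Each record needs ``name``, ``category``, ``eopd_matches`` and
    ``lopd_matches`` (mixed candidates may give ``matches`` instead).
    Criterion 1 is taken as already satisfied (it concerns training data
    only). Useful for auditing published match tables.
    """
    report = FilterReport()
    c1 = {"n_unique": None, "threshold": None, "pass": True}
    for rec in records:
        category = rec["category"]
        if category == "mixed" and "matches" in rec:
            eopd_m, lopd_m = rec["matches"], 0
        else:
            eopd_m, lopd_m = rec["eopd_matches"], rec["lopd_matches"]
        row = _assemble_row(rec["name"], category, rec.get("depth"), None, c1,
                            eopd_m, lopd_m, n_eopd, n_lopd, fraction)
        report.rows.append(row)
    report.survivors = [r["name"] for r in report.rows if r["pass"]]
    return report
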