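"""Cross-cohort feature mapping.

Rules are learned on one cohort's vocabulary and validated on another, so
features must be renamed (exact matches) or computed (derived matches, e.g.
PD duration as assessment age minus age of onset) before rules transfer.
Name matching is case-sensitive after whitespace trimming: clinical data
dictionaries use exact codes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .cohort import Cohort, FeatureInfo

EXACT = "exact"
DERIVED = "derived"

#: Packaged fixture reproducing the published 80-feature mapping between the
#: training (LRRK2) and validation (MDS) cohort dictionaries.
BUNDLED_MAP = "lrrk2_mds_feature_map.tsv"


@dataclass(frozen=True)
class FeatureMapEntry:
    """One mapping row.

    For ``kind="exact"`` the entry is a pure rename ``source -> target``.
    For ``kind="derived"`` the target column is computed row-wise from the
    ``derivation`` expression over input-cohort features; derived entries
    are one-way (never inverted by the reverse direction).
    """

    source: str
    target: str
    kind: str = EXACT
    derivation: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (EXACT, DERIVED):
            raise ValueError(f"kind must be 'exact' or 'derived', got {self.kind!r}")
        if self.kind == DERIVED and not self.derivation:
            raise ValueError(f"derived entry {self.source!r} needs a derivation")


_DERIVATION_PATTERNS = [
    (re.compile(r"^\s*(\S+)\s+minus\s+(\S+)\s*$", re.IGNORECASE), "sub"),
    (re.compile(r"^\s*product\s+of\s+(\S+)\s+and\s+(\S+)\s*$", re.IGNORECASE), "mul"),
    (re.compile(r"^\s*(\S+)\s+plus\s+(\S+)\s*$", re.IGNORECASE), "add"),
]


def parse_derivation(expression: str) -> tuple[str, str, str]:
    """Split a derivation like ``"A minus B"`` into (op, A, B)."""
    for pattern, op in _DERIVATION_PATTERNS:
        match = pattern.match(expression)
        if match:
            return op, match.group(1), match.group(2)
    raise ValueError(f"cannot parse derivation expression {expression!r}")


def load_feature_map(path: str | Path, *, on_duplicate: str = "error") -> list[FeatureMapEntry]:
    """Parse a TSV feature map with columns source, target, kind, derivation.

    ``on_duplicate`` controls repeated source names: ``"error"`` rejects the
    file, ``"first"`` keeps the first occurrence and warns (the published
    mapping table lists the Hoehn & Yahr item twice).
    """
    entries: list[FeatureMapEntry] = []
    seen: set[str] = set()
    with open(path) as handle:
        lines = handle.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if lineno == 1 and fields[:2] == ["source", "target"]:
            continue
        if len(fields) < 3:
            raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
        source, target, kind = fields[0], fields[1], fields[2]
        derivation = fields[3] if len(fields) > 3 else ""
        if source in seen:
            if on_duplicate == "first":
                warnings.warn(
                    f"duplicate source {source!r} at line {lineno}; keeping the "
                    "first occurrence", stacklevel=2)
                continue
            raise ValueError(f"{path}: duplicate source {source!r} at line {lineno}")
        if kind == DERIVED:
            parse_derivation(derivation)  # fail fast on malformed expressions
        entries.append(FeatureMapEntry(source, target, kind, derivation))
        seen.add(source)
    return entries


def bundled_feature_map(*, on_duplicate: str = "first") -> list[FeatureMapEntry]:
    """The packaged LRRK2 <-> MDS mapping fixture."""
    ref = resources.files("pdsubtypes").joinpath("data", BUNDLED_MAP)
    with resources.as_file(ref) as path:
        return load_feature_map(path, on_duplicate=on_duplicate)


def _derive(frame: pd.DataFrame, entry: FeatureMapEntry) -> pd.Series | None:
    op, a, b = parse_derivation(entry.derivation)
    for name in (a, b):
        if name not in frame.columns:
            return None
    if op == "sub":
        return frame[a] - frame[b]
    if op == "mul":
        return frame[a] * frame[b]
    return frame[a] + frame[b]


def apply_feature_map(
    cohort: Cohort,
    entries: list[FeatureMapEntry],
    direction: str = "forward",
) -> tuple[Cohort, pd.DataFrame]:
    """Harmonize a cohort into the other schema's vocabulary.

    Forward renames ``source -> target`` and computes derived targets from
    the input columns; reverse inverts exact entries only. Entries whose
    inputs are absent from the cohort are skipped with a warning. Derived
    values with missing inputs stay missing (propagated, never imputed
    here). Unmapped clinical features are dropped from the harmonized view
    and returned in the auxiliary table.

    Returns
    -------
    (harmonized, auxiliary)
        The harmonized :class:`Cohort` and a DataFrame of the unmapped
        columns (indexed like the input, patient_id first).
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    frame = cohort.frame.copy()
    rename: dict[str, str] = {}
    derived: dict[str, pd.Series] = {}
    mapped_inputs: set[str] = set()
    for entry in entries:
        if entry.kind == EXACT:
            old, new = (entry.source, entry.target) if direction == "forward" \
                else (entry.target, entry.source)
            if old not in frame.columns:
                warnings.warn(f"skipping map entry {entry.source!r}: column "
                              f"{old!r} not in cohort", stacklevel=2)
                continue
            rename[old] = new
            mapped_inputs.add(old)
        elif direction == "forward":  # derived entries are one-way
            series = _derive(frame, entry)
            if series is None:
                warnings.warn(
                    f"skipping derived entry {entry.target!r}: derivation "
                    f"{entry.derivation!r} references a missing column",
                    stacklevel=2)
                continue
            derived[entry.target] = series
            op, a, b = parse_derivation(entry.derivation)
            mapped_inputs.update((a, b))

    kept_mapped = [c for c in frame.columns
                   if c == "patient_id" or c in rename]
    aux_cols = ["patient_id"] + [c for c in frame.columns
                                 if c != "patient_id" and c not in rename]
    auxiliary = frame[aux_cols].copy()

    harmonized = frame[kept_mapped].rename(columns=rename)
    for name, series in derived.items():
        harmonized[name] = series

    dictionary: dict[str, FeatureInfo] = {}
    for old, new in rename.items():
        if old in cohort.dictionary:
            dictionary[new] = cohort.dictionary[old]
    for name in derived:
        dictionary[name] = FeatureInfo("numeric", float("-inf"), float("inf"))
    return Cohort(frame=harmonized, dictionary=dictionary, planted=cohort.planted), auxiliary
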