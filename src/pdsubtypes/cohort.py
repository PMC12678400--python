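"""Patient cohort container and plain-text I/O.

A :class:`Cohort` couples a patient-level table with a data dictionary
describing each clinical feature (kind, value range, observed missingness).
Cohorts round-trip through CSV plus a sidecar JSON dictionary so that every
artifact of the pipeline stays human-readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Columns that always lead the table, in this order.
RESERVED_COLUMNS = ("patient_id", "ageonset", "assessment_age", "gender")


@dataclass(frozen=True)
class FeatureInfo:
    """Metadata for one clinical feature.

    Parameters
    ----------
    kind : str
        One of ``"ordinal"``, ``"integer"``, ``"binary"`` or ``"numeric"``.
    low, high : float
        Inclusive value range of the feature.
    """

    kind: str
    low: float
    high: float

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass
class Cohort:
    """A patient table plus its data dictionary.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per patient. Always contains ``patient_id``; clinical
        columns follow the reserved demographic columns.
    dictionary : dict of str -> FeatureInfo
        Feature metadata for every non-id column.
    planted : dict of str -> frozenset, optional
        Bookkeeping from the synthetic generator: the patient ids that were
        planted as members of each ground-truth subtype. ``None`` for real
        or loaded cohorts unless the sidecar carries it.
    """

    frame: pd.DataFrame
    dictionary: dict[str, FeatureInfo]
    planted: dict[str, frozenset] | None = None

    def __post_init__(self) -> None:
        if "patient_id" not in self.frame.columns:
            raise ValueError("cohort frame must contain a 'patient_id' column")
        self.frame = self.frame[order_columns(list(self.frame.columns))]

    @property
    def n_patients(self) -> int:
        return len(self.frame)

    @property
    def clinical_features(self) -> list[str]:
        """Feature columns excluding patient_id and the age columns."""
        skip = {"patient_id", "ageonset", "assessment_age"}
        return [c for c in self.frame.columns if c not in skip]

    def missing_fractions(self) -> pd.Series:
        cols = [c for c in self.frame.columns if c != "patient_id"]
        return self.frame[cols].isna().mean()

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the table as CSV and the dictionary as sidecar JSON."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".dict.json")
        missing = self.missing_fractions()
        entries = {
            name: {
                "kind": info.kind,
                "range": [info.low, info.high],
                "pct_missing": round(100.0 * float(missing.get(name, 0.0)), 3),
            }
            for name, info in self.dictionary.items()
        }
        payload: dict = {"features": entries}
        if self.planted is not None:
            payload["planted"] = {k: sorted(v) for k, v in self.planted.items()}
        sidecar.write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "Cohort":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".dict.json")
        payload = json.loads(sidecar.read_text())
        dictionary = {
            name: FeatureInfo(spec["kind"], spec["range"][0], spec["range"][1])
            for name, spec in payload["features"].items()
        }
        planted = None
        if "planted" in payload:
            planted = {k: frozenset(v) for k, v in payload["planted"].items()}
        return cls(frame=frame, dictionary=dictionary, planted=planted)

    def copy(self) -> "Cohort":
        planted = dict(self.planted) if self.planted is not None else None
        return Cohort(self.frame.copy(), dict(self.dictionary), planted)


def order_columns(columns: list[str]) -> list[str]:
    """Reserved demographic columns first, then clinical items in given order."""
    lead = [c for c in RESERVED_COLUMNS if c in columns]
    rest = [c for c in columns if c not in RESERVED_COLUMNS]
    return lead + rest


def feature_matrix(frame: pd.DataFrame, features: list[str]) -> np.ndarray:
    """Float matrix view of the selected feature columns."""
    return frame[features].to_numpy(dtype=float)
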