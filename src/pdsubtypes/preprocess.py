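"""Model-ready preparation of a harmonized cohort.

Assigns early/late onset labels from age of onset, excludes boundary and
juvenile patients, drops unusable features, imputes missing values with
normative values fitted on training data only, splits train/test, and
balances classes by random oversampling of the minority class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Cohort

EOPD, LOPD = 0, 1  # late onset carries the positive label

#: Age-of-onset class boundaries: early onset is 21 < AO < 50, late onset
#: AO > 50; AO = 50 (class boundary) and AO < 22 (juvenile) are excluded.
JUVENILE_MAX_AO = 21
BOUNDARY_AO = 50


@dataclass
class PreprocessConfig:
    """Knobs of the preparation stage (defaults follow the study protocol)."""

    missing_threshold: float = 0.15
    onset_feature_blocklist: tuple[str, ...] = ("ageonset", "assessment_age", "PD_duration", "durat_pd")
    collinearity_threshold: float = 0.999
    test_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_threshold", "collinearity_threshold", "test_fraction"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must be in (0, 1), got {value}")


def assign_onset_labels(cohort: Cohort) -> tuple[Cohort, dict]:
    """Attach a binary onset label and drop excluded patients.

    Returns the labeled cohort (``onset_label`` column, 0 = early, 1 = late)
    and a report of exclusions split into juvenile (AO < 22), boundary
    (AO = 50) and missing-AO groups.
    """
    frame = cohort.frame
    ao = frame["ageonset"]
    missing = ao.isna()
    juvenile = (~missing) & (ao <= JUVENILE_MAX_AO)
    boundary = (~missing) & (ao == BOUNDARY_AO)
    early = (~missing) & (ao > JUVENILE_MAX_AO) & (ao < BOUNDARY_AO)
    late = (~missing) & (ao > BOUNDARY_AO)
    keep = early | late

    labeled = frame.loc[keep].copy()
    labeled["onset_label"] = np.where(late.loc[keep], LOPD, EOPD)
    report = {
        "n_input": len(frame),
        "n_retained": int(keep.sum()),
        "n_early": int(early.sum()),
        "n_late": int(late.sum()),
        "excluded_juvenile": frame.loc[juvenile, "patient_id"].tolist(),
        "excluded_boundary": frame.loc[boundary, "patient_id"].tolist(),
        "excluded_missing_ao": frame.loc[missing, "patient_id"].tolist(),
    }
    out = Cohort(labeled, dict(cohort.dictionary), cohort.planted)
    return out, report


def select_features(cohort: Cohort, config: PreprocessConfig | None = None) -> tuple[Cohort, dict]:
    """Drop unusable features and report every drop with its reason.

    Removes (i) features with more than ``missing_threshold`` missing data,
    (ii) blocklisted onset-derived features (the label is computed from age
    of onset), (iii) one of each pair of collinear features
    (|Pearson r| >= ``collinearity_threshold`` on complete cases; the later
    column in order is dropped).
    """
    config = config or PreprocessConfig()
    frame = cohort.frame
    keep_always = {"patient_id", "onset_label"}
    drops: list[dict] = []
    candidates = [c for c in frame.columns if c not in keep_always]

    surviving: list[str] = []
    for col in candidates:
        if col in config.onset_feature_blocklist:
            drops.append({"feature": col, "reason": "onset-derived (blocklist)"})
            continue
        frac = float(frame[col].isna().mean())
        if frac > config.missing_threshold:
            drops.append({"feature": col, "reason": f"missing fraction {frac:.3f} "
                          f"> {config.missing_threshold}"})
            continue
        surviving.append(col)

    # pairwise collinearity on complete cases; later column dropped
    collinear_dropped: set[str] = set()
    values = frame[surviving].astype(float)
    corr = values.corr()
    for i, a in enumerate(surviving):
        if a in collinear_dropped:
            continue
        for b in surviving[i + 1:]:
            if b in collinear_dropped:
                continue
            r = corr.at[a, b]
            if pd.notna(r) and abs(r) >= config.collinearity_threshold:
                collinear_dropped.add(b)
                drops.append({"feature": b,
                              "reason": f"collinear with {a} (|r| = {abs(r):.4f})"})
    surviving = [c for c in surviving if c not in collinear_dropped]

    if len(surviving) < 2:
        raise ValueError("fewer than 2 features survive selection")
    kept_cols = [c for c in frame.columns if c in keep_always or c in surviving]
    reduced = Cohort(frame[kept_cols].copy(),
                     {k: v for k, v in cohort.dictionary.items() if k in surviving},
                     cohort.planted)
    report = {"n_dropped": len(drops), "dropped": drops, "n_surviving": len(surviving)}
    return reduced, report


class NormativeImputer(BaseEstimator, TransformerMixin):
    """Impute with normative values fitted on training data only.

    Numeric features are filled with the training median, categorical
    (ordinal/binary) features with the training mode; mode ties break to the
    smallest value. Chosen over model-based imputation for interpretability.

    Parameters
    ----------
    kinds : dict of str -> str
        Feature kind per column (``"numeric"`` uses the median, everything
        else the mode). Columns absent from the dict default to the mode.
    """

    def __init__(self, kinds: dict[str, str] | None = None):
        self.kinds = kinds

    def fit(self, X: pd.DataFrame, y=None) -> "NormativeImputer":
        kinds = self.kinds or {}
        values: dict[str, float] = {}
        for col in X.columns:
            if col == "patient_id":
                continue
            series = X[col].dropna()
            if series.empty:
                raise ValueError(f"feature {col!r} is entirely missing in the "
                                 "training data; cannot fit a normative value")
            if kinds.get(col) == "numeric":
                values[col] = float(series.median())
            else:
                counts = series.value_counts()
                top = counts.max()
                values[col] = float(min(counts[counts == top].index))  # tie -> smallest
        self.normative_values_ = values
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col, value in self.normative_values_.items():
            if col in out.columns:
                out[col] = out[col].fillna(value)
        return out


def impute_missing(train: Cohort, *others: Cohort,
                   kinds: dict[str, str] | None = None
                   ) -> tuple[list[Cohort], NormativeImputer]:
    """Fit normative values on ``train`` and apply them to all cohorts."""
    if kinds is None:
        kinds = {name: info.kind for name, info in train.dictionary.items()}
    imputer = NormativeImputer(kinds=kinds).fit(train.frame)
    imputed = []
    for cohort in (train, *others):
        frame = imputer.transform(cohort.frame)
        imputed.append(Cohort(frame, dict(cohort.dictionary), cohort.planted))
    return imputed, imputer


def split_train_test(cohort: Cohort, config: PreprocessConfig | None = None
                     ) -> tuple[Cohort, Cohort]:
    """Seeded random split; train gets floor(n * (1 - test_fraction)) rows."""
    config = config or PreprocessConfig()
    n = cohort.n_patients
    n_train = int(n * (1 - config.test_fraction))
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    frame = cohort.frame
    train = frame.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = frame.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return (Cohort(train, dict(cohort.dictionary), cohort.planted),
            Cohort(test, dict(cohort.dictionary), cohort.planted))


def random_oversample(frame: pd.DataFrame, seed: int = 0,
                      label_col: str = "onset_label") -> pd.DataFrame:
    """Resample the minority class (with replacement) up to the majority count.

    Original rows are all kept, so restricting the result to unique
    patient_ids recovers the input table; added rows keep their source
    patient_id, which keeps unique-patient counts computable downstream.
    """
    counts = frame[label_col].value_counts()
    if len(counts) < 2 or (counts == 0).any():
        raise ValueError("random_oversample needs two non-empty classes")
    majority = counts.max()
    rng = np.random.default_rng(seed)
    parts = [frame]
    for label, count in counts.items():
        deficit = int(majority - count)
        if deficit > 0:
            pool = frame[frame[label_col] == label]
            picks = rng.integers(0, len(pool), size=deficit)
            parts.append(pool.iloc[picks])
    return pd.concat(parts, ignore_index=True)


def minority_duplication_chance(n_major: int, n_minor: int) -> float:
    """Chance a given minority row appears more than once after oversampling.

    With ``n_major - n_minor`` uniform draws over ``n_minor`` rows, the
    expected duplication load per minority row is (n_major - n_minor) /
    n_minor, the study's quoted duplication chance.
    """
    if n_minor <= 0:
        raise ValueError("n_minor must be positive")
    return (n_major - n_minor) / n_minor


def class_counts(frame: pd.DataFrame, label_col: str = "onset_label") -> tuple[int, int]:
    """(n_early, n_late) over unique patients."""
    unique = frame.drop_duplicates("patient_id")
    return (int((unique[label_col] == EOPD).sum()),
            int((unique[label_col] == LOPD).sum()))
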