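"""Post-hoc description of the final subtypes.

Summary demographics per subtype, binary check-sheet positive ratios, the
distinguishable-feature screen (subtype mean deviating from the overall
cohort mean by more than 0.1), and agreement with external clustering
labelings via the unadjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import rand_score


def summarize_subtype(member_ids, frame: pd.DataFrame,
                      mutation_col: str | None = None) -> dict:
    """Demographic summary row for one subtype.

    Means and standard deviations (sample, n-1 convention) of assessment
    age and age of onset; gender counts; PD duration as the difference of
    the two mean ages; optional mutation-carrier ratio. A single-member
    subtype reports sd 0 with a flag.
    """
    members = frame[frame["patient_id"].isin(set(member_ids))]
    if members.empty:
        raise ValueError("subtype has no members in this cohort")
    n = len(members)
    single = n == 1

    def mean_sd(col: str) -> tuple[float, float]:
        values = members[col].dropna()
        mean = float(values.mean())
        sd = 0.0 if len(values) < 2 else float(values.std(ddof=1))
        return mean, sd

    assess_mean, assess_sd = mean_sd("assessment_age")
    onset_mean, onset_sd = mean_sd("ageonset")
    row = {
        "n": n,
        "assessment_age_mean": assess_mean, "assessment_age_sd": assess_sd,
        "ageonset_mean": onset_mean, "ageonset_sd": onset_sd,
        "pd_duration": assess_mean - onset_mean,
        "single_member": single,
    }
    if "gender" in members.columns:
        gender = members["gender"]
        row["n_male"] = int((gender == 1).sum())
        row["n_female"] = int((gender == 0).sum())
    if mutation_col and mutation_col in members.columns:
        row["mutation_carrier_ratio"] = float(members[mutation_col].mean())
    return row


def checksheet_ratios(member_ids, frame: pd.DataFrame, binary_features: list[str],
                      max_missing: float = 0.30) -> pd.Series:
    """Positive ratio per binary check-sheet feature within a subtype.

    Features with ``max_missing`` or more missing data (over the full
    cohort) are excluded. The denominator is the subtype's full patient
    count; missing values count as non-positive.
    """
    kept = [f for f in binary_features
            if float(frame[f].isna().mean()) < max_missing]
    members = frame[frame["patient_id"].isin(set(member_ids))]
    n = len(members)
    if n == 0:
        raise ValueError("subtype has no members in this cohort")
    return pd.Series({f: float((members[f] == 1).sum()) / n for f in kept})


def distinguishable_features(subtype_means: pd.DataFrame, overall_means: pd.Series,
                             delta: float = 0.1, set_fraction: float = 0.5
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """Flag features whose subtype mean deviates from the overall mean.

    Parameters
    ----------
    subtype_means : DataFrame
        Features as rows, subtypes as columns.
    overall_means : Series
        Whole-cohort mean per feature.
    delta : float
        A feature is distinguishable for a subtype when
        ``|subtype mean - overall mean| > delta``.
    set_fraction : float
        A feature distinguishes the subtype *set* when it is flagged for at
        least this fraction of subtypes.

    Returns
    -------
    (flags, set_level)
        Boolean DataFrame of per-subtype flags, and a boolean Series of
        set-level distinguishers.
    """
    aligned = subtype_means.sub(overall_means, axis=0)
    flags = aligned.abs() > delta
    set_level = flags.mean(axis=1) >= set_fraction
    return flags, set_level


def rand_index(labels_a, labels_b) -> float:
    """Unadjusted Rand index: fraction of patient pairs on which two
    partitions agree (placed together in both, or apart in both).

    Label names are arbitrary; unassigned/noise markers simply form their
    own group.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors have different lengths")
    # factorize so string / negative noise labels are accepted uniformly
    a = pd.factorize(labels_a)[0]
    b = pd.factorize(labels_b)[0]
    return float(rand_score(a, b))


def drop_small_clusters(labels: pd.Series, min_size: int = 10,
                        drop_marker: str = "dropped") -> pd.Series:
    """Merge clusters with fewer than ``min_size`` patients into one group."""
    counts = labels.value_counts()
    small = set(counts[counts < min_size].index)
    return labels.where(~labels.isin(small), other=drop_marker)


def cluster_overlap(subtype_members: dict[str, set], cluster_members: dict[str, set],
                    min_overlap: int = 10) -> pd.DataFrame:
    """(subtype, cluster) pairs sharing at least ``min_overlap`` patients."""
    records = []
    for s_name, s_set in subtype_members.items():
        for c_name, c_set in cluster_members.items():
            overlap = len(set(s_set) & set(c_set))
            if overlap >= min_overlap:
                records.append({"subtype": s_name, "cluster": c_name,
                                "n_overlap": overlap})
    return pd.DataFrame.from_records(records,
                                     columns=["subtype", "cluster", "n_overlap"])


def load_cluster_labels(path) -> pd.Series:
    """Read external clustering labels from a two-column CSV
    (patient_id, label)."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("cluster label file needs columns patient_id, label")
    return frame.set_index(frame.columns[0])[frame.columns[1]]


def tidy_feature_values(subtype_members: dict[str, set], frame: pd.DataFrame,
                        features: list[str]) -> pd.DataFrame:
    """Long-format (subtype, patient_id, variable, value) table for plotting."""
    parts = []
    for name, ids in subtype_members.items():
        members = frame[frame["patient_id"].isin(set(ids))]
        melted = members.melt(id_vars="patient_id", value_vars=features,
                              var_name="variable", value_name="value")
        melted.insert(0, "subtype", name)
        parts.append(melted)
    return pd.concat(parts, ignore_index=True)
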