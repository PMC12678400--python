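import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pdsubtypes.cohort import Cohort, FeatureInfo

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_labeled_frame(n_early: int, n_late: int, seed: int = 0,
                       n_features: int = 3) -> pd.DataFrame:
    """Small labeled patient table with random ordinal features."""
    rng = np.random.default_rng(seed)
    n = n_early + n_late
    frame = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "onset_label": [0] * n_early + [1] * n_late,
    })
    for j in range(n_features):
        frame[f"item{j}"] = rng.integers(0, 5, size=n).astype(float)
    return frame


@pytest.fixture
def labeled_frame():
    return make_labeled_frame(12, 20, seed=1)


@pytest.fixture
def tiny_cohort():
    """Six-patient cohort with known ages and two clinical items."""
    frame = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(6)],
        "ageonset": [45.0, 51.0, 60.0, 30.0, 55.0, 48.0],
        "assessment_age": [53.0, 55.0, 68.0, 38.0, 60.0, 56.0],
        "gender": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        "item0": [0.0, 1.0, 2.0, 0.0, 4.0, 1.0],
        "item1": [1.0, 0.0, 0.0, 3.0, 2.0, 0.0],
    })
    dictionary = {
        "ageonset": FeatureInfo("numeric", 0, 120),
        "assessment_age": FeatureInfo("numeric", 0, 120),
        "gender": FeatureInfo("binary", 0, 1),
        "item0": FeatureInfo("ordinal", 0, 4),
        "item1": FeatureInfo("ordinal", 0, 4),
    }
    return Cohort(frame, dictionary)
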