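import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/helpers.py

from radformal import (
    FeatureMatrix,
    FeaturePanel,
    canonical_panel,
    discretize_matrix,
    filter_incomplete_patients,
    fit_discretization,
)
from radformal.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return canonical_panel()


@pytest.fixture(scope="session")
def tiny_panel():
    """Three features spread over the six mandatory classes (others empty)."""
    return FeaturePanel(
        classes={
            "FIRST": ("Mean", "Skewness"),
            "GLCM": ("JointEntropy",),
            "GLDM": (),
            "GLSZM": (),
            "SHAPE": (),
            "GLRLM": (),
        }
    )


def make_matrix(rows):
    """rows: iterable of (patient_id, slice_index, feature_name, value)."""
    return FeatureMatrix(
        pd.DataFrame(rows, columns=["patient_id", "slice_index", "feature_name", "value"])
    )


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A small but fully featured cohort: 8 healthy + 8 MAP, default effect."""
    cfg = CohortConfig(
        n_healthy=8,
        n_map=8,
        healthy_slice_mean=8.0,
        healthy_slice_range=(5, 11),
        map_slice_mean=9.0,
        map_slice_range=(6, 12),
        ctsi_proportions=(0.0, 0.0, 0.0, 1.0),
        seed=7,
    )
    fm, labels = generate_cohort(cfg, panel)
    return fm, labels


@pytest.fixture(scope="session")
def small_discretized(small_cohort, panel):
    fm, labels = small_cohort
    fm, _ = filter_incomplete_patients(fm, panel)
    scheme = fit_discretization(fm, panel)
    return discretize_matrix(fm, scheme), labels, scheme
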