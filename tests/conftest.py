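import numpy as np
import pandas as pd
import pytest

from ppmet.core import FeatureTable
from ppmet.simulate import CohortSpec, EffectSpec, generate_cohort, generate_feature_table


@pytest.fixture(scope="session")
def small_cohort():
    """8 participants, 4/4 split, no subset label — fast fixture."""
    return generate_cohort(
        CohortSpec(n_participants=8, class_sizes=(4, 4), subset_name=None, seed=7)
    )


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """8 participants x 3 meals x 5 times, 12 features (3 responsive)."""
    table, truth = generate_feature_table(
        small_cohort,
        EffectSpec(
            n_features=12, n_responsive=3, n_discriminative=1,
            dose_amplitudes=(0.1, 0.5, 1.0), noise_sd=0.1, missing_rate=0.0, seed=5,
        ),
    )
    return table, truth


def make_table(values: np.ndarray, feature_ids=None, qc_mask=None, **meta_cols) -> FeatureTable:
    """Hand-built FeatureTable for unit fixtures."""
    n = len(values)
    feature_ids = feature_ids or [f"f{j}" for j in range(values.shape[1])]
    idx = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "participant_id": meta_cols.get("participant_id", [f"P{i}" for i in range(n)]),
            "meal": meta_cols.get("meal", ["WC"] * n),
            "time_min": meta_cols.get("time_min", [0] * n),
            "age": meta_cols.get("age", [40.0] * n),
            "bmi": meta_cols.get("bmi", [28.0] * n),
            "batch": meta_cols.get("batch", [1] * n),
            "injection_order": meta_cols.get("injection_order", list(range(n))),
            "is_qc": qc_mask if qc_mask is not None else [False] * n,
        },
        index=idx,
    )
    return FeatureTable(pd.DataFrame(values, index=idx, columns=feature_ids), meta)
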