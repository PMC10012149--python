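"""Imputation, drift correction, CV filter and normalization contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ppmet.core import FeatureTable
from ppmet.preprocess import (
    PreprocessConfig,
    drift_correct_loess,
    impute_knn,
    normalize,
    qc_cv_filter,
)
from ppmet.simulate import EffectSpec, generate_feature_table, generate_qc_injections

from conftest import make_table


class TestImputeKNN:
    def test_complete_table_returned_unchanged(self, small_table):
        table, _ = small_table
        out = impute_knn(table, k=3)
        assert out is table

    def test_k1_copies_nearest_complete_sample(self):
        # 4 samples, 3 features; s3 is missing f2 and is closest to s1
        V = np.array(
            [[1.0, 2.0, 3.0], [10.0, 10.0, 10.0], [5.0, 5.0, 5.0], [1.1, 2.1, np.nan]]
        )
        table = make_table(V)
        out = impute_knn(table, k=1)
        assert out.values.iloc[3, 2] == 3.0

    def test_two_missing_rows_completed_others_bitwise_identical(self):
        rng = np.random.default_rng(0)
        V = rng.normal(size=(10, 5))
        V[2, 1] = np.nan
        V[7, 3] = np.nan
        table = make_table(V.copy())
        out = impute_knn(table, k=3)
        assert not out.values.isna().to_numpy().any()
        complete = [i for i in range(10) if i not in (2, 7)]
        assert np.array_equal(out.values.to_numpy()[complete], V[complete])

    def test_too_few_complete_samples_rejected(self):
        V = np.array([[1.0, np.nan], [np.nan, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="complete"):
            impute_knn(make_table(V), k=2)

    def test_fully_missing_row_rejected(self):
        V = np.array([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
        with pytest.raises(ValueError, match="observed"):
            impute_knn(make_table(V), k=1)


def _drifted_table(drift, noise_sd=0.0, n_features=20, seed=0):
    from ppmet.simulate import CohortSpec, generate_cohort

    cohort = generate_cohort(CohortSpec(n_participants=6, class_sizes=(3, 3), subset_name=None, seed=seed))
    table, _ = generate_feature_table(
        cohort,
        EffectSpec(n_features=n_features, n_responsive=0, n_discriminative=0, missing_rate=0.0, seed=seed),
    )
    return generate_qc_injections(table, n_qc=8, drift=drift, noise_sd=noise_sd, seed=seed)


class TestDriftCorrection:
    def test_flat_qc_is_identity(self):
        table = _drifted_table(drift=0.0)
        out = drift_correct_loess(table)
        assert np.allclose(out.values.to_numpy(), table.values.to_numpy(), rtol=1e-9)

    def test_planted_drift_reduces_qc_cv(self):
        """Multiplicative linear drift: post-correction QC CV must shrink for
        nearly all features."""
        table = _drifted_table(drift=0.004, noise_sd=0.01, n_features=100, seed=3)
        out = drift_correct_loess(table)

        def qc_cv(t):
            qc = t.qc_rows().values.to_numpy()
            return qc.std(axis=0, ddof=1) / qc.mean(axis=0)

        improved = qc_cv(out) < qc_cv(table)
        assert improved.mean() >= 0.95

    def test_single_qc_row_in_batch_rejected(self):
        V = np.ones((4, 2))
        table = make_table(V, qc_mask=[True, False, False, False])
        with pytest.raises(ValueError, match="batch"):
            drift_correct_loess(table)

    def test_class_mean_differences_preserved_for_drift_free_features(self):
        table = _drifted_table(drift=0.0, noise_sd=0.0, n_features=10, seed=5)
        out = drift_correct_loess(table)
        meta = table.study_rows().meta
        cls = meta["ethnicity"]
        for fid in table.feature_ids[:5]:
            before = table.study_rows().values[fid].groupby(cls).mean()
            after = out.study_rows().values[fid].groupby(cls).mean()
            assert np.allclose(before - before.mean(), after - after.mean(), rtol=1e-6)


class TestQCCVFilter:
    def test_cv_at_limit_removed(self):
        # QC values {69, 100, 131}: sd = 31, mean = 100, CV = 0.31 >= 0.30
        qc_vals = np.array([69.0, 100.0, 131.0])
        assert np.isclose(qc_vals.std(ddof=1) / qc_vals.mean(), 0.31)
        V = np.vstack([np.full((2, 1), 50.0), qc_vals[:, None]])
        table = make_table(V, qc_mask=[False, False, True, True, True])
        out, report = qc_cv_filter(table, limit=0.30)
        assert out.feature_ids == []
        assert report.loc[0, "reason"] == "qc_cv_at_or_above_limit"

    def test_identical_qc_values_retained(self):
        V = np.array([[5.0], [5.0], [7.0], [7.0]])
        table = make_table(V, qc_mask=[False, False, True, True])
        out, report = qc_cv_filter(table, limit=0.30)
        assert out.feature_ids == ["f0"]
        assert report.empty

    def test_hand_computed_cv(self):
        V = np.array([[1.0], [90.0], [100.0], [110.0]])
        table = make_table(V, qc_mask=[False, True, True, True])
        out, _ = qc_cv_filter(table, limit=0.30)
        qc = np.array([90.0, 100.0, 110.0])
        assert np.isclose(qc.std(ddof=1) / qc.mean(), 0.10)
        assert out.feature_ids == ["f0"]

    def test_undetected_in_qc_removed(self):
        V = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 0.0], [3.0, 4.0]])
        table = make_table(V, qc_mask=[False, False, True, True])
        out, report = qc_cv_filter(table)
        assert out.feature_ids == ["f0"]
        assert "not detected" in report.loc[0, "reason"]

    def test_no_qc_rows_rejected(self):
        with pytest.raises(ValueError):
            qc_cv_filter(make_table(np.ones((3, 2))))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_never_removes_feature_below_limit(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.lognormal(mean=2.0, sigma=0.5, size=(8, 6))
        table = make_table(V, qc_mask=[False] * 4 + [True] * 4)
        out, _ = qc_cv_filter(table, limit=0.30)
        qc = V[4:]
        cv = qc.std(axis=0, ddof=1) / qc.mean(axis=0)
        below = {f"f{j}" for j in range(6) if cv[j] < 0.30}
        assert below <= set(out.feature_ids)


class TestNormalize:
    def _table(self, n=360, seed=0):
        rng = np.random.default_rng(seed)
        V = np.column_stack(
            [
                rng.lognormal(mean=1.0, sigma=1.0, size=n),  # heavy-tailed
                rng.normal(10.0, 1.0, size=n),               # gaussian
            ]
        )
        return make_table(V, feature_ids=["skewed", "gaussian"])

    def test_output_columns_centred(self):
        out, _ = normalize(self._table())
        assert np.all(np.abs(out.values.sum(axis=0)) < 1e-9)

    def test_lognormal_flagged_gaussian_not(self):
        _, logged = normalize(self._table())
        assert logged == ["skewed"]

    def test_unit_variance_scaling(self):
        out, _ = normalize(self._table(), PreprocessConfig(scaling_mode="unit_variance"))
        assert np.allclose(out.values.std(ddof=1), 1.0)

    def test_idempotent_under_unit_variance(self):
        once, _ = normalize(self._table(), PreprocessConfig(scaling_mode="unit_variance"))
        twice, _ = normalize(once, PreprocessConfig(scaling_mode="unit_variance"))
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-9)

    def test_nonpositive_values_handled_without_nan(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=100) - 0.5  # some negatives, heavy tailed
        table = make_table(x[:, None])
        out, logged = normalize(table)
        assert not out.values.isna().to_numpy().any()

    def test_missing_values_rejected(self):
        V = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError):
            normalize(make_table(V))

    def test_pareto_and_level_modes(self):
        for mode in ("pareto", "level"):
            out, _ = normalize(self._table(), PreprocessConfig(scaling_mode=mode))
            assert np.all(np.abs(out.values.mean(axis=0)) < 1e-9)
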