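"""Peak detection, incremental AUC and the fold-change gate."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ppmet.response import (
    GATE_NOT_SHORTLISTED,
    GATE_REMOVED_LP_ONLY,
    GATE_SHORTLISTED_BOTH,
    GATE_SHORTLISTED_HP_ONLY,
    PeakParams,
    compute_auc_records,
    compute_iauc,
    compute_log2fc,
    detect_peaks,
    gate_features,
)
from ppmet.evaluation import _plain_net_trapezoid

T5 = [0, 30, 60, 120, 240]


class TestDetectPeaks:
    def test_run_of_two_points_excluded(self):
        assert detect_peaks(T5, [0, 1, 1, 0, 0], 0.0) == []

    def test_apex_below_height_fraction_excluded(self):
        # first peak apex = 1.4 = 70% of the series' 0..2 range
        t = [0, 10, 20, 30, 40, 50, 60, 70]
        v = [0, 1.4, 1.4, 1.4, 0, 2.0, 2.0, 2.0]
        kept = detect_peaks(t, v, 0.0, PeakParams(height_fraction=0.75))
        assert len(kept) == 1 and kept[0].apex_value == 2.0

    def test_flat_series_has_no_peaks(self):
        assert detect_peaks(T5, [5.0] * 5, 5.0) == []

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks([0, 30, 20], [1, 2, 3], 0.0)

    def test_min_adjacent_one_keeps_single_points(self):
        kept = detect_peaks(T5, [0, 1, 0, 1, 0], 0.0, PeakParams(min_adjacent_points=1))
        assert len(kept) == 2


class TestComputeIAUC:
    def test_worked_example_210(self):
        net, n = compute_iauc(T5, [0, 1, 2, 1, 0], 0.0)
        assert net == pytest.approx(210.0)
        assert n == 1

    def test_constant_series_zero(self):
        net, n = compute_iauc(T5, [3.0] * 5, 3.0)
        assert net == 0.0 and n == 0

    def test_pure_deficit_minus_225(self):
        net, n = compute_iauc(T5, [0, -1, -1, -1, -1], 0.0)
        assert net == pytest.approx(-225.0)
        assert n == 0

    def test_short_peak_counts_only_as_deficit_free_excursion(self):
        # 2-point excursion is ignored above baseline; nothing below baseline
        net, n = compute_iauc(T5, [0, 1, 1, 0, 0], 0.0)
        assert net == 0.0 and n == 0

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_equals_plain_trapezoid_when_filters_disabled(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        t = np.sort(rng.choice(np.arange(300), size=n, replace=False)).astype(float)
        v = rng.normal(0, 2, n)
        b = float(rng.normal(0, 1))
        got, _ = compute_iauc(t, v, b, PeakParams(height_fraction=1e-9, min_adjacent_points=1))
        assert got == pytest.approx(_plain_net_trapezoid(t, v, b), abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 100_000), st.floats(-50, 50))
    def test_shift_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 2, 5)
        b = float(rng.normal(0, 1))
        a0, _ = compute_iauc(T5, v, b)
        a1, _ = compute_iauc(T5, v + shift, b + shift)
        assert a0 == pytest.approx(a1, abs=1e-8)


class TestAUCRecords:
    def test_baseline_is_participant_mean_of_t0(self):
        # one participant, two visits; T0 values 10 and 20 -> baseline 15
        idx = [f"s{i}" for i in range(4)]
        values = pd.DataFrame({"f": [10.0, 30.0, 20.0, 30.0]}, index=idx)
        meta = pd.DataFrame(
            {
                "participant_id": ["P1"] * 4,
                "meal": ["WC", "WC", "HP", "HP"],
                "time_min": [0, 60, 0, 60],
                "age": 40.0,
                "bmi": 28.0,
                "batch": 1,
                "injection_order": range(4),
                "is_qc": False,
            },
            index=idx,
        )
        from ppmet.core import FeatureTable

        rec = compute_auc_records(
            FeatureTable(values, meta), params=PeakParams(min_adjacent_points=1, height_fraction=0.5)
        )
        # WC visit: values (10, 30) around baseline 15 -> crossing split
        wc = rec.loc[rec["meal"] == "WC", "net_area"].iloc[0]
        assert wc == pytest.approx(_plain_net_trapezoid(np.array([0.0, 60.0]), np.array([10.0, 30.0]), 15.0))


class TestLog2FC:
    def _auc(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "meal", "feature_id", "net_area", "n_peaks_kept"])

    def test_fourfold_ratio_gives_log2fc_2(self):
        rows = [("P1", "HP", "f", 400.0, 1), ("P1", "WC", "f", 100.0, 1),
                ("P1", "LP", "f", 100.0, 1)]
        fc = compute_log2fc(self._auc(rows))
        assert fc.loc[0, "log2fc_hp"] == pytest.approx(2.0)
        assert fc.loc[0, "log2fc_lp"] == pytest.approx(0.0)

    def test_both_comparisons_reported(self):
        rows = [("P1", m, "f", 100.0, 1) for m in ("WC", "LP", "HP")]
        fc = compute_log2fc(self._auc(rows))
        assert {"log2fc_lp", "log2fc_hp", "sig_lp", "sig_hp"} <= set(fc.columns)

    def test_nonpositive_mean_flagged_indeterminate_not_significant(self):
        rows = [("P1", "HP", "f", -50.0, 0), ("P1", "WC", "f", 100.0, 1),
                ("P1", "LP", "f", 300.0, 1)]
        fc = compute_log2fc(self._auc(rows))
        assert bool(fc.loc[0, "indeterminate_hp"])
        assert not bool(fc.loc[0, "sig_hp"])
        assert bool(fc.loc[0, "sig_lp"])  # log2(3) > 1

    def test_no_shared_participants_rejected(self):
        rows = [("P1", "HP", "f", 1.0, 1), ("P2", "WC", "f", 1.0, 1)]
        with pytest.raises(ValueError, match="shared"):
            compute_log2fc(self._auc(rows))


class TestGate:
    def _fc(self, sig_lp, sig_hp):
        return pd.DataFrame(
            {"feature_id": ["f"], "log2fc_lp": [1.0], "log2fc_hp": [1.0],
             "sig_lp": [sig_lp], "sig_hp": [sig_hp]}
        )

    @pytest.mark.parametrize(
        "sig_lp,sig_hp,expected,shortlisted",
        [
            (True, False, GATE_REMOVED_LP_ONLY, False),
            (True, True, GATE_SHORTLISTED_BOTH, True),
            (False, True, GATE_SHORTLISTED_HP_ONLY, True),
            (False, False, GATE_NOT_SHORTLISTED, False),
        ],
    )
    def test_truth_table(self, sig_lp, sig_hp, expected, shortlisted):
        out, shortlist = gate_features(self._fc(sig_lp, sig_hp))
        assert out.loc[0, "gate"] == expected
        assert (out.loc[0, "feature_id"] in shortlist) == shortlisted

    def test_gate_partitions_features(self):
        rows = pd.concat(
            [self._fc(lp, hp).assign(feature_id=f"f{lp}{hp}")
             for lp, hp in itertools.product([True, False], repeat=2)],
            ignore_index=True,
        )
        out, shortlist = gate_features(rows)
        assert out["gate"].notna().all()
        assert len(out) == out["gate"].isin(
            [GATE_REMOVED_LP_ONLY, GATE_SHORTLISTED_BOTH,
             GATE_SHORTLISTED_HP_ONLY, GATE_NOT_SHORTLISTED]
        ).sum()

    def test_dose_ordered_synthetic_mean_hp_fc_at_least_lp(self, small_table):
        table, truth = small_table
        rec = compute_auc_records(table, truth.responsive_ids)
        fc = compute_log2fc(rec)
        ok = fc["log2fc_hp"].notna() & fc["log2fc_lp"].notna()
        assert fc.loc[ok, "log2fc_hp"].mean() >= fc.loc[ok, "log2fc_lp"].mean()
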