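"""Reporter-quantification cascade: impurity inversion, quality filtering,
collapse, and the normalization fixed points."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_records
from kinmotif.quant import (FilterPolicy, collapse_to_protein, correct_impurities,
                            filter_records, log2_table, median_center,
                            normalize_equal_loading, normalize_phospho_to_protein)


class TestCorrectImpurities:
    def test_identity(self):
        np.testing.assert_allclose(
            correct_impurities([100.0, 50.0], np.eye(2)), [100.0, 50.0])

    def test_two_channel_leak_hand_solution(self):
        # 10% of reagent 1 leaks into channel 2: columns [[0.9, 0.1], [0, 1]]
        m = np.array([[0.9, 0.0],
                      [0.1, 1.0]])
        # hand oracle: x1 = 90/0.9 = 100; x2 = 60 - 0.1*100 = 50
        np.testing.assert_allclose(correct_impurities([90.0, 60.0], m), [100.0, 50.0])

    def test_all_zero(self):
        m = np.array([[0.9, 0.02], [0.05, 0.95]])
        np.testing.assert_allclose(correct_impurities([0.0, 0.0], m), [0.0, 0.0])

    def test_singular_matrix_fails(self):
        m = np.array([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(np.linalg.LinAlgError):
            correct_impurities([1.0, 1.0], m)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            correct_impurities([1.0, 2.0, 3.0], np.eye(2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        diag = rng.uniform(0.85, 0.95, n)
        m = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(m, 0.0)
        m *= (1.0 - diag) / m.sum(axis=0)
        np.fill_diagonal(m, diag)
        x = rng.uniform(0, 1000, n)
        mixed = m @ x
        np.testing.assert_allclose(correct_impurities(mixed, m), x,
                                   rtol=1e-9, atol=1e-9)


class TestFilterRecords:
    policy = FilterPolicy.phospho()

    def test_isolation_below_threshold_rejected(self):
        records = make_records([{"isolation_specificity": 0.79}])
        kept, rejected = filter_records(records, self.policy)
        assert kept.empty
        assert list(rejected["reject_reason"]) == ["isolation_specificity"]

    def test_isolation_at_threshold_kept(self):
        records = make_records([{"isolation_specificity": 0.8}])
        kept, _ = filter_records(records, self.policy)
        assert len(kept) == 1

    def test_summed_sn_boundary_exactly_160_kept(self):
        records = make_records([{"intensities": [40.0] * 4},          # sum 160
                                {"intensities": [39.999] * 4}])       # sum < 160
        kept, rejected = filter_records(records, self.policy)
        assert list(kept["record_id"]) == ["R000001"]
        assert list(rejected["reject_reason"]) == ["summed_sn"]

    def test_localization_below_13_rejected(self):
        records = make_records([{"localization_score": 12.9},
                                {"localization_score": 13.0}])
        kept, rejected = filter_records(records, self.policy)
        assert list(rejected["reject_reason"]) == ["localization"]
        assert len(kept) == 1

    def test_missing_channels_threshold(self):
        nan = float("nan")
        many_missing = {"intensities": [nan] * 12 + [500.0] * 4}
        few_missing = {"intensities": [nan] * 11 + [500.0] * 5}
        records = make_records([many_missing, few_missing], n_channels=16)
        kept, rejected = filter_records(records, self.policy)
        assert list(rejected["reject_reason"]) == ["missing_channels"]
        assert len(kept) == 1

    def test_total_proteome_policy_differs(self):
        nan = float("nan")
        records = make_records(
            [{"isolation_specificity": 0.75},
             {"intensities": [nan] * 8 + [500.0] * 8}], n_channels=16)
        kept, rejected = filter_records(records, FilterPolicy.phospho())
        assert len(kept) == 1  # 0.75 < 0.8 rejected; 8 missing of 16 kept
        assert list(rejected["reject_reason"]) == ["isolation_specificity"]
        kept_tp, rejected_tp = filter_records(records, FilterPolicy.total_proteome())
        assert len(kept_tp) == 1  # 0.75 >= 0.7 kept; 8 missing of 16 rejected
        assert list(rejected_tp["reject_reason"]) == ["missing_channels"]

    def test_first_failing_reason_order(self):
        nan = float("nan")
        records = make_records(
            [{"intensities": [nan] * 13 + [10.0] * 3, "isolation_specificity": 0.1}],
            n_channels=16)
        _, rejected = filter_records(records, self.policy)
        assert list(rejected["reject_reason"]) == ["missing_channels"]

    def test_partition_and_idempotence(self):
        rng = np.random.default_rng(0)
        rows = [{"isolation_specificity": float(rng.uniform(0.5, 1.0)),
                 "localization_score": float(rng.uniform(5, 40)),
                 "intensities": list(rng.uniform(0, 100, 4))}
                for _ in range(50)]
        records = make_records(rows)
        kept, rejected = filter_records(records, self.policy)
        assert len(kept) + len(rejected) == len(records)
        kept_again, rejected_again = filter_records(kept, self.policy)
        assert rejected_again.empty
        assert len(kept_again) == len(kept)

    def test_empty_input(self):
        records = make_records([]).reindex(columns=make_records([{}]).columns).iloc[:0]
        kept, rejected = filter_records(records, self.policy)
        assert kept.empty and rejected.empty


class TestCollapse:
    def test_additivity(self):
        records = make_records([
            {"protein_id": "P1", "intensities": [1.0, 2.0]},
            {"protein_id": "P1", "intensities": [3.0, 4.0]},
        ], n_channels=2)
        table = collapse_to_protein(records)
        np.testing.assert_allclose(table.loc["P1"], [4.0, 6.0])

    def test_single_record_identity(self):
        records = make_records([{"protein_id": "P9", "intensities": [5.0, 7.0]}],
                               n_channels=2)
        np.testing.assert_allclose(collapse_to_protein(records).loc["P9"], [5.0, 7.0])

    def test_per_channel_conservation(self):
        rng = np.random.default_rng(1)
        rows = [{"protein_id": f"P{int(rng.integers(1, 6))}",
                 "intensities": list(rng.uniform(0, 50, 3))} for _ in range(40)]
        records = make_records(rows, n_channels=3)
        table = collapse_to_protein(records)
        chans = [c for c in records.columns if c.startswith("ch")]
        np.testing.assert_allclose(table.sum(axis=0).to_numpy(),
                                   records[chans].sum(axis=0).to_numpy())

    def test_missing_assignment_skipped(self):
        records = make_records([{"protein_id": "P1", "intensities": [1.0, 1.0]},
                                {"protein_id": "", "intensities": [9.0, 9.0]}],
                               n_channels=2)
        table = collapse_to_protein(records)
        assert list(table.index) == ["P1"]

    def test_all_missing_cell_stays_missing(self):
        nan = float("nan")
        records = make_records([
            {"protein_id": "P1", "intensities": [nan, 2.0]},
            {"protein_id": "P1", "intensities": [nan, 4.0]},
        ], n_channels=2)
        table = collapse_to_protein(records)
        assert np.isnan(table.loc["P1"].iloc[0])
        assert table.loc["P1"].iloc[1] == 6.0


class TestNormalization:
    def test_equal_loading_hand_example(self):
        table = pd.DataFrame([[2.0, 6.0], [2.0, 2.0]], columns=["ch01", "ch02"])
        out = normalize_equal_loading(table)
        np.testing.assert_allclose(out.to_numpy(), [[3.0, 4.5], [3.0, 1.5]])

    def test_equal_loading_fixed_point_and_idempotence(self):
        table = pd.DataFrame([[1.0, 2.0], [3.0, 2.0]], columns=["ch01", "ch02"])
        once = normalize_equal_loading(table)
        sums = once.sum(axis=0)
        np.testing.assert_allclose(sums, sums.mean(), rtol=1e-9)
        pd.testing.assert_frame_equal(normalize_equal_loading(once), once)

    def test_equal_loading_preserves_grand_total(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.uniform(1, 100, (20, 6)))
        out = normalize_equal_loading(table)
        np.testing.assert_allclose(out.to_numpy().sum(), table.to_numpy().sum(),
                                   rtol=1e-9)

    def test_equal_loading_zero_column_names_channel(self):
        table = pd.DataFrame([[1.0, 0.0]], columns=["ch01", "ch02"])
        with pytest.raises(ValueError, match="ch02"):
            normalize_equal_loading(table)

    def test_phospho_to_protein_flat_profile_unchanged(self):
        phospho = pd.DataFrame([[8.0, 8.0]], index=["P1_S5"], columns=["ch01", "ch02"])
        protein = pd.DataFrame([[4.0, 4.0]], index=["P1"], columns=["ch01", "ch02"])
        out, flags = normalize_phospho_to_protein(phospho, protein)
        np.testing.assert_allclose(out.loc["P1_S5"], [8.0, 8.0])
        assert not flags.any()

    def test_phospho_to_protein_hand_example(self):
        phospho = pd.DataFrame([[8.0, 8.0]], index=["P1_S5"], columns=["ch01", "ch02"])
        protein = pd.DataFrame([[2.0, 6.0]], index=["P1"], columns=["ch01", "ch02"])
        out, _ = normalize_phospho_to_protein(phospho, protein)
        np.testing.assert_allclose(out.loc["P1_S5"], [16.0, 16.0 / 3.0])

    def test_phospho_without_protein_flagged(self):
        phospho = pd.DataFrame([[8.0, 8.0]], index=["PX_S5"], columns=["ch01", "ch02"])
        protein = pd.DataFrame([[2.0, 6.0]], index=["P1"], columns=["ch01", "ch02"])
        out, flags = normalize_phospho_to_protein(phospho, protein)
        np.testing.assert_allclose(out.loc["PX_S5"], [8.0, 8.0])
        assert flags["PX_S5"]

    def test_median_center(self):
        table = pd.DataFrame({"ch01": [1.0, 3.0, 5.0], "ch02": [0.0, 0.0, 0.0]})
        out = median_center(table)
        np.testing.assert_allclose(out["ch01"], [-2.0, 0.0, 2.0])
        np.testing.assert_allclose(out["ch02"], 0.0)
        assert (out.median(axis=0) == 0).all()

    def test_median_center_all_missing_column(self):
        table = pd.DataFrame({"ch01": [1.0], "ch02": [float("nan")]})
        with pytest.raises(ValueError, match="ch02"):
            median_center(table)

    def test_log2_table_nonpositive_to_missing(self):
        table = pd.DataFrame({"ch01": [4.0, 0.0]})
        out = log2_table(table)
        assert out["ch01"].iloc[0] == 2.0
        assert np.isnan(out["ch01"].iloc[1])
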