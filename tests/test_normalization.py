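"""GC-bin and quantile normalization, thresholds, QC, replicate pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plastotile.normalization import (
    DetectionThreshold,
    IntensityMatrix,
    average_replicates,
    condition_thresholds,
    detection_threshold,
    gc_normalize,
    qc_replicates,
    quantile_normalize,
)


def _matrix(values: np.ndarray, cols=None) -> IntensityMatrix:
    values = np.asarray(values, float)
    cols = cols or [f"WT_ZT0_R{i + 1}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=cols,
                      index=[f"p{i}" for i in range(values.shape[0])])
    return IntensityMatrix(df)


class TestGcNormalize:
    def test_single_bin_identity(self):
        m = _matrix(np.exp(np.array([[1.0], [2.0], [3.0]])))
        gc = pd.Series([5, 5, 5], index=m.values.index)
        out = gc_normalize(m, gc)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())
        assert out.stage == "gc_normalized"

    def test_equal_size_bins_map_by_sorting(self):
        # oracle: sort-and-assign for equal-size bins — after mapping, both
        # bins hold the reference bin's values in their original rank order
        vals = np.exp(np.array([[1.0], [2.0], [3.0], [4.0],
                                [11.0], [12.0], [13.0], [14.0]]))
        m = _matrix(vals)
        gc = pd.Series([7, 7, 7, 7, 9, 9, 9, 9], index=m.values.index)
        out = np.log(gc_normalize(m, gc).values.to_numpy()).ravel()
        np.testing.assert_allclose(out[:4], out[4:])
        assert (np.allclose(out[:4], [1, 2, 3, 4])
                or np.allclose(out[:4], [11, 12, 13, 14]))

    def test_reference_bin_unchanged(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(5, 1, size=(60, 2)))
        m = _matrix(vals, cols=["WT_ZT0_R1", "WT_ZT0_R2"])
        gc = pd.Series([10] * 40 + [12] * 20, index=m.values.index)
        out = gc_normalize(m, gc)
        np.testing.assert_allclose(out.values.to_numpy()[:40],
                                   m.values.to_numpy()[:40])

    def test_small_bin_passthrough_warns(self):
        vals = np.exp(np.array([[1.0], [2.0], [3.0], [9.0]]))
        m = _matrix(vals)
        gc = pd.Series([5, 5, 5, 20], index=m.values.index)
        with pytest.warns(UserWarning, match="passed through"):
            out = gc_normalize(m, gc)
        assert np.isclose(out.values.to_numpy()[3, 0], np.exp(9.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_within_bin_rank_order_preserved(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        vals = np.exp(rng.normal(3, 1, size=(n, 1)))
        gc = pd.Series(rng.integers(4, 7, size=n))
        m = _matrix(vals)
        gc.index = m.values.index
        out = np.log(gc_normalize(m, gc).values.to_numpy()).ravel()
        logv = np.log(vals).ravel()
        for b in np.unique(gc):
            mask = (gc == b).to_numpy()
            if mask.sum() >= 2:
                assert (np.argsort(np.argsort(out[mask]))
                        == np.argsort(np.argsort(logv[mask]))).all()

    def test_missing_gc_errors(self):
        m = _matrix(np.ones((3, 1)))
        with pytest.raises(ValueError, match="GC value"):
            gc_normalize(m, pd.Series([1, 2], index=m.values.index[:2]))


class TestQuantileNormalize:
    def test_hand_oracle_two_arrays(self):
        m = _matrix(np.exp(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])),
                    cols=["WT_ZT0_R1", "WT_ZT0_R2"])
        out = np.log(quantile_normalize(m).values.to_numpy())
        np.testing.assert_allclose(out, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_arrays_unchanged(self):
        v = np.exp(np.array([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]]))
        m = _matrix(v, cols=["WT_ZT0_R1", "WT_ZT0_R2"])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), v)

    def test_single_array_unchanged(self):
        v = np.exp(np.array([[1.0], [2.0]]))
        out = quantile_normalize(_matrix(v))
        np.testing.assert_allclose(out.values.to_numpy(), v)

    def test_ties_get_mean_of_spanned_reference_values(self):
        # column 0 has a 2-way tie at the bottom ranks 1-2
        m = _matrix(np.exp(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])),
                    cols=["WT_ZT0_R1", "WT_ZT0_R2"])
        out = np.log(quantile_normalize(m).values.to_numpy())
        ref = np.array([(1 + 10) / 2, (1 + 20) / 2, (5 + 30) / 2])
        expected_tie = (ref[0] + ref[1]) / 2
        np.testing.assert_allclose(out[:2, 0], expected_tie)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sorted_columns_identical_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        v = np.exp(rng.normal(0, 1, size=(30, 4)))
        m = _matrix(v, cols=[f"WT_ZT0_R{i}" for i in range(1, 5)])
        once = quantile_normalize(m)
        lv = np.log(once.values.to_numpy())
        ref = np.sort(lv[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(lv[:, j]), ref)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy())


class TestDetectionThreshold:
    def test_formula_with_sample_sd(self):
        vals = pd.Series([10.0, 12.0, 14.0, 100.0], index=list("abcd"))
        nc = pd.Series([True, True, True, False], index=list("abcd"))
        th = detection_threshold(vals, nc, log=False)
        assert th.value == pytest.approx(16.0)  # 12 + 2·2

    def test_constant_controls(self):
        vals = pd.Series([7.0, 7.0, 7.0], index=list("abc"))
        nc = pd.Series(True, index=list("abc"))
        assert detection_threshold(vals, nc, log=False).value == 7.0

    def test_two_value_example(self):
        vals = pd.Series([0.5, 1.5], index=list("ab"))
        nc = pd.Series(True, index=list("ab"))
        th = detection_threshold(vals, nc, log=False)
        assert th.value == pytest.approx(1 + 2 * np.sqrt(2) / 2, abs=1e-9)

    def test_shift_invariance(self):
        vals = pd.Series([3.0, 5.0, 9.0], index=list("abc"))
        nc = pd.Series(True, index=list("abc"))
        a = detection_threshold(vals, nc, log=False).value
        b = detection_threshold(vals + 10, nc, log=False).value
        assert b == pytest.approx(a + 10)

    def test_too_few_controls_errors(self):
        vals = pd.Series([1.0, 2.0], index=list("ab"))
        nc = pd.Series([True, False], index=list("ab"))
        with pytest.raises(ValueError, match="at least 2"):
            detection_threshold(vals, nc)

    def test_pooling_modes(self, default_dataset):
        m = default_dataset.raw
        nc = pd.Series(default_dataset.probes.table["is_nc"].to_numpy(),
                       index=default_dataset.probes.table["id"])
        per = condition_thresholds(m, nc, pool="none")
        glob = condition_thresholds(m, nc, pool="global")
        assert len(set(t.value for t in glob.values())) == 1
        # pooled and per-array thresholds agree closely (iid controls)
        assert abs(list(glob.values())[0].value
                   - np.mean([t.value for t in per.values()])) < 0.1


class TestQcAndAveraging:
    def test_exact_duplicate_passes(self):
        rng = np.random.default_rng(1)
        col = np.exp(rng.normal(5, 1, 50))
        m = _matrix(np.column_stack([col, col]),
                    cols=["WT_ZT0_R1", "WT_ZT0_R2"])
        qc = qc_replicates(m)
        assert qc.min_pearson == pytest.approx(1.0)
        assert qc.passed

    def test_independent_noise_fails(self):
        rng = np.random.default_rng(2)
        m = _matrix(np.exp(rng.normal(5, 1, size=(100, 2))),
                    cols=["WT_ZT0_R1", "WT_ZT0_R2"])
        qc = qc_replicates(m)
        assert abs(qc.min_pearson) < 0.5
        assert not qc.passed

    def test_cv_from_duplicate_spots(self):
        m = _matrix(np.ones((3, 2)), cols=["WT_ZT0_R1", "WT_ZT0_R2"])
        spots = pd.DataFrame({"probe_id": ["p0", "p1"],
                              "array": ["WT_ZT0_R1", "WT_ZT0_R1"],
                              "spot1": [10.0, 10.0], "spot2": [10.0, 30.0]})
        qc = qc_replicates(m, duplicate_spots=spots)
        # CVs: 0 and sd([10,30])/20
        assert qc.mean_cv == pytest.approx(
            0.5 * (0 + np.std([10, 30], ddof=1) / 20))

    @pytest.mark.parametrize("reps", [[2.0, 4.0, 6.0]])
    def test_average_replicates_mean_and_permutation(self, reps):
        for order in ([0, 1, 2], [2, 0, 1]):
            v = np.exp(np.array([[reps[i] for i in order]]))
            m = _matrix(v, cols=[f"WT_ZT7_R{i + 1}" for i in range(3)])
            out = average_replicates(m)
            assert out.iloc[0, 0] == pytest.approx(4.0)

    def test_average_single_replicate_identity(self):
        v = np.exp(np.array([[1.3], [2.7]]))
        m = _matrix(v)
        np.testing.assert_allclose(average_replicates(m)["WT_ZT0"],
                                   np.log(v).ravel())


def test_matrix_validation():
    with pytest.raises(ValueError, match="strictly positive"):
        _matrix(np.array([[1.0], [-2.0]]))
    df = pd.DataFrame({"WT_ZT0_R1": [1.0, np.nan]})
    with pytest.raises(ValueError, match="missing"):
        IntensityMatrix(df)
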