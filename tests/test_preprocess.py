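"""Preprocessing chain: replicate collapsing, presence/missingness filters,
outlier masking, quantile normalization, kNN imputation."""
import numpy as np
import pandas as pd
import pytest

from mirlink import (
    ExpressionMatrix,
    GroupDesign,
    collapse_replicates,
    filter_mirna,
    filter_mrna,
    knn_impute,
    mask_outliers,
    quantile_normalize,
)
from mirlink.containers import CASE, CONTROL


def _em(values, kind="miRNA", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), kind=kind)


def _design(n_case, n_control, replicate_map=None):
    ids = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_control)]
    return GroupDesign(
        pd.Series([CASE] * n_case + [CONTROL] * n_control, index=ids),
        replicate_map or {},
    )


class TestCollapseReplicates:
    def test_mean_and_missing_aware_mean(self):
        design = GroupDesign(
            pd.Series({"a": CASE, "b": CONTROL, "c": CONTROL}),
            {"a_r1": "a", "a_r2": "a"},
        )
        m = _em([[1.0, 3.0, 5.0, np.nan], [1.0, np.nan, 2.0, 2.0]],
                samples=["a_r1", "a_r2", "b", "c"])
        out = collapse_replicates(m, design)
        assert out.sample_ids == ["a", "b", "c"]
        assert out.data.loc["f0", "a"] == 2.0       # mean of (1, 3)
        assert out.data.loc["f1", "a"] == 1.0       # missing-aware mean of (1, NA)
        assert np.isnan(out.data.loc["f0", "c"])    # missing in all replicates

    def test_default_synth_collapses_50_to_43(self, default_dataset):
        mirna, _, design, _ = default_dataset
        out = collapse_replicates(mirna, design)
        assert out.n_samples == 43

    def test_unknown_column_raises(self):
        design = _design(2, 2)
        m = _em(np.ones((2, 5)), samples=["c0", "c1", "n0", "n1", "mystery"])
        with pytest.raises(KeyError):
            collapse_replicates(m, design)


class TestFilterMirna:
    def _matrix(self, case_present, ctrl_present, n_case=10, n_control=10):
        row = [1.0] * case_present + [np.nan] * (n_case - case_present)
        row += [1.0] * ctrl_present + [np.nan] * (n_control - ctrl_present)
        return _em([row], samples=[f"c{i}" for i in range(n_case)] +
                   [f"n{i}" for i in range(n_control)])

    def test_kept_if_present_in_one_group(self):
        # 50% present in cases, 10% in controls: fails the both-groups-low
        # condition, so it is kept
        m = self._matrix(5, 1)
        out = filter_mirna(m, _design(10, 10), missing_frac=1.0)
        assert out.n_features == 1

    def test_dropped_if_absent_everywhere(self):
        m = self._matrix(0, 0)
        assert filter_mirna(m, _design(10, 10)).n_features == 0

    def test_either_mode_drops_one_low_group(self):
        m = self._matrix(5, 1)
        out = filter_mirna(m, _design(10, 10), missing_frac=1.0, filter_mode="either")
        assert out.n_features == 0

    def test_overall_missing_over_40_percent_dropped(self):
        # 100 samples, 41 missing: overall missingness 41% > 40% -> dropped,
        # even though presence passes in one group
        row = [1.0] * 50 + [np.nan] * 41 + [1.0] * 9
        m = _em([row], samples=[f"c{i}" for i in range(50)] + [f"n{i}" for i in range(50)])
        assert filter_mirna(m, _design(50, 50)).n_features == 0
        # exactly 40% missing is kept (strict >)
        row = [1.0] * 60 + [np.nan] * 40
        m = _em([row], samples=[f"c{i}" for i in range(50)] + [f"n{i}" for i in range(50)])
        assert filter_mirna(m, _design(50, 50)).n_features == 1


class TestFilterMrna:
    @pytest.mark.parametrize("n_missing,kept", [(2, False), (1, True), (0, True)])
    def test_50_percent_boundary(self, n_missing, kept):
        row = [np.nan] * n_missing + [1.0] * (4 - n_missing)
        out = filter_mrna(_em([row], kind="mRNA"))
        assert out.n_features == (1 if kept else 0)


class TestMaskOutliers:
    def test_constant_feature_untouched(self):
        m = _em([[5.0] * 10])
        out = mask_outliers(m)
        assert not out.missing_mask.any()

    def test_single_extreme_point_masked(self):
        # 100 values with mean ~0 and SD ~1 plus one at 10: only the 10 is
        # beyond 3 SD of the feature mean (direct computation oracle)
        base = np.resize([1.0, -1.0], 100)
        vals = np.append(base, 10.0)
        mean, sd = vals.mean(), vals.std(ddof=1)
        expected = np.abs(vals - mean) > 3 * sd
        assert expected.sum() == 1 and expected[-1]
        out = mask_outliers(_em([vals]))
        np.testing.assert_array_equal(out.missing_mask[0], expected)

    def test_exactly_three_sd_kept(self):
        # construct a vector whose extreme sits at exactly 3 SD: strict
        # inequality keeps it
        vals = np.array([-1.0, 1.0] * 50 + [0.0])
        mean, sd = vals.mean(), vals.std(ddof=1)
        vals2 = np.append(vals, mean + 3 * sd)
        mean2, sd2 = vals2.mean(), vals2.std(ddof=1)
        # re-solve so the appended point is exactly at 3 SD of the final vector
        from scipy.optimize import brentq

        def gap(x):
            v = np.append(vals, x)
            return (x - v.mean()) - 3 * v.std(ddof=1)

        x = brentq(gap, 0.0, 100.0)
        v = np.append(vals, x - 1e-9)  # just inside the boundary
        out = mask_outliers(_em([v]))
        assert not out.missing_mask.any()

    def test_too_few_observations_skipped(self):
        m = _em([[1.0, np.nan, np.nan, 100.0]])
        out = mask_outliers(m)
        assert out.data.equals(m.data)


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        m = _em(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_are_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        m = _em(np.column_stack([col, col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_complete_columns_share_sorted_values(self, rng):
        V = rng.normal(size=(50, 6))
        out = quantile_normalize(_em(V))
        ref = np.sort(out.values[:, 0])
        for c in range(1, 6):
            np.testing.assert_allclose(np.sort(out.values[:, c]), ref, atol=1e-12)

    def test_preserves_rank_order_and_missing(self, rng):
        V = rng.normal(size=(30, 4))
        V[rng.random(V.shape) < 0.2] = np.nan
        out = quantile_normalize(_em(V))
        np.testing.assert_array_equal(np.isnan(out.values), np.isnan(V))
        for c in range(4):
            obs = ~np.isnan(V[:, c])
            orig = V[obs, c]
            newv = out.values[obs, c]
            assert np.array_equal(np.argsort(orig, kind="stable"),
                                  np.argsort(newv, kind="stable"))

    def test_ties_get_equal_values(self):
        m = _em(np.array([[1.0, 1.0], [1.0, 2.0], [3.0, 3.0]]))
        out = quantile_normalize(m)
        assert out.values[0, 0] == out.values[1, 0]  # tied inputs map equally


class TestKnnImpute:
    def test_complete_matrix_unchanged(self, rng):
        m = _em(rng.normal(size=(5, 4)))
        out = knn_impute(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_k1_copies_identical_neighbor(self):
        V = np.array([[1.0, 2.0, 3.0, np.nan],
                      [1.0, 2.0, 3.0, 4.0],
                      [9.0, 9.0, 9.0, 9.0]])
        out = knn_impute(_em(V), k=1)
        assert out.values[0, 3] == 4.0

    def test_k2_matches_brute_force_oracle(self, rng):
        V = rng.normal(size=(4, 4))
        V[1, 2] = np.nan
        # brute-force neighbor search with the same RMS distance definition
        def dist(a, b):
            joint = ~np.isnan(V[a]) & ~np.isnan(V[b])
            return np.sqrt(np.mean((V[a, joint] - V[b, joint]) ** 2))

        others = [i for i in range(4) if i != 1]
        order = sorted(others, key=lambda i: dist(1, i))
        expected = np.mean([V[i, 2] for i in order[:2]])
        out = knn_impute(_em(V), k=2)
        assert out.values[1, 2] == pytest.approx(expected)
        assert not out.missing_mask.any()

    def test_fallback_to_own_mean_when_neighbors_missing(self):
        V = np.array([[1.0, 3.0, np.nan],
                      [np.nan, np.nan, 5.0]])
        out = knn_impute(_em(V), k=1)
        # the only other feature is unobserved at the target sample for f0
        assert out.values[0, 2] == pytest.approx(2.0)

    def test_all_missing_feature_raises(self):
        V = np.array([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            knn_impute(_em(V))
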