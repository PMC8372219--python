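"""Preprocessing stages against their definitions and bookkeeping invariants."""

import numpy as np
import pandas as pd
import pytest

from tabml import Dataset, PreprocessConfig, preprocess_data
from tabml.core_data import DataError
from tabml.preprocess import (
    collapse_correlated,
    encode_categorical,
    normalize_continuous,
    remove_constant_features,
    remove_near_zero_variance,
)

from _oracles import random_mixed_table


def _ds(features: dict, outcome=None) -> Dataset:
    n = len(next(iter(features.values())))
    df = pd.DataFrame(features)
    df["y"] = outcome if outcome is not None else (["a", "b"] * n)[:n]
    return Dataset.from_dataframe(df, "y")


class TestConstantRemoval:
    def test_constant_removed_varying_kept(self):
        ds = _ds({"const": [5, 5, 5, 5], "varies": [5, 5, 5, 6]})
        out, removed = remove_constant_features(ds)
        assert removed == ["const"]
        assert out.feature_names == ["varies"]

    def test_constant_over_nonmissing_removed(self):
        ds = _ds({"c": [5.0, np.nan, 5.0, 5.0], "x": [1.0, 2.0, 3.0, 4.0]})
        _, removed = remove_constant_features(ds)
        assert removed == ["c"]

    def test_all_constant_errors(self):
        ds = _ds({"c1": [1, 1, 1, 1], "c2": [2, 2, 2, 2]})
        with pytest.raises(DataError, match="no features remain"):
            remove_constant_features(ds)


class TestEncodeCategorical:
    def test_three_levels_give_three_indicators(self):
        ds = _ds({"site": list("aabbcc")})
        out, name_map = encode_categorical(ds)
        assert name_map["site"] == ["site_a", "site_b", "site_c"]
        assert list(out.table["site_a"]) == [1, 1, 0, 0, 0, 0]
        assert list(out.table["site_b"]) == [0, 0, 1, 1, 0, 0]
        assert list(out.table["site_c"]) == [0, 0, 0, 0, 1, 1]

    def test_two_levels_give_one_indicator_named_second_level(self):
        ds = _ds({"sex": ["f", "m", "f", "m"]})
        out, name_map = encode_categorical(ds)
        assert name_map["sex"] == ["sex_m"]
        assert list(out.table["sex_m"]) == [0, 1, 0, 1]

    def test_missing_propagates_to_all_indicators(self):
        ds = _ds({"f": ["a", np.nan, "b", "c"]})
        out, name_map = encode_categorical(ds)
        for col in name_map["f"]:
            assert np.isnan(out.table[col].iloc[1])

    def test_name_collision_suffixed_with_warning(self):
        ds = _ds({"f": ["a", "b", "a", "b"], "f_b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="collides"):
            out, name_map = encode_categorical(ds)
        assert name_map["f"] == ["f_b_1"]
        assert "f_b" in out.table.columns


class TestNormalize:
    def test_closed_form_zscore(self):
        ds = _ds({"x": [1.0, 2.0, 3.0], "z": [0.0, 1.0, 0.0]})
        out, params = normalize_continuous(ds)
        np.testing.assert_allclose(out.table["x"], [-1.0, 0.0, 1.0])
        assert params["x"] == (2.0, 1.0)

    def test_median_imputation_before_scaling(self):
        ds = _ds({"x": [10.0, np.nan, 20.0], "pad": [1.0, 2.0, 3.0]})
        out, params = normalize_continuous(ds)
        mean, sd = params["x"]
        np.testing.assert_allclose(out.table["x"] * sd + mean, [10.0, 15.0, 20.0])

    def test_method_none_is_identity(self):
        ds = _ds({"x": [1.0, 2.0, 3.0]})
        out, params = normalize_continuous(ds, method="none")
        assert params == {}
        pd.testing.assert_frame_equal(out.table, ds.table)

    def test_binary_indicators_untouched(self):
        ds = _ds({"ind": [0.0, 1.0, 0.0, 1.0], "x": [1.0, 2.0, 3.0, 4.0]})
        out, params = normalize_continuous(ds)
        assert list(out.table["ind"]) == [0, 1, 0, 1]
        assert "ind" not in params


class TestNearZeroVariance:
    def test_99_to_1_removed(self):
        vals = np.zeros(100)
        vals[0] = 1.0
        ds = _ds({"nzv": vals, "x": np.arange(100.0)})
        _, removed = remove_near_zero_variance(ds)
        assert removed == ["nzv"]

    def test_balanced_feature_kept(self):
        ds = _ds({"f": np.r_[np.zeros(50), np.ones(50)], "x": np.arange(100.0)})
        _, removed = remove_near_zero_variance(ds)
        assert removed == []

    def test_all_distinct_kept(self):
        ds = _ds({"f": np.arange(100.0)})
        _, removed = remove_near_zero_variance(ds)
        assert removed == []

    def test_single_value_always_removed(self):
        ds = _ds({"f": np.ones(10), "x": np.arange(10.0)})
        _, removed = remove_near_zero_variance(ds)
        assert removed == ["f"]


class TestCollapseCorrelated:
    def test_affine_copy_collapsed_keeping_first(self):
        x = np.arange(10.0)
        ds = _ds({"x": x, "y2": 2 * x + 3})
        out, groups = collapse_correlated(ds)
        assert out.feature_names == ["x"]
        assert groups == {"x": ["x", "y2"]}

    def test_negative_correlation_collapsed(self):
        x = np.arange(10.0)
        ds = _ds({"x": x, "neg": -x})
        out, groups = collapse_correlated(ds)
        assert groups == {"x": ["x", "neg"]}

    def test_independent_feature_is_singleton_group(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        ds = _ds({"x": x, "x2": x.copy(), "z": z})
        _, groups = collapse_correlated(ds)
        assert groups == {"x": ["x", "x2"], "z": ["z"]}

    def test_threshold_below_one(self, rng):
        x = rng.normal(size=200)
        noisy = x + 0.1 * rng.normal(size=200)
        ds = _ds({"x": x, "noisy": noisy})
        _, strict = collapse_correlated(ds, corr_threshold=1.0)
        _, loose = collapse_correlated(ds, corr_threshold=0.9)
        assert strict == {"x": ["x"], "noisy": ["noisy"]}
        assert loose == {"x": ["x", "noisy"]}


class TestPreprocessData:
    def test_composition_of_stages(self):
        n = 6
        ds = _ds({
            "const": [3.0] * n,
            "sex": ["f", "m"] * 3,
            "x": [1.0, 4.0, 2.0, 5.0, 3.0, 6.0],
        })
        res = preprocess_data(ds)
        assert res.removed_features == {"constant": ["const"]}
        assert sorted(res.dataset.feature_names) == ["sex_m", "x"]
        assert res.dataset.is_all_numeric()

    def test_idempotent_on_own_output(self, rng):
        df = random_mixed_table(rng, n_max=60, p_max=12)
        ds = Dataset.from_dataframe(df, "outcome")
        first = preprocess_data(ds)
        second = preprocess_data(first.dataset)
        pd.testing.assert_frame_equal(second.dataset.table, first.dataset.table)
        assert second.removed_features == {}

    def test_row_count_and_order_preserved(self, rng):
        df = random_mixed_table(rng, n_max=50, p_max=10)
        ds = Dataset.from_dataframe(df, "outcome")
        res = preprocess_data(ds)
        assert len(res.dataset.table) == len(df)
        pd.testing.assert_series_equal(
            res.dataset.outcome, ds.outcome, check_names=False
        )

    def test_accounting_completeness(self, rng):
        """Every original feature lands in exactly one bookkeeping bucket."""
        for trial in range(10):
            df = random_mixed_table(rng, n_max=80, p_max=20)
            ds = Dataset.from_dataframe(df, "outcome")
            res = preprocess_data(ds)
            surviving = set(res.dataset.feature_names)
            removed = {f for lst in res.removed_features.values() for f in lst}
            collapsed_away = {
                m for k, members in res.correlated_groups.items() for m in members
            } - set(res.correlated_groups)
            derived_of = res.encoding_map
            for orig in ds.feature_names:
                if orig in removed:  # removed as constant before encoding
                    assert orig not in surviving
                    continue
                derived = derived_of[orig]
                for d in derived:
                    buckets = [d in surviving, d in removed, d in collapsed_away]
                    assert sum(buckets) == 1, (orig, d, buckets)

    def test_no_remaining_perfect_correlation(self, rng):
        for trial in range(5):
            df = random_mixed_table(rng, n_max=60, p_max=15)
            res = preprocess_data(Dataset.from_dataframe(df, "outcome"))
            X = res.dataset.features.to_numpy(dtype=float)
            if X.shape[1] < 2:
                continue
            corr = np.corrcoef(X, rowvar=False)
            off = np.abs(corr[np.triu_indices_from(corr, k=1)])
            assert (off < 1 - 1e-10).all()

    def test_config_validation(self):
        with pytest.raises(DataError):
            PreprocessConfig(corr_threshold=1.5)
        with pytest.raises(DataError):
            PreprocessConfig(freq_cut=0.5)
        with pytest.raises(DataError):
            PreprocessConfig(normalize_method="bogus")
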