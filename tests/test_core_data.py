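"""Dataset construction, delimited I/O, and column-kind inference."""

import numpy as np
import pandas as pd
import pytest

from tabml import Dataset, read_dataset, write_table
from tabml.core_data import DataError, RunConfig, _infer_outcome_kind


def _write(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDataset:
    def test_binary_outcome_and_feature_count(self, tmp_path):
        p = _write(tmp_path, "dx,otu1,otu2\nh,1,2\nc,3,4\nh,5,6\nc,7,8\n")
        ds = read_dataset(p, outcome_name="dx")
        assert ds.outcome_name == "dx"
        assert ds.feature_names == ["otu1", "otu2"]
        assert ds.outcome_kind == "binary"
        assert ds.feature_kinds == {"otu1": "continuous", "otu2": "continuous"}

    def test_missing_outcome_column_names_it(self, tmp_path):
        p = _write(tmp_path, "dx,otu1\nh,1\nc,2\n")
        with pytest.raises(DataError, match="missing_col"):
            read_dataset(p, outcome_name="missing_col")

    def test_numeric_with_na_token_is_continuous(self, tmp_path):
        p = _write(tmp_path, "dx,x\nh,1.5\nc,2.0\nh,NA\nc,3.0\n")
        ds = read_dataset(p, outcome_name="dx")
        assert ds.feature_kinds["x"] == "continuous"
        assert ds.table["x"].isna().sum() == 1

    @pytest.mark.parametrize("token", ["", "NA", "NaN", "null", "na", "NULL"])
    def test_missing_tokens_case_insensitive(self, tmp_path, token):
        p = _write(tmp_path, f"dx,x\nh,1\nc,{token}\nh,3\nc,4\n")
        ds = read_dataset(p, outcome_name="dx")
        assert ds.table["x"].isna().sum() == 1

    def test_duplicate_columns_error(self, tmp_path):
        p = _write(tmp_path, "dx,x,x\nh,1,2\nc,3,4\n")
        with pytest.raises(DataError, match="duplicate"):
            read_dataset(p, outcome_name="dx")

    def test_all_missing_outcome_error(self, tmp_path):
        p = _write(tmp_path, "dx,x\nNA,1\nNA,2\n")
        with pytest.raises(DataError, match="missing"):
            read_dataset(p, outcome_name="dx")

    def test_tsv_delimiter_autodetected(self, tmp_path):
        p = _write(tmp_path, "dx\tx\nh\t1\nc\t2\n", name="data.tsv")
        ds = read_dataset(p, outcome_name="dx")
        assert ds.feature_names == ["x"]

    def test_group_column_popped_into_metadata(self, tmp_path):
        p = _write(tmp_path, "dx,x,batch\nh,1,b1\nc,2,b1\nh,3,b2\nc,4,b2\n")
        ds = read_dataset(p, outcome_name="dx", group_column="batch")
        assert "batch" not in ds.feature_names
        assert list(ds.group_labels) == ["b1", "b1", "b2", "b2"]

    def test_mixed_column_is_categorical_with_warning(self, tmp_path):
        p = _write(tmp_path, "dx,x\nh,1\nc,apple\nh,2\nc,3\n")
        with pytest.warns(UserWarning, match="mixes"):
            ds = read_dataset(p, outcome_name="dx")
        assert ds.feature_kinds["x"] == "categorical"


class TestWriteTable:
    def test_round_trip_preserves_values(self, tmp_path):
        df = pd.DataFrame({"a": [1.5, 2.5], "b": ["x", "y"]})
        path = tmp_path / "t.csv"
        write_table(df, path)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, df)

    def test_empty_records_gives_header_only(self, tmp_path):
        path = tmp_path / "t.csv"
        write_table(pd.DataFrame(columns=["a", "b"]), path)
        assert path.read_text().strip() == "a,b"

    def test_values_with_commas_are_quoted(self, tmp_path):
        path = tmp_path / "t.csv"
        write_table([{"a": "x,y", "b": 1}], path)
        assert '"x,y"' in path.read_text()
        assert pd.read_csv(path).loc[0, "a"] == "x,y"

    def test_unwritable_path_errors(self, tmp_path):
        with pytest.raises(DataError):
            write_table(pd.DataFrame({"a": [1]}), tmp_path / "no" / "dir" / "t.csv")


class TestDatasetInvariants:
    def test_outcome_not_in_features(self, binary_dataset):
        assert binary_dataset.outcome_name not in binary_dataset.feature_names

    def test_single_row_rejected(self):
        with pytest.raises(DataError, match="2 rows"):
            Dataset.from_dataframe(
                pd.DataFrame({"y": ["a"], "x": [1]}), "y", outcome_kind="multiclass"
            )

    def test_group_label_length_mismatch(self, binary_df):
        with pytest.raises(DataError, match="one label per sample"):
            Dataset.from_dataframe(binary_df, "dx", group_labels=["g1", "g2"])

    def test_binary_kind_requires_two_levels(self, binary_df):
        df = binary_df.copy()
        df["dx"] = "same_level_" + df.index.astype(str)
        with pytest.raises(DataError):
            Dataset.from_dataframe(df, "dx", outcome_kind="binary")

    def test_subset_preserves_groups(self, binary_df):
        ds = Dataset.from_dataframe(binary_df, "dx", group_labels=list("pqpqpq"))
        sub = ds.subset([0, 2, 4])
        assert list(sub.group_labels) == ["p", "p", "p"]
        assert sub.n_samples == 3


class TestKindInference:
    def test_numeric_many_levels_is_continuous(self):
        assert _infer_outcome_kind(pd.Series(np.arange(30.0))) == "continuous"

    def test_numeric_few_levels_is_categorical(self):
        assert _infer_outcome_kind(pd.Series([0, 1, 0, 1])) == "binary"
        assert _infer_outcome_kind(pd.Series([0, 1, 2, 0])) == "multiclass"

    def test_inference_independent_of_row_order(self, rng):
        vals = pd.Series(rng.choice(["a", "b", "c"], size=40))
        shuffled = vals.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert _infer_outcome_kind(vals) == _infer_outcome_kind(shuffled)

    def test_feature_kind_inference_order_invariant(self, rng):
        df = pd.DataFrame({
            "y": rng.choice(["a", "b"], size=30),
            "x1": rng.normal(size=30),
            "x2": rng.choice(["u", "v"], size=30),
        })
        ds1 = Dataset.from_dataframe(df, "y")
        ds2 = Dataset.from_dataframe(
            df.sample(frac=1.0, random_state=1).reset_index(drop=True), "y"
        )
        assert ds1.feature_kinds == ds2.feature_kinds


class TestRunConfig:
    def test_unknown_model_rejected(self):
        with pytest.raises(DataError, match="glmnet_logistic"):
            RunConfig(model_type="neuralnet")

    @pytest.mark.parametrize("kwargs", [
        {"training_frac": 0.0}, {"training_frac": 1.0},
        {"kfold": 1}, {"cv_times": 0}, {"nperm": 0},
    ])
    def test_invalid_numeric_fields(self, kwargs):
        with pytest.raises(DataError):
            RunConfig(**kwargs)

    def test_metric_resolution_by_outcome_kind(self):
        cfg = RunConfig()
        assert cfg.resolved_metric("binary") == "auroc"
        assert cfg.resolved_metric("continuous") == "rmse"
        assert RunConfig(perf_metric="f1").resolved_metric("binary") == "f1"
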