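"""AUROC/curve correctness against a pairwise-concordance oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tabml import Dataset, auroc, auprc, calc_performance, roc_points
from tabml.core_data import DataError
from tabml.evaluate import compute_metric, mean_ovr_auroc

from _oracles import oracle_auroc


class _FixedScoreHandle:
    """Minimal predictor satisfying the model-handle contracts."""

    def __init__(self, scores, classes=("neg", "pos"), outcome_kind="binary"):
        self._scores = np.asarray(scores, dtype=float)
        self.classes = list(classes)
        self.positive_class = self.classes[1] if len(self.classes) == 2 else None
        self.outcome_kind = outcome_kind
        self.feature_names = []

    def predict(self, X):
        if self.outcome_kind == "continuous":
            return self._scores[: len(X)]
        s = self._scores[: len(X)]
        return np.where(s >= 0.5, self.positive_class, self.classes[0])

    def score_matrix(self, X):
        s = self._scores[: len(X)]
        return np.column_stack([1 - s, s])

    def positive_score(self, X):
        return self._scores[: len(X)]


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant(self):
        assert auroc([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(DataError, match="AUROC undefined"):
            auroc([0.1, 0.2], [1, 1])

    def test_positive_class_is_lexicographically_second(self):
        # "b" is positive by default: high scores on "b" -> AUROC 1
        assert auroc([0.9, 0.1], ["b", "a"]) == 1.0
        assert auroc([0.9, 0.1], ["b", "a"], pos_label="a") == 0.0

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.integers(0, 10)), min_size=4, max_size=50)
        .filter(lambda rows: 0 < sum(r[0] for r in rows) < len(rows))
    )
    def test_equals_pairwise_concordance_oracle(self, rows):
        labels = [r[0] for r in rows]
        scores = [r[1] / 10.0 for r in rows]  # coarse grid forces ties
        assert auroc(scores, labels) == pytest.approx(
            oracle_auroc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            n = int(rng.integers(6, 60))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            s = rng.integers(0, 8, size=n) / 7.0
            assert auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @given(
        st.lists(st.integers(0, 1), min_size=4, max_size=30)
        .filter(lambda l: 0 < sum(l) < len(l)),
        st.integers(0, 2**20),
    )
    def test_label_flip_symmetry_tie_free(self, labels, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(len(labels)).astype(float)  # distinct scores
        a1 = auroc(scores, labels)
        a2 = auroc(scores, [1 - l for l in labels])
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


class TestRocPoints:
    def test_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        pts = roc_points(scores, labels)
        assert (pts.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (pts.iloc[-1][["fpr", "tpr"]] == 1).all()
        assert (np.diff(pts["fpr"]) >= 0).all()
        assert (np.diff(pts["tpr"]) >= 0).all()


class TestAuprc:
    def test_random_scorer_converges_to_prevalence(self):
        rng = np.random.default_rng(77)
        prevalence = 0.3
        vals = []
        for _ in range(200):
            n = 200
            y = (rng.random(n) < prevalence).astype(int)
            if y.sum() in (0, n):
                continue
            vals.append(auprc(rng.random(n), y))
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - prevalence) <= 3 * se + 0.01


def _test_dataset(y, x=None):
    n = len(y)
    df = pd.DataFrame({"x": x if x is not None else np.arange(n, dtype=float), "y": y})
    kind = "continuous" if np.asarray(y).dtype.kind == "f" else "binary"
    return Dataset.from_dataframe(df, "y", outcome_kind=kind)


class TestCalcPerformance:
    def test_perfect_scores_balanced(self):
        y = ["pos", "pos", "neg", "neg"]
        handle = _FixedScoreHandle([0.9, 0.8, 0.2, 0.1])
        rep = calc_performance(handle, _test_dataset(y), "binary")
        assert rep.metrics["auroc"] == 1.0
        assert rep.metrics["accuracy"] == 1.0
        assert rep.metrics["f1"] == 1.0
        assert rep.positive_class == "pos"
        assert rep.n_test == 4

    def test_constant_predictor_balanced(self):
        y = ["pos", "neg", "pos", "neg"]
        handle = _FixedScoreHandle([0.7, 0.7, 0.7, 0.7])
        rep = calc_performance(handle, _test_dataset(y), "binary")
        assert rep.metrics["accuracy"] == 0.5
        assert rep.metrics["balanced_accuracy"] == 0.5
        assert rep.metrics["auroc"] == 0.5

    def test_regression_identity(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        handle = _FixedScoreHandle(y, outcome_kind="continuous")
        rep = calc_performance(handle, _test_dataset(y), "continuous")
        assert rep.metrics["rmse"] == 0.0
        assert rep.metrics["r2"] == 1.0

    def test_sensitivity_specificity_direction(self):
        # scores call everything positive: sensitivity 1, specificity 0
        y = ["pos", "neg", "pos", "neg"]
        handle = _FixedScoreHandle([0.9, 0.9, 0.9, 0.9])
        rep = calc_performance(handle, _test_dataset(y), "binary")
        assert rep.metrics["sensitivity"] == 1.0
        assert rep.metrics["specificity"] == 0.0


class TestComputeMetric:
    def test_metric_outcome_mismatch_errors(self):
        handle = _FixedScoreHandle([0.5, 0.5])
        ds = _test_dataset(["pos", "neg"])
        with pytest.raises(DataError, match="undefined"):
            compute_metric("rmse", handle, ds.features, ds.outcome, "binary")
        with pytest.raises(DataError, match="unknown metric"):
            compute_metric("bogus", handle, ds.features, ds.outcome, "binary")

    def test_mean_ovr_auroc_perfect(self):
        scores = np.eye(3)[[0, 1, 2, 0, 1, 2]]
        y = ["c0", "c1", "c2", "c0", "c1", "c2"]
        assert mean_ovr_auroc(scores, y, ["c0", "c1", "c2"]) == 1.0
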