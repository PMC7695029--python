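"""Bench contracts: block-aware splitting, leakage guards, metric
arithmetic, and reproducibility of seeded learners."""

import numpy as np
import pytest

from fameclass.classification_bench import (DEFAULT_HYPERPARAMETERS, FAMILIES,
                                            ClassifierSpec, ValidationScheme,
                                            compute_metrics, evaluate_holdout,
                                            evaluate_loso_cv, split_holdout)
from fameclass.data_model import LabeledDataset


class TestClassifierSpec:
    def test_published_hyperparameter_defaults(self):
        assert DEFAULT_HYPERPARAMETERS["knn"] == {
            "n_neighbors": 3, "metric": "euclidean", "weights": "distance"}
        assert DEFAULT_HYPERPARAMETERS["svm"]["C"] == 15.0
        assert DEFAULT_HYPERPARAMETERS["svm"]["gamma"] == "auto"
        assert DEFAULT_HYPERPARAMETERS["decision_tree"] == {
            "max_depth": 100, "min_samples_split": 2, "min_samples_leaf": 3}
        assert DEFAULT_HYPERPARAMETERS["random_forest"] == {
            "n_estimators": 15, "min_samples_split": 5}
        assert DEFAULT_HYPERPARAMETERS["ann"]["hidden_layer_sizes"] == (300,)
        assert DEFAULT_HYPERPARAMETERS["ann"]["alpha"] == 0.02
        assert DEFAULT_HYPERPARAMETERS["adaboost"] == {
            "n_estimators": 80, "learning_rate": 0.7}

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec("gradient_boosting")

    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_builds_and_fits(self, family, small_dataset):
        spec = ClassifierSpec(family, seed=0)
        if family == "ann":  # keep the unit test quick
            spec = ClassifierSpec(family, {"max_iter": 80}, seed=0)
        clf = spec.build()
        clf.fit(small_dataset.X(), small_dataset.y)
        assert clf.predict(small_dataset.X()[:5]).shape == (5,)


class TestSplitHoldout:
    def test_stratified_counts_on_study_design(self, default_dataset):
        train, test = split_holdout(
            default_dataset, ValidationScheme(kind="holdout", seed=0))
        counts = test.class_sample_counts()
        assert test.n_samples == 20
        assert all(4 <= counts[c] <= 6 for c in range(4))
        assert train.n_samples == 80

    def test_no_block_straddles_the_split(self, default_dataset):
        train, test = split_holdout(
            default_dataset, ValidationScheme(kind="holdout", seed=1))
        assert not set(train.sample_ids) & set(test.sample_ids)
        assert train.n_instances + test.n_instances == \
            default_dataset.n_instances

    def test_identical_split_on_rerun(self, default_dataset):
        scheme = ValidationScheme(kind="holdout", seed=9)
        a = split_holdout(default_dataset, scheme)
        b = split_holdout(default_dataset, scheme)
        assert list(a[1].sample_ids) == list(b[1].sample_ids)

    def test_single_block_class_cannot_stratify(self, small_dataset):
        lone = small_dataset.subset_samples(
            [s for s in np.unique(small_dataset.sample_ids)
             if not s.startswith("G2") or s == "G2S000"])
        with pytest.raises(ValueError, match="single sample block"):
            split_holdout(lone, ValidationScheme(kind="holdout", seed=0))


class TestComputeMetrics:
    def test_hand_computed_binary_example(self):
        # class 0: P=1, R=1/2, F1=2/3; class 1: P=2/3, R=1, F1=4/5
        ca, f1, (cnt, prop) = compute_metrics([0, 0, 1, 1], [0, 1, 1, 1],
                                              labels=[0, 1])
        assert ca == pytest.approx(0.75)
        assert f1 == pytest.approx((2 / 3 + 4 / 5) / 2, abs=1e-12)
        assert f1 == pytest.approx(0.73333, abs=5e-6)

    def test_perfect_prediction(self):
        y = [0, 1, 2, 3] * 3
        ca, f1, (cnt, prop) = compute_metrics(y, y)
        assert ca == 1.0 and f1 == 1.0
        np.testing.assert_array_equal(prop.to_numpy(), np.eye(4))

    def test_majority_class_predictor_on_balanced_data(self):
        y_true = [0, 1, 2, 3] * 5
        ca, _, _ = compute_metrics(y_true, [0] * 20)
        assert ca == pytest.approx(0.25)

    def test_confusion_counts_and_proportions_consistent(self):
        y_true = [0] * 10 + [1] * 5
        y_pred = [0] * 4 + [1] * 6 + [1] * 5
        _, _, (cnt, prop) = compute_metrics(y_true, y_pred, labels=[0, 1])
        assert cnt.loc[0, 1] == 6
        assert cnt.to_numpy().sum() == 15
        np.testing.assert_allclose(prop.sum(axis=1), [1.0, 1.0])

    def test_absent_class_row_is_zero(self):
        _, _, (cnt, prop) = compute_metrics([0, 0, 1], [0, 0, 1])
        np.testing.assert_array_equal(prop.loc[3].to_numpy(), 0.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 40)
        y_pred = rng.integers(0, 4, 40)
        perm = rng.permutation(40)
        a = compute_metrics(y_true, y_pred)
        b = compute_metrics(y_true[perm], y_pred[perm])
        assert a[0] == b[0] and a[1] == pytest.approx(b[1])

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestEvaluateHoldout:
    def test_report_carries_provenance(self, small_dataset):
        spec = ClassifierSpec("knn", seed=4)
        scheme = ValidationScheme(kind="holdout", seed=4)
        rep = evaluate_holdout(small_dataset, spec, scheme,
                               features=["16:0", "18:2n6c"])
        assert rep.feature_names == ("16:0", "18:2n6c")
        assert rep.n_test == rep.confusion_counts.to_numpy().sum()
        assert 0.0 <= rep.accuracy <= 1.0

    def test_seeded_rerun_reproducible(self, small_dataset):
        spec = ClassifierSpec("random_forest", seed=7)
        scheme = ValidationScheme(kind="holdout", seed=7)
        a = evaluate_holdout(small_dataset, spec, scheme)
        b = evaluate_holdout(small_dataset, spec, scheme)
        assert a.accuracy == b.accuracy
        assert a.confusion_counts.equals(b.confusion_counts)


class TestEvaluateLosoCv:
    def test_one_fold_per_block_all_predicted(self, small_dataset):
        rep = evaluate_loso_cv(small_dataset, ClassifierSpec("knn", seed=0))
        assert len(rep.per_fold) == small_dataset.n_samples
        assert rep.n_test == small_dataset.n_instances

    def test_identical_replicates_distinct_blocks_perfect_1nn(self):
        """Blocks whose replicates are identical vectors, distinct between
        blocks: removing a block leaves its class's other blocks as nearest
        neighbors, so distance-weighted kNN is exact."""
        rng = np.random.default_rng(0)
        rows, sids, labels, reps = [], [], [], []
        for code in range(4):
            for b in range(3):
                centre = rng.normal(loc=10.0 * code, scale=0.5, size=3)
                for r in (1, 2):
                    rows.append(centre)
                    sids.append(f"c{code}b{b}")
                    labels.append(code)
                    reps.append(r)
        ds = LabeledDataset.from_arrays(np.array(rows), sids, labels, reps,
                                        ("a", "b", "c"))
        rep = evaluate_loso_cv(ds, ClassifierSpec("knn", seed=0))
        assert rep.accuracy == 1.0

    def test_two_blocks_minimum(self, small_dataset):
        lone = small_dataset.subset_samples([small_dataset.sample_ids[0]])
        with pytest.raises(ValueError, match=">= 2 sample blocks"):
            evaluate_loso_cv(lone, ClassifierSpec("knn"))
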