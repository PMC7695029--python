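"""Multi-classifier bench with block-aware validation.

Seven classifier families (kNN, decision tree, SVM, random forest, a
single-hidden-layer neural network, Gaussian naive Bayes, AdaBoost) with
fixed published hyperparameters, evaluated either on a block-aware,
class-stratified 20:80 holdout split or by leave-one-sample-out
cross-validation (one fold per fish, the fold's test set being that fish's
whole block of chromatograms).

Replicate chromatograms of one fish are near-copies of each other; letting
them straddle a train/test boundary would leak the test fish into training
and inflate accuracy.  Every split here therefore assigns sample blocks
whole, and every evaluation asserts the no-straddling invariant.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_model import LabeledDataset

FAMILIES = ("knn", "decision_tree", "svm", "random_forest", "ann",
            "naive_bayes", "adaboost")

#: Published tuning of each family (kNN: 3 neighbors, Euclidean,
#: distance-weighted; tree: depth<=100, min split 2, min leaf 3; SVM: C=15,
#: RBF, gamma=auto; forest: 15 trees, min split 5; ANN: one hidden layer of
#: 300 ReLU units, Adam, L2 regularization 0.02; AdaBoost: 80 boosted
#: trees, learning rate 0.7).  naive Bayes has no tunables.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "knn": {"n_neighbors": 3, "metric": "euclidean", "weights": "distance"},
    "decision_tree": {"max_depth": 100, "min_samples_split": 2,
                      "min_samples_leaf": 3},
    "svm": {"C": 15.0, "kernel": "rbf", "gamma": "auto"},
    "random_forest": {"n_estimators": 15, "min_samples_split": 5},
    "ann": {"hidden_layer_sizes": (300,), "activation": "relu",
            "solver": "adam", "alpha": 0.02, "max_iter": 1000},
    "naive_bayes": {},
    "adaboost": {"n_estimators": 80, "learning_rate": 0.7},
}


#: Families whose decision rule depends on feature scale.  Fatty-acid
#: percentages span two orders of magnitude (18:1n9c ~42%, 24:1n9 ~0.2%),
#: so distance-, kernel- and gradient-based learners get a standardizing
#: preprocessor (fit on training data only), as chemometric practice — and
#: the GUI toolkit the emulated study ran on — prescribe.  Tree-based
#: learners and Gaussian naive Bayes are scale-invariant and run raw.
SCALE_SENSITIVE = ("knn", "svm", "ann")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}; "
                             f"choose from {FAMILIES}")
        merged = {**DEFAULT_HYPERPARAMETERS[self.family], **self.hyperparameters}
        object.__setattr__(self, "hyperparameters", merged)

    def build(self):
        """Instantiate a fresh (seeded) scikit-learn estimator.

        Scale-sensitive families come wrapped in a standardizing pipeline
        (see :data:`SCALE_SENSITIVE`)."""
        hp = self.hyperparameters
        if self.family == "knn":
            est = KNeighborsClassifier(**hp)
        elif self.family == "decision_tree":
            est = DecisionTreeClassifier(random_state=self.seed, **hp)
        elif self.family == "svm":
            est = SVC(random_state=self.seed, **hp)
        elif self.family == "random_forest":
            est = RandomForestClassifier(random_state=self.seed, **hp)
        elif self.family == "ann":
            est = MLPClassifier(random_state=self.seed, **hp)
        elif self.family == "naive_bayes":
            est = GaussianNB(**hp)
        else:
            # AdaBoost over full decision trees (the base learner the
            # study's toolkit boosts); SAMME is the boosting variant
            # current scikit-learn provides.  Depth-1 stumps under SAMME
            # are wildly unstable on this 4-class problem.
            est = AdaBoostClassifier(
                estimator=DecisionTreeClassifier(),
                random_state=self.seed, **hp)
        if self.family in SCALE_SENSITIVE:
            from sklearn.pipeline import make_pipeline
            from sklearn.preprocessing import StandardScaler
            return make_pipeline(StandardScaler(), est)
        return est


@dataclass(frozen=True)
class ValidationScheme:
    """How train and test data are formed; always block-aware."""

    kind: str = "holdout"           # "holdout" | "loso_cv"
    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("holdout", "loso_cv"):
            raise ValueError("kind must be 'holdout' or 'loso_cv'")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class EvaluationReport:
    """Metrics and provenance of one classifier evaluation."""

    accuracy: float
    f1: float
    confusion_counts: pd.DataFrame       # rows: actual code, cols: predicted
    confusion_proportions: pd.DataFrame  # rows normalized by actual count
    feature_names: tuple[str, ...]
    classifier: ClassifierSpec
    scheme: ValidationScheme
    n_test: int
    per_fold: tuple[dict, ...] | None = None
    wall_time_s: float = 0.0  # logged only, never asserted

    def to_dict(self, include_timing: bool = False) -> dict:
        d = {
            "model": self.classifier.family,
            "CA": round(self.accuracy, 6),
            "F1": round(self.f1, 6),
            "n_test": self.n_test,
            "features": list(self.feature_names),
            "scheme": self.scheme.kind,
            "seed": self.classifier.seed,
            "confusion_counts": self.confusion_counts.to_numpy().tolist(),
            "confusion_proportions": np.round(
                self.confusion_proportions.to_numpy(), 6).tolist(),
        }
        if include_timing:
            d["wall_time_s"] = self.wall_time_s
        return d


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                    labels: Sequence[int] = (0, 1, 2, 3)):
    """Accuracy, class-frequency-weighted F1, and confusion matrices.

    The confusion matrix is returned both as counts and as
    proportion-of-actual (each row divided by that class's true count; rows
    of absent classes are zero).
    """
    from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    labels = list(labels)
    ca = float(accuracy_score(y_true, y_pred))
    f1 = float(f1_score(y_true, y_pred, labels=labels, average="weighted",
                        zero_division=0))
    counts = confusion_matrix(y_true, y_pred, labels=labels)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(row_tot > 0, counts / row_tot, 0.0)
    idx = pd.Index(labels, name="actual")
    cols = pd.Index(labels, name="predicted")
    return ca, f1, (pd.DataFrame(counts, index=idx, columns=cols),
                    pd.DataFrame(prop, index=idx, columns=cols))


def split_holdout(dataset: LabeledDataset, scheme: ValidationScheme,
                  ) -> tuple[LabeledDataset, LabeledDataset]:
    """Block-aware stratified holdout split at the sample level.

    Per class, round(test_fraction * n_blocks) blocks go to the test side
    (at least one), chosen by the scheme's seed; blocks are never split.
    """
    tab = dataset.sample_table()
    rng = np.random.default_rng(scheme.seed)
    test_ids: list[str] = []
    if scheme.stratified:
        groups = tab.groupby("class_code")
        for code, sub in groups:
            ids = np.array(sorted(sub.index))
            if len(ids) < 2:
                raise ValueError(f"class {code} has a single sample block; "
                                 "cannot stratify")
            n_test = max(1, round(scheme.test_fraction * len(ids)))
            test_ids.extend(rng.choice(ids, size=n_test, replace=False))
    else:
        ids = np.array(sorted(tab.index))
        n_test = max(1, round(scheme.test_fraction * len(ids)))
        test_ids.extend(rng.choice(ids, size=n_test, replace=False))
    test_set = set(test_ids)
    train_ids = [s for s in tab.index if s not in test_set]
    train = dataset.subset_samples(train_ids)
    test = dataset.subset_samples(test_set)
    _assert_no_leakage(train, test)
    return train, test


def _assert_no_leakage(train: LabeledDataset, test: LabeledDataset):
    overlap = set(train.sample_ids) & set(test.sample_ids)
    if overlap:
        raise AssertionError(f"sample blocks straddle train/test: {overlap}")


def evaluate_holdout(dataset: LabeledDataset, spec: ClassifierSpec,
                     scheme: ValidationScheme,
                     features: Sequence[str] | None = None) -> EvaluationReport:
    """Train on the 80% blocks, report metrics on the held-out chromatograms."""
    feats = tuple(features) if features is not None else dataset.feature_names
    train, test = split_holdout(dataset, scheme)
    clf = spec.build()
    clf.fit(train.X(feats), train.y)
    t0 = time.perf_counter()
    y_pred = clf.predict(test.X(feats))
    elapsed = time.perf_counter() - t0
    ca, f1, (cnt, prop) = compute_metrics(test.y, y_pred)
    return EvaluationReport(ca, f1, cnt, prop, feats, spec, scheme,
                            n_test=test.n_instances, wall_time_s=elapsed)


def evaluate_loso_cv(dataset: LabeledDataset, spec: ClassifierSpec,
                     features: Sequence[str] | None = None,
                     scheme: ValidationScheme | None = None) -> EvaluationReport:
    """Leave-one-sample-out CV: one fold per fish, metrics pooled.

    Each fold trains on every other block and predicts the held-out block's
    chromatograms; predictions are pooled over all folds before computing
    metrics (so CA is the fraction of all chromatograms classified
    correctly when their fish was unseen).
    """
    feats = tuple(features) if features is not None else dataset.feature_names
    scheme = scheme or ValidationScheme(kind="loso_cv", seed=spec.seed)
    sids = dataset.sample_ids
    blocks = pd.unique(sids)
    if len(blocks) < 2:
        raise ValueError("leave-one-sample-out needs >= 2 sample blocks")
    X = dataset.X(feats)
    y = dataset.y
    y_pred = np.empty_like(y)
    folds = []
    t0 = time.perf_counter()
    for block in blocks:
        test_mask = sids == block
        assert not (set(sids[test_mask]) & set(sids[~test_mask]))
        clf = spec.build()
        clf.fit(X[~test_mask], y[~test_mask])
        pred = clf.predict(X[test_mask])
        y_pred[test_mask] = pred
        folds.append({"sample_id": str(block),
                      "n_correct": int((pred == y[test_mask]).sum()),
                      "n": int(test_mask.sum())})
    elapsed = time.perf_counter() - t0
    ca, f1, (cnt, prop) = compute_metrics(y, y_pred)
    return EvaluationReport(ca, f1, cnt, prop, feats, spec,
                            replace(scheme, kind="loso_cv"),
                            n_test=len(y), per_fold=tuple(folds),
                            wall_time_s=elapsed)


def prefix_evaluator(dataset: LabeledDataset, ranking, spec: ClassifierSpec,
                     scheme: ValidationScheme | None = None):
    """Evaluator for the minimal-feature search: prefix length -> accuracy.

    Uses leave-one-sample-out CV by default (deterministic for a fixed
    dataset and classifier seed); pass a holdout scheme for the external
    validation variant.
    """
    def evaluate(prefix_len: int) -> float:
        feats = ranking.top(prefix_len)
        if scheme is not None and scheme.kind == "holdout":
            rep = evaluate_holdout(dataset, spec, scheme, features=feats)
        else:
            rep = evaluate_loso_cv(dataset, spec, features=feats, scheme=scheme)
        return rep.accuracy
    return evaluate
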