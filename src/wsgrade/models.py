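"""Classifiers and the repeated stratified-holdout evaluation protocol.

Four model families grade the severity degree from the retained features:
random forest, RBF support vector machine, one-hidden-layer multilayer
perceptron, and a weighted fuzzy rule-based classifier in the Ishibuchi
style (fuzzy-W).  Each repetition draws a fresh stratified 70/30 split,
tunes hyper-parameters by grid search with internal cross-validation on
the training side only, and scores the held-out images; accuracy, error
(= 1 - accuracy) and macro precision/recall/F-score are aggregated over
repetitions, together with a per-image accumulated error map (fraction of
test-set appearances misclassified).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

ALGORITHMS = ("RF", "SVM", "MLP", "FUZZYW")


@dataclass(frozen=True)
class SplitSpec:
    """Repeated stratified-holdout specification."""

    train_fraction: float = 0.70
    n_repetitions: int = 50
    seed: int = 0


@dataclass
class EvalSummary:
    """Aggregate of the repeated-holdout protocol for one algorithm."""

    algorithm: str
    metrics_mean: dict[str, float]
    metrics_std: dict[str, float]
    per_repetition: pd.DataFrame
    error_map: pd.DataFrame  # image_id, appearances, misclassified, error_rate
    most_misclassified: pd.DataFrame
    confusion: np.ndarray  # summed 3x3 confusion matrix (rows = true)
    classes: list[str] = field(default_factory=list)


def stratified_split(labels, spec: SplitSpec, rep: int):
    """Per-class 70/30 partition, deterministic in (spec.seed, rep)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, rep]))
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_train = int(round(spec.train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


# ---------------------------------------------------------------------------
# fuzzy-W: Ishibuchi-style weighted fuzzy rule-based classifier


class FuzzyWClassifier(BaseEstimator, ClassifierMixin):
    """Grid-partition fuzzy rule-based classifier with certainty weights.

    Each feature axis carries ``n_partitions`` triangular membership
    functions forming a Ruspini partition of [0, 1] (memberships sum to 1
    everywhere).  Candidate rules come from the occupied antecedent cells:
    for every training example, the cell combining each feature's
    maximum-membership fuzzy set.  A rule's consequent is the class q
    maximizing the confidence

        c(A -> q) = sum_{x in q} mu_A(x) / sum_x mu_A(x)

    with product-t-norm membership mu_A; its certainty weight is the
    confidence margin over the best competing class.  Rules with
    non-positive weight are dropped.  Inference is single-winner:
    argmax over rules of mu_A(x) * weight, ties broken by larger weight
    then lower class index.  Features are min-max scaled to [0, 1] with
    train-set extremes and clamped at predict time.

    Because rules exist only for occupied cells, a test point can have
    exactly zero product membership in every rule (one feature a full
    partition away suffices).  Inference therefore floors each feature
    membership at a tiny ``epsilon`` so rule ranking degrades gracefully
    to "fewest mismatched features, then the product over the rest"
    instead of collapsing to a majority-class fallback.
    """

    def __init__(self, n_partitions: int = 3, epsilon: float = 1e-6):
        self.n_partitions = n_partitions
        self.epsilon = epsilon

    # triangular membership of value x in fuzzy set k of an n-set partition
    def _memberships(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_features, n_partitions) membership array."""
        n = self.n_partitions
        centers = np.linspace(0.0, 1.0, n)
        width = 1.0 / (n - 1)
        mu = 1.0 - np.abs(X[..., None] - centers) / width
        return np.clip(mu, 0.0, 1.0)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.span_ > 0, self.span_, 1.0)
        return np.clip((X - self.min_) / span, 0.0, 1.0)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if self.n_partitions < 2:
            raise ValueError("n_partitions must be >= 2")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.min_ = X.min(axis=0)
        self.span_ = X.max(axis=0) - self.min_
        Xs = self._scale(X)
        mu = self._memberships(Xs)  # (n, p, k)

        cells = np.argmax(mu, axis=2)  # each example's max-membership cell
        cells_unique = np.unique(cells, axis=0)

        antecedents, consequents, weights = [], [], []
        n_classes = self.classes_.size
        for cell in cells_unique:
            # product t-norm membership of every training point in this cell
            mu_a = np.prod(mu[:, np.arange(cell.size), cell], axis=1)
            total = mu_a.sum()
            if total <= 0:
                continue
            conf = np.array([mu_a[y_idx == q].sum() / total
                             for q in range(n_classes)])
            q = int(np.argmax(conf))
            rest = np.delete(conf, q)
            weight = conf[q] - (rest.max() if rest.size else 0.0)
            if weight > 0:
                antecedents.append(cell)
                consequents.append(q)
                weights.append(weight)
        if not antecedents:
            raise ValueError("no discriminative rules")
        self.rule_cells_ = np.array(antecedents)
        self.rule_classes_ = np.array(consequents)
        self.rule_weights_ = np.array(weights)
        return self

    def _activations(self, X) -> np.ndarray:
        """(n_samples, n_rules) rule activation mu_A(x) * weight."""
        Xs = self._scale(np.asarray(X, dtype=np.float64))
        mu = np.maximum(self._memberships(Xs), self.epsilon)  # (n, p, k)
        p_idx = np.arange(self.rule_cells_.shape[1])
        mu_rules = np.stack(
            [np.prod(mu[:, p_idx, cell], axis=1) for cell in self.rule_cells_],
            axis=1,
        )
        return mu_rules * self.rule_weights_

    def predict(self, X):
        check_is_fitted(self, "rule_weights_")
        act = self._activations(X)
        n = act.shape[0]
        out = np.empty(n, dtype=self.classes_.dtype)
        for s in range(n):
            scores = act[s]
            best = scores.max()
            if best <= 0:  # no rule fires: majority-class fallback
                counts = np.bincount(self.rule_classes_,
                                     weights=self.rule_weights_)
                out[s] = self.classes_[int(np.argmax(counts))]
                continue
            tied = np.flatnonzero(scores == best)
            # ties: larger weight, then lower class index
            key = sorted(tied, key=lambda r: (-self.rule_weights_[r],
                                              self.rule_classes_[r]))
            out[s] = self.classes_[self.rule_classes_[key[0]]]
        return out


def fuzzyw_fit(X, y, n_partitions: int = 3) -> FuzzyWClassifier:
    """Fit a fuzzy-W rule base (functional wrapper)."""
    return FuzzyWClassifier(n_partitions=n_partitions).fit(X, y)


def fuzzyw_predict(model: FuzzyWClassifier, X):
    """Predict severity degrees with a fitted fuzzy-W rule base."""
    return model.predict(np.atleast_2d(X))


# ---------------------------------------------------------------------------
# tuned training of the four algorithm families


def _median_heuristic_gamma(X: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    d2 = pdist(X, metric="sqeuclidean")
    med = np.median(d2[d2 > 0]) if (d2 > 0).any() else 1.0
    return 1.0 / med


def train_model(algorithm: str, X, y, seed: int = 0, cv: int = 3,
                n_jobs: int = 1):
    """Grid-search-tuned fit of one algorithm on the training split only.

    Hyper-parameter grids: RF trees {100, 500} x per-split features
    {sqrt(p), p/3}; SVM RBF cost {0.1, 1, 10, 100} with the median
    heuristic kernel width; MLP one hidden layer {5, 10, 20} units; fuzzy-W
    partitions {3, 5}.  SVM and MLP standardize features inside the
    pipeline so folds never leak test statistics.
    """
    algorithm = algorithm.upper()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("degenerate training set: fewer than 2 classes")
    p = X.shape[1]
    if algorithm == "RF":
        est = RandomForestClassifier(random_state=seed)
        grid = {"n_estimators": [100, 500],
                "max_features": ["sqrt", max(1, p // 3)]}
    elif algorithm == "SVM":
        gamma = _median_heuristic_gamma(StandardScaler().fit_transform(X))
        est = Pipeline([("scale", StandardScaler()),
                        ("svc", SVC(kernel="rbf", gamma=gamma))])
        grid = {"svc__C": [0.1, 1.0, 10.0, 100.0]}
    elif algorithm == "MLP":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(max_iter=500, random_state=seed)),
        ])
        grid = {"mlp__hidden_layer_sizes": [(5,), (10,), (20,)]}
    elif algorithm == "FUZZYW":
        est = FuzzyWClassifier()
        grid = {"n_partitions": [3, 5]}
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    search = GridSearchCV(est, grid, cv=cv, scoring="accuracy", n_jobs=n_jobs,
                          refit=True)
    search.fit(X, y)
    return search.best_estimator_


# ---------------------------------------------------------------------------
# metrics and the repeated protocol

METRIC_NAMES = ("accuracy", "error", "precision", "recall", "fscore")


def confusion_metrics(y_true, y_pred) -> dict[str, float]:
    """Accuracy, error and macro precision/recall/F over the three degrees."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size or y_true.size == 0:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    acc = float((y_true == y_pred).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0,
        labels=np.unique(y_true),
    )
    return {"accuracy": acc, "error": 1.0 - acc, "precision": float(prec),
            "recall": float(rec), "fscore": float(f1)}


def evaluate_repeated(
    table: pd.DataFrame,
    algorithm: str,
    spec: SplitSpec,
    feature_numbers: list[int] | None = None,
    label_col: str = "degree",
    tune_cv: int = 3,
) -> EvalSummary:
    """Run the repeated stratified-holdout protocol for one algorithm.

    ``feature_numbers`` selects the retained feature columns (all f<N>
    columns when None).  Returns per-repetition metrics, their mean/STD,
    the summed test confusion matrix, the per-image accumulated error map,
    and the most-misclassified image list.
    """
    if feature_numbers is None:
        cols = [c for c in table.columns
                if c.startswith("f") and c[1:].isdigit()]
    else:
        cols = [f"f{k}" for k in feature_numbers]
    X = table[cols].to_numpy(dtype=np.float64)
    y = table[label_col].to_numpy()
    image_ids = (table["image_id"].to_numpy()
                 if "image_id" in table.columns
                 else np.arange(len(table)))
    classes = sorted(np.unique(y).tolist())
    cls_index = {c: k for k, c in enumerate(classes)}

    rows = []
    appearances = np.zeros(len(table), dtype=np.int64)
    misses = np.zeros(len(table), dtype=np.int64)
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for rep in range(spec.n_repetitions):
        train_idx, test_idx = stratified_split(y, spec, rep)
        rep_seed = int(np.random.SeedSequence([spec.seed, rep]).
                       generate_state(1)[0] % (2**31 - 1))
        try:
            model = train_model(algorithm, X[train_idx], y[train_idx],
                                seed=rep_seed, cv=tune_cv)
            y_pred = np.asarray(model.predict(X[test_idx]))
        except Exception as exc:
            raise RuntimeError(f"repetition {rep}: {exc}") from exc
        m = confusion_metrics(y[test_idx], y_pred)
        rows.append({"repetition": rep, **m})
        wrong = y_pred != y[test_idx]
        appearances[test_idx] += 1
        misses[test_idx] += wrong
        for t, pr in zip(y[test_idx], y_pred):
            confusion[cls_index[t], cls_index[pr]] += 1

    per_rep = pd.DataFrame(rows)
    means = {k: float(per_rep[k].mean()) for k in METRIC_NAMES}
    stds = {k: float(per_rep[k].std(ddof=1)) if len(per_rep) > 1 else 0.0
            for k in METRIC_NAMES}
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(appearances > 0, misses / np.maximum(appearances, 1),
                        np.nan)  # never tested -> not evaluated, not 0
    error_map = pd.DataFrame({
        "image_id": image_ids,
        "degree": y,
        "appearances": appearances,
        "misclassified": misses,
        "error_rate": rate,
    })
    worst = (error_map[error_map["appearances"] > 0]
             .sort_values(["error_rate", "misclassified"],
                          ascending=False, kind="stable")
             .head(10).reset_index(drop=True))
    return EvalSummary(
        algorithm=algorithm.upper(), metrics_mean=means, metrics_std=stds,
        per_repetition=per_rep, error_map=error_map,
        most_misclassified=worst, confusion=confusion, classes=classes,
    )
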