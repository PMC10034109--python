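"""Classifiers, cross-validation and confusion-matrix metrics.

Responder ("R") is the positive class.  Feature z-scoring is always fit on
the training portion only.  The headline metrics are accuracy, sensitivity,
specificity and precision in percent; the 2-decimal report truncates rather
than rounds, matching the convention of the published tables these metrics
reproduce.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

POSITIVE = "R"


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm"  # svm | knn | mlp
    svm_kernel: str = "rbf"  # rbf | poly
    #: RBF kernel width, k(x,x') = exp(-||x-x'||^2 / 2 sigma^2).  None picks a
    #: dimension-aware width (sklearn's "scale"); a fixed sigma is only
    #: meaningful relative to the feature dimensionality it was tuned at.
    sigma: float | None = None
    degree: int = 3
    C: float = 1.0
    k_neighbors: int = 7
    mlp_hidden: int | str = "search"

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "knn", "mlp"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.degree not in (1, 2, 3):
            raise ValueError("polynomial order must be 1, 2 or 3")
        if self.k_neighbors < 1:
            raise ValueError("K must be >= 1")

    def label(self) -> str:
        if self.kind == "svm":
            if self.svm_kernel == "poly":
                return f"SVM-Poly (d = {self.degree})"
            return f"SVM-RBF (sigma = {'auto' if self.sigma is None else self.sigma})"
        if self.kind == "knn":
            return f"KNN (K = {self.k_neighbors})"
        return "MLP"


class _MLPWithSearch:
    """Three-layer perceptron with train-internal hidden-size search.

    Sigmoid hidden layer, backpropagation with adaptive learning rate, and a
    stop at 1000 iterations.  The hidden size is chosen on an internal
    stratified split of the *training* data only.
    """

    _CANDIDATES = (2, 4, 8, 16)

    def __init__(self, hidden: int | str = "search", seed: int = 0):
        self.hidden = hidden
        self.seed = seed
        self._est = None

    def _make(self, h: int):
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(
            hidden_layer_sizes=(h,), activation="logistic", solver="sgd",
            learning_rate="adaptive", learning_rate_init=0.1, momentum=0.9,
            max_iter=1000, tol=1e-4, n_iter_no_change=25, random_state=self.seed,
        )

    def fit(self, X, y):
        from sklearn.model_selection import train_test_split

        if isinstance(self.hidden, int):
            h = self.hidden
        else:
            Xa, Xv, ya, yv = train_test_split(
                X, y, test_size=0.25, random_state=self.seed, stratify=y
            )
            scores = []
            for h in self._CANDIDATES:
                est = self._make(h)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(Xa, ya)
                scores.append(float((est.predict(Xv) == yv).mean()))
            h = self._CANDIDATES[int(np.argmax(scores))]
        self._est = self._make(h)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._est.fit(X, y)
        return self

    def predict(self, X):
        return self._est.predict(X)


def make_estimator(spec: ClassifierSpec, seed: int = 0):
    if spec.kind == "svm":
        from sklearn.svm import SVC

        if spec.svm_kernel == "rbf":
            gamma = "scale" if spec.sigma is None else 1.0 / (2.0 * spec.sigma**2)
            return SVC(C=spec.C, kernel="rbf", gamma=gamma)
        return SVC(C=spec.C, kernel="poly", degree=spec.degree, gamma=1.0, coef0=1.0)
    if spec.kind == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(n_neighbors=spec.k_neighbors)
    return _MLPWithSearch(hidden=spec.mlp_hidden, seed=seed)


# ------------------------------------------------------------------ z-score
def zscore_fit_apply(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize with mean/SD (population convention) fit on train only."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mu = train.mean(axis=0)
    sd = train.std(axis=0)  # ddof=0
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-SD feature column(s) passed through centred", RuntimeWarning)
        sd = np.where(zero, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


# ------------------------------------------------------- confusion & metrics
@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @classmethod
    def from_labels(cls, y_true, y_pred, positive: str = POSITIVE) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int((pos_t & pos_p).sum()),
            fp=int((~pos_t & pos_p).sum()),
            fn=int((pos_t & ~pos_p).sum()),
            tn=int((~pos_t & ~pos_p).sum()),
        )


def _truncate2(v: float | None) -> float | None:
    if v is None:
        return None
    return math.floor(round(v * 100.0, 6)) / 100.0


@dataclass(frozen=True)
class Metrics:
    """Percent accuracy/sensitivity/specificity/precision; None = undefined."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None

    def rounded(self) -> "Metrics":
        """Two-decimal report, truncated (the published-table convention)."""
        return Metrics(*(_truncate2(getattr(self, f)) for f in
                         ("accuracy", "sensitivity", "specificity", "precision")))

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
        }


def metrics_from_confusion(cm: ConfusionMatrix) -> Metrics:
    """AC=(TP+TN)/n, SN=TP/(TP+FN), SP=TN/(TN+FP), P=TP/(TP+FP), in percent."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return Metrics(
        accuracy=ratio(cm.tp + cm.tn, cm.n),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        precision=ratio(cm.tp, cm.tp + cm.fp),
    )


# ------------------------------------------------------------ training / CV
def train_predict(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit on (already normalized) training data, predict test labels."""
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("refusing to fit on a single-class training set")
    est = make_estimator(spec, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(train_X, train_y)
    return np.asarray(est.predict(test_X))


@dataclass
class CVResult:
    fold_assignments: np.ndarray  # fold index per subject
    fold_confusions: list[ConfusionMatrix]
    fold_metrics: list[Metrics]
    selected_per_fold: list[list[str]] | None

    @property
    def pooled(self) -> ConfusionMatrix:
        cm = ConfusionMatrix(0, 0, 0, 0)
        for f in self.fold_confusions:
            cm = cm + f
        return cm

    @property
    def pooled_metrics(self) -> Metrics:
        return metrics_from_confusion(self.pooled)

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = [getattr(m, metric) for m in self.fold_metrics if getattr(m, metric) is not None]
        return float(np.mean(vals)), float(np.std(vals))


def cross_validate(
    table,
    spec: ClassifierSpec,
    selector=None,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV with per-fold z-scoring and optional nested
    feature selection (``selector(train_table, fold_seed) -> column names``).

    Pooling the per-fold confusion matrices over all subjects gives the
    headline counts; per-fold metrics give the mean +/- SD view.
    """
    from sklearn.model_selection import StratifiedKFold

    X = table.features.to_numpy(dtype=float)
    y = table.groups.to_numpy()
    if len(y) < folds:
        raise ValueError("fewer subjects than folds")
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError("stratified CV needs at least `folds` subjects per class")
    cols = np.array(table.features.columns)

    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
    assignments = np.empty(len(y), dtype=int)
    fold_cms: list[ConfusionMatrix] = []
    fold_metrics: list[Metrics] = []
    selected: list[list[str]] = []
    for fold, (tr, te) in enumerate(splits):
        assignments[te] = fold
        use = np.arange(len(cols))
        if selector is not None:
            from .features import FeatureTable

            train_tab = FeatureTable(table.features.iloc[tr].copy(), table.groups.iloc[tr].copy())
            names = selector(train_tab, seed * 1000 + fold)
            use = np.array([np.flatnonzero(cols == nm)[0] for nm in names])
            selected.append(list(names))
        Xtr, Xte = zscore_fit_apply(X[tr][:, use], X[te][:, use])
        pred = train_predict(spec, Xtr, y[tr], Xte, seed=seed)
        cm = ConfusionMatrix.from_labels(y[te], pred)
        fold_cms.append(cm)
        fold_metrics.append(metrics_from_confusion(cm))
    return CVResult(
        fold_assignments=assignments,
        fold_confusions=fold_cms,
        fold_metrics=fold_metrics,
        selected_per_fold=selected or None,
    )


# --------------------------------------------------------------- grid report
def default_grid() -> list[ClassifierSpec]:
    """Classifier grid of the parameter study: SVM poly d in {1,2,3}, RBF
    sigma in {0.7, 0.8, 1.0, 1.2, 1.3} (union of the two reported sets),
    KNN K in 1..13."""
    grid = [ClassifierSpec(kind="svm", svm_kernel="poly", degree=d) for d in (1, 2, 3)]
    grid += [ClassifierSpec(kind="svm", svm_kernel="rbf", sigma=s) for s in (0.7, 0.8, 1.0, 1.2, 1.3)]
    grid += [ClassifierSpec(kind="knn", k_neighbors=k) for k in range(1, 14)]
    return grid


def grid_report(table, selector=None, folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Sensitivity/specificity/accuracy per grid spec (pooled over folds)."""
    rows = []
    for spec in default_grid():
        cv = cross_validate(table, spec, selector=selector, folds=folds, seed=seed)
        m = cv.pooled_metrics.rounded()
        rows.append(
            {"classifier": spec.label(), "sensitivity": m.sensitivity,
             "specificity": m.specificity, "accuracy": m.accuracy}
        )
    return pd.DataFrame(rows)
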