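"""Dimensionality reduction and classification of pooled deep features.

Features are z-scored per column (average- and max-pool blocks live on
different scales), reduced by PCA to the smallest number of components
reaching a cumulative explained-variance target (default 0.95, capped at
n_cases - 1), and classified by an RBF-kernel SVM by default; random-forest,
gradient-boosting and MLP backends are available for comparison.  Class
weighting is inverse-frequency wherever the backend supports it, which
matters for imbalanced cohorts (e.g. 11 positive vs 60 negative cases).

Multi-modality fusion either concatenates per-modality feature vectors
case-wise before reduction (default) or averages per-modality classifier
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

BACKENDS = ("svm", "rf", "gbm", "mlp")


@dataclass
class FeatureTable:
    """Case-by-dimension feature matrix with aligned binary labels."""

    X: np.ndarray
    y: np.ndarray
    case_ids: list[str] = field(default_factory=list)
    modality: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be 2D with one label per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains missing/non-finite values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not self.case_ids:
            self.case_ids = [str(i) for i in range(len(self.y))]


def table_from_vectors(vectors, y, modality: str = "") -> FeatureTable:
    return FeatureTable(
        X=np.stack([v.values for v in vectors]),
        y=np.asarray(y, int),
        case_ids=[v.case_id for v in vectors],
        modality=modality,
    )


@dataclass
class ReducerModel:
    """Column standardization + principal axes retained to a variance target."""

    mean: np.ndarray
    std: np.ndarray
    kept_columns: np.ndarray
    components: np.ndarray  # (k, d_kept), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int
    dropped_columns: np.ndarray = field(default_factory=lambda: np.array([], int))


def fit_reducer(table: FeatureTable, variance_target: float | int = 0.95) -> ReducerModel:
    """Standardize columns, drop zero-variance ones, fit PCA on training rows.

    ``variance_target``: a fraction in (0, 1] selects the smallest component
    count whose cumulative explained variance reaches it; an integer fixes
    the count.  Either way the count is capped at n_cases - 1.
    """
    X = table.X
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 rows to fit the reducer")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    kept = np.flatnonzero(std > 0)
    dropped = np.flatnonzero(std == 0)
    if kept.size == 0:
        raise ValueError("all feature columns are constant")
    Z = (X[:, kept] - mean[kept]) / std[kept]
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    ratios = pca.explained_variance_ratio_
    cap = min(n - 1, kept.size)
    if isinstance(variance_target, (int, np.integer)) and not isinstance(variance_target, bool):
        k = int(variance_target)
    else:
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, float(variance_target) - 1e-12) + 1)
    k = max(1, min(k, cap, len(ratios)))
    return ReducerModel(
        mean=mean,
        std=std,
        kept_columns=kept,
        components=pca.components_[:k],
        explained_variance_ratio=ratios[:k],
        n_components=k,
        dropped_columns=dropped,
    )


def transform(reducer: ReducerModel, X: np.ndarray | FeatureTable) -> np.ndarray:
    if isinstance(X, FeatureTable):
        X = X.X
    X = np.asarray(X, float)
    if X.shape[1] != reducer.mean.size:
        raise ValueError(
            f"dimension mismatch: fitted on {reducer.mean.size} columns, got {X.shape[1]}"
        )
    kept = reducer.kept_columns
    Z = (X[:, kept] - reducer.mean[kept]) / reducer.std[kept]
    return Z @ reducer.components.T


@dataclass
class ClassifierModel:
    backend: str
    estimator: object
    n_features: int
    # input standardization fitted on the training rows: PCA projections have
    # variance proportional to their eigenvalue, so without this the RBF
    # distance is dominated by the top (often nuisance) components
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None


def _make_estimator(backend: str, seed: int):
    if backend == "svm":
        return SVC(C=1.0, kernel="rbf", gamma="scale", class_weight="balanced",
                   random_state=seed)
    if backend == "rf":
        return RandomForestClassifier(n_estimators=500, class_weight="balanced",
                                      random_state=seed)
    if backend == "gbm":
        return GradientBoostingClassifier(n_estimators=200, learning_rate=0.1,
                                          random_state=seed)
    if backend == "mlp":
        # "three-layer nonlinear perceptron": two hidden layers, widths 64/16
        return MLPClassifier(hidden_layer_sizes=(64, 16), max_iter=2000,
                             random_state=seed)
    raise ValueError(f"backend must be one of {BACKENDS}")


def fit_classifier(Z: np.ndarray, y: np.ndarray, backend: str = "svm",
                   seed: int = 0) -> ClassifierModel:
    Z = np.asarray(Z, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a classifier")
    mean = Z.mean(axis=0)
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    Zs = (Z - mean) / scale
    est = _make_estimator(backend, seed)
    if backend == "gbm":
        # inverse-frequency sample weights (GBM has no class_weight argument)
        counts = np.bincount(y, minlength=2)
        w = (len(y) / (2.0 * counts))[y]
        est.fit(Zs, y, sample_weight=w)
    else:
        est.fit(Zs, y)
    return ClassifierModel(backend=backend, estimator=est, n_features=Z.shape[1],
                           input_mean=mean, input_scale=scale)


def predict_scores(model: ClassifierModel, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores (higher = class 1) and hard labels."""
    Z = np.asarray(Z, float)
    if Z.size == 0:
        return np.array([]), np.array([], int)
    if Z.shape[1] != model.n_features:
        raise ValueError(
            f"dimension mismatch: fitted on {model.n_features} features, got {Z.shape[1]}"
        )
    if model.input_mean is not None:
        Z = (Z - model.input_mean) / model.input_scale
    if model.backend == "svm":
        scores = model.estimator.decision_function(Z)
        hard = (scores > 0).astype(int)
    else:
        scores = model.estimator.predict_proba(Z)[:, 1]
        hard = (scores > 0.5).astype(int)
    return scores, hard


def fuse_modalities(tables: list[FeatureTable], strategy: str = "feature_concat"):
    """Case-wise fusion across modalities.

    ``feature_concat`` returns one wide FeatureTable; ``score_average``
    expects per-modality score arrays instead of tables (see
    ``average_scores``).
    """
    if strategy != "feature_concat":
        raise ValueError("fuse_modalities fuses tables; use average_scores for scores")
    ids = tables[0].case_ids
    y = tables[0].y
    for t in tables[1:]:
        if t.case_ids != ids or not np.array_equal(t.y, y):
            raise ValueError("case ordering/labels differ across modality tables")
    return FeatureTable(
        X=np.concatenate([t.X for t in tables], axis=1),
        y=y.copy(),
        case_ids=list(ids),
        modality="+".join(t.modality for t in tables),
    )


def average_scores(score_lists) -> np.ndarray:
    scores = np.stack([np.asarray(s, float) for s in score_lists])
    if len({s.size for s in scores}) != 1:
        raise ValueError("score lists differ in length")
    return scores.mean(axis=0)
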