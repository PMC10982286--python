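"""ML-GCS (multiclass) and ML-ISS (regression) models.

GCS is modeled over its 13 integer classes (3..15) and ISS as a regression
on exact values.  Class imbalance is handled by inverse-frequency case
weights computed on coarsened categories (GCS: mild/moderate/severe; ISS:
mild/moderate/severe/profound), so each coarse category carries equal total
weight.  Hyperparameters are tuned by randomized search with k-fold
cross-validation, replicated with fresh draws; the best configuration and
its CV score are retained on the fitted model.

Model kinds: ``gbt`` (XGBoost, receives missing values natively), ``rf``
(random forest, median-imputed), ``linear`` (elastic-net penalized logistic
regression for GCS / elastic-net regression for ISS, median-imputed and
standardized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.impute import SimpleImputer
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import KFold, ParameterSampler
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .categories import GCS_CATEGORIES, ISS_CATEGORIES

__all__ = [
    "GCS_CLASSES",
    "SeverityEstimate",
    "TuningConfig",
    "SeverityModel",
    "compute_case_weights",
    "train_gcs_model",
    "train_iss_model",
    "predict_severity",
    "variable_importance",
]

GCS_CLASSES = np.arange(3, 16)


@dataclass
class SeverityEstimate:
    """Per-patient severity estimate."""

    gcs_class_probs: np.ndarray  # over classes 3..15, sums to 1
    gcs_point_estimate: int
    iss_estimate: float

    def __post_init__(self):
        p = np.asarray(self.gcs_class_probs, dtype=float)
        if p.size != GCS_CLASSES.size or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("gcs_class_probs must be a simplex over 13 classes")
        if not 3 <= self.gcs_point_estimate <= 15:
            raise ValueError("gcs_point_estimate out of range")
        if not 1.0 <= self.iss_estimate <= 75.0:
            raise ValueError("iss_estimate out of range")


@dataclass(frozen=True)
class TuningConfig:
    """Randomized-search budget and spaces.

    Defaults mirror the reference tuning protocol (five-fold CV, 10
    replicates); pipeline experiments typically pass a smaller desk-scale
    budget.
    """

    model_kind: str = "gbt"
    n_draws: int = 50
    folds: int = 5
    replicates: int = 10
    seed: int = 0
    search_space: Optional[dict] = None

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.model_kind not in ("gbt", "rf", "linear"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")


_TREE_SPACE = {
    "n_estimators": [40, 60, 80, 120, 160],
    "max_depth": [3, 4, 5, 6],
    "learning_rate": [0.05, 0.1, 0.2, 0.3],
    "colsample_bytree": [0.5, 0.7, 0.9, 1.0],
}
_RF_SPACE = {
    "n_estimators": [100, 200, 300],
    "max_depth": [4, 6, 8, None],
    "max_features": [0.3, 0.5, 0.8, "sqrt"],
}
_LINEAR_SPACE = {
    "penalty_weight": [0.001, 0.01, 0.1, 1.0, 10.0],
    "l1_ratio": [0.0, 0.25, 0.5, 0.75, 1.0],
}


def compute_case_weights(labels: Sequence[int], task: str) -> np.ndarray:
    """Inverse-category-frequency case weights.

    Labels are coarsened (GCS -> 3 TBI categories, ISS -> 4 categories) and
    each case receives N / (K * count(category)), K the number of non-empty
    categories, so the weighted mass of every category equals N / K exactly.
    """
    labels = np.asarray(labels)
    if task == "gcs":
        cats = GCS_CATEGORIES(labels)
        n_cat = 3
    elif task == "iss":
        cats = ISS_CATEGORIES(labels)
        n_cat = 4
    else:
        raise ValueError(f"task must be 'gcs' or 'iss', got {task!r}")
    counts = np.bincount(cats, minlength=n_cat)
    present = counts > 0
    k = int(present.sum())
    if k < n_cat:
        warnings.warn(
            f"{task}: empty categories {np.nonzero(~present)[0].tolist()} "
            "contribute no weight constraint"
        )
    n = labels.size
    w = np.zeros(n_cat, dtype=float)
    w[present] = n / (k * counts[present])
    return w[cats]


class _EncodedXGBClassifier:
    """XGBClassifier accepting non-consecutive integer labels (a CV training
    fold can miss a rare class)."""

    def __init__(self, **params):
        import xgboost as xgb

        self._est = xgb.XGBClassifier(**params)
        self.classes_ = None

    def fit(self, X, y, sample_weight=None):
        self.classes_ = np.unique(y)
        enc = np.searchsorted(self.classes_, y)
        self._est.fit(X, enc, sample_weight=sample_weight)
        return self

    def predict_proba(self, X):
        return self._est.predict_proba(X)

    def predict(self, X):
        return self.classes_[self._est.predict(X)]


def _make_estimator(kind: str, task: str, params: dict, seed: int):
    if kind == "gbt":
        import xgboost as xgb

        common = dict(tree_method="hist", n_jobs=1, random_state=seed, verbosity=0)
        if task == "gcs":
            return _EncodedXGBClassifier(**common, **params)
        return xgb.XGBRegressor(**common, **params)
    if kind == "rf":
        cls = RandomForestClassifier if task == "gcs" else RandomForestRegressor
        est = cls(n_jobs=1, random_state=seed, **params)
        return make_pipeline(SimpleImputer(strategy="median"), est)
    # linear: elastic-net logistic (classification) / elastic-net (regression)
    alpha = params.get("penalty_weight", 1.0)
    l1 = params.get("l1_ratio", 0.5)
    if task == "gcs":
        est = LogisticRegression(
            solver="saga",
            C=1.0 / max(alpha, 1e-12),
            l1_ratio=l1,
            max_iter=2000,
            random_state=seed,
        )
    else:
        est = ElasticNet(alpha=alpha, l1_ratio=l1, max_iter=5000, random_state=seed)
    return make_pipeline(
        SimpleImputer(strategy="median"), StandardScaler(), est
    )


def _micro_auc(y_true_enc: np.ndarray, probs: np.ndarray, n_classes: int, w=None) -> float:
    from .evaluation import binary_auc

    onehot = np.zeros((y_true_enc.size, n_classes))
    onehot[np.arange(y_true_enc.size), y_true_enc] = 1.0
    ww = None if w is None else np.repeat(w, n_classes)
    return binary_auc(probs.ravel(), onehot.ravel(), sample_weight=ww)


@dataclass
class SeverityModel:
    """Fitted model wrapper with feature schema and tuning log."""

    task: str  # "gcs" | "iss"
    kind: str
    estimator: object
    feature_names: list[str]
    classes_: Optional[np.ndarray] = None  # present GCS classes
    best_params: dict = field(default_factory=dict)
    cv_score: float = np.nan
    tuning_log: list = field(default_factory=list)

    def _check_schema(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        extra = [c for c in X.columns if c not in self.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing={missing}, extra={extra}"
            )
        return X[self.feature_names].to_numpy(dtype=float)

    def predict_gcs_probs(self, X: pd.DataFrame) -> np.ndarray:
        """Probability matrix over the full 3..15 class range (absent
        training classes get zero probability)."""
        assert self.task == "gcs"
        arr = self._impute(self._check_schema(X))
        raw = self.estimator.predict_proba(arr)
        out = np.zeros((arr.shape[0], GCS_CLASSES.size))
        for j, cls in enumerate(self.classes_):
            out[:, int(cls) - 3] = raw[:, j]
        out /= out.sum(axis=1, keepdims=True)
        return out

    def predict_iss(self, X: pd.DataFrame) -> np.ndarray:
        assert self.task == "iss"
        arr = self._impute(self._check_schema(X))
        return np.clip(self.estimator.predict(arr), 1.0, 75.0)

    def _impute(self, arr: np.ndarray) -> np.ndarray:
        # trees route NaN natively; sklearn pipelines impute internally
        return arr

    def score(self, X: pd.DataFrame, y: np.ndarray) -> float:
        """Micro one-vs-rest AUC (gcs) or Spearman correlation (iss)."""
        if self.task == "gcs":
            enc = np.searchsorted(GCS_CLASSES, np.asarray(y))
            return _micro_auc(enc, self.predict_gcs_probs(X), GCS_CLASSES.size)
        rho = spearmanr(self.predict_iss(X), y).statistic
        return float(rho)


def _random_search(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    task: str,
    tuning: TuningConfig,
    score_fn,
):
    space = tuning.search_space or (
        _LINEAR_SPACE
        if tuning.model_kind == "linear"
        else (_RF_SPACE if tuning.model_kind == "rf" else _TREE_SPACE)
    )
    log = []
    best = None
    for rep in range(tuning.replicates):
        rep_seed = tuning.seed + 1000 * rep
        sampler = ParameterSampler(space, n_iter=tuning.n_draws, random_state=rep_seed)
        kf = KFold(n_splits=tuning.folds, shuffle=True, random_state=rep_seed)
        splits = list(kf.split(X))
        for params in sampler:
            scores = []
            for tr, va in splits:
                est = _make_estimator(tuning.model_kind, task, params, rep_seed)
                _fit(est, X[tr], y[tr], w[tr], tuning.model_kind)
                scores.append(score_fn(est, X[va], y[va], w[va]))
            mean_score = float(np.mean(scores))
            log.append({"params": params, "cv_score": mean_score, "replicate": rep})
            if best is None or mean_score > best[0]:
                best = (mean_score, params, rep_seed)
    return best, log


def _fit(est, X, y, w, kind):
    if kind in ("rf", "linear"):
        # sample weights must reach the final pipeline step
        est.fit(X, y, **{f"{est.steps[-1][0]}__sample_weight": w})
    else:
        est.fit(X, y, sample_weight=w)


def train_gcs_model(
    features: pd.DataFrame,
    gcs_labels: Sequence[int],
    weights: Optional[np.ndarray] = None,
    tuning: TuningConfig = TuningConfig(),
) -> SeverityModel:
    """Fit the multiclass ML-GCS model with randomized-search CV tuning.

    CV selection metric: case-weighted micro one-vs-rest AUC.  Classes
    absent from training are predicted with zero probability (a warning is
    emitted).
    """
    y = np.asarray(gcs_labels, dtype=int)
    if np.any((y < 3) | (y > 15)):
        raise ValueError("gcs labels must be in [3, 15]")
    w = np.asarray(weights, dtype=float) if weights is not None else np.ones(y.size)
    X = features.to_numpy(dtype=float)
    classes_present = np.unique(y)
    if classes_present.size < GCS_CLASSES.size:
        warnings.warn(
            f"GCS classes absent from training data: "
            f"{sorted(set(GCS_CLASSES.tolist()) - set(classes_present.tolist()))}"
        )
    enc = np.searchsorted(classes_present, y)

    def score_fn(est, Xv, yv, wv):
        probs = est.predict_proba(Xv)
        # validation folds can miss classes; expand to training classes
        full = np.zeros((Xv.shape[0], classes_present.size))
        for j, cls in enumerate(est.classes_):
            full[:, int(cls)] = probs[:, j]
        return _micro_auc(yv, full, classes_present.size, w=wv)

    best, log = _random_search(X, enc, w, "gcs", tuning, score_fn)
    cv_score, params, seed = best
    est = _make_estimator(tuning.model_kind, "gcs", params, tuning.seed)
    _fit(est, X, enc, w, tuning.model_kind)
    model = SeverityModel(
        task="gcs",
        kind=tuning.model_kind,
        estimator=est,
        feature_names=list(features.columns),
        classes_=classes_present,
        best_params=params,
        cv_score=cv_score,
        tuning_log=log,
    )
    return model


def train_iss_model(
    features: pd.DataFrame,
    iss_labels: Sequence[float],
    weights: Optional[np.ndarray] = None,
    tuning: TuningConfig = TuningConfig(),
) -> SeverityModel:
    """Fit the ML-ISS regression model (weighted squared error; CV metric is
    the negative weighted RMSE)."""
    y = np.asarray(iss_labels, dtype=float)
    w = np.asarray(weights, dtype=float) if weights is not None else np.ones(y.size)
    X = features.to_numpy(dtype=float)

    def score_fn(est, Xv, yv, wv):
        pred = est.predict(Xv)
        return -float(np.sqrt(np.average((pred - yv) ** 2, weights=wv)))

    best, log = _random_search(X, y, w, "iss", tuning, score_fn)
    cv_score, params, seed = best
    est = _make_estimator(tuning.model_kind, "iss", params, tuning.seed)
    _fit(est, X, y, w, tuning.model_kind)
    return SeverityModel(
        task="iss",
        kind=tuning.model_kind,
        estimator=est,
        feature_names=list(features.columns),
        best_params=params,
        cv_score=cv_score,
        tuning_log=log,
    )


def predict_severity(
    gcs_model: SeverityModel, iss_model: SeverityModel, features: pd.DataFrame
) -> list[SeverityEstimate]:
    """Predict GCS class probabilities (argmax point estimate; ties resolve
    to the lowest = most severe GCS) and the clamped ISS estimate."""
    probs = gcs_model.predict_gcs_probs(features)
    iss = iss_model.predict_iss(features)
    out = []
    for p, i in zip(probs, iss):
        point = int(GCS_CLASSES[int(np.argmax(p))])  # argmax -> first max -> lowest
        out.append(SeverityEstimate(p, point, float(i)))
    return out


def variable_importance(
    model: SeverityModel,
    features: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance on held-out data.

    Each feature column is permuted ``n_repeats`` times (seeded) and the
    drop of the model's score (micro AUC for GCS, Spearman for ISS) is
    averaged.  Direction is summarized by the Spearman correlation of the
    feature with the model prediction.  Returns a DataFrame sorted by
    importance (rank 1 = most important).
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rng = np.random.default_rng(seed)
    base = model.score(features, y)
    pred = (
        model.predict_iss(features)
        if model.task == "iss"
        else model.predict_gcs_probs(features) @ GCS_CLASSES
    )
    rows = []
    Xp = features.copy()
    for col in features.columns:
        orig = Xp[col].to_numpy().copy()
        drops = []
        for _ in range(n_repeats):
            Xp[col] = rng.permutation(orig)
            drops.append(base - model.score(Xp, y))
        Xp[col] = orig
        vals = features[col].to_numpy()
        ok = np.isfinite(vals)
        direction = (
            float(spearmanr(vals[ok], np.asarray(pred)[ok]).statistic)
            if ok.sum() > 2 and np.unique(vals[ok]).size > 1
            else np.nan
        )
        rows.append(
            {
                "feature": col,
                "importance": float(np.mean(drops)),
                "importance_sd": float(np.std(drops)),
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows).sort_values("importance", ascending=False)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
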