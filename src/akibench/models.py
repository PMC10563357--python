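"""Classifier training, calibration and threshold selection.

Four families (logistic regression, random forest, gradient boosting,
single-hidden-layer perceptron), each tuned by 5-fold cross-validation
for f1 with positive-class up-sampling applied *inside* each fold's
training part only — validation folds, the validation partition and the
test partition never contain duplicated rows.

Calibration is a Platt sigmoid map fitted on the validation partition
(isotonic available behind a flag); the decision threshold is the f1
maximiser over the validation probabilities, ties broken toward the
larger threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier


@dataclass(frozen=True)
class SplitConfig:
    """60/20/20 train/validation/test split, stratified on the outcome."""

    ratios: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")


def split_data(y: pd.Series, config: SplitConfig = SplitConfig()) -> pd.Series:
    """Partition tags ('train'/'validation'/'test') indexed like ``y``.

    Deterministic under the seed; stratification keeps outcome
    prevalence aligned across partitions.
    """
    n = len(y)
    if n < 50:
        raise ValueError(f"need at least 50 rows to split, got {n}")
    rng = np.random.default_rng(config.seed)
    n_test = int(round(config.ratios[2] * n))
    n_val = int(round(config.ratios[1] * n))

    order = np.arange(n)
    if config.stratified:
        tags = np.empty(n, dtype=object)
        for cls in np.unique(y.to_numpy()):
            idx = np.flatnonzero(y.to_numpy() == cls)
            rng.shuffle(idx)
            share = len(idx) / n
            k_test = int(round(n_test * share))
            k_val = int(round(n_val * share))
            tags[idx[:k_test]] = "test"
            tags[idx[k_test : k_test + k_val]] = "validation"
            tags[idx[k_test + k_val :]] = "train"
    else:
        rng.shuffle(order)
        tags = np.empty(n, dtype=object)
        tags[order[:n_test]] = "test"
        tags[order[n_test : n_test + n_val]] = "validation"
        tags[order[n_test + n_val :]] = "train"

    part = pd.Series(tags, index=y.index, name="partition")
    for p in ("train", "validation", "test"):
        sub = y[part == p]
        if sub.nunique() < 2:
            warnings.warn(f"partition {p!r} contains a single outcome class")
    return part


# ---------------------------------------------------------------------------
# model registry and tuning
# ---------------------------------------------------------------------------

DEFAULT_GRIDS: Dict[str, List[dict]] = {
    "LR": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "RF": [
        {"n_estimators": 200, "max_depth": d, "min_samples_leaf": leaf}
        for d in (6, None)
        for leaf in (1, 5)
    ],
    # The published best boosting configuration used leaf-wise naming
    # (num_leaves / min_child_samples); mapped to the nearest gradient
    # boosting equivalents (max_leaves under hist growth, min_child_weight).
    "XGB": [
        {
            "n_estimators": 200,
            "max_leaves": 10,
            "grow_policy": "lossguide",
            "min_child_weight": 1,
            "subsample": 0.2,
            "reg_alpha": 50.0,
            "reg_lambda": 0.0,
        },
        {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.1},
        {"n_estimators": 100, "max_depth": 2, "learning_rate": 0.1, "subsample": 0.8},
        {
            "n_estimators": 200,
            "max_depth": 3,
            "learning_rate": 0.05,
            "reg_lambda": 10.0,
            "min_child_weight": 10,
        },
    ],
    "ANN": [
        {"hidden_layer_sizes": (16,), "max_iter": 400},
        {"hidden_layer_sizes": (64,), "max_iter": 400},
    ],
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with its hyperparameter search space."""

    family: str  # LR | RF | XGB | ANN
    grid: Optional[List[dict]] = None
    cv_folds: int = 5
    objective: str = "f1"

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model family {self.family!r}")

    def search_space(self) -> List[dict]:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]


def _make_estimator(family: str, params: dict, seed: int):
    if family == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "XGB":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            **params,
        )
    if family == "ANN":
        return MLPClassifier(random_state=seed, **params)
    raise ValueError(family)


def upsample_positives(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Duplicate positive rows (with replacement) up to a 1:1 ratio.

    Negative rows are untouched; if positives already reach parity the
    data is returned as-is.
    """
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("up-sampling requires both classes")
    if pos.size >= neg.size:
        return X, y
    extra = rng.choice(pos, size=neg.size - pos.size, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X[idx], y[idx]


def tune_and_train(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ModelSpec,
    seed: int = 0,
):
    """Grid search by mean cross-validated f1, then refit on the full
    (up-sampled) training partition.

    Up-sampling happens inside each fold's training part only, so every
    fold's validation part is untouched original data.
    """
    Xa, ya = X.to_numpy(), y.to_numpy().astype(int)
    if len(np.unique(ya)) < 2:
        raise ValueError("training data contains a single class")
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xa, ya))

    results = []
    for gi, params in enumerate(spec.search_space()):
        fold_f1 = []
        for fi, (tr, va) in enumerate(folds):
            rng = np.random.default_rng(np.random.SeedSequence([seed, gi, fi]))
            Xu, yu = upsample_positives(Xa[tr], ya[tr], rng)
            est = _make_estimator(spec.family, params, seed)
            est.fit(Xu, yu)
            pred = (est.predict_proba(Xa[va])[:, 1] >= 0.5).astype(int)
            fold_f1.append(f1_score(ya[va], pred, zero_division=0))
        results.append({"params": params, "mean_f1": float(np.mean(fold_f1))})

    best = max(results, key=lambda r: r["mean_f1"])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 987]))
    Xu, yu = upsample_positives(Xa, ya, rng)
    model = _make_estimator(spec.family, best["params"], seed)
    model.fit(Xu, yu)
    return model, best["params"], pd.DataFrame(results)


# ---------------------------------------------------------------------------
# calibration and thresholding
# ---------------------------------------------------------------------------

class _SigmoidMap:
    """Platt scaling: p' = sigmoid(a·s + b) with a >= 0 enforced on scores."""

    def __init__(self, a: float, b: float) -> None:
        self.a, self.b = a, b

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(self.a * np.asarray(scores) + self.b)))


class _IdentityMap:
    def __call__(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float)


@dataclass
class CalibratedModel:
    """Fitted classifier + validation-fitted monotone calibration map."""

    estimator: object
    calibration: object
    threshold: Optional[float] = None

    def raw_scores(self, X) -> np.ndarray:
        X = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X)
        return self.estimator.predict_proba(X)[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        return np.clip(self.calibration(self.raw_scores(X)), 0.0, 1.0)

    def predict(self, X) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("no decision threshold selected yet")
        return (self.predict_proba(X) >= self.threshold).astype(int)


def calibrate(
    estimator,
    X_val: pd.DataFrame,
    y_val: pd.Series,
    method: str = "sigmoid",
) -> CalibratedModel:
    """Fit a monotone probability-calibration map on the validation set."""
    yv = np.asarray(y_val).astype(int)
    if len(np.unique(yv)) < 2:
        raise ValueError("calibration requires both classes in validation data")
    scores = estimator.predict_proba(
        X_val.to_numpy() if hasattr(X_val, "to_numpy") else np.asarray(X_val)
    )[:, 1]
    if np.ptp(scores) < 1e-12:
        warnings.warn("constant classifier scores; calibration map left as identity")
        return CalibratedModel(estimator, _IdentityMap())
    if method == "isotonic":
        iso = IsotonicRegression(out_of_bounds="clip", y_min=0.0, y_max=1.0)
        iso.fit(scores, yv)
        return CalibratedModel(estimator, iso.predict)
    if method != "sigmoid":
        raise ValueError(f"unknown calibration method {method!r}")
    lr = LogisticRegression(C=1e10, max_iter=2000)
    lr.fit(scores.reshape(-1, 1), yv)
    a = float(lr.coef_[0, 0])
    b = float(lr.intercept_[0])
    if a < 0:
        warnings.warn("anti-monotone calibration fit; map forced to identity")
        return CalibratedModel(estimator, _IdentityMap())
    return CalibratedModel(estimator, _SigmoidMap(a, b))


def select_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """f1-maximising threshold over all distinct probability values.

    Classification rule is ``p >= threshold``; ties in f1 are broken
    toward the larger threshold so the positive call is as conservative
    as the optimum allows.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    best_thr, best_f1 = None, -1.0
    for thr in np.unique(probs):
        pred = (probs >= thr).astype(int)
        score = f1_score(labels, pred, zero_division=0)
        if score >= best_f1:
            best_f1, best_thr = score, float(thr)
    return best_thr
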