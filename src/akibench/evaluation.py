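"""Discriminative metrics, calibration error metrics and the
cross-baseline statistical comparison.

Calibration metrics follow the standard definitions: ECE is the
bin-weighted mean absolute gap between predicted probability and
observed event rate over equal-width bins; the Brier score is the mean
squared probability error; the calibration slope is the maximum
likelihood slope of a univariate logistic model of the outcome on the
logit of the predicted probability (1.0 = calibrated spread).

The comparison machinery bootstraps per-model f1 distributions on the
test set (500 with-replacement resamples by default) and runs one-way
ANOVA plus Tukey's honestly-significant-difference pairwise test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd

_EPS = 1e-6


@dataclass
class MetricReport:
    """Per-model metric bundle; unset entries stay None."""

    auc: Optional[float] = None
    recall: Optional[float] = None
    precision: Optional[float] = None
    f1: Optional[float] = None
    ece: Optional[float] = None
    brier: Optional[float] = None
    calibration_slope: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass(frozen=True)
class ComparisonConfig:
    """Bootstrap/ANOVA settings for the cross-baseline comparison.

    ``subsample_size=None`` resamples at full test-set size; the
    alternative reading (500-record subsets) is available by setting it
    explicitly.
    """

    n_bootstrap: int = 500
    subsample_size: Optional[int] = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return probs


def discriminative_metrics(
    probs: np.ndarray, threshold: float, labels: np.ndarray
) -> MetricReport:
    """AUC plus precision/recall/f1 at the supplied threshold.

    Zero-denominator conventions: precision, recall and f1 are 0 when
    undefined.  AUC is None (flagged) for single-class labels.
    """
    probs = _check_probs(probs)
    labels = np.asarray(labels).astype(int)
    pred = (probs >= threshold).astype(int)
    if np.unique(labels).size < 2:
        warnings.warn("single-class labels: AUC undefined")
        auc = None
    else:
        auc = float(roc_auc_score(labels, probs))
    return MetricReport(
        auc=auc,
        recall=float(recall_score(labels, pred, zero_division=0)),
        precision=float(precision_score(labels, pred, zero_division=0)),
        f1=float(f1_score(labels, pred, zero_division=0)),
    )


def ece(probs: np.ndarray, labels: np.ndarray, n_bins: int = 10) -> float:
    """Estimated calibration error over equal-width probability bins."""
    probs = _check_probs(probs)
    labels = np.asarray(labels).astype(float)
    n = probs.size
    if n == 0:
        raise ValueError("empty prediction set")
    bins = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    total = 0.0
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            continue
        gap = abs(probs[mask].mean() - labels[mask].mean())
        total += mask.sum() / n * gap
    return float(total)


def brier(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared difference between probability and {0,1} outcome."""
    probs = _check_probs(probs)
    labels = np.asarray(labels).astype(float)
    return float(np.mean((probs - labels) ** 2))


def calibration_slope(probs: np.ndarray, labels: np.ndarray) -> float:
    """MLE slope of outcome on logit(prob); 1.0 indicates calibrated spread."""
    probs = np.clip(_check_probs(probs), _EPS, 1.0 - _EPS)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("calibration slope requires both outcome classes")
    logits = np.log(probs / (1.0 - probs))
    if np.ptp(logits) < 1e-12:
        raise ValueError("constant probabilities: slope undefined")
    design = sm.add_constant(logits)
    try:
        fit = sm.Logit(labels, design).fit(disp=0)
    except Exception as exc:  # non-convergence / separation
        warnings.warn(f"calibration slope fit failed: {exc}")
        return float("nan")
    return float(fit.params[1])


def calibration_report(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> MetricReport:
    """ECE, Brier and slope in one report."""
    return MetricReport(
        ece=ece(probs, labels, n_bins),
        brier=brier(probs, labels),
        calibration_slope=calibration_slope(probs, labels),
    )


def bootstrap_f1(
    probs: np.ndarray,
    threshold: float,
    labels: np.ndarray,
    config: ComparisonConfig = ComparisonConfig(),
) -> np.ndarray:
    """f1 on with-replacement resamples of the test set.

    Resamples with zero predicted or true positives score 0 (the f1
    zero-denominator convention).
    """
    probs = _check_probs(probs)
    labels = np.asarray(labels).astype(int)
    n = probs.size
    if n == 0:
        raise ValueError("empty test set")
    size = config.subsample_size or n
    pred = (probs >= threshold).astype(int)
    rng = np.random.default_rng(config.seed)
    out = np.empty(config.n_bootstrap)
    for i in range(config.n_bootstrap):
        idx = rng.integers(0, n, size)
        out[i] = f1_score(labels[idx], pred[idx], zero_division=0)
    return out


def anova_tukey(groups: Dict[str, np.ndarray], alpha: float = 0.05):
    """One-way ANOVA + Tukey HSD pairwise comparison of f1 vectors.

    Parameters
    ----------
    groups
        Mapping of group name (e.g. baseline method) to its bootstrap f1
        vector; lengths may differ, each must be >= 2.

    Returns
    -------
    (f_statistic, p_value, table)
        ``table`` has one row per unordered pair: mean difference,
        Tukey-adjusted p-value and a flag at ``p <= alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if np.ptp(arr) == 0.0:
            warnings.warn(f"group {name!r} has zero variance")

    f_stat, f_p = stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    tags = np.concatenate([[name] * arr.size for name, arr in arrays.items()])
    hsd = pairwise_tukeyhsd(values, tags, alpha=alpha)
    summary = hsd.summary().data
    table = pd.DataFrame(summary[1:], columns=summary[0])
    table["significant"] = table["p-adj"] <= alpha
    return float(f_stat), float(f_p), table
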