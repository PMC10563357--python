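"""Error auditing: confusion partition, additive break-down and
ordering-averaged Shapley attributions, and the relabel-and-retrain
experiment on the false-positive cohort.

Attributions use the marginal (interventional) value function: v(S) is
the mean model output over a background sample with the features in S
fixed to the audited instance's values.  A break-down report gives the
sequential conditional contributions for one feature ordering; the
Shapley report averages them over uniformly random orderings.  Both are
exactly additive: intercept + sum(contributions) = prediction.

False positives — admissions the model flags that KDIGO labels negative
— are the alert-fatigue cohort; ``relabel_experiment`` re-labels the
data under the modified baseline definitions, retrains, and reports how
many original false positives become true positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class AttributionReport:
    """Additive decomposition of one prediction."""

    instance_id: object
    intercept: float  # mean model output over the background
    contributions: pd.Series  # per-feature, ordered or order-averaged
    prediction: float
    kind: str = "breakdown"  # breakdown | shapley

    def additivity_gap(self) -> float:
        return abs(self.intercept + self.contributions.sum() - self.prediction)


def confusion_partition(
    predictions: np.ndarray, labels: np.ndarray, index: Optional[pd.Index] = None
) -> Dict[str, np.ndarray]:
    """Exhaustive disjoint split into TP / FP / TN / FN id sets."""
    pred = np.asarray(predictions).astype(int)
    lab = np.asarray(labels).astype(int)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must align")
    ids = np.asarray(index) if index is not None else np.arange(pred.size)
    return {
        "TP": ids[(pred == 1) & (lab == 1)],
        "FP": ids[(pred == 1) & (lab == 0)],
        "TN": ids[(pred == 0) & (lab == 0)],
        "FN": ids[(pred == 0) & (lab == 1)],
    }


def _ordering_contributions(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    instance: np.ndarray,
    ordering: Sequence[int],
    background: np.ndarray,
) -> tuple:
    """(v0, per-feature deltas) for one feature ordering.

    Builds the p+1 progressively-fixed background copies and evaluates
    the model once on the stacked matrix.
    """
    n_bg, p = background.shape
    stack = np.tile(background, (p + 1, 1))
    for step, j in enumerate(ordering, start=1):
        for later in range(step, p + 1):
            stack[later * n_bg : (later + 1) * n_bg, j] = instance[j]
    v = predict_fn(stack).reshape(p + 1, n_bg).mean(axis=1)
    deltas = np.diff(v)
    return float(v[0]), deltas


def breakdown_attribution(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    instance: pd.Series,
    ordering: Sequence[str],
    background: pd.DataFrame,
    instance_id: object = None,
) -> AttributionReport:
    """Sequential conditional contributions for one explicit ordering.

    Contribution of feature j (at its position in ``ordering``) is
    v(S ∪ {j}) − v(S), S the set of features fixed before it.  The
    representation is ordering-dependent whenever the model has
    interactions; that non-uniqueness is the reason the Shapley average
    exists.
    """
    cols = list(background.columns)
    unknown = [f for f in ordering if f not in cols]
    if unknown:
        raise ValueError(f"unknown features in ordering: {unknown}")
    if len(set(ordering)) != len(cols):
        raise ValueError("ordering must be a permutation of the feature set")
    if len(background) == 0:
        raise ValueError("background sample is empty")
    order_idx = [cols.index(f) for f in ordering]
    v0, deltas = _ordering_contributions(
        predict_fn, instance[cols].to_numpy(dtype=float), order_idx,
        background.to_numpy(dtype=float),
    )
    contrib = pd.Series(deltas, index=list(ordering), name="contribution")
    return AttributionReport(
        instance_id=instance_id,
        intercept=v0,
        contributions=contrib,
        prediction=v0 + float(deltas.sum()),
        kind="breakdown",
    )


def shapley_attribution(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    instance: pd.Series,
    background: pd.DataFrame,
    n_orderings: int = 25,
    seed: int = 0,
    instance_id: object = None,
) -> AttributionReport:
    """Monte-Carlo Shapley values: break-down contributions averaged
    over uniformly random feature orderings."""
    if n_orderings < 1:
        raise ValueError("n_orderings must be >= 1")
    cols = list(background.columns)
    p = len(cols)
    x = instance[cols].to_numpy(dtype=float)
    bg = background.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    total = np.zeros(p)
    v0 = 0.0
    for _ in range(n_orderings):
        ordering = rng.permutation(p)
        v0, deltas = _ordering_contributions(predict_fn, x, ordering, bg)
        total[ordering] += deltas
    contrib = pd.Series(total / n_orderings, index=cols, name="shapley")
    return AttributionReport(
        instance_id=instance_id,
        intercept=v0,
        contributions=contrib,
        prediction=v0 + float(contrib.sum()),
        kind="shapley",
    )


def global_importance(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    instances: pd.DataFrame,
    background: pd.DataFrame,
    n_orderings: int = 25,
    seed: int = 0,
) -> pd.Series:
    """Mean |Shapley attribution| per feature over an instance set,
    descending — the global ranking behind feature-importance plots."""
    if len(instances) == 0:
        raise ValueError("instance set is empty")
    acc = np.zeros(background.shape[1])
    for k, (iid, row) in enumerate(instances.iterrows()):
        rep = shapley_attribution(
            predict_fn, row, background, n_orderings,
            seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)),
            instance_id=iid,
        )
        acc += np.abs(rep.contributions.to_numpy())
    imp = pd.Series(acc / len(instances), index=background.columns, name="mean_abs_shapley")
    return imp.sort_values(ascending=False)


def relabel_experiment(
    bundle,
    reference_result,
    fp_ids: Sequence,
    methods: Sequence = ("M1_min_180to7_or_mdrd", "M2_min_180to0_or_mdrd", "M3_mean_180to0_or_mdrd"),
    seed: int = 0,
    family: str = "XGB",
) -> Dict[str, dict]:
    """Relabel under modified baseline definitions, retrain, evaluate.

    For each modified method: rebuild the cohort (same exclusion
    cascade), retrain/calibrate/threshold the reference family, and
    report test metrics, the f1 delta against the reference run, and the
    fraction of the original false-positive admissions whose KDIGO label
    becomes positive under the new baseline.
    """
    from .baselines import BaselineMethod
    from .pipeline import run_single

    fp_ids = list(fp_ids)
    out: Dict[str, dict] = {}
    for method in methods:
        method = BaselineMethod(method)
        result = run_single(bundle, method, family=family, seed=seed)
        relabels = result.dataset.labels.set_index("admission_id")
        present = [i for i in fp_ids if i in relabels.index]
        became_positive = (
            float(relabels.loc[present, "outcome"].mean()) if present else float("nan")
        )
        out[method.value] = {
            "result": result,
            "metrics": result.test_metrics,
            "delta_f1": result.test_metrics.f1 - reference_result.test_metrics.f1,
            "fp_relabelled_positive_fraction": became_positive,
        }
    return out
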