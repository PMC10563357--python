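"""Model-ready cohort construction.

Pipeline (mirroring the study design): KDIGO-label every admission
under the active baseline method, apply the exclusion cascade, aggregate
first-24h events into per-admission features, drop columns with more
than 20% missingness, impute the remainder with chained equations and
min-max scale to [0, 1] — with the imputer and scaler fitted on the
training partition only.

The outcome is AKI *first detected* on day 2 or 3: admissions whose
first detection is day 1 are excluded (formula-screened for the
two-stage baseline method, own-baseline detection otherwise), since the
aim is predicting new AKI from first-day data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .baselines import (
    BaselineMethod,
    IneligibleAdmissionError,
    estimate_baseline,
    screening_baseline,
)
from .kdigo import KDIGOThresholds, detect_aki
from .renal import ckdepi_egfr
from .series import MeasurementSeries
from .synthetic_ehr import EHRBundle


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-construction settings."""

    min_age: float = 18.0
    missingness_drop_threshold: float = 0.20
    mice_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.missingness_drop_threshold < 1.0):
            raise ValueError("missingness_drop_threshold must be in (0, 1)")


@dataclass
class CohortDataset:
    """Labelled feature table with partition tags and provenance."""

    X: pd.DataFrame  # rows = admissions (index = admission_id)
    y: pd.Series  # AKI first detected on day 2 or 3
    partition: pd.Series  # train | validation | test
    baseline_method: BaselineMethod
    labels: pd.DataFrame
    exclusion_audit: pd.DataFrame
    dropped_columns: pd.Series
    scaler_params: pd.DataFrame

    def rows(self, part: str) -> pd.Index:
        return self.partition.index[self.partition == part]

    def xy(self, part: str) -> Tuple[pd.DataFrame, pd.Series]:
        idx = self.rows(part)
        return self.X.loc[idx], self.y.loc[idx]


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def _grouped_arrays(df: pd.DataFrame, key: str, cols: Tuple[str, str]) -> dict:
    out = {}
    for aid, g in df.groupby(key, sort=False):
        out[aid] = (g[cols[0]].to_numpy(), g[cols[1]].to_numpy())
    return out


def label_admissions(
    bundle: EHRBundle,
    method: BaselineMethod,
    thresholds: KDIGOThresholds = KDIGOThresholds(),
) -> pd.DataFrame:
    """Estimate the baseline and run KDIGO detection for every admission.

    Returns one row per admission: the baseline value and provenance,
    the KDIGO label, the day-1 flag used for exclusion (evaluated
    against the two-stage method's formula screen where applicable) and
    the day-2/3 outcome.
    """
    method = BaselineMethod(method)
    creat = bundle.icu_events[bundle.icu_events["variable"] == "creatinine"]
    creat_by_adm = _grouped_arrays(creat, "admission_id", ("offset_h", "value"))
    pre_by_adm = _grouped_arrays(bundle.preicu_labs, "admission_id", ("days_before", "value"))
    demo = bundle.admissions.merge(bundle.patients, on="patient_id")

    empty = (np.array([]), np.array([]))
    rows = []
    for adm in demo.itertuples(index=False):
        aid = adm.admission_id
        off, val = creat_by_adm.get(aid, empty)
        series = MeasurementSeries(off, val)
        pre_d, pre_v = pre_by_adm.get(aid, empty)
        try:
            if adm.age < 18:  # adult equations undefined; excluded by age anyway
                raise IneligibleAdmissionError("minor")
            base = estimate_baseline(series, pre_d, pre_v, adm.age, adm.sex, method)
        except IneligibleAdmissionError:
            rows.append(
                dict(admission_id=aid, eligible=False, baseline=np.nan,
                     baseline_source="none", n_baseline_values=0, flagged=False,
                     first_detection_day=np.nan, criterion="none",
                     day1_flag=False, outcome=0)
            )
            continue
        label = detect_aki(series, base.value, thresholds)
        if method is BaselineMethod.B2_mdrd_then_min24h:
            screen_label = detect_aki(series, screening_baseline(base), thresholds)
            day1 = screen_label.flagged and screen_label.first_detection_day == 1
        else:
            day1 = label.flagged and label.first_detection_day == 1
        rows.append(
            dict(
                admission_id=aid,
                eligible=True,
                baseline=base.value,
                baseline_source=base.source,
                n_baseline_values=base.n_values_used,
                flagged=label.flagged,
                first_detection_day=(
                    label.first_detection_day if label.flagged else np.nan
                ),
                criterion=label.criterion or "none",
                day1_flag=bool(day1),
                outcome=int(
                    label.flagged and label.first_detection_day in (2, 3)
                ),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    bundle: EHRBundle,
    labels: pd.DataFrame,
    min_age: float = 18.0,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Ordered exclusion cascade with a per-step audit.

    Steps: adult age -> first ICU stay -> no maintenance RRT ->
    creatinine present on each of days 1, 2 and 3 -> no day-1 AKI.
    """
    demo = bundle.admissions.merge(bundle.patients, on="patient_id")
    demo = demo.set_index("admission_id")
    lab = labels.set_index("admission_id")

    creat = bundle.icu_events[bundle.icu_events["variable"] == "creatinine"].copy()
    creat["day"] = (creat["offset_h"] // 24).astype(int) + 1
    days = creat[creat["day"].isin([1, 2, 3])].groupby("admission_id")["day"].nunique()
    has_d123 = set(days.index[days == 3])

    steps = [
        ("age_lt_min", lambda ids: demo.loc[ids, "age"] >= min_age),
        ("not_first_icu_stay", lambda ids: demo.loc[ids, "stay_number"] == 1),
        ("maintenance_rrt", lambda ids: demo.loc[ids, "rrt"] == 0),
        ("no_scr_days_1_2_3", lambda ids: pd.Series([i in has_d123 for i in ids], index=ids)),
        ("aki_on_day1", lambda ids: ~(lab.loc[ids, "day1_flag"] | ~lab.loc[ids, "eligible"])),
    ]

    ids = pd.Index(demo.index)
    audit_rows = [dict(step="input", n_excluded=0, n_remaining=len(ids))]
    for name, keep_fn in steps:
        keep = keep_fn(ids).to_numpy(dtype=bool)
        audit_rows.append(
            dict(step=name, n_excluded=int((~keep).sum()), n_remaining=int(keep.sum()))
        )
        ids = ids[keep]
    audit = pd.DataFrame(audit_rows)
    if len(ids) == 0:
        warnings.warn("exclusion cascade removed every admission")
    return ids.to_numpy(), audit


# ---------------------------------------------------------------------------
# feature aggregation
# ---------------------------------------------------------------------------

def aggregate_features(bundle: EHRBundle, included_ids: Iterable) -> pd.DataFrame:
    """First-24h min/max aggregates plus demographics and history flags.

    Continuous variables get ``<var>_min``/``<var>_max`` over events in
    hours [0, 24); urine output its first-24h mean; ethnicity is one-hot
    with no reference category dropped; the CKD-EPI eGFR feature is
    computed from the minimum day-1 creatinine.
    """
    ids = pd.Index(included_ids, name="admission_id")
    if len(ids) == 0:
        raise ValueError("included id set is empty")

    demo = bundle.admissions.merge(bundle.patients, on="patient_id")
    demo = demo.set_index("admission_id").loc[ids]

    feats = pd.DataFrame(index=ids)
    feats["age"] = demo["age"]
    feats["sex_female"] = (demo["sex"] == "female").astype(float)
    onehot = pd.get_dummies(demo["ethnicity"], prefix="ethnicity", dtype=float)
    feats = feats.join(onehot)

    ev = bundle.icu_events
    first24 = ev[(ev["offset_h"] < 24.0) & ev["admission_id"].isin(ids)]
    agg = first24.groupby(["admission_id", "variable"])["value"].agg(["min", "max"])
    wide = agg.unstack("variable")
    wide.columns = [f"{var}_{stat}" for stat, var in wide.columns]
    feats = feats.join(wide.reindex(ids))

    uo = bundle.urine_output
    uo24 = uo[(uo["offset_h"] < 24.0) & uo["admission_id"].isin(ids)]
    feats["urine_output_mean"] = uo24.groupby("admission_id")["volume_ml"].mean().reindex(ids)

    comorb = bundle.comorbidities.set_index("admission_id").reindex(ids)
    feats = feats.join(comorb.astype(float))

    def _egfr(row) -> float:
        scr = row.get("creatinine_min", np.nan)
        if not np.isfinite(scr) or scr <= 0 or row["age"] < 18:
            return np.nan
        return ckdepi_egfr(scr, row["age"], "female" if row["sex_female"] else "male")

    feats["egfr_ckdepi"] = feats.apply(_egfr, axis=1)
    return feats


# ---------------------------------------------------------------------------
# missingness filter, imputation, scaling
# ---------------------------------------------------------------------------

def filter_missing_columns(
    features: pd.DataFrame, threshold: float = 0.20
) -> Tuple[pd.DataFrame, pd.Series]:
    """Drop columns whose missing fraction is strictly above ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    frac = features.isna().mean()
    dropped = frac[frac > threshold].sort_values(ascending=False)
    return features.drop(columns=dropped.index), dropped


def impute_chained(
    features: pd.DataFrame,
    train_index: pd.Index,
    config: CohortConfig = CohortConfig(),
) -> pd.DataFrame:
    """Chained-equations imputation, fitted on the training rows only.

    Single-imputation mode (one completed matrix); deterministic under
    the config seed.  Columns with zero observed training values should
    have been dropped by the missingness filter and raise here.
    """
    train = features.loc[train_index]
    if (train.notna().sum() == 0).any():
        bad = list(train.columns[train.notna().sum() == 0])
        raise ValueError(f"columns with no observed training values: {bad}")
    if not features.isna().any().any():
        return features.copy()
    imputer = IterativeImputer(
        max_iter=config.mice_iterations,
        random_state=config.seed,
        sample_posterior=False,
        keep_empty_features=True,
    )
    imputer.fit(train.to_numpy())
    completed = imputer.transform(features.to_numpy())
    return pd.DataFrame(completed, index=features.index, columns=features.columns)


def fit_minmax(features: pd.DataFrame, train_index: pd.Index) -> pd.DataFrame:
    """Min-max scaler parameters from the training partition."""
    train = features.loc[train_index]
    params = pd.DataFrame({"min": train.min(), "range": train.max() - train.min()})
    zero_var = params.index[params["range"] == 0.0]
    if len(zero_var):
        warnings.warn(f"zero-variance columns mapped to 0: {list(zero_var)}")
    return params


def apply_minmax(features: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Scale to [0, 1]; out-of-training-range values are clipped."""
    rng = params["range"].replace(0.0, np.inf)  # zero-variance -> 0 after divide
    scaled = (features - params["min"]) / rng
    return scaled.clip(lower=0.0, upper=1.0)


def normalize(
    features: pd.DataFrame, train_index: pd.Index
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fit on train, transform everything, clip to [0, 1]."""
    params = fit_minmax(features, train_index)
    return apply_minmax(features, params), params


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_cohort(
    bundle: EHRBundle,
    method: BaselineMethod,
    cohort_config: CohortConfig = CohortConfig(),
    split_config: Optional["SplitConfig"] = None,
    labels: Optional[pd.DataFrame] = None,
) -> CohortDataset:
    """Label, exclude, aggregate, split, impute and scale in one pass."""
    from .models import SplitConfig, split_data  # late import, avoids cycle

    if split_config is None:
        split_config = SplitConfig(seed=cohort_config.seed)
    if labels is None:
        labels = label_admissions(bundle, method)
    ids, audit = apply_exclusions(bundle, labels, cohort_config.min_age)
    feats = aggregate_features(bundle, ids)
    y = labels.set_index("admission_id").loc[ids, "outcome"].astype(int)

    partition = split_data(y, split_config)
    feats, dropped = filter_missing_columns(
        feats, cohort_config.missingness_drop_threshold
    )
    train_idx = partition.index[partition == "train"]
    feats = impute_chained(feats, train_idx, cohort_config)
    feats, scaler_params = normalize(feats, train_idx)

    return CohortDataset(
        X=feats,
        y=y,
        partition=partition,
        baseline_method=BaselineMethod(method),
        labels=labels,
        exclusion_audit=audit,
        dropped_columns=dropped,
        scaler_params=scaler_params,
    )
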