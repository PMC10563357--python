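"""Synthetic ICU admissions with a known, injected AKI process.

The generator emulates the structure of an ICU EHR extract — per-patient
demographics, sparse pre-ICU outpatient creatinine history, irregular
in-ICU creatinine over days 1–7, first-24h vitals/labs, urine output and
comorbidity flags — with ground truth recorded in a sidecar table so the
whole labelling/modelling pipeline is testable without any real data.

Creatinine model
----------------
Each subject has a piecewise-constant true baseline ``b`` (log-normal
across subjects, median 0.9 mg/dL) plus i.i.d. Gaussian measurement
noise.  AKI trajectories are step rises planted on a target day:

* ``absolute_rise`` — a step of >= 0.3 mg/dL + 4·sd above the highest
  pre-step level, so the 48-h criterion fires on the target day and
  measurement noise cannot de-flag it;
* ``ratio_rise`` — a step to >= 1.5·b + 4·sd, firing the ratio
  criterion against the true baseline on the target day.

A ratio-sized step usually also clears the 0.3 mg/dL absolute rise (any
step of 0.5·b with b >= 0.6 does), so the planted *mode* records which
criterion the trajectory was sized for, not an exclusive firing.

Admissions destined for day-2/3 AKI carry a small day-1 "prodrome"
elevation, capped strictly below both criteria margins, so first-24h
creatinine features are genuinely informative — mirroring the clinical
observation that minimum/maximum creatinine dominate AKI models.

Whether an admission receives an AKI trajectory follows a logistic risk
model on age, chronic kidney disease, invasive ventilation, sepsis and
the true baseline, with the intercept calibrated so the mean event
probability equals the configured rate; downstream models therefore
have covariate signal to learn.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .series import MeasurementSeries

# Continuous first-24h variables: (median, IQR, unit).  IQR/1.349 is used
# as the normal sd.  Highly missing variables (albumin, bilirubin,
# globulin, thrombin) exist so the >20% missingness filter has work to do.
VARIABLE_ROSTER: Dict[str, tuple] = {
    "heart_rate": (99.0, 25.0, "bpm"),
    "systolic_bp": (146.0, 27.0, "mmHg"),
    "diastolic_bp": (85.0, 23.0, "mmHg"),
    "respiratory_rate": (26.0, 7.0, "insp/min"),
    "temperature": (37.22, 0.73, "C"),
    "spo2": (96.0, 4.0, "%"),
    "weight": (80.0, 28.0, "kg"),
    "wbc": (12.1, 7.4, "K/uL"),
    "hemoglobin": (10.5, 3.2, "g/dL"),
    "hematocrit": (31.4, 9.6, "%"),
    "platelets": (180.0, 108.0, "K/uL"),
    "sodium": (140.0, 5.0, "mEq/L"),
    "potassium": (4.3, 0.6, "mEq/L"),
    "chloride": (106.0, 6.0, "mEq/L"),
    "bicarbonate": (25.0, 4.0, "mEq/L"),
    "anion_gap": (14.0, 5.0, "mEq/L"),
    "bun": (14.0, 9.0, "mg/dL"),
    "calcium": (8.6, 0.9, "mg/dL"),
    "prothrombin_time": (13.9, 3.6, "s"),
    "albumin": (3.1, 0.9, "g/dL"),
    "bilirubin": (0.8, 0.9, "mg/dL"),
    "globulin": (3.0, 0.8, "g/dL"),
    "thrombin": (20.0, 5.0, "s"),
}

DEFAULT_MISSING_RATES: Dict[str, float] = {
    "albumin": 0.6837,
    "bilirubin": 0.5085,
    "globulin": 0.9869,
    "thrombin": 0.9983,
    "prothrombin_time": 0.10,
    "calcium": 0.08,
    "bun": 0.05,
    "weight": 0.12,
}

DEFAULT_ETHNICITY_PROBS: Dict[str, float] = {
    "White": 0.3073,
    "African-American": 0.0770,
    "Hispanic-Latino": 0.0335,
    "Asian": 0.0299,
    "Other": 0.1669,
    "Unknown": 0.3854,
}

DEFAULT_COMORBIDITY_PREVALENCE: Dict[str, float] = {
    "obesity": 0.0671,
    "mild_liver_disease": 0.0825,
    "supplemental_oxygen": 0.4266,
    "sepsis": 0.0892,
    "peripheral_vascular_disease": 0.1024,
    "chronic_heart_failure": 0.1206,
    "chronic_kidney_disease": 0.0947,
    "hypertension": 0.4885,
    "severe_liver_disease": 0.0330,
    "myocardial_infarction": 0.1523,
    "tracheostomy": 0.0028,
    "congestive_heart_failure": 0.2042,
    "invasive_ventilation": 0.2960,
    "diabetes_type2": 0.2435,
    "chronic_pulmonary_disease": 0.2346,
}

#: Logistic risk coefficients shared by the day-1 and day-2/3 AKI
#: processes: (age-65)/10, chronic kidney disease, invasive ventilation,
#: sepsis, true baseline - 0.9.
_RISK_COEFS = {"age": 0.25, "chronic_kidney_disease": 0.9,
               "invasive_ventilation": 0.8, "sepsis": 0.6, "baseline": 0.8}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic cohort generator.

    Defaults reproduce the study regime: ~17.32% day-2/3 AKI, ~28.87%
    day-1 AKI (excluded downstream) and 64.19% of admissions lacking any
    pre-ICU baseline creatinine.
    """

    n_patients: int = 1000
    aki_day2or3_rate: float = 0.1732
    aki_day1_rate: float = 0.2887
    preicu_baseline_missing_rate: float = 0.6419
    missing_rates: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    age_mean: float = 65.0
    age_sd: float = 17.0
    age_range: tuple = (16.0, 100.0)
    female_prob: float = 0.5575
    ethnicity_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_PROBS)
    )
    comorbidity_prevalence: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    true_baseline_median: float = 0.9
    true_baseline_sigma: float = 0.30
    noise_sd: float = 0.05  # mg/dL
    creat_per_day_early: int = 3  # days 1-3 (sampling frequency not fixed by design)
    creat_per_day_late: int = 1  # days 4-7
    preicu_mean_extra_draws: float = 2.0  # history size is 1 + Poisson(this)
    preicu_recent_draw_prob: float = 0.30  # draw falls in [0, 7) days before
    second_stay_rate: float = 0.08
    rrt_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "aki_day2or3_rate": self.aki_day2or3_rate,
            "aki_day1_rate": self.aki_day1_rate,
            "preicu_baseline_missing_rate": self.preicu_baseline_missing_rate,
            "female_prob": self.female_prob,
            "preicu_recent_draw_prob": self.preicu_recent_draw_prob,
            "second_stay_rate": self.second_stay_rate,
            "rrt_rate": self.rrt_rate,
            **{f"missing_rates[{k}]": v for k, v in self.missing_rates.items()},
            **{f"comorbidity[{k}]": v for k, v in self.comorbidity_prevalence.items()},
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.aki_day1_rate + self.aki_day2or3_rate > 1.0:
            raise ConfigError("aki_day1_rate + aki_day2or3_rate must be <= 1")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        probs = sum(self.ethnicity_probs.values())
        if abs(probs - 1.0) > 1e-6:
            raise ConfigError(f"ethnicity probabilities must sum to 1, got {probs}")


@dataclass
class EHRBundle:
    """Long-format tables of one synthetic (or adapted real) extract.

    ``truth`` is a test-only sidecar recording the latent AKI process;
    it must never feed the modelling pipeline.
    """

    patients: pd.DataFrame  # patient_id, age, sex, ethnicity
    admissions: pd.DataFrame  # admission_id, patient_id, stay_number, rrt
    preicu_labs: pd.DataFrame  # admission_id, days_before, value
    icu_events: pd.DataFrame  # admission_id, offset_h, variable, value, unit
    urine_output: pd.DataFrame  # admission_id, offset_h, volume_ml
    comorbidities: pd.DataFrame  # admission_id + one 0/1 column per flag
    truth: Optional[pd.DataFrame] = None  # admission_id, true_baseline, planned, mode

    TABLES = ("patients", "admissions", "preicu_labs", "icu_events",
              "urine_output", "comorbidities", "truth")

    def admission_ids(self) -> np.ndarray:
        return self.admissions["admission_id"].to_numpy()

    def creatinine_series(self, admission_id: int) -> MeasurementSeries:
        ev = self.icu_events
        rows = ev[(ev["admission_id"] == admission_id) & (ev["variable"] == "creatinine")]
        return MeasurementSeries(rows["offset_h"].to_numpy(), rows["value"].to_numpy())

    def preicu_arrays(self, admission_id: int) -> tuple:
        rows = self.preicu_labs[self.preicu_labs["admission_id"] == admission_id]
        return rows["days_before"].to_numpy(), rows["value"].to_numpy()

    def demographics(self, admission_id: int) -> pd.Series:
        adm = self.admissions.set_index("admission_id").loc[admission_id]
        return self.patients.set_index("patient_id").loc[adm["patient_id"]]

    def write_csv(self, directory) -> None:
        """Thin CSV adapter: one file per long-format table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.TABLES:
            table = getattr(self, name)
            if table is not None:
                table.to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def read_csv(cls, directory) -> "EHRBundle":
        directory = Path(directory)
        kwargs = {}
        for name in cls.TABLES:
            path = directory / f"{name}.csv"
            kwargs[name] = pd.read_csv(path) if path.exists() else None
        if any(kwargs[n] is None for n in cls.TABLES[:-1]):
            missing = [n for n in cls.TABLES[:-1] if kwargs[n] is None]
            raise FileNotFoundError(f"bundle tables missing in {directory}: {missing}")
        return cls(**kwargs)


def _calibrated_probs(linear: np.ndarray, target_rate: float) -> np.ndarray:
    """Per-subject event probabilities with mean exactly ``target_rate``.

    Solves for the logistic intercept by bisection on the sampled linear
    predictors, so the realised rate is binomial around the target.
    """
    if target_rate <= 0.0:
        return np.zeros_like(linear)
    if target_rate >= 1.0:
        return np.ones_like(linear)
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + linear)))) < target_rate:
            lo = mid
        else:
            hi = mid
    return 1.0 / (1.0 + np.exp(-(0.5 * (lo + hi) + linear)))


def inject_aki_trajectory(
    series: MeasurementSeries,
    target_day: int,
    mode: str,
    rng: np.random.Generator,
    true_baseline: float,
    noise_sd: float = 0.05,
    prodrome: float = 0.0,
) -> MeasurementSeries:
    """Plant a step rise so a KDIGO criterion first fires on ``target_day``.

    ``prodrome`` is the (already present) sub-threshold elevation of the
    pre-step measurements; the absolute-mode step is sized on top of it
    so the 48-h rise keeps its >= 4·sd margin.  For ``target_day=1`` the
    step starts at the second day-1 measurement when one exists, leaving
    an in-window comparator for the 48-h criterion.
    """
    if mode not in ("absolute_rise", "ratio_rise"):
        raise ValueError(f"unknown trajectory mode {mode!r}")
    if target_day not in (1, 2, 3):
        raise ValueError(f"target_day must be 1, 2 or 3, got {target_day}")
    day_mask = (series.offsets_h >= 24.0 * (target_day - 1)) & (
        series.offsets_h < 24.0 * target_day
    )
    if not day_mask.any():
        raise ValueError(f"series has no measurement on day {target_day}")

    day_offsets = np.sort(series.offsets_h[day_mask])
    start = day_offsets[1] if (target_day == 1 and day_offsets.size > 1) else day_offsets[0]

    margin = 4.0 * noise_sd
    if mode == "absolute_rise":
        rise = 0.3 + margin + prodrome + rng.uniform(0.0, 0.2)
        new_level = true_baseline + rise
    else:
        new_level = 1.5 * true_baseline + margin + rng.uniform(0.0, 0.2)

    values = series.values.copy()
    step_mask = series.offsets_h >= start
    values[step_mask] += new_level - true_baseline - prodrome
    return MeasurementSeries(series.offsets_h, values, series.variable)


def _max_prodrome(baseline: float, noise_sd: float) -> float:
    """Largest day-1 elevation that cannot fire either criterion."""
    cap = min(0.3 - 4.0 * noise_sd, 0.5 * baseline - 4.0 * noise_sd) - 0.02
    return max(cap, 0.0)


def generate_population(config: SimConfig) -> EHRBundle:
    """Generate the complete (pre-missingness) synthetic bundle.

    Every admission carries creatinine on each of days 1-7, so the
    "creatinine on days 1, 2 and 3" inclusion rule is satisfiable by
    construction; exclusions are exercised through minors, repeat ICU
    stays and renal-replacement-therapy flags instead.
    """
    rng = np.random.default_rng(config.seed)
    n_pat = config.n_patients

    # --- patients -------------------------------------------------------
    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, n_pat), *config.age_range
    ).round(0)
    sex = np.where(rng.random(n_pat) < config.female_prob, "female", "male")
    eth_names = list(config.ethnicity_probs)
    ethnicity = rng.choice(eth_names, size=n_pat, p=[config.ethnicity_probs[k] for k in eth_names])
    patients = pd.DataFrame(
        {"patient_id": np.arange(n_pat), "age": age, "sex": sex, "ethnicity": ethnicity}
    )

    # --- admissions (some patients get a second, later stay) ------------
    second = rng.random(n_pat) < config.second_stay_rate
    adm_patient = np.concatenate([np.arange(n_pat), np.flatnonzero(second)])
    stay_number = np.concatenate([np.ones(n_pat, int), np.full(second.sum(), 2, int)])
    n_adm = adm_patient.size
    admissions = pd.DataFrame(
        {
            "admission_id": np.arange(n_adm),
            "patient_id": adm_patient,
            "stay_number": stay_number,
            "rrt": (rng.random(n_adm) < config.rrt_rate).astype(int),
        }
    )

    # --- comorbidity flags (independent Bernoulli) -----------------------
    comorb = {"admission_id": np.arange(n_adm)}
    for name, prev in config.comorbidity_prevalence.items():
        comorb[name] = (rng.random(n_adm) < prev).astype(int)
    comorbidities = pd.DataFrame(comorb)

    # --- latent AKI process ----------------------------------------------
    b = np.maximum(
        np.exp(rng.normal(np.log(config.true_baseline_median),
                          config.true_baseline_sigma, n_adm)),
        0.3,
    )
    adm_age = age[adm_patient]
    linear = (
        _RISK_COEFS["age"] * (adm_age - 65.0) / 10.0
        + _RISK_COEFS["chronic_kidney_disease"] * comorbidities["chronic_kidney_disease"].to_numpy()
        + _RISK_COEFS["invasive_ventilation"] * comorbidities["invasive_ventilation"].to_numpy()
        + _RISK_COEFS["sepsis"] * comorbidities["sepsis"].to_numpy()
        + _RISK_COEFS["baseline"] * (b - 0.9)
    )
    p_day1 = _calibrated_probs(linear, config.aki_day1_rate)
    p_day23 = _calibrated_probs(linear, config.aki_day2or3_rate)
    total = p_day1 + p_day23
    scale = np.minimum(1.0, 1.0 / np.maximum(total, 1e-12))
    p_day1, p_day23 = p_day1 * scale, p_day23 * scale
    u = rng.random(n_adm)
    is_day1 = u < p_day1
    is_day23 = (~is_day1) & (u < p_day1 + p_day23)
    target_day = np.full(n_adm, 0, int)
    target_day[is_day1] = 1
    target_day[is_day23] = rng.integers(2, 4, is_day23.sum())
    modes = np.where(rng.random(n_adm) < 0.5, "absolute_rise", "ratio_rise")
    modes[target_day == 0] = "none"

    # --- in-ICU creatinine -----------------------------------------------
    k1, k2 = config.creat_per_day_early, config.creat_per_day_late
    day_blocks = [d for d in range(1, 4) for _ in range(k1)] + [
        d for d in range(4, 8) for _ in range(k2)
    ]
    day_arr = np.array(day_blocks)
    m = day_arr.size
    offsets = 24.0 * (day_arr - 1) + rng.uniform(0.0, 24.0, (n_adm, m))
    offsets.sort(axis=1)
    day_of = (offsets // 24.0).astype(int) + 1

    values = b[:, None] + rng.normal(0.0, config.noise_sd, (n_adm, m))
    # day-1 prodrome for day-2/3 cases, capped below both criteria
    prodrome = np.zeros(n_adm)
    d23 = target_day >= 2
    if d23.any():
        cap = np.array([_max_prodrome(bb, config.noise_sd) for bb in b[d23]])
        prodrome[d23] = rng.uniform(np.minimum(0.02, cap), cap)
        pre_mask = d23[:, None] & (day_of < target_day[:, None])
        values += pre_mask * prodrome[:, None]
    # step rises
    rise_u = rng.uniform(0.0, 0.2, n_adm)
    margin = 4.0 * config.noise_sd
    new_level = np.where(
        modes == "absolute_rise",
        b + 0.3 + margin + prodrome + rise_u,
        1.5 * b + margin + rise_u,
    )
    start = np.full(n_adm, np.inf)
    flagged = target_day > 0
    start[flagged] = 24.0 * (target_day[flagged] - 1)
    # day-1 targets step at the 2nd day-1 measurement to leave a comparator
    if k1 > 1 and (target_day == 1).any():
        idx1 = np.flatnonzero(target_day == 1)
        start[idx1] = offsets[idx1, 1]
    step_mask = offsets >= start[:, None]
    values += step_mask * (new_level - b)[:, None]
    values = np.maximum(values, 0.05)

    adm_rep = np.repeat(np.arange(n_adm), m)
    icu_rows = [
        pd.DataFrame(
            {
                "admission_id": adm_rep,
                "offset_h": offsets.ravel(),
                "variable": "creatinine",
                "value": values.ravel().round(4),
                "unit": "mg/dL",
            }
        )
    ]

    # --- other first-24h variables ---------------------------------------
    for var, (median, iqr, unit) in VARIABLE_ROSTER.items():
        k = 2
        sd = iqr / 1.349
        v = rng.normal(median, sd, (n_adm, k))
        v = np.maximum(v, 0.01 if median < 50 else 1.0)
        off = rng.uniform(0.0, 24.0, (n_adm, k))
        icu_rows.append(
            pd.DataFrame(
                {
                    "admission_id": np.repeat(np.arange(n_adm), k),
                    "offset_h": off.ravel(),
                    "variable": var,
                    "value": v.ravel().round(3),
                    "unit": unit,
                }
            )
        )
    icu_events = pd.concat(icu_rows, ignore_index=True)

    # --- urine output (ml per 4-h epoch over the first 24 h) --------------
    n_uo = 6
    uo = rng.lognormal(np.log(200.0), 0.6, (n_adm, n_uo))
    urine_output = pd.DataFrame(
        {
            "admission_id": np.repeat(np.arange(n_adm), n_uo),
            "offset_h": np.tile(np.arange(n_uo) * 4.0 + 2.0, n_adm),
            "volume_ml": uo.ravel().round(1),
        }
    )

    # --- pre-ICU creatinine history (everyone; thinned later) -------------
    n_draws = 1 + rng.poisson(config.preicu_mean_extra_draws, n_adm)
    adm_hist = np.repeat(np.arange(n_adm), n_draws)
    total_draws = int(n_draws.sum())
    recent = rng.random(total_draws) < config.preicu_recent_draw_prob
    days_before = np.where(
        recent, rng.uniform(0.0, 7.0, total_draws), rng.uniform(7.0, 180.0, total_draws)
    )
    hist_vals = np.maximum(
        b[adm_hist] + rng.normal(0.0, config.noise_sd, total_draws), 0.05
    )
    preicu_labs = pd.DataFrame(
        {
            "admission_id": adm_hist,
            "days_before": days_before.round(3),
            "value": hist_vals.round(4),
        }
    )

    truth = pd.DataFrame(
        {
            "admission_id": np.arange(n_adm),
            "true_baseline": b,
            "planned_day": target_day,  # 0 = no AKI trajectory
            "mode": modes,
            "prodrome": prodrome,
        }
    )

    return EHRBundle(
        patients=patients,
        admissions=admissions,
        preicu_labs=preicu_labs,
        icu_events=icu_events,
        urine_output=urine_output,
        comorbidities=comorbidities,
        truth=truth,
    )


def apply_missingness(bundle: EHRBundle, config: SimConfig) -> EHRBundle:
    """Delete data per the configured rates.

    Per-variable missingness removes *all* of a variable's events for a
    Bernoulli-selected set of admissions (feature-level missingness, as
    aggregation is per-admission).  Creatinine is exempt so the day-1/2/3
    inclusion rule is never broken.  Pre-ICU history is removed entirely
    for ``preicu_baseline_missing_rate`` of admissions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 715517]))
    adm_ids = bundle.admission_ids()
    n_adm = adm_ids.size

    events = bundle.icu_events
    drop = np.zeros(len(events), dtype=bool)
    for var, rate in config.missing_rates.items():
        if var == "creatinine":
            continue
        missing_adm = set(adm_ids[rng.random(n_adm) < rate])
        var_rows = events["variable"] == var
        drop |= var_rows.to_numpy() & events["admission_id"].isin(missing_adm).to_numpy()
    events = events[~drop].reset_index(drop=True)

    no_history = set(adm_ids[rng.random(n_adm) < config.preicu_baseline_missing_rate])
    preicu = bundle.preicu_labs[
        ~bundle.preicu_labs["admission_id"].isin(no_history)
    ].reset_index(drop=True)

    return dataclasses.replace(bundle, icu_events=events, preicu_labs=preicu)


def simulate(config: SimConfig) -> EHRBundle:
    """Generate a population and apply the configured missingness."""
    return apply_missingness(generate_population(config), config)
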