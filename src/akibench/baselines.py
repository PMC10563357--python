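"""The six baseline serum-creatinine estimators.

The baseline is the reference value the KDIGO ratio criterion is judged
against; how it is estimated is the variable under study.  Six methods:

========  ================================================================
B1        minimum creatinine in the first 24 h of ICU admission
B2        MDRD backward value (eGFR 75) used only to *screen* for day-1
          AKI, then the minimum day-1 creatinine as the working baseline
B3        mean of pre-ICU creatinine 180 to 7 days before admission,
          MDRD backward fallback when the window is empty
M1        minimum over 180 to 7 days, MDRD fallback
M2        minimum over 180 to 0 days, MDRD fallback
M3        mean over 180 to 0 days, MDRD fallback
========  ================================================================

Window convention: a pre-ICU draw taken d days before ICU admission is
in window [a, b] iff b <= d <= a; "0 days before" admits same-day draws
taken strictly before the ICU admission time.  Duplicate timestamps are
kept; min/mean run over the multiset.  Fallback to the formula fires iff
the window's value set is empty.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .renal import backward_mdrd
from .series import MeasurementSeries


class BaselineMethod(str, enum.Enum):
    """The six estimation methods (original 1-3 and modified 1-3)."""

    B1_min_first24h = "B1_min_first24h"
    B2_mdrd_then_min24h = "B2_mdrd_then_min24h"
    B3_mean_180to7_or_mdrd = "B3_mean_180to7_or_mdrd"
    M1_min_180to7_or_mdrd = "M1_min_180to7_or_mdrd"
    M2_min_180to0_or_mdrd = "M2_min_180to0_or_mdrd"
    M3_mean_180to0_or_mdrd = "M3_mean_180to0_or_mdrd"


#: (window_start_days_before, window_end_days_before, aggregator) for the
#: pre-ICU-window methods; None for the first-24h methods.
_WINDOWS = {
    BaselineMethod.B3_mean_180to7_or_mdrd: (180.0, 7.0, np.mean),
    BaselineMethod.M1_min_180to7_or_mdrd: (180.0, 7.0, np.min),
    BaselineMethod.M2_min_180to0_or_mdrd: (180.0, 0.0, np.min),
    BaselineMethod.M3_mean_180to0_or_mdrd: (180.0, 0.0, np.mean),
}


class IneligibleAdmissionError(ValueError):
    """Admission cannot support the requested baseline (no day-1 creatinine)."""


@dataclass(frozen=True)
class BaselineResult:
    """Estimated baseline with provenance.

    ``screening_value`` is set only by the two-stage B2 method: the
    formula value used to flag day-1 AKI for exclusion, distinct from
    the working baseline in ``value``.
    """

    value: float  # mg/dL
    source: str  # observed_preicu | formula_imputed | first24h_min
    n_values_used: int
    screening_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError(f"baseline must be > 0 mg/dL, got {self.value}")
        if self.source == "formula_imputed" and self.n_values_used != 0:
            raise ValueError("formula-imputed baseline uses no observed values")


def preicu_window_values(
    preicu_days_before: np.ndarray,
    preicu_values: np.ndarray,
    start_days_before: float,
    end_days_before: float,
) -> np.ndarray:
    """Pre-ICU creatinine values whose offset lies in [end, start] days."""
    d = np.asarray(preicu_days_before, dtype=float)
    v = np.asarray(preicu_values, dtype=float)
    mask = (d >= end_days_before) & (d <= start_days_before)
    return v[mask]


def estimate_baseline(
    icu_creatinine: MeasurementSeries,
    preicu_days_before: np.ndarray,
    preicu_values: np.ndarray,
    age: float,
    sex: str,
    method: BaselineMethod,
) -> BaselineResult:
    """Estimate the baseline creatinine for one admission.

    Parameters
    ----------
    icu_creatinine
        In-ICU creatinine series (hours from ICU admission).
    preicu_days_before, preicu_values
        Outpatient creatinine history; offsets are days *before* ICU
        admission (>= 0), values mg/dL.  May be empty.
    age, sex
        Demographics for the MDRD backward fallback.
    method
        One of the six :class:`BaselineMethod` members.
    """
    method = BaselineMethod(method)

    if method in (BaselineMethod.B1_min_first24h, BaselineMethod.B2_mdrd_then_min24h):
        day1 = icu_creatinine.on_day(1)
        if len(day1) == 0:
            raise IneligibleAdmissionError(
                "no creatinine in the first 24 h; admission ineligible for "
                f"{method.value}"
            )
        working = float(np.min(day1.values))
        screening = None
        if method is BaselineMethod.B2_mdrd_then_min24h:
            screening = backward_mdrd(age, sex)
        return BaselineResult(working, "first24h_min", len(day1), screening)

    start, end, agg = _WINDOWS[method]
    window = preicu_window_values(preicu_days_before, preicu_values, start, end)
    if window.size:
        return BaselineResult(float(agg(window)), "observed_preicu", int(window.size))
    return BaselineResult(backward_mdrd(age, sex), "formula_imputed", 0)


def screening_baseline(result: BaselineResult) -> float:
    """Value the day-1 AKI screen should use (B2's formula, else the value)."""
    return result.screening_value if result.screening_value is not None else result.value
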