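"""KDIGO serum-creatinine AKI detection over irregular measurement series.

Two criteria, both inclusive (>=):

* absolute: a rise of >= 0.3 mg/dL relative to the minimum creatinine in
  the preceding 48 h of the same admission;
* ratio: creatinine >= 1.5x the baseline, within 7 days of ICU
  admission.

"Day d" means the 24-h block [24*(d-1), 24*d) anchored on the ICU
admission timestamp, not a calendar day.  The 48-h comparator is the
rolling minimum over the half-open window (t-48, t] restricted to
in-ICU measurements; pre-ICU draws never enter the rolling window.

:func:`detect_aki` uses a monotonic-deque sliding-window minimum;
:func:`detect_aki_oracle` is an exhaustive pairwise scan kept only as an
independent reference for tests.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .series import MeasurementSeries


@dataclass(frozen=True)
class KDIGOThresholds:
    """Creatinine-criterion thresholds of the KDIGO AKI definition."""

    absolute_rise: float = 0.3  # mg/dL
    absolute_window_h: float = 48.0
    ratio_rise: float = 1.5  # x baseline
    ratio_window_h: float = 168.0  # 7 days from ICU admission


@dataclass(frozen=True)
class AKILabel:
    """Outcome of KDIGO detection for one admission."""

    flagged: bool
    first_detection_day: Optional[int]  # 24-h block of earliest firing, 1-based
    criterion: Optional[str]  # "absolute" | "ratio" | "both"
    trigger_offset_h: Optional[float]

    def __post_init__(self) -> None:
        if self.flagged != (self.first_detection_day is not None):
            raise ValueError("flagged must match presence of a detection day")
        if self.flagged != (self.criterion is not None):
            raise ValueError("criterion must be set iff flagged")


NOT_FLAGGED = AKILabel(False, None, None, None)


def _validate(series: MeasurementSeries, baseline: float) -> None:
    if len(series) == 0:
        raise ValueError("empty creatinine series")
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError(f"baseline creatinine must be > 0 mg/dL, got {baseline}")


def _label_from_times(t_abs: float, t_ratio: float) -> AKILabel:
    t = min(t_abs, t_ratio)
    if not np.isfinite(t):
        return NOT_FLAGGED
    if t_abs == t_ratio:
        crit = "both"
    elif t == t_abs:
        crit = "absolute"
    else:
        crit = "ratio"
    return AKILabel(True, int(t // 24.0) + 1, crit, float(t))


def detect_aki(
    series: MeasurementSeries,
    baseline: float,
    thresholds: KDIGOThresholds = KDIGOThresholds(),
) -> AKILabel:
    """Earliest KDIGO sCr-criterion firing for one admission.

    Parameters
    ----------
    series
        In-ICU creatinine measurements, offsets in hours from ICU
        admission (days 1-7 are the relevant range).
    baseline
        Baseline creatinine (mg/dL) for the ratio criterion; the 48-h
        rise criterion is independent of it.
    """
    _validate(series, baseline)
    t, v = series.offsets_h, series.values

    # Absolute criterion: sliding-window minimum over (t_i - 48, t_i].
    # Equal timestamps are pushed as a group first, since co-timed draws
    # are inside each other's windows (u <= t).
    t_abs = np.inf
    window: deque[int] = deque()  # indices, values monotone non-decreasing
    n = len(v)
    i = 0
    while i < n and not np.isfinite(t_abs):
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        while window and t[window[0]] <= t[i] - thresholds.absolute_window_h:
            window.popleft()
        for k in range(i, j):
            while window and v[window[-1]] >= v[k]:
                window.pop()
            window.append(k)
        wmin = v[window[0]]
        if np.max(v[i:j]) - wmin >= thresholds.absolute_rise:
            t_abs = t[i]
        i = j

    # Ratio criterion: first measurement >= 1.5x baseline within 7 days.
    ratio_hits = np.flatnonzero(
        (v >= thresholds.ratio_rise * baseline) & (t <= thresholds.ratio_window_h)
    )
    t_ratio = t[ratio_hits[0]] if ratio_hits.size else np.inf

    return _label_from_times(t_abs, t_ratio)


def detect_aki_oracle(
    series: MeasurementSeries,
    baseline: float,
    thresholds: KDIGOThresholds = KDIGOThresholds(),
) -> AKILabel:
    """Exhaustive O(n²) reference implementation (tests only).

    Scans every ordered measurement pair for the 48-h rise and every
    single measurement for the ratio criterion.
    """
    _validate(series, baseline)
    t = [float(x) for x in series.offsets_h]
    v = [float(x) for x in series.values]
    n = len(v)

    t_abs = np.inf
    for i in range(n):
        for j in range(n):
            in_window = t[j] <= t[i] and t[i] - t[j] < thresholds.absolute_window_h
            if in_window and v[i] - v[j] >= thresholds.absolute_rise:
                t_abs = min(t_abs, t[i])
    t_ratio = np.inf
    for i in range(n):
        if t[i] <= thresholds.ratio_window_h and v[i] >= thresholds.ratio_rise * baseline:
            t_ratio = min(t_ratio, t[i])

    return _label_from_times(t_abs, t_ratio)


def day1_aki_flag(
    series: MeasurementSeries,
    screening_baseline: float,
    thresholds: KDIGOThresholds = KDIGOThresholds(),
) -> bool:
    """True iff either criterion first fires in hours [0, 24).

    Used by the formula-screened baseline method to exclude admissions
    that already satisfy KDIGO on day 1; ``screening_baseline`` feeds the
    ratio criterion.
    """
    if len(series.on_day(1)) == 0:
        raise ValueError("no day-1 creatinine measurements")
    label = detect_aki(series, screening_baseline, thresholds)
    return label.flagged and label.first_detection_day == 1
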