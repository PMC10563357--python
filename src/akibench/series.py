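"""Light container for time-stamped measurements of one admission."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MeasurementSeries:
    """Measurements of a single variable for one admission.

    Offsets are hours from ICU admission; values keep the variable's
    native unit (mg/dL for creatinine).  Stored sorted by offset;
    duplicate timestamps are kept as a multiset.
    """

    offsets_h: np.ndarray
    values: np.ndarray
    variable: str = "creatinine"

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets_h, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if off.shape != val.shape or off.ndim != 1:
            raise ValueError("offsets and values must be 1-D arrays of equal length")
        if off.size and (not np.all(np.isfinite(off)) or not np.all(np.isfinite(val))):
            raise ValueError("non-finite measurement in series")
        order = np.argsort(off, kind="stable")
        object.__setattr__(self, "offsets_h", off[order])
        object.__setattr__(self, "values", val[order])

    def __len__(self) -> int:
        return int(self.offsets_h.size)

    def on_day(self, day: int) -> "MeasurementSeries":
        """Sub-series in the 24-h block [24·(day−1), 24·day)."""
        lo, hi = 24.0 * (day - 1), 24.0 * day
        mask = (self.offsets_h >= lo) & (self.offsets_h < hi)
        return MeasurementSeries(self.offsets_h[mask], self.values[mask], self.variable)
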