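"""Closed-form renal equations.

The central primitive is the MDRD *backward* calculation: solving the
four-variable MDRD eGFR equation for serum creatinine at an assumed
eGFR of 75 ml/min/1.73 m², the standard surrogate baseline when no
pre-admission creatinine exists::

    sCr_GFR-75 = (75 / (186 · age^-0.203 · [0.742 if female])) ^ -0.887

The outer exponent is kept at the published value of -0.887 rather than
the algebraic inverse of the MDRD creatinine exponent (-1/1.154 ≈
-0.8666).  The two disagree slightly, so the forward/backward round trip
lands near — not exactly at — 75; ``backward_mdrd`` exposes the exact
inverse behind ``exact_inverse=True`` for sensitivity analysis.

All creatinine values are mg/dL internally; :func:`mgdl_to_umoll`
converts at I/O boundaries only.
"""

from __future__ import annotations

import math
from typing import Literal

Sex = Literal["male", "female"]

#: MDRD scale factor.
MDRD_SCALE = 186.0
#: MDRD age exponent.
MDRD_AGE_EXP = -0.203
#: MDRD creatinine exponent (forward form).
MDRD_SCR_EXP = -1.154
#: MDRD female factor.
MDRD_FEMALE = 0.742
#: Published backward exponent (not exactly -1/1.154).
MDRD_BACKWARD_EXP = -0.887
#: Assumed eGFR for the backward calculation, ml/min/1.73 m².
ASSUMED_EGFR = 75.0

#: Creatinine molar mass, g/mol.
CREATININE_MOLAR_MASS = 113.12


def _check_sex(sex: str) -> bool:
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return sex == "female"


def backward_mdrd(age: float, sex: Sex, *, exact_inverse: bool = False) -> float:
    """Baseline creatinine (mg/dL) backward-calculated from MDRD at eGFR 75.

    Parameters
    ----------
    age
        Age in years, must be >= 18 (adult equation).
    sex
        ``"male"`` or ``"female"``.
    exact_inverse
        Use the algebraically exact exponent -1/1.154 instead of the
        published -0.887.

    Returns
    -------
    float
        Estimated baseline serum creatinine in mg/dL, strictly positive.
    """
    if not math.isfinite(age) or age < 18:
        raise ValueError(f"backward MDRD is defined for adults (age >= 18), got {age}")
    female = _check_sex(sex)
    denom = MDRD_SCALE * age**MDRD_AGE_EXP * (MDRD_FEMALE if female else 1.0)
    exponent = 1.0 / MDRD_SCR_EXP if exact_inverse else MDRD_BACKWARD_EXP
    return (ASSUMED_EGFR / denom) ** exponent


def forward_mdrd(scr: float, age: float, sex: Sex) -> float:
    """Four-variable MDRD eGFR (ml/min/1.73 m²), race term omitted.

    eGFR = 186 · sCr^-1.154 · age^-0.203 · (0.742 if female)
    """
    if not math.isfinite(scr) or scr <= 0:
        raise ValueError(f"serum creatinine must be > 0 mg/dL, got {scr}")
    if not math.isfinite(age) or age < 18:
        raise ValueError(f"MDRD is defined for adults (age >= 18), got {age}")
    female = _check_sex(sex)
    return (
        MDRD_SCALE
        * scr**MDRD_SCR_EXP
        * age**MDRD_AGE_EXP
        * (MDRD_FEMALE if female else 1.0)
    )


def ckdepi_egfr(scr: float, age: float, sex: Sex) -> float:
    """2009 CKD-EPI creatinine eGFR (ml/min/1.73 m²), no race coefficient.

    Used only as a model input feature, never for labelling.  Sex-specific
    knots: kappa = 0.7 (F) / 0.9 (M), alpha = -0.329 (F) / -0.411 (M).
    """
    if not math.isfinite(scr) or scr <= 0:
        raise ValueError(f"serum creatinine must be > 0 mg/dL, got {scr}")
    if not math.isfinite(age) or age < 18:
        raise ValueError(f"CKD-EPI is defined for adults (age >= 18), got {age}")
    female = _check_sex(sex)
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    ratio = scr / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993**age
    if female:
        egfr *= 1.018
    return egfr


def mgdl_to_umoll(x: float) -> float:
    """Convert creatinine mg/dL -> µmol/L (0.3 mg/dL ≈ 26.5 µmol/L)."""
    return x * 10000.0 / CREATININE_MOLAR_MASS


def umoll_to_mgdl(x: float) -> float:
    """Convert creatinine µmol/L -> mg/dL (inverse of :func:`mgdl_to_umoll`)."""
    return x * CREATININE_MOLAR_MASS / 10000.0
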