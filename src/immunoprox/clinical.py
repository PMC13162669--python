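"""ALBI score and modified ALBI (mALBI) grade for hepatic reserve function.

ALBI = 0.66 * log10(total bilirubin, µmol/L) - 0.085 * (albumin, g/L).

Grades: 1 (<= -2.60), 2a (-2.60, -2.270], 2b (-2.270, -1.39], 3 (> -1.39).
Inputs in conventional units are converted first: bilirubin mg/dL ->
µmol/L via the molar factor 17.104, albumin g/dL -> g/L via 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

MGDL_TO_UMOLL = 17.104   # bilirubin, molar mass 584.66 g/mol
GDL_TO_GL = 10.0

_BILIRUBIN_UNITS = {"umol/l": 1.0, "µmol/l": 1.0, "mg/dl": MGDL_TO_UMOLL}
_ALBUMIN_UNITS = {"g/l": 1.0, "g/dl": GDL_TO_GL}


@dataclass(frozen=True)
class AlbiResult:
    albi_score: float
    grade: str  # one of "1", "2a", "2b", "3"


def albi_grade(score: float) -> str:
    """mALBI grade; boundaries closed on the lower-grade side."""
    if score <= -2.60:
        return "1"
    if score <= -2.270:
        return "2a"
    if score <= -1.39:
        return "2b"
    return "3"


def albi_score(
    total_bilirubin: float,
    albumin: float,
    bilirubin_unit: str = "mg/dL",
    albumin_unit: str = "g/dL",
) -> AlbiResult:
    """ALBI score and mALBI grade from total bilirubin and serum albumin."""
    if not total_bilirubin > 0:
        raise ValueError("total bilirubin must be positive")
    if not albumin > 0:
        raise ValueError("albumin must be positive")
    try:
        bili_umol = total_bilirubin * _BILIRUBIN_UNITS[bilirubin_unit.lower()]
    except KeyError:
        raise ValueError(f"unknown bilirubin unit: {bilirubin_unit!r}")
    try:
        alb_gl = albumin * _ALBUMIN_UNITS[albumin_unit.lower()]
    except KeyError:
        raise ValueError(f"unknown albumin unit: {albumin_unit!r}")
    score = 0.66 * math.log10(bili_umol) - 0.085 * alb_gl
    return AlbiResult(albi_score=score, grade=albi_grade(score))


def add_albi_columns(
    patients: pd.DataFrame,
    bilirubin_col: str = "bilirubin_mg_dl",
    albumin_col: str = "albumin_g_dl",
) -> pd.DataFrame:
    """Append ``albi_score`` and ``malbi_grade`` columns to a patient table."""
    out = patients.copy()
    results = [
        albi_score(b, a)
        for b, a in zip(out[bilirubin_col], out[albumin_col])
    ]
    out["albi_score"] = [r.albi_score for r in results]
    out["malbi_grade"] = [r.grade for r in results]
    return out
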