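"""Anthropometric and renal-function covariates.

Derived quantities used throughout the amikacin model and the cohort
generator: body mass index, Dubois body surface area, Lorentz ideal body
weight, Traynor adjusted body weight, and three creatinine-based estimates
of renal function (2009 CKD-EPI, Cockcroft-Gault, MDRD).

Serum creatinine is expressed in µmol/L at every interface (the unit used
by French laboratories); the conversion to mg/dL (factor 88.4) happens
internally.  The CKD-EPI and MDRD race coefficients are omitted: ethnicity
is not recorded in the cohorts this package emulates, and the omission is
deliberate rather than an oversight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PatientCovariates",
    "bmi",
    "bsa_dubois",
    "ibw_lorentz",
    "abw_traynor",
    "egfr_ckdepi",
    "crcl_cockcroft_gault",
    "egfr_mdrd",
    "scr_from_ckdepi",
    "derive_covariates",
]

#: µmol/L per mg/dL of creatinine
CREATININE_UMOL_PER_MGDL = 88.4


def _normalize_sex(sex) -> str:
    """Map common encodings to 'male'/'female'."""
    if isinstance(sex, str):
        s = sex.strip().lower()
        if s in ("male", "m", "1"):
            return "male"
        if s in ("female", "f", "0"):
            return "female"
        raise ValueError(f"unrecognized sex: {sex!r}")
    if sex in (0, 1):
        return "male" if int(sex) == 1 else "female"
    raise ValueError(f"unrecognized sex: {sex!r}")


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be strictly positive, got {value}")


def bmi(tbw: float, height: float) -> float:
    """Body mass index (kg/m²) from total body weight (kg) and height (cm)."""
    _require_positive(tbw=tbw, height=height)
    h_m = height / 100.0
    return tbw / h_m**2


def bsa_dubois(tbw: float, height: float) -> float:
    """Dubois body surface area (m²): 0.007184 · height^0.725 · weight^0.425."""
    _require_positive(tbw=tbw, height=height)
    return 0.007184 * height**0.725 * tbw**0.425


def ibw_lorentz(height: float, sex) -> float:
    """Lorentz ideal body weight (kg).

    male:   height − 100 − (height − 150)/4
    female: height − 100 − (height − 150)/2.5

    The correction term is only meaningful above 150 cm; below that the
    function degrades to ``height − 100`` with a warning, so that synthetic
    cohorts sampling short statures do not fail.
    """
    _require_positive(height=height)
    sex = _normalize_sex(sex)
    if height < 150.0:
        warnings.warn(
            f"Lorentz IBW ill-defined below 150 cm (height={height}); "
            "falling back to height - 100",
            stacklevel=2,
        )
        return height - 100.0
    divisor = 4.0 if sex == "male" else 2.5
    return height - 100.0 - (height - 150.0) / divisor


def abw_traynor(ibw: float, tbw: float) -> float:
    """Traynor adjusted body weight: IBW + 0.4 · (TBW − IBW).

    A convex combination, so the result always lies between IBW and TBW
    (the formula is applied symmetrically when TBW < IBW).
    """
    _require_positive(ibw=ibw, tbw=tbw)
    return ibw + 0.4 * (tbw - ibw)


def egfr_ckdepi(serum_creatinine: float, age: float, sex) -> float:
    """2009 CKD-EPI estimated GFR (mL/min/1.73 m²), race coefficient omitted.

    ``serum_creatinine`` in µmol/L; converted internally to mg/dL.
    """
    _require_positive(serum_creatinine=serum_creatinine, age=age)
    sex = _normalize_sex(sex)
    scr = serum_creatinine / CREATININE_UMOL_PER_MGDL
    if sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    ratio = scr / kappa
    return (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**age
        * sex_factor
    )


def scr_from_ckdepi(egfr: float, age: float, sex) -> float:
    """Invert the 2009 CKD-EPI equation: creatinine (µmol/L) giving ``egfr``.

    Exact piecewise-analytic inverse; used when a synthetic cohort sampled
    on eGFR must carry a consistent serum creatinine.
    """
    _require_positive(egfr=egfr, age=age)
    sex = _normalize_sex(sex)
    if sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    g = egfr / (141.0 * 0.993**age * sex_factor)
    if g <= 1.0:  # creatinine at or above kappa
        scr = kappa * g ** (-1.0 / 1.209)
    else:
        scr = kappa * g ** (1.0 / alpha)
    return scr * CREATININE_UMOL_PER_MGDL


def crcl_cockcroft_gault(serum_creatinine: float, age: float, tbw: float, sex) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min), weight = TBW."""
    _require_positive(serum_creatinine=serum_creatinine, age=age, tbw=tbw)
    if age >= 140:
        raise ValueError(f"age {age} outside the Cockcroft-Gault domain (< 140)")
    sex = _normalize_sex(sex)
    scr = serum_creatinine / CREATININE_UMOL_PER_MGDL
    crcl = (140.0 - age) * tbw / (72.0 * scr)
    if sex == "female":
        crcl *= 0.85
    return crcl


def egfr_mdrd(serum_creatinine: float, age: float, sex) -> float:
    """4-variable MDRD estimated GFR (mL/min/1.73 m²), race coefficient omitted."""
    _require_positive(serum_creatinine=serum_creatinine, age=age)
    sex = _normalize_sex(sex)
    scr = serum_creatinine / CREATININE_UMOL_PER_MGDL
    value = 175.0 * scr**-1.154 * age**-0.203
    if sex == "female":
        value *= 0.742
    return value


@dataclass
class PatientCovariates:
    """All covariates for one patient, raw and derived."""

    age: float
    sex: str
    height: float
    tbw: float
    serum_creatinine: float
    bmi: float
    bsa: float
    ibw: float
    abw: float
    egfr_ckdepi: float
    crcl_cg: float
    egfr_mdrd: float

    @classmethod
    def derive(
        cls, age: float, sex, height: float, tbw: float, serum_creatinine: float
    ) -> "PatientCovariates":
        sex = _normalize_sex(sex)
        ibw = ibw_lorentz(height, sex)
        return cls(
            age=age,
            sex=sex,
            height=height,
            tbw=tbw,
            serum_creatinine=serum_creatinine,
            bmi=bmi(tbw, height),
            bsa=bsa_dubois(tbw, height),
            ibw=ibw,
            abw=abw_traynor(ibw, tbw),
            egfr_ckdepi=egfr_ckdepi(serum_creatinine, age, sex),
            crcl_cg=crcl_cockcroft_gault(serum_creatinine, age, tbw, sex),
            egfr_mdrd=egfr_mdrd(serum_creatinine, age, sex),
        )


def derive_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Append derived covariate columns to a cohort table.

    Expects columns ID, AGE, SEX (1=male/0=female or strings), HT (cm),
    WT (kg), SCR (µmol/L); appends BMI, BSA, IBW, ABW, EGFR_CKDEPI,
    CRCL_CG, EGFR_MDRD.
    """
    required = {"AGE", "SEX", "HT", "WT", "SCR"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    out = table.copy()
    derived = [
        PatientCovariates.derive(
            age=row.AGE, sex=row.SEX, height=row.HT, tbw=row.WT,
            serum_creatinine=row.SCR,
        )
        for row in table.itertuples()
    ]
    out["BMI"] = [d.bmi for d in derived]
    out["BSA"] = [d.bsa for d in derived]
    out["IBW"] = [d.ibw for d in derived]
    out["ABW"] = [d.abw for d in derived]
    out["EGFR_CKDEPI"] = [d.egfr_ckdepi for d in derived]
    out["CRCL_CG"] = [d.crcl_cg for d in derived]
    out["EGFR_MDRD"] = [d.egfr_mdrd for d in derived]
    return out
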