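"""Closed-form clinical indices: fatty liver index and MDRD-estimated GFR.

The fatty liver index (FLI) is a logistic score on the open interval
(0, 100) built from triglycerides, body mass index, gamma glutamyl
transpeptidase and waist circumference:

    L   = 0.953*ln(TG) + 0.139*BMI + 0.718*ln(GGT) + 0.053*WC - 15.745
    FLI = 100 * exp(L) / (1 + exp(L))

with TG in mg/dL, GGT in IU/L, BMI in kg/m^2 and WC in cm; logarithms are
natural. All four coefficients are positive, so the score is strictly
increasing in each input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

FLI_COEF_TG = 0.953
FLI_COEF_BMI = 0.139
FLI_COEF_GGT = 0.718
FLI_COEF_WC = 0.053
FLI_INTERCEPT = -15.745

MDRD_MULTIPLIER = 175.0  # IDMS-traceable 4-variable form
MDRD_FEMALE_FACTOR = 0.742


def fli_linear_predictor(tg, ggt, bmi, wc):
    """The logit-scale linear predictor L of the fatty liver index."""
    tg = np.asarray(tg, dtype=float)
    ggt = np.asarray(ggt, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (
            FLI_COEF_TG * np.log(tg)
            + FLI_COEF_BMI * np.asarray(bmi, dtype=float)
            + FLI_COEF_GGT * np.log(ggt)
            + FLI_COEF_WC * np.asarray(wc, dtype=float)
            + FLI_INTERCEPT
        )


def compute_fli(tg, ggt, bmi, wc):
    """Fatty liver index on the 0-100 scale.

    Accepts scalars or arrays. Scalar calls validate their inputs
    strictly (non-positive TG or GGT, or a missing value, raises
    ``ValueError``); array calls propagate NaN for invalid entries so
    whole cohort columns can be scored in one pass.
    """
    scalar = np.isscalar(tg) and np.isscalar(ggt) and np.isscalar(bmi) and np.isscalar(wc)
    if scalar:
        values = {"tg": tg, "ggt": ggt, "bmi": bmi, "wc": wc}
        for name, v in values.items():
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"missing FLI input: {name}")
        if tg <= 0 or ggt <= 0:
            raise ValueError("tg and ggt must be positive (logarithm undefined)")
        if bmi <= 0 or wc <= 0:
            raise ValueError("bmi and wc must be positive")
    result = 100.0 * expit(fli_linear_predictor(tg, ggt, bmi, wc))
    return float(result) if scalar else result


def add_fli_column(cohort: pd.DataFrame, column: str = "fli") -> pd.DataFrame:
    """Return a copy of the cohort with an FLI score column appended.

    Rows with missing or non-positive inputs get NaN.
    """
    out = cohort.copy()
    tg = out["tg"].to_numpy(dtype=float)
    ggt = out["ggt"].to_numpy(dtype=float)
    tg = np.where(tg > 0, tg, np.nan)
    ggt = np.where(ggt > 0, ggt, np.nan)
    out[column] = compute_fli(tg, ggt, out["bmi"].to_numpy(dtype=float),
                              out["wc"].to_numpy(dtype=float))
    return out


def compute_gfr_mdrd(creatinine, age, sex):
    """Estimated GFR (mL/min/1.73 m^2), 4-variable MDRD study equation.

    eGFR = 175 * Scr^-1.154 * age^-0.203 * (0.742 if female). The
    ethnicity coefficient is omitted. Scalars or arrays; for arrays,
    ``sex`` is an array of "male"/"female" strings.
    """
    scalar = np.isscalar(creatinine) and np.isscalar(age)
    cr = np.asarray(creatinine, dtype=float)
    ag = np.asarray(age, dtype=float)
    if scalar and (cr <= 0 or ag <= 0):
        raise ValueError("creatinine and age must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        cr = np.where(cr > 0, cr, np.nan)
        ag = np.where(ag > 0, ag, np.nan)
        gfr = MDRD_MULTIPLIER * cr ** -1.154 * ag ** -0.203
    female = np.asarray(sex) == "female"
    gfr = np.where(female, gfr * MDRD_FEMALE_FACTOR, gfr)
    return float(gfr) if scalar else gfr


def add_gfr_column(cohort: pd.DataFrame, column: str = "gfr") -> pd.DataFrame:
    out = cohort.copy()
    out[column] = compute_gfr_mdrd(
        out["creatinine"].to_numpy(dtype=float),
        out["age"].to_numpy(dtype=float),
        out["sex"].to_numpy(),
    )
    return out
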