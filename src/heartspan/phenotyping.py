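"""Anthropometric and comorbidity phenotyping.

Deterministic classifiers for body-mass index (BMI), waist circumference
(WC), the composite four-level adiposity phenotype that combines them, and
the cardiometabolic comorbidity flags (hypertension, diabetes,
hypercholesterolaemia, low HDL) used by the comorbidity-exclusion
sensitivity analysis.

All thresholds follow the WHO / AACE-ACE conventions used in Dutch cohort
practice:

* BMI: normal < 25, overweight 25 to < 30, obesity >= 30 kg/m^2.
* WC (sex-specific): healthy < 94/80 cm, abdominal overweight 94-<102 /
  80-<88 cm, abdominal obesity >= 102/88 cm for men/women.
* Composite adiposity: low, increased, high, very high (see
  ``DEFAULT_ADIPOSITY_MAPPING``).

Every interval is half-open with an inclusive lower bound, so a value
sitting exactly on a threshold classifies upward.

Functions accept scalars or array-likes and vectorize via numpy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

BMI_CATEGORIES = ("normal", "overweight", "obesity")
WC_CATEGORIES = ("healthy", "abdominal_overweight", "abdominal_obesity")
ADIPOSITY_CATEGORIES = ("low", "increased", "high", "very_high")

#: sex -> (lower, upper) WC cut points in cm
WC_CUTS = {"men": (94.0, 102.0), "women": (80.0, 88.0)}
BMI_CUTS = (25.0, 30.0)

#: (BMICategory, WCCategory) -> composite adiposity category.
#: BMI obesity dominates (very high regardless of WC); abdominal obesity
#: with BMI < 30 maps to high (including the discordant normal-BMI cell);
#: the remaining overweight/abdominal-overweight cells are "increased";
#: only concordantly healthy anthropometry is "low".  The mapping is
#: exposed so an alternative grid can be swapped in.
DEFAULT_ADIPOSITY_MAPPING = {
    ("normal", "healthy"): "low",
    ("normal", "abdominal_overweight"): "increased",
    ("normal", "abdominal_obesity"): "high",
    ("overweight", "healthy"): "increased",
    ("overweight", "abdominal_overweight"): "increased",
    ("overweight", "abdominal_obesity"): "high",
    ("obesity", "healthy"): "very_high",
    ("obesity", "abdominal_overweight"): "very_high",
    ("obesity", "abdominal_obesity"): "very_high",
}


def _check_sex(sex) -> np.ndarray:
    sex = np.asarray(sex, dtype=object)
    bad = ~np.isin(sex, ("men", "women"))
    if bad.any():
        raise ValueError(f"unknown sex value(s): {np.unique(sex[bad])!r}")
    return sex


def compute_bmi(weight, height):
    """BMI = weight / height^2 (kg/m^2), exact quotient.

    Parameters
    ----------
    weight : kg (scalar or array)
    height : m (scalar or array)
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(height[~np.isnan(height)] <= 0):
            raise ValueError("height must be positive")
        if np.any(weight[~np.isnan(weight)] <= 0):
            raise ValueError("weight must be positive")
    out = weight / height**2
    return float(out) if out.ndim == 0 else out


def classify_bmi(bmi):
    """BMI category: normal < 25, overweight [25, 30), obesity >= 30."""
    bmi = np.asarray(bmi, dtype=float)
    out = np.select(
        [bmi < BMI_CUTS[0], bmi < BMI_CUTS[1]],
        ["normal", "overweight"],
        default="obesity",
    ).astype(object)
    out = np.where(np.isnan(bmi), None, out)
    return out.item() if out.ndim == 0 else out


def classify_wc(wc, sex):
    """Sex-specific WC category with half-open, lower-inclusive intervals."""
    wc = np.asarray(wc, dtype=float)
    sex = _check_sex(sex)
    lo = np.where(sex == "men", WC_CUTS["men"][0], WC_CUTS["women"][0])
    hi = np.where(sex == "men", WC_CUTS["men"][1], WC_CUTS["women"][1])
    out = np.select(
        [wc < lo, wc < hi],
        ["healthy", "abdominal_overweight"],
        default="abdominal_obesity",
    ).astype(object)
    out = np.where(np.isnan(wc), None, out)
    return out.item() if out.ndim == 0 else out


def classify_adiposity(bmi_cat, wc_cat, mapping=None):
    """Composite adiposity category from (BMI category, WC category).

    Total and deterministic over the 3x3 grid; ``mapping`` may override
    ``DEFAULT_ADIPOSITY_MAPPING``.
    """
    mapping = DEFAULT_ADIPOSITY_MAPPING if mapping is None else mapping
    bmi_cat = np.asarray(bmi_cat, dtype=object)
    wc_cat = np.asarray(wc_cat, dtype=object)
    if bmi_cat.ndim == 0:
        if bmi_cat.item() is None or wc_cat.item() is None:
            return None
        return mapping[(bmi_cat.item(), wc_cat.item())]
    out = np.empty(bmi_cat.shape, dtype=object)
    for i, (b, w) in enumerate(zip(bmi_cat.ravel(), wc_cat.ravel())):
        out.ravel()[i] = None if (b is None or w is None) else mapping[(b, w)]
    return out


def classify_hypertension(sbp, dbp, on_meds):
    """SBP >= 140 and/or DBP >= 90 and/or antihypertensive medication."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    out = (sbp >= 140.0) | (dbp >= 90.0) | np.asarray(on_meds, dtype=bool)
    return bool(out) if out.ndim == 0 else out


def classify_diabetes(glucose, self_report):
    """Random plasma glucose >= 11.1 mmol/L or self-reported diabetes."""
    glucose = np.asarray(glucose, dtype=float)
    out = (glucose >= 11.1) | np.asarray(self_report, dtype=bool)
    return bool(out) if out.ndim == 0 else out


def classify_lipids(tc, hdl, on_lipid_meds, sex):
    """(hypercholesterolaemia, low HDL) flags.

    Hypercholesterolaemia: total cholesterol >= 6.5 mmol/L or lipid-lowering
    therapy.  Low HDL: < 1.03 mmol/L (men) / < 1.29 mmol/L (women).
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    sex = _check_sex(sex)
    hyperchol = (tc >= 6.5) | np.asarray(on_lipid_meds, dtype=bool)
    cut = np.where(sex == "men", 1.03, 1.29)
    low_hdl = hdl < cut
    if hyperchol.ndim == 0:
        return bool(hyperchol), bool(low_hdl)
    return hyperchol, low_hdl


def add_phenotypes(waves: pd.DataFrame, sex_by_id=None, mapping=None) -> pd.DataFrame:
    """Append bmi, bmi_cat, wc_cat and adiposity_cat columns to a wave table.

    ``waves`` needs columns id, height, weight, wc and either a ``sex``
    column or a ``sex_by_id`` mapping (Series indexed by id).  If the table
    already carries a ``bmi`` column that disagrees with weight/height^2 by
    more than 0.5 kg/m^2 it is recomputed with a warning: measured height
    and weight are the single source of truth.
    """
    waves = waves.copy()
    if "sex" not in waves.columns:
        waves["sex"] = waves["id"].map(sex_by_id)
    bmi = waves["weight"].to_numpy(float) / waves["height"].to_numpy(float) ** 2
    if "bmi" in waves.columns:
        old = waves["bmi"].to_numpy(float)
        clash = np.abs(old - bmi) > 0.5
        if np.any(clash & ~np.isnan(old) & ~np.isnan(bmi)):
            warnings.warn(
                f"{int(np.nansum(clash))} bmi values inconsistent with "
                "weight/height^2; recomputed",
                stacklevel=2,
            )
    waves["bmi"] = bmi
    waves["bmi_cat"] = classify_bmi(bmi)
    waves["wc_cat"] = classify_wc(waves["wc"].to_numpy(float), waves["sex"])
    waves["adiposity_cat"] = classify_adiposity(
        waves["bmi_cat"].to_numpy(object), waves["wc_cat"].to_numpy(object), mapping
    )
    return waves


def comorbidity_flags(participants: pd.DataFrame) -> pd.DataFrame:
    """Baseline comorbidity flags from raw biomarkers.

    Expects columns sbp, dbp, bp_meds, glucose, diabetes_self_report, tc,
    hdl, lipid_meds, copd, sex; returns a frame of boolean columns
    hypertension, diabetes, hypercholesterolaemia, low_hdl, copd indexed
    like the input.
    """
    p = participants
    hyperchol, low_hdl = classify_lipids(p["tc"], p["hdl"], p["lipid_meds"], p["sex"])
    return pd.DataFrame(
        {
            "hypertension": classify_hypertension(p["sbp"], p["dbp"], p["bp_meds"]),
            "diabetes": classify_diabetes(p["glucose"], p["diabetes_self_report"]),
            "hypercholesterolaemia": hyperchol,
            "low_hdl": low_hdl,
            "copd": p["copd"].astype(bool),
        },
        index=p.index,
    )
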