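"""Prevalence-calibrated multistate (illness-death) life tables.

Combines three ingredients estimated upstream — overall sex-specific
Gompertz transition rates, adjusted category hazard ratios, and
sex/age-band/CVD-status-specific exposure-category prevalences — into
category-specific life tables from age 50 to 80, and decomposes the
resulting temporary life expectancy into CVD-free years and years lived
with CVD.

The calibration identity recovers reference-category rates from overall
rates:

    r_ref(a) = r_overall(a) / sum_c p_c(a) HR_c,     r_c(a) = r_ref(a) HR_c

so that the prevalence-weighted average of category rates reproduces the
overall rate exactly at every age.  Within each 1-year interval rates are
treated as constant and the illness-death process is solved exactly (see
:func:`build_lifetable` for the two exposed conventions).  The table closes
at age 80 with no further accrual, so all quantities are temporary
(ages 50-80) expectancies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import GompertzRateModel, HazardRatioSet, REFERENCE_AGE

AGE_BANDS = ((50.0, 60.0), (60.0, 70.0), (70.0, 80.0))
BAND_LABELS = ("50-59", "60-69", "70-79")


def _band_of(age):
    """Band label per age (ages outside 50-80 return None)."""
    age = np.asarray(age, dtype=float)
    out = np.full(age.shape, None, dtype=object)
    for (lo, hi), lab in zip(AGE_BANDS, BAND_LABELS):
        out[(age >= lo) & (age < hi)] = lab
    return out


@dataclass
class PrevalenceTable:
    """Exposure-category distribution per (sex, 10-year band, CVD status).

    ``probs`` rows sum to one; ``pyears`` holds the person-years behind each
    cell (used as Dirichlet concentrations by the bootstrap).  Cells with no
    person-time borrow from the nearest populated band of the same sex and
    status; such cells are listed in ``borrowed``.
    """

    probs: pd.DataFrame  # MultiIndex (sex, band, cvd_status) x categories
    pyears: pd.DataFrame
    categories: tuple
    borrowed: list = field(default_factory=list)

    def vector(self, sex, band, cvd_status) -> np.ndarray:
        return self.probs.loc[(sex, band, int(cvd_status))].to_numpy(float)


def estimate_prevalences(pt: pd.DataFrame, categories=None) -> PrevalenceTable:
    """Occurrence-weighted category prevalences from person-time segments.

    Healthy-state shares come from the CVD-incidence segments, with-CVD
    shares from the CVD-mortality segments; weights are person-years within
    the 50-80 window, banded by segment mid-age.
    """
    if categories is None:
        from .cohort import EXPOSURE_CATEGORIES

        categories = EXPOSURE_CATEGORIES[pt.attrs.get("exposure_kind", "composite")]
    frames = []
    for status, transition in ((0, "healthy-cvd"), (1, "cvd-death")):
        sub = pt[pt["transition"] == transition].copy()
        sub["band"] = _band_of(sub["age_mid"])
        sub = sub[sub["band"].notna()]
        g = (
            sub.groupby(["sex", "band", "category"], observed=True)["pyears"]
            .sum()
            .unstack("category")
            .reindex(columns=list(categories))
            .fillna(0.0)
        )
        g["cvd_status"] = status
        frames.append(g.set_index("cvd_status", append=True))
    pyears = pd.concat(frames)
    full_index = pd.MultiIndex.from_product(
        [sorted(pt["sex"].unique()), BAND_LABELS, (0, 1)],
        names=["sex", "band", "cvd_status"],
    )
    pyears = pyears.reindex(full_index).fillna(0.0)

    probs = pyears.copy()
    borrowed = []
    for key, row in pyears.iterrows():
        total = row.sum()
        if total <= 0:
            sex, band, status = key
            donor = _nearest_band(pyears, sex, band, status)
            if donor is None:
                raise ValueError(f"no person-time anywhere for sex={sex}, status={status}")
            probs.loc[key] = (pyears.loc[donor] / pyears.loc[donor].sum()).to_numpy()
            pyears.loc[key] = pyears.loc[donor].to_numpy()
            borrowed.append(key)
            warnings.warn(f"prevalence cell {key} empty; borrowed from {donor}")
        else:
            probs.loc[key] = (row / total).to_numpy()
    return PrevalenceTable(probs, pyears, tuple(categories), borrowed)


def _nearest_band(pyears, sex, band, status):
    i = BAND_LABELS.index(band)
    order = sorted(range(len(BAND_LABELS)), key=lambda j: (abs(j - i), j))
    for j in order[1:]:
        key = (sex, BAND_LABELS[j], status)
        if pyears.loc[key].sum() > 0:
            return key
    return None


def estimate_initial_cvd(pt: pd.DataFrame, band: str = "50-59") -> pd.DataFrame:
    """Observed with-CVD person-time fraction per sex x category in a band.

    Used as the default mixed initial state of the life table at age 50.
    """
    sub = pt[pt["transition"].isin(["healthy-cvd", "cvd-death"])].copy()
    sub["band"] = _band_of(sub["age_mid"])
    sub = sub[sub["band"] == band]
    sub["state"] = np.where(sub["transition"] == "cvd-death", "cvd", "healthy")
    g = (
        sub.groupby(["sex", "category", "state"], observed=True)["pyears"]
        .sum()
        .unstack("state")
        .fillna(0.0)
    )
    for col in ("healthy", "cvd"):
        if col not in g:
            g[col] = 0.0
    frac = g["cvd"] / (g["cvd"] + g["healthy"]).replace(0.0, np.nan)
    return frac.fillna(0.0).unstack("category")


def calibrate_category_rates(overall_rate, hrs: dict, prev: dict) -> dict:
    """Reference-rate calibration at one age.

    ``overall_rate`` may be scalar or array; ``hrs`` and ``prev`` map
    category -> hazard ratio / prevalence.  Returns category -> rate such
    that sum_c p_c r_c equals the overall rate exactly.
    """
    cats = list(prev)
    denom = sum(prev[c] * hrs[c] for c in cats)
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("prevalence-weighted HR sum is zero")
    return {c: overall_rate / denom * hrs[c] for c in cats}


def rate_schedule_from_params(
    b0: float,
    gamma: float,
    hrs: dict,
    prev_probs: pd.DataFrame,
    sex: str,
    cvd_status: int,
    ages=None,
    step: float = 1.0,
) -> pd.DataFrame:
    """Per-age, per-category calibrated rates from raw parameter values.

    Overall rates are evaluated at interval midpoints; prevalences are step
    functions over 10-year bands.  Shared by the point-estimate path and
    the parametric bootstrap.
    """
    ages = np.arange(50.0, 80.0, step) if ages is None else np.asarray(ages, float)
    mid = ages + step / 2.0
    overall = np.exp(b0 + gamma * (mid - REFERENCE_AGE))
    cats = list(hrs)
    out = np.empty((len(ages), len(cats)))
    bands = _band_of(mid)
    for i, (a, band) in enumerate(zip(ages, bands)):
        p = prev_probs.loc[(sex, band, cvd_status)]
        r = calibrate_category_rates(overall[i], hrs, {c: p[c] for c in cats})
        out[i] = [r[c] for c in cats]
    return pd.DataFrame(out, index=pd.Index(ages, name="age"), columns=cats)


def category_rate_schedule(
    overall: GompertzRateModel,
    hr_set: HazardRatioSet,
    prev: PrevalenceTable,
    sex: str,
    ages=None,
    step: float = 1.0,
) -> pd.DataFrame:
    """Calibrated per-category rate schedule for one fitted transition."""
    status = 1 if overall.transition == "cvd-death" else 0
    return rate_schedule_from_params(
        overall.b0, overall.gamma, hr_set.hr_dict(), prev.probs, sex, status, ages, step
    )


@dataclass
class MultistateLifeTable:
    """Age-indexed state occupancies, transition probabilities, person-years."""

    df: pd.DataFrame  # per-age rows
    step: float
    start: float
    close: float

    @property
    def ages(self):
        return self.df["age"].to_numpy()


@dataclass
class LifeExpectancyEstimate:
    total: float
    cvd_free: float
    with_cvd: float

    def as_tuple(self):
        return (self.total, self.cvd_free, self.with_cvd)


def build_lifetable(
    r12, r13, r23, start=50.0, close=80.0, step=1.0, init_cvd=0.0,
    convention: str = "exponential",
):
    """Deterministic illness-death life table on a fixed age grid.

    ``r12``, ``r13``, ``r23`` are per-interval transition rates (1/yr),
    constant within each ``step``-year interval, for CVD incidence, healthy
    mortality and CVD mortality.  ``init_cvd`` is the with-CVD occupancy at
    the starting age (the rest starts healthy).

    Two within-interval conventions are exposed.  The default,
    ``"exponential"``, is the exact closed-form solution of the
    constant-rate illness-death process within each interval: people
    acquiring CVD mid-interval are exposed to the CVD-mortality rate for
    the remainder of the interval, and person-years are exact sojourn
    expectations.  ``"trapezoid"`` is the simpler textbook flow (entrants
    carry no within-interval mortality; person-years by the trapezoid
    rule, i.e. transitioners credited half an interval); it overstates
    with-CVD years by O(q12*q23) per interval and is retained only for
    comparison.  In both, the probability of leaving the healthy state is
    1 - exp(-(r12+r13) step), apportioned in proportion to the
    cause-specific rates, and q23 = 1 - exp(-r23 step).
    """
    if convention not in ("exponential", "trapezoid"):
        raise ValueError(f"unknown convention {convention!r}")
    ages = np.arange(start, close, step)
    r12, r13, r23 = (np.broadcast_to(np.asarray(r, float), ages.shape) for r in (r12, r13, r23))
    if np.any(r12 < 0) or np.any(r13 < 0) or np.any(r23 < 0):
        raise ValueError("negative transition rates")
    n = len(ages)
    h = step
    lh = np.empty(n + 1)
    lc = np.empty(n + 1)
    ld = np.empty(n + 1)
    lh[0], lc[0], ld[0] = 1.0 - init_cvd, init_cvd, 0.0
    q12 = np.zeros(n)
    q13 = np.zeros(n)
    q23 = -np.expm1(-r23 * h)
    Lh = np.empty(n)
    Lc = np.empty(n)
    for i in range(n):
        R = r12[i] + r13[i]
        m23 = r23[i]
        if R > 0:
            leave = -np.expm1(-R * h)
            q12[i] = r12[i] / R * leave
            q13[i] = r13[i] / R * leave
        if convention == "trapezoid":
            lh[i + 1] = lh[i] * (1.0 - q12[i] - q13[i])
            lc[i + 1] = lc[i] * (1.0 - q23[i]) + lh[i] * q12[i]
            ld[i + 1] = ld[i] + lh[i] * q13[i] + lc[i] * q23[i]
            Lh[i] = 0.5 * (lh[i] + lh[i + 1]) * h
            Lc[i] = 0.5 * (lc[i] + lc[i + 1]) * h
            continue
        # exact constant-rate solution within the interval
        eh = _sojourn(R, h)  # expected healthy time per person starting healthy
        ec = _sojourn(m23, h)  # expected with-CVD time per person starting with CVD
        if R > 0:
            # P(healthy->CVD and still alive at interval end)
            if abs(R - m23) > 1e-12:
                q12_surv = r12[i] * np.exp(-m23 * h) * -np.expm1(-(R - m23) * h) / (R - m23)
            else:
                q12_surv = r12[i] * h * np.exp(-R * h)
            # expected with-CVD time accrued by entrants within the interval
            if m23 > 1e-12:
                ec_new = (q12[i] - q12_surv) / m23
            else:
                # r23 ~ 0: entrants survive; integrate remaining time directly
                ec_new = r12[i] * (
                    h * -np.expm1(-R * h) / R
                    - (1.0 - (1.0 + R * h) * np.exp(-R * h)) / R**2
                )
        else:
            q12_surv = 0.0
            ec_new = 0.0
        lh[i + 1] = lh[i] * (1.0 - q12[i] - q13[i])
        lc[i + 1] = lc[i] * (1.0 - q23[i]) + lh[i] * q12_surv
        ld[i + 1] = (
            ld[i] + lh[i] * q13[i] + lc[i] * q23[i] + lh[i] * (q12[i] - q12_surv)
        )
        Lh[i] = lh[i] * eh
        Lc[i] = lc[i] * ec + lh[i] * ec_new
    df = pd.DataFrame(
        {
            "age": ages,
            "l_healthy": lh[:-1],
            "l_cvd": lc[:-1],
            "l_dead": ld[:-1],
            "q12": q12,
            "q13": q13,
            "q23": q23,
            "L_healthy": Lh,
            "L_cvd": Lc,
        }
    )
    return MultistateLifeTable(df, step=step, start=start, close=close)


def _sojourn(rate, h):
    """Expected time spent in a state over [0, h) at constant exit rate."""
    return -np.expm1(-rate * h) / rate if rate > 1e-12 else h * (1.0 - rate * h / 2.0)


def le_decompose(table: MultistateLifeTable) -> LifeExpectancyEstimate:
    """Temporary life expectancies over [start, close): total = free + with."""
    cvd_free = float(table.df["L_healthy"].sum())
    with_cvd = float(table.df["L_cvd"].sum())
    return LifeExpectancyEstimate(cvd_free + with_cvd, cvd_free, with_cvd)


def le_difference(
    est: LifeExpectancyEstimate, ref: LifeExpectancyEstimate
) -> LifeExpectancyEstimate:
    """Category-minus-reference differences, component-wise."""
    return LifeExpectancyEstimate(
        est.total - ref.total, est.cvd_free - ref.cvd_free, est.with_cvd - ref.with_cvd
    )


def lifetables_by_category(
    overall_models: dict,
    hr_sets: dict,
    prev: PrevalenceTable,
    sex: str,
    init_cvd=None,
    start=50.0,
    close=80.0,
    step=1.0,
):
    """Category-specific life tables for one sex.

    ``overall_models``/``hr_sets`` are keyed by (sex, transition);
    ``init_cvd`` maps category -> with-CVD occupancy at the start age
    (default: everyone starts CVD-free).
    """
    ages = np.arange(start, close, step)
    scheds = {
        tr: category_rate_schedule(
            overall_models[(sex, tr)], hr_sets[(sex, tr)], prev, sex, ages, step
        )
        for tr in ("healthy-cvd", "healthy-death", "cvd-death")
    }
    out = {}
    for c in scheds["healthy-cvd"].columns:
        if init_cvd is None:
            ic = 0.0
        else:
            val = init_cvd.loc[sex].get(c, 0.0)
            ic = float(val) if pd.notna(val) else 0.0
        out[c] = build_lifetable(
            scheds["healthy-cvd"][c].to_numpy(),
            scheds["healthy-death"][c].to_numpy(),
            scheds["cvd-death"][c].to_numpy(),
            start=start,
            close=close,
            step=step,
            init_cvd=ic,
        )
    return out
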