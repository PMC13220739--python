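"""Synthetic longitudinal cohort generator.

Emulates a Dutch population-based cohort of adults aged 50+ followed over
repeated examination waves for incident cardiovascular disease (CVD) and
death, with the statistical structure the downstream multistate analysis
assumes:

* bivariate log-normal (BMI, WC) anthropometry per sex, calibrated so that
  the marginal BMI/WC category prevalences and the composite adiposity
  categories reproduce the reference cohort's baseline table, and the pooled
  BMI-WC Pearson correlation is ~0.81;
* per-wave anthropometry evolving by a small correlated random walk, so
  exposure is genuinely time-varying;
* a Markov illness-death process (healthy -> CVD -> dead, plus
  healthy -> dead) with Gompertz (log-linear in attained age) baseline
  hazards and category-specific proportional effects;
* exclusion-flagged extras (cancer history, unknown cancer status,
  pregnancy) so the eligibility filter has work to do, and an optional
  missing-anthropometry fraction so complete-case selection has work to do.

The default configuration is the generator's "stated world": cohort scale
(2,566-person roster filtering to 2,323 eligible), 49% women, entry ages
50-80 weighted like the reference age distribution, five waves ~5 years
apart, 22 years of administrative censoring, true hazard ratios set to the
published adjusted estimates, and baseline Gompertz hazards calibrated once
so that ~695 incident CVD events and ~587 deaths occur over follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import phenotyping
from .phenotyping import ADIPOSITY_CATEGORIES

TRANSITIONS = ("healthy-cvd", "healthy-death", "cvd-death")
SEXES = ("men", "women")

# Log-normal anthropometry parameters solved by probit inversion from the
# reference cohort's marginal BMI and WC category prevalences (men: normal
# 25.3%, overweight 58.4%; healthy WC 26.5%, abdominal overweight 33.6%;
# women: 34.1%/44.0% and 14.5%/24.9%).  rho = 0.873 on the log scale makes
# the pooled (both-sex) raw-scale Pearson correlation between BMI and WC
# equal 0.81.
DEFAULT_ANTHRO_PARAMS = {
    "men": dict(
        mu_log_bmi=3.29249, sd_log_bmi=0.11068,
        mu_log_wc=4.60132, sd_log_wc=0.09240,
        rho=0.873, height_mean=1.78, height_sd=0.066,
    ),
    "women": dict(
        mu_log_bmi=3.28190, sd_log_bmi=0.15382,
        mu_log_wc=4.50981, sd_log_wc=0.12077,
        rho=0.873, height_mean=1.65, height_sd=0.062,
    ),
}

# True hazard ratios: the published sex-specific adjusted estimates per
# transition and adiposity category (low is the reference).
DEFAULT_TRUE_HR = {
    "men": {
        "healthy-cvd": {"low": 1.0, "increased": 1.07, "high": 1.14, "very_high": 1.66},
        "healthy-death": {"low": 1.0, "increased": 0.90, "high": 1.23, "very_high": 1.25},
        "cvd-death": {"low": 1.0, "increased": 1.21, "high": 1.45, "very_high": 1.84},
    },
    "women": {
        "healthy-cvd": {"low": 1.0, "increased": 0.77, "high": 1.03, "very_high": 1.02},
        "healthy-death": {"low": 1.0, "increased": 1.13, "high": 1.30, "very_high": 0.98},
        "cvd-death": {"low": 1.0, "increased": 0.69, "high": 0.91, "very_high": 0.81},
    },
}

# Baseline (low-category) Gompertz hazards (rate/yr at age 50, slope /yr),
# calibrated once by simulation so the default cohort produces ~401/294
# incident CVD events and ~323/264 deaths (men/women) over 22 years.
DEFAULT_BASELINE_HAZARDS = {
    "men": {
        "healthy-cvd": (0.00356, 0.075),
        "healthy-death": (0.00110, 0.095),
        "cvd-death": (0.00275, 0.090),
    },
    "women": {
        "healthy-cvd": (0.00288, 0.075),
        "healthy-death": (0.00077, 0.095),
        "cvd-death": (0.00495, 0.090),
    },
}

# Covariate category probabilities per sex (baseline table of the reference
# cohort, renormalised where the printed column does not sum to 100%).
DEFAULT_COVARIATE_MIXTURE = {
    "men": dict(
        household_with_others=0.933,
        education=(0.109, 0.636, 0.255),
        pa_index=(0.142, 0.290, 0.259, 0.309),
        smoking=(0.228, 0.236, 0.536),
        cigs_log_median=15.0, cigs_log_sigma=0.51,
        dhd15_mean=64.0, dhd15_sd=13.4,
        alcohol=(0.087, 0.132, 0.033, 0.441, 0.307),
        copd=0.160,
        sbp_mean=135.0, sbp_sd=18.0, dbp_mean=82.0, dbp_sd=10.0, bp_corr=0.6,
        bp_meds=0.14,
        glucose_log_median=5.5, glucose_log_sigma=0.25, diabetes_self_report=0.045,
        tc_mean=5.75, tc_sd=0.96, lipid_meds=0.013,
        hdl_log_median=1.29, hdl_log_sigma=0.214,
    ),
    "women": dict(
        household_with_others=0.850,
        education=(0.128, 0.712, 0.160),
        pa_index=(0.119, 0.313, 0.296, 0.272),
        smoking=(0.452, 0.216, 0.332),
        cigs_log_median=12.0, cigs_log_sigma=0.68,
        dhd15_mean=70.0, dhd15_sd=13.2,
        alcohol=(0.196, 0.233, 0.072, 0.231, 0.268),
        copd=0.162,
        sbp_mean=131.0, sbp_sd=18.0, dbp_mean=79.0, dbp_sd=10.0, bp_corr=0.6,
        bp_meds=0.175,
        glucose_log_median=5.4, glucose_log_sigma=0.24, diabetes_self_report=0.032,
        tc_mean=6.05, tc_sd=1.04, lipid_meds=0.015,
        hdl_log_median=1.58, hdl_log_sigma=0.13,
    ),
}

EDUCATION_LEVELS = ("low", "medium", "high")
PA_LEVELS = ("inactive", "moderately_inactive", "moderately_active", "active")
SMOKING_LEVELS = ("never", "current", "former")
ALCOHOL_LEVELS = ("none", "occasional", "light", "moderate", "heavy")


@dataclass
class SyntheticCohortConfig:
    """Stated world of the synthetic cohort.

    ``n_participants`` is the full roster *before* eligibility exclusions;
    with the default exclusion fractions a 2,566-person roster filters to
    2,323 eligible participants.
    """

    n_participants: int = 2566
    fraction_women: float = 0.498
    age_range_at_entry: tuple = (50.0, 80.0)
    #: probability of entering in the 50-59 / 60-69 / 70-79 band
    age_band_probs: tuple = (0.592, 0.392, 0.016)
    n_waves: int = 5
    wave_spacing: float = 5.0
    anthro_params: dict = field(default_factory=lambda: _deepcopy(DEFAULT_ANTHRO_PARAMS))
    #: per-wave SD of the correlated random walk on log BMI / log WC
    wave_drift_sd: float = 0.035
    covariate_mixture: dict = field(default_factory=lambda: _deepcopy(DEFAULT_COVARIATE_MIXTURE))
    baseline_hazards: dict = field(default_factory=lambda: _deepcopy(DEFAULT_BASELINE_HAZARDS))
    true_hr: dict = field(default_factory=lambda: _deepcopy(DEFAULT_TRUE_HR))
    exclusion_fractions: dict = field(
        default_factory=lambda: {
            "cancer_history": 114 / 2566,
            "cancer_unknown": 128 / 2566,
            "pregnant": 1 / 2566,
        }
    )
    #: fraction of participants per sex with no valid anthropometry at any wave
    missing_exposure_fraction: dict = field(
        default_factory=lambda: {"men": 0.105, "women": 0.056}
    )
    admin_censoring: float = 22.0
    #: > 0 links smoking/physical-activity to both adiposity and hazards
    confounding_strength: float = 0.0
    seed: int = 20260917

    def __post_init__(self):
        if not 0 <= self.fraction_women <= 1:
            raise ValueError("fraction_women must be in [0, 1]")
        if self.wave_spacing <= 0:
            raise ValueError("wave_spacing must be positive")
        if self.admin_censoring <= 0:
            raise ValueError("admin_censoring must be positive")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        for frac in self.exclusion_fractions.values():
            if not 0 <= frac <= 1:
                raise ValueError("exclusion fractions must be in [0, 1]")
        for sex in SEXES:
            p = self.anthro_params[sex]
            if p["sd_log_bmi"] <= 0 or p["sd_log_wc"] <= 0:
                raise ValueError("anthropometry SDs must be positive")
            if abs(p["rho"]) > 1:
                raise ValueError("|rho| must be <= 1")
            for tr in TRANSITIONS:
                lam, gamma = self.baseline_hazards[sex][tr]
                if lam < 0:
                    raise ValueError("baseline rate must be >= 0")
                if not math.isfinite(gamma):
                    raise ValueError("Gompertz slope must be finite")
                if self.true_hr[sex][tr]["low"] != 1.0:
                    raise ValueError("reference-category hazard ratio must be 1")

    def with_(self, **kwargs) -> "SyntheticCohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _deepcopy(obj):
    import copy

    return copy.deepcopy(obj)


@dataclass
class Cohort:
    """In-memory synthetic cohort: three tidy tables sharing an ``id`` key."""

    participants: pd.DataFrame  # one row per person: sex, entry age, covariates, flags
    waves: pd.DataFrame  # one row per person-wave: age, height, weight, wc
    events: pd.DataFrame  # one row per person: entry_age, age_cvd, age_death, age_censor
    config: Optional[SyntheticCohortConfig] = None

    def copy(self) -> "Cohort":
        return Cohort(
            self.participants.copy(), self.waves.copy(), self.events.copy(), self.config
        )


# ---------------------------------------------------------------------------
# samplers


def sample_gompertz_time(lam, gamma, u):
    """Inverse-transform sample of a Gompertz event time.

    Solves S(t) = u with S(t) = exp(-(lam/gamma)(e^{gamma t} - 1)); returns
    +inf where the distribution is defective (gamma < 0 and u below the
    survival plateau) or lam = 0.  ``lam``/``u`` may be arrays.
    """
    lam = np.asarray(lam, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly inside (0, 1)")
    neglogu = -np.log(u)
    if gamma == 0.0:
        with np.errstate(divide="ignore"):
            t = np.where(lam > 0, neglogu / np.where(lam > 0, lam, 1.0), np.inf)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            arg = 1.0 + gamma * neglogu / np.where(lam > 0, lam, np.nan)
            t = np.where(
                (lam > 0) & (arg > 0), np.log(np.maximum(arg, 1e-300)) / gamma, np.inf
            )
    return float(t) if t.ndim == 0 else t


def generate_anthropometry(n, sex, anthro_params=None, rng=None):
    """Sample (height m, weight kg, wc cm, bmi kg/m^2) for ``n`` people of one sex.

    BMI and WC are jointly log-normal with log-scale correlation
    ``anthro_params[sex]['rho']``; height is sampled separately and weight
    back-solved from BMI, which guarantees positive values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = (anthro_params or DEFAULT_ANTHRO_PARAMS)[sex]
    if params["sd_log_bmi"] <= 0 or params["sd_log_wc"] <= 0:
        raise ValueError("SDs must be positive")
    if abs(params["rho"]) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(rng)
    z = _correlated_normals(n, params["rho"], rng)
    bmi = np.exp(params["mu_log_bmi"] + params["sd_log_bmi"] * z[:, 0])
    wc = np.exp(params["mu_log_wc"] + params["sd_log_wc"] * z[:, 1])
    height = rng.normal(params["height_mean"], params["height_sd"], size=n)
    height = np.clip(height, 1.30, 2.20)
    weight = bmi * height**2
    return pd.DataFrame({"height": height, "weight": weight, "wc": wc, "bmi": bmi})


def _correlated_normals(n, rho, rng):
    z = rng.standard_normal((n, 2))
    z[:, 1] = rho * z[:, 0] + math.sqrt(1.0 - rho**2) * z[:, 1]
    return z


# ---------------------------------------------------------------------------
# event histories


def simulate_event_histories(
    entry_ages, cat_idx, sex, config, rng, loghr_extra=None
):
    """Vectorised illness-death simulation for one sex.

    Parameters
    ----------
    entry_ages : (n,) entry ages in years.
    cat_idx : (n, n_waves) int indices into ``ADIPOSITY_CATEGORIES`` giving
        each participant's current exposure category per wave interval
        (hazards update at wave times, i.e. last observation carried forward
        on the *true* trajectory).
    loghr_extra : optional (n,) additive log-hazard per participant applied
        to every transition (confounding knob).

    Returns a DataFrame with entry_age, age_cvd, age_death, age_censor.
    Competing first events from the healthy state; after CVD, mortality
    follows the CVD->death hazard on the attained-age clock (Markov).  No
    backflows by construction; administrative censoring caps everything.
    """
    entry_ages = np.asarray(entry_ages, dtype=float)
    n = entry_ages.shape[0]
    cat_idx = np.asarray(cat_idx)
    if cat_idx.ndim == 1:
        cat_idx = np.tile(cat_idx[:, None], (1, config.n_waves))
    extra = np.zeros(n) if loghr_extra is None else np.asarray(loghr_extra, float)

    haz = config.baseline_hazards[sex]
    hr = {
        tr: np.array([config.true_hr[sex][tr][c] for c in ADIPOSITY_CATEGORIES])
        for tr in TRANSITIONS
    }
    lam12, g12 = haz["healthy-cvd"]
    lam13, g13 = haz["healthy-death"]
    lam23, g23 = haz["cvd-death"]

    bounds = [k * config.wave_spacing for k in range(config.n_waves)]
    bounds = [b for b in bounds if b < config.admin_censoring] + [config.admin_censoring]

    state = np.zeros(n, dtype=int)  # 0 healthy, 1 cvd, 2 dead
    age_cvd = np.full(n, np.nan)
    age_death = np.full(n, np.nan)
    emult = np.exp(extra)

    for k in range(len(bounds) - 1):
        t0, t1 = bounds[k], bounds[k + 1]
        seg = t1 - t0
        cat = cat_idx[:, min(k, cat_idx.shape[1] - 1)]
        a0 = entry_ages + t0
        u = rng.random((n, 4))
        u = np.clip(u, 1e-12, 1 - 1e-12)

        healthy = state == 0
        l12 = lam12 * np.exp(g12 * (a0 - 50.0)) * hr["healthy-cvd"][cat] * emult
        l13 = lam13 * np.exp(g13 * (a0 - 50.0)) * hr["healthy-death"][cat] * emult
        t12 = sample_gompertz_time(l12, g12, u[:, 0])
        t13 = sample_gompertz_time(l13, g13, u[:, 1])
        tmin = np.minimum(t12, t13)
        hit = healthy & (tmin < seg)
        cvd_first = hit & (t12 <= t13)
        death_first = hit & ~cvd_first
        age_death[death_first] = a0[death_first] + t13[death_first]
        state[death_first] = 2
        age_cvd[cvd_first] = a0[cvd_first] + t12[cvd_first]
        state[cvd_first] = 1
        # mortality for the remainder of the interval after incident CVD
        a1 = np.where(cvd_first, age_cvd, a0)
        l23_new = lam23 * np.exp(g23 * (a1 - 50.0)) * hr["cvd-death"][cat] * emult
        t23 = sample_gompertz_time(l23_new, g23, u[:, 2])
        die_new = cvd_first & (a1 + t23 < entry_ages + t1)
        age_death[die_new] = a1[die_new] + t23[die_new]
        state[die_new] = 2
        # mortality for people already in the CVD state at interval start
        was_cvd = (state == 1) & ~cvd_first
        l23_old = lam23 * np.exp(g23 * (a0 - 50.0)) * hr["cvd-death"][cat] * emult
        t23_old = sample_gompertz_time(l23_old, g23, u[:, 3])
        die_old = was_cvd & (t23_old < seg)
        age_death[die_old] = a0[die_old] + t23_old[die_old]
        state[die_old] = 2

    return pd.DataFrame(
        {
            "entry_age": entry_ages,
            "age_cvd": age_cvd,
            "age_death": age_death,
            "age_censor": entry_ages + config.admin_censoring,
        }
    )


def simulate_event_history(entry_age, exposure_category, sex, config, rng=None):
    """Single-participant wrapper with a fixed exposure category."""
    lo, hi = config.age_range_at_entry
    if not lo <= entry_age <= hi:
        raise ValueError(f"entry_age {entry_age} outside configured range {lo}-{hi}")
    if exposure_category not in ADIPOSITY_CATEGORIES:
        raise ValueError(f"unknown exposure category {exposure_category!r}")
    rng = np.random.default_rng(rng)
    cat = ADIPOSITY_CATEGORIES.index(exposure_category)
    out = simulate_event_histories(
        np.array([entry_age]), np.array([cat]), sex, config, rng
    )
    return out.iloc[0]


# ---------------------------------------------------------------------------
# full cohort


def generate_cohort(config: Optional[SyntheticCohortConfig] = None, seed=None) -> Cohort:
    """Generate a full synthetic roster (participants, waves, events).

    Reproducible: a fixed (config, seed) pair yields byte-identical tables.
    ``seed`` overrides ``config.seed``.
    """
    config = config or SyntheticCohortConfig()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("structure", "anthro", "covariates", "events", "selection"),
            root.spawn(5),
        )
    }
    n = config.n_participants
    rng = streams["structure"]

    ids = np.arange(n)
    n_women = int(round(config.fraction_women * n))
    sex = np.array(["men"] * n, dtype=object)
    sex[rng.choice(n, size=n_women, replace=False)] = "women"

    band = rng.choice(3, size=n, p=np.asarray(config.age_band_probs))
    band_edges = np.array([[50.0, 60.0], [60.0, 70.0], [70.0, 80.0]])
    entry_age = band_edges[band, 0] + rng.random(n) * (
        band_edges[band, 1] - band_edges[band, 0]
    )
    lo, hi = config.age_range_at_entry
    entry_age = np.clip(entry_age, lo, hi)

    participants = pd.DataFrame({"id": ids, "sex": sex, "entry_age": entry_age})
    covs = _generate_covariates(sex, config, streams["covariates"])
    participants = pd.concat([participants, covs], axis=1)

    # confounding knob: smoking/inactivity raise both adiposity and hazards
    conf_score = 0.6 * (covs["smoking"] == "current").to_numpy(float) + 0.3 * (
        covs["pa_index"] == "inactive"
    ).to_numpy(float)
    kappa = config.confounding_strength
    loghr_extra = kappa * 0.25 * conf_score

    # anthropometry paths: baseline + correlated random walk per wave
    arng = streams["anthro"]
    K = config.n_waves
    log_bmi = np.empty((n, K))
    log_wc = np.empty((n, K))
    height = np.empty(n)
    for s in SEXES:
        m = sex == s
        p = config.anthro_params[s]
        z = _correlated_normals(int(m.sum()), p["rho"], arng)
        log_bmi[m, 0] = p["mu_log_bmi"] + p["sd_log_bmi"] * z[:, 0] + kappa * 0.10 * conf_score[m]
        log_wc[m, 0] = p["mu_log_wc"] + p["sd_log_wc"] * z[:, 1] + kappa * 0.08 * conf_score[m]
        height[m] = np.clip(
            arng.normal(p["height_mean"], p["height_sd"], size=int(m.sum())), 1.30, 2.20
        )
        rho_w = p["rho"]
        for k in range(1, K):
            dz = _correlated_normals(int(m.sum()), rho_w, arng)
            log_bmi[m, k] = log_bmi[m, k - 1] + config.wave_drift_sd * dz[:, 0]
            log_wc[m, k] = log_wc[m, k - 1] + config.wave_drift_sd * dz[:, 1]

    bmi_path = np.exp(log_bmi)
    wc_path = np.exp(log_wc)

    # true exposure category per wave (drives the hazards)
    cat_idx = np.empty((n, K), dtype=int)
    cat_lookup = {c: i for i, c in enumerate(ADIPOSITY_CATEGORIES)}
    for k in range(K):
        bmi_cat = phenotyping.classify_bmi(bmi_path[:, k])
        wc_cat = phenotyping.classify_wc(wc_path[:, k], sex)
        adip = phenotyping.classify_adiposity(bmi_cat, wc_cat)
        cat_idx[:, k] = [cat_lookup[c] for c in adip]

    # events, per sex (different baseline hazards and HRs)
    erng = streams["events"]
    events = pd.DataFrame(
        index=ids,
        columns=["entry_age", "age_cvd", "age_death", "age_censor"],
        dtype=float,
    )
    for s in SEXES:
        m = sex == s
        ev = simulate_event_histories(
            entry_age[m], cat_idx[m], s, config, erng, loghr_extra=loghr_extra[m]
        )
        events.loc[m, :] = ev.to_numpy()
    events.insert(0, "id", ids)
    events = events.reset_index(drop=True)

    # selection: exclusion flags (mutually exclusive) and missing anthropometry
    srng = streams["selection"]
    flags = pd.DataFrame(
        False, index=ids, columns=["cancer_history", "cancer_unknown", "pregnant"]
    )
    order = srng.permutation(n)
    pos = 0
    for name in ("cancer_history", "cancer_unknown", "pregnant"):
        count = int(round(config.exclusion_fractions.get(name, 0.0) * n))
        take = order[pos : pos + count]
        if name == "pregnant":
            take = np.array([i for i in take if sex[i] == "women"], dtype=int)
        flags.loc[take, name] = True
        pos += count
    participants = pd.concat([participants, flags.reset_index(drop=True)], axis=1)

    missing = np.zeros(n, dtype=bool)
    for s in SEXES:
        m_ids = ids[sex == s]
        k = int(round(config.missing_exposure_fraction.get(s, 0.0) * len(m_ids)))
        if k:
            missing[srng.choice(m_ids, size=k, replace=False)] = True
    participants["missing_anthro"] = missing

    # wave table: one row per wave attended (alive and before censoring)
    wave_age = entry_age[:, None] + config.wave_spacing * np.arange(K)[None, :]
    end_age = np.fmin(events["age_death"].to_numpy(), events["age_censor"].to_numpy())
    attended = wave_age <= end_age[:, None]
    ii, kk = np.nonzero(attended)
    waves = pd.DataFrame(
        {
            "id": ids[ii],
            "wave": kk,
            "age": wave_age[ii, kk],
            "height": height[ii],
            "weight": bmi_path[ii, kk] * height[ii] ** 2,
            "wc": wc_path[ii, kk],
        }
    )
    masked = missing[ii]
    waves.loc[masked, ["height", "weight", "wc"]] = np.nan

    return Cohort(participants, waves, events, config)


def _generate_covariates(sex, config, rng) -> pd.DataFrame:
    """Baseline covariates and biomarkers from per-sex mixture distributions."""
    n = len(sex)
    out = pd.DataFrame(index=np.arange(n))
    cols = {
        "household": np.empty(n, object),
        "education": np.empty(n, object),
        "pa_index": np.empty(n, object),
        "smoking": np.empty(n, object),
        "alcohol": np.empty(n, object),
        "dhd15": np.empty(n),
        "cigs_per_day": np.full(n, np.nan),
        "copd": np.zeros(n, bool),
        "sbp": np.empty(n),
        "dbp": np.empty(n),
        "bp_meds": np.zeros(n, bool),
        "glucose": np.empty(n),
        "diabetes_self_report": np.zeros(n, bool),
        "tc": np.empty(n),
        "hdl": np.empty(n),
        "lipid_meds": np.zeros(n, bool),
    }
    for s in SEXES:
        m = np.asarray(sex) == s
        k = int(m.sum())
        mix = config.covariate_mixture[s]
        cols["household"][m] = np.where(
            rng.random(k) < mix["household_with_others"], "with_others", "alone"
        )
        cols["education"][m] = rng.choice(
            EDUCATION_LEVELS, size=k, p=_norm(mix["education"])
        )
        cols["pa_index"][m] = rng.choice(PA_LEVELS, size=k, p=_norm(mix["pa_index"]))
        smoking = rng.choice(SMOKING_LEVELS, size=k, p=_norm(mix["smoking"]))
        cols["smoking"][m] = smoking
        cigs = np.full(k, np.nan)
        cur = smoking == "current"
        cigs[cur] = np.maximum(
            1,
            np.round(
                np.exp(
                    math.log(mix["cigs_log_median"])
                    + mix["cigs_log_sigma"] * rng.standard_normal(int(cur.sum()))
                )
            ),
        )
        cols["cigs_per_day"][m] = cigs
        cols["dhd15"][m] = np.clip(
            rng.normal(mix["dhd15_mean"], mix["dhd15_sd"], size=k), 1.0, 130.0
        )
        cols["alcohol"][m] = rng.choice(ALCOHOL_LEVELS, size=k, p=_norm(mix["alcohol"]))
        cols["copd"][m] = rng.random(k) < mix["copd"]
        zb = rng.standard_normal(k)
        zd = mix["bp_corr"] * zb + math.sqrt(1 - mix["bp_corr"] ** 2) * rng.standard_normal(k)
        cols["sbp"][m] = mix["sbp_mean"] + mix["sbp_sd"] * zb
        cols["dbp"][m] = mix["dbp_mean"] + mix["dbp_sd"] * zd
        cols["bp_meds"][m] = rng.random(k) < mix["bp_meds"]
        cols["glucose"][m] = np.exp(
            math.log(mix["glucose_log_median"])
            + mix["glucose_log_sigma"] * rng.standard_normal(k)
        )
        cols["diabetes_self_report"][m] = rng.random(k) < mix["diabetes_self_report"]
        cols["tc"][m] = rng.normal(mix["tc_mean"], mix["tc_sd"], size=k)
        cols["hdl"][m] = np.exp(
            math.log(mix["hdl_log_median"]) + mix["hdl_log_sigma"] * rng.standard_normal(k)
        )
        cols["lipid_meds"][m] = rng.random(k) < mix["lipid_meds"]
    for name, arr in cols.items():
        out[name] = arr
    return out


def _norm(p):
    p = np.asarray(p, dtype=float)
    return p / p.sum()
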