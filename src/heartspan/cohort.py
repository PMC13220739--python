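"""Eligibility filtering and transition-specific person-time construction.

The estimation unit downstream is the *person-time segment*: one row per
(participant x transition x exposure interval x 1-year attained-age
interval), with entry/exit age, person-years, an event flag, the current
exposure category (last observation carried forward from examination
waves) and the participant's baseline covariates.

Healthy person-time contributes simultaneously to the CVD-incidence and
healthy-mortality transitions (the event flag is set on whichever was
realised); person-time after incident CVD contributes to the CVD-mortality
transition.  No backflows: only the first event within a state counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import Cohort
from . import phenotyping

#: person-level covariates carried onto segments (baseline adjustment set)
COVARIATE_COLS = [
    "household",
    "education",
    "pa_index",
    "dhd15",
    "smoking",
    "cigs_per_day",
    "alcohol",
    "copd",
]

EXPOSURE_COLUMN = {
    "composite": "adiposity_cat",
    "wc_only": "wc_cat",
    "bmi_only": "bmi_cat",
}

EXPOSURE_CATEGORIES = {
    "composite": phenotyping.ADIPOSITY_CATEGORIES,
    "wc_only": phenotyping.WC_CATEGORIES,
    "bmi_only": phenotyping.BMI_CATEGORIES,
}

SENSITIVITY_MODES = ("none", "early_events_2y", "baseline_comorbidity")


def apply_eligibility(cohort: Cohort, min_age: float = 50.0):
    """Apply the eligibility cascade and return (eligible cohort, log).

    Removal order: age below ``min_age`` at the index wave, then cancer
    history, then unknown cancer status, then pregnancy.  A participant
    matching several criteria is removed once, counted under the first
    matching rule.
    """
    p = cohort.participants
    remaining = np.ones(len(p), dtype=bool)
    log = {}
    for name, mask in [
        ("age_under_min", p["entry_age"].to_numpy() < min_age),
        ("cancer_history", p["cancer_history"].to_numpy(bool)),
        ("cancer_unknown", p["cancer_unknown"].to_numpy(bool)),
        ("pregnant", p["pregnant"].to_numpy(bool)),
    ]:
        hit = remaining & mask
        log[name] = int(hit.sum())
        remaining &= ~mask
    log["eligible"] = int(remaining.sum())
    keep_ids = p.loc[remaining, "id"]
    out = Cohort(
        p[remaining].reset_index(drop=True),
        cohort.waves[cohort.waves["id"].isin(keep_ids)].reset_index(drop=True),
        cohort.events[cohort.events["id"].isin(keep_ids)].reset_index(drop=True),
        cohort.config,
    )
    return out, log


def sensitivity_filters(cohort: Cohort, mode: str) -> Cohort:
    """Sensitivity-analysis roster filters.

    ``early_events_2y`` drops anyone with CVD or death within two years of
    their index age (reverse-causation guard); ``baseline_comorbidity``
    drops anyone with baseline hypertension, diabetes,
    hypercholesterolaemia, low HDL or COPD.
    """
    if mode not in SENSITIVITY_MODES:
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    if mode == "none":
        return cohort.copy()
    p, ev = cohort.participants, cohort.events
    if mode == "early_events_2y":
        ev = ev.set_index("id").loc[p["id"]].reset_index()
        cutoff = ev["entry_age"].to_numpy() + 2.0
        early = (ev["age_cvd"].to_numpy() < cutoff) | (
            ev["age_death"].to_numpy() < cutoff
        )
        keep = ~np.nan_to_num(early, nan=0.0).astype(bool)
    else:
        flags = phenotyping.comorbidity_flags(p)
        keep = ~flags.any(axis=1).to_numpy()
    keep_ids = p.loc[keep, "id"]
    return Cohort(
        p[keep].reset_index(drop=True),
        cohort.waves[cohort.waves["id"].isin(keep_ids)].reset_index(drop=True),
        cohort.events[cohort.events["id"].isin(keep_ids)].reset_index(drop=True),
        cohort.config,
    )


def build_person_time(
    cohort: Cohort,
    exposure_kind: str = "composite",
    step: float = 1.0,
    age_window=None,
) -> pd.DataFrame:
    """Split follow-up into transition-specific person-time segments.

    The cohort's wave table must be phenotyped (see
    :func:`heartspan.phenotyping.add_phenotypes`).  Exposure is carried
    forward from the most recent wave with a valid measurement; person-time
    before the first valid measurement is not used, and participants with
    no valid measurement at all are dropped (complete-case; fractions
    recorded in ``result.attrs['complete_case']``).  Segments are split at
    every wave where exposure updates and additionally into ``step``-year
    attained-age intervals; ``age_window=(50, 80)`` further clips them to
    the life-table window.
    """
    exposure_col = EXPOSURE_COLUMN[exposure_kind]
    if exposure_col not in cohort.waves.columns:
        raise ValueError(
            f"wave table lacks {exposure_col!r}; run add_phenotypes first"
        )
    waves = cohort.waves[["id", "wave", "age", exposure_col]].rename(
        columns={exposure_col: "category"}
    )
    valid = waves[waves["category"].notna()].sort_values(["id", "age"])

    events = cohort.events.set_index("id")
    all_ids = cohort.participants["id"]
    have = valid["id"].unique()
    dropped = np.setdiff1d(all_ids.to_numpy(), have)
    sex_by_id = cohort.participants.set_index("id")["sex"]
    cc = {}
    for s in ("men", "women"):
        ids_s = all_ids[sex_by_id.loc[all_ids].to_numpy() == s]
        cc[s] = float(np.isin(ids_s, dropped).mean()) if len(ids_s) else 0.0

    # exposure episodes: [wave age, next valid wave age)
    valid = valid.copy()
    valid["ep_start"] = valid["age"].to_numpy()
    nxt = valid.groupby("id")["age"].shift(-1)
    valid["ep_stop"] = nxt.fillna(np.inf).to_numpy()

    ev = events.loc[valid["id"]]
    age_cvd = ev["age_cvd"].to_numpy()
    age_death = ev["age_death"].to_numpy()
    age_censor = ev["age_censor"].to_numpy()
    if np.any(age_cvd > np.fmin(age_death, np.inf)):
        raise ValueError("CVD after death in event table")
    h_end = np.fmin(np.fmin(age_cvd, age_death), age_censor)
    c_start = age_cvd
    c_end = np.fmin(age_death, age_censor)

    frames = []
    # --- healthy state: feeds transitions healthy-cvd and healthy-death
    start = valid["ep_start"].to_numpy()
    stop = np.minimum(valid["ep_stop"].to_numpy(), h_end)
    keep = stop > start
    died_healthy = np.isnan(age_cvd) & ~np.isnan(age_death) & (age_death <= age_censor)
    got_cvd = ~np.isnan(age_cvd) & (age_cvd <= age_censor)
    base = pd.DataFrame(
        {
            "id": valid["id"].to_numpy()[keep],
            "category": valid["category"].to_numpy()[keep],
            "start": start[keep],
            "stop": stop[keep],
            "state_end": h_end[keep],
        }
    )
    for transition, ev_flag in [
        ("healthy-cvd", got_cvd[keep]),
        ("healthy-death", died_healthy[keep]),
    ]:
        seg, reps = _split_steps(base, step)
        seg["transition"] = transition
        seg["event"] = (
            np.repeat(ev_flag, reps)
            & seg["is_last"].to_numpy()
            & np.isclose(seg["exit_age"].to_numpy(), seg["state_end_rep"].to_numpy())
        ).astype(int)
        frames.append(seg)

    # --- CVD state: feeds transition cvd-death
    start_c = np.maximum(valid["ep_start"].to_numpy(), c_start)
    stop_c = np.minimum(valid["ep_stop"].to_numpy(), c_end)
    keep_c = ~np.isnan(start_c) & ~np.isnan(stop_c) & (stop_c > start_c)
    died_cvd = got_cvd & ~np.isnan(age_death) & (age_death <= age_censor)
    base_c = pd.DataFrame(
        {
            "id": valid["id"].to_numpy()[keep_c],
            "category": valid["category"].to_numpy()[keep_c],
            "start": start_c[keep_c],
            "stop": stop_c[keep_c],
            "state_end": c_end[keep_c],
        }
    )
    seg, reps = _split_steps(base_c, step)
    seg["transition"] = "cvd-death"
    seg["event"] = (
        np.repeat(died_cvd[keep_c], reps)
        & seg["is_last"].to_numpy()
        & np.isclose(seg["exit_age"].to_numpy(), seg["state_end_rep"].to_numpy())
    ).astype(int)
    frames.append(seg)

    pt = pd.concat(frames, ignore_index=True)
    pt = pt.drop(columns=["is_last", "state_end_rep"])
    if age_window is not None:
        lo, hi = age_window
        pt["entry_age"] = np.maximum(pt["entry_age"], lo)
        pt["exit_age"] = np.minimum(pt["exit_age"], hi)
        pt = pt[pt["exit_age"] > pt["entry_age"]].reset_index(drop=True)
    pt["pyears"] = pt["exit_age"] - pt["entry_age"]
    pt["age_mid"] = 0.5 * (pt["entry_age"] + pt["exit_age"])

    keep_cols = ["id", "sex", "entry_age"] + COVARIATE_COLS
    pinfo = cohort.participants[keep_cols].rename(columns={"entry_age": "baseline_age"})
    pt = pt.merge(pinfo, on="id", how="left")
    pt = pt[
        [
            "id",
            "sex",
            "transition",
            "entry_age",
            "exit_age",
            "pyears",
            "age_mid",
            "event",
            "category",
            "baseline_age",
        ]
        + COVARIATE_COLS
    ]
    # categorical dtypes keep big person-time tables compact in memory
    for col in ("sex", "transition", "category", "household", "education",
                "pa_index", "smoking", "alcohol"):
        pt[col] = pt[col].astype("category")
    pt.attrs["exposure_kind"] = exposure_kind
    pt.attrs["complete_case"] = cc
    return pt


def _split_steps(base: pd.DataFrame, step: float) -> pd.DataFrame:
    """Split [start, stop) rows at the fixed ``step``-year attained-age grid."""
    start = base["start"].to_numpy(float)
    stop = base["stop"].to_numpy(float)
    grid0 = np.floor(start / step) * step
    reps = np.ceil((stop - grid0) / step - 1e-9).astype(int)
    reps = np.maximum(reps, 1)
    idx = np.repeat(np.arange(len(base)), reps)
    within = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    seg_start = np.maximum(start[idx], grid0[idx] + within * step)
    seg_stop = np.minimum(stop[idx], grid0[idx] + (within + 1) * step)
    out = pd.DataFrame(
        {
            "id": base["id"].to_numpy()[idx],
            "category": base["category"].to_numpy()[idx],
            "entry_age": seg_start,
            "exit_age": seg_stop,
            "is_last": within == reps[idx] - 1,
            "state_end_rep": base["state_end"].to_numpy()[idx],
        }
    )
    return out, reps
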