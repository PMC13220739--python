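"""Shared fixtures: cohorts and fitted models are expensive, so the default
cohort pipeline and the large recovery cohorts are built once per session."""

import warnings

import numpy as np
import pandas as pd
import pytest

import heartspan as hs

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_cohort():
    return hs.generate_cohort(hs.SyntheticCohortConfig())


@pytest.fixture(scope="session")
def eligible(default_cohort):
    cohort = default_cohort.copy()
    cohort.waves = hs.add_phenotypes(
        cohort.waves, cohort.participants.set_index("id")["sex"]
    )
    out, log = hs.apply_eligibility(cohort)
    out.eligibility_log = log
    return out


@pytest.fixture(scope="session")
def pt_default(eligible):
    return hs.build_person_time(eligible)


@pytest.fixture(scope="session")
def fitted(pt_default):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        overall, hrs = hs.models.fit_all_transitions(pt_default)
    return overall, hrs


@pytest.fixture(scope="session")
def prev_default(pt_default):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hs.estimate_prevalences(pt_default)


def _recovery_config(**kw):
    """Cohort config for parameter-recovery runs: clean 50-70 entry window,
    no exclusions or missingness, exposure fixed over time."""
    base = dict(
        n_participants=50_000,
        age_band_probs=(0.6, 0.4, 0.0),
        exclusion_fractions={"cancer_history": 0.0, "cancer_unknown": 0.0, "pregnant": 0.0},
        missing_exposure_fraction={"men": 0.0, "women": 0.0},
    )
    base.update(kw)
    return hs.SyntheticCohortConfig(**base)


def build_pt(config, seed):
    cohort = hs.generate_cohort(config, seed=seed)
    cohort.waves = hs.add_phenotypes(
        cohort.waves, cohort.participants.set_index("id")["sex"]
    )
    cohort, _ = hs.apply_eligibility(cohort)
    return hs.build_person_time(cohort)


@pytest.fixture(scope="session")
def male50k_pt():
    return build_pt(_recovery_config(fraction_women=0.0), seed=1234)


@pytest.fixture(scope="session")
def female50k_pt():
    return build_pt(_recovery_config(fraction_women=1.0), seed=1235)


def make_pt_from_times(entry, time, event, transition="healthy-cvd", sex="men", step=1.0):
    """Minimal person-time table from raw (entry age, follow-up time, event)
    triples, year-split like the real builder; for oracle tests that need
    hand-made survival data."""
    from heartspan.cohort import _split_steps

    entry = np.asarray(entry, float)
    stop = entry + np.asarray(time, float)
    base = pd.DataFrame(
        {
            "id": np.arange(len(entry)),
            "category": "low",
            "start": entry,
            "stop": stop,
            "state_end": stop,
        }
    )
    seg, reps = _split_steps(base, step)
    seg["transition"] = transition
    seg["sex"] = sex
    seg["event"] = (
        np.repeat(np.asarray(event, bool), reps) & seg["is_last"].to_numpy()
    ).astype(int)
    seg["pyears"] = seg["exit_age"] - seg["entry_age"]
    seg["age_mid"] = 0.5 * (seg["entry_age"] + seg["exit_age"])
    return seg.drop(columns=["is_last", "state_end_rep"])
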