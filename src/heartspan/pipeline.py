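"""End-to-end orchestration: simulate -> phenotype -> prepare -> fit ->
life table -> bootstrap -> report.

``run_all`` executes the whole analysis from a single :class:`RunConfig`
and writes plain delimited-text/JSON artifacts plus a manifest with content
hashes, so a run is fully auditable and reproducible; ``report`` renders
the headline tables and a stacked-bar life-expectancy figure from a
completed run directory.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SyntheticCohortConfig, generate_cohort, TRANSITIONS, SEXES
from .phenotyping import add_phenotypes
from .cohort import apply_eligibility, build_person_time, sensitivity_filters
from .models import DEFAULT_ADJUSTMENT, fit_all_transitions
from .lifetable import (
    estimate_prevalences,
    estimate_initial_cvd,
    lifetables_by_category,
    le_decompose,
)
from .uncertainty import LifetableInputs, bootstrap_le


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: str = "heartspan_run"
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    exposure_kind: str = "composite"
    sensitivity: str = "none"
    adjust: tuple = DEFAULT_ADJUSTMENT
    lifetable_start: float = 50.0
    lifetable_close: float = 80.0
    lifetable_step: float = 1.0
    init: str = "observed"  # "observed" mixed start or "healthy"
    bootstrap_B: int = 1000
    seed: int = 20260917

    def __post_init__(self):
        if self.exposure_kind not in ("composite", "wc_only", "bmi_only"):
            raise ValueError(f"unknown exposure_kind {self.exposure_kind!r}")
        if self.sensitivity not in ("none", "early_events_2y", "baseline_comorbidity"):
            raise ValueError(f"unknown sensitivity mode {self.sensitivity!r}")
        if self.init not in ("observed", "healthy"):
            raise ValueError(f"unknown init {self.init!r}")
        if not self.lifetable_start < self.lifetable_close:
            raise ValueError("lifetable_start must precede lifetable_close")
        if self.lifetable_step <= 0:
            raise ValueError("lifetable_step must be positive")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")


def _write_csv(df: pd.DataFrame, path: Path, round_ages=()):
    df = df.copy()
    for col in round_ages:
        if col in df.columns:
            df[col] = df[col].round(2)
    df.to_csv(path, index=False, na_rep="")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Run every stage and write all artifacts into ``config.outdir``.

    Returns the run directory.  Any stage failure raises with a
    stage-tagged message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    def emit(name, df, **kw):
        written[name] = _write_csv(df, out / name, **kw)

    stage = "simulate"
    try:
        cohort = generate_cohort(config.cohort, seed=config.seed)
        emit("cohort_waves.csv", cohort.waves, round_ages=("age",))
        emit("events.csv", cohort.events,
             round_ages=("entry_age", "age_cvd", "age_death", "age_censor"))

        stage = "phenotype"
        sex_by_id = cohort.participants.set_index("id")["sex"]
        cohort.waves = add_phenotypes(cohort.waves, sex_by_id)
        emit("cohort_phenotyped.csv", cohort.waves, round_ages=("age",))

        stage = "prepare"
        eligible, excl_log = apply_eligibility(cohort)
        eligible = sensitivity_filters(eligible, config.sensitivity)
        pt = build_person_time(eligible, config.exposure_kind)
        (out / "exclusion_log.json").write_text(
            json.dumps({**excl_log, "complete_case": pt.attrs["complete_case"]}, indent=2)
        )
        emit("person_time.csv", pt, round_ages=("entry_age", "exit_age", "age_mid"))

        stage = "fit"
        overall, hrs = fit_all_transitions(pt, config.exposure_kind, config.adjust)
        models_json = {}
        hr_rows = []
        for (sex, tr), model in overall.items():
            models_json[f"{sex}/{tr}"] = {
                "params": model.params.to_dict(),
                "vcov_model": model.vcov_model.to_numpy().tolist(),
                "vcov_robust": model.vcov_robust.to_numpy().tolist(),
                "loglik": model.loglik,
                "aic": model.aic,
                "n_events": model.n_events,
                "person_years": model.person_years,
            }
            t = hrs[(sex, tr)].table.reset_index()
            t.insert(0, "transition", tr)
            t.insert(0, "sex", sex)
            hr_rows.append(t)
        (out / "models.json").write_text(json.dumps(models_json, indent=2))
        hr_table = pd.concat(hr_rows, ignore_index=True)
        emit("hr_table.csv", hr_table)

        stage = "lifetable"
        prev = estimate_prevalences(pt)
        emit("prevalences.csv", prev.probs.reset_index())
        init_cvd = estimate_initial_cvd(pt) if config.init == "observed" else None
        le_rows = []
        for sex in SEXES:
            tables = lifetables_by_category(
                overall, hrs, prev, sex, init_cvd,
                config.lifetable_start, config.lifetable_close, config.lifetable_step,
            )
            for cat, lt in tables.items():
                _write_csv(lt.df, out / f"lifetable_{sex}_{cat}.csv")
                est = le_decompose(lt)
                le_rows.append(dict(sex=sex, category=cat, total=est.total,
                                    cvd_free=est.cvd_free, with_cvd=est.with_cvd))
        emit("le_summary.csv", pd.DataFrame(le_rows))

        stage = "bootstrap"
        inputs = LifetableInputs(
            overall, hrs, prev, init_cvd,
            config.lifetable_start, config.lifetable_close, config.lifetable_step,
        )
        boot = bootstrap_le(inputs, B=config.bootstrap_B, seed=config.seed)
        emit("le_summary_ci.csv", boot.summary)
        draws_rows = []
        for (sex, cat), arr in boot.draws.items():
            frame = pd.DataFrame(arr, columns=["total", "cvd_free", "with_cvd"])
            frame.insert(0, "draw", np.arange(len(frame)))
            frame.insert(0, "category", cat)
            frame.insert(0, "sex", sex)
            draws_rows.append(frame)
        emit("le_draws.csv", pd.concat(draws_rows, ignore_index=True))

        stage = "report"
        report(out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from . import __version__ as pkg_version

    cfg = asdict(config)
    (out / "config_used.json").write_text(json.dumps(cfg, indent=2, default=str))
    manifest = {
        "package_version": pkg_version,
        "seed": config.seed,
        "active_knobs": {
            "exposure_kind": config.exposure_kind,
            "sensitivity": config.sensitivity,
            "lifetable": [config.lifetable_start, config.lifetable_close,
                          config.lifetable_step],
            "init": config.init,
            "bootstrap_B": config.bootstrap_B,
            "adjustment": list(config.adjust),
        },
        "hashes": {name: _sha256(path) for name, path in sorted(written.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def report(run_dir) -> dict:
    """Render headline outputs from a completed run directory.

    Produces one stacked-bar figure per sex (CVD-free + with-CVD years at
    age 50 by category) and returns the paths of the tables and figures.
    """
    run_dir = Path(run_dir)
    le_path = run_dir / "le_summary.csv"
    hr_path = run_dir / "hr_table.csv"
    if not le_path.exists() or not hr_path.exists():
        raise FileNotFoundError(f"missing stage outputs in {run_dir}")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    le = pd.read_csv(le_path)
    paths = {"le_summary": le_path, "hr_table": hr_path}
    for sex, sub in le.groupby("sex"):
        fig, ax = plt.subplots(figsize=(5, 4))
        x = np.arange(len(sub))
        ax.bar(x, sub["cvd_free"], label="CVD-free years", color="#4878d0")
        ax.bar(x, sub["with_cvd"], bottom=sub["cvd_free"], label="Years with CVD",
               color="#d65f5f")
        ax.set_xticks(x, sub["category"])
        ax.set_ylabel("Expected years in [50, 80)")
        ax.set_title(f"Life expectancy at 50 by adiposity category ({sex})")
        ax.legend(frameon=False)
        fig.tight_layout()
        fpath = run_dir / f"le_stacked_{sex}.png"
        fig.savefig(fpath, dpi=120)
        plt.close(fig)
        paths[f"figure_{sex}"] = fpath
    return paths
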