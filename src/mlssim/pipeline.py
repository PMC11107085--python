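"""End-to-end study replication on a synthetic cohort.

For every synthetic athlete the pipeline runs the full measurement chain —
sprint test → VLa_max, ramp test → VO2max, equilibrium model → calculated
PMLSS, constant-load titration (driven by the athlete's *latent* physiology)
→ measured PMLSS — and then produces the cohort summary table, the
method-agreement report and the perturbation sensitivity report.

Everything is reproducible from a :class:`RunConfig` alone: all randomness
derives from the master seed via per-athlete substreams, and output files
embed the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model as _model
from .adjudication import TitrationResult, titrate
from .agreement import AgreementReport, SensitivityReport, sensitivity_analysis, validate_pair_set
from .cohort import (
    CohortParams,
    apply_day_to_day,
    athlete_rng,
    generate_ramp_session,
    generate_sprint_trace,
    sample_cohort,
    simulate_constant_load_trial,
)
from .io import to_jsonable, write_json
from .model import ModelConstants, compute_pmlss
from .ramp import compute_vo2max
from .sprint import analyze_sprint
from .types import Athlete

__all__ = ["RunConfig", "StudyReport", "run_study_replication"]


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one study replication."""

    seed: int = 0
    n_male: int = 19
    n_female: int = 10
    cohort: CohortParams = None
    constants: ModelConstants = None
    trial_duration: float = 30.0  # min
    titration_step: float = 10.0  # W
    max_trials: int = 5
    steady_criterion: float = 0.2  # mmol·L⁻¹
    strict_boundary: bool = True
    warmup_intensity: float = 1.5  # W·kg⁻¹
    include_day_to_day: bool = False

    def __post_init__(self):
        if self.cohort is None:
            object.__setattr__(self, "cohort", CohortParams(seed=self.seed))
        if self.constants is None:
            object.__setattr__(self, "constants", _model.DEFAULT_CONSTANTS)

    def to_dict(self) -> dict:
        return to_jsonable(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class StudyReport:
    """Bundle of everything one replication produced."""

    config: RunConfig
    cohort: list
    per_athlete: pd.DataFrame
    summary: dict  # cohort means ± SD by sex and total
    agreement: AgreementReport
    sensitivity: SensitivityReport
    config_hash: str


def _mean_sd(values) -> dict:
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0}


def _summarize(df: pd.DataFrame) -> dict:
    cols = [
        "vo2max_measured",
        "vlamax_measured",
        "mlss_blc",
        "pmlss_measured",
        "pmlss_calculated",
        "pmlss_pct_vo2max",
    ]
    out = {}
    for label, sub in (
        ("female", df[df.sex == "female"]),
        ("male", df[df.sex == "male"]),
        ("total", df),
    ):
        if len(sub):
            out[label] = {c: _mean_sd(sub[c]) for c in cols}
            out[label]["n"] = int(len(sub))
    return out


def _measure_athlete(
    athlete: Athlete, index: int, config: RunConfig
) -> tuple[Athlete, dict]:
    """Run the sprint and ramp measurement chain for one athlete."""
    params = config.cohort
    sprint_rng = athlete_rng(params, index, purpose=1)
    ramp_rng = athlete_rng(params, index, purpose=2)
    tested = athlete
    if config.include_day_to_day:
        tested = apply_day_to_day(athlete, params, athlete_rng(params, index, purpose=5))

    t_alac_true = float(np.clip(3.5 + 0.5 * sprint_rng.standard_normal(), 2.0, 6.0))
    trace, pre, post = generate_sprint_trace(tested, t_alac_true, params, sprint_rng)
    sprint = analyze_sprint(trace, pre, post)

    session = generate_ramp_session(
        tested, params, ramp_rng, config.constants, config.warmup_intensity
    )
    ramp = compute_vo2max(session, athlete.body_mass)

    measured = athlete.replace(vo2max_rel=ramp.vo2max_rel, vlamax=sprint.vlamax)
    details = {
        "t_alac_true": t_alac_true,
        "t_alac_detected": sprint.t_alac,
        "ramp_maximal": ramp.is_maximal,
    }
    return measured, details


def _adjudicate(
    athlete: Athlete, index: int, start_load: float, config: RunConfig
) -> TitrationResult:
    params = config.cohort
    trial_rng = athlete_rng(params, index, purpose=3)

    def trial_source(load: float):
        return simulate_constant_load_trial(
            athlete, load, config.trial_duration, config.constants, params, trial_rng
        )

    return titrate(
        trial_source,
        start_load,
        step=config.titration_step,
        max_trials=config.max_trials,
        criterion=config.steady_criterion,
        strict_boundary=config.strict_boundary,
        min_duration=config.trial_duration,
    )


def run_study_replication(config: RunConfig, out_dir=None) -> StudyReport:
    """Simulate the full study once and assemble all reports.

    Raises with a stage-tagged message if any per-athlete stage fails.
    """
    params = config.cohort.replace(seed=config.seed)
    config = dataclasses.replace(config, cohort=params)
    cohort = sample_cohort(config.n_male, config.n_female, params)

    rows = []
    measured_athletes = []
    for index, athlete in enumerate(cohort):
        try:
            measured, details = _measure_athlete(athlete, index, config)
            model_out = compute_pmlss(measured, config.constants)
            start = (
                math.floor(model_out.pmlss / config.titration_step)
                * config.titration_step
            )
            titration = _adjudicate(athlete, index, start, config)
        except Exception as exc:  # noqa: BLE001 - re-tag with athlete/stage
            raise RuntimeError(
                f"pipeline failed for athlete {athlete.id}: {exc}"
            ) from exc
        measured_athletes.append(measured)
        rows.append(
            {
                "id": athlete.id,
                "sex": athlete.sex,
                "body_mass": athlete.body_mass,
                "body_fat": athlete.body_fat,
                "vo2max_true": athlete.vo2max_rel,
                "vlamax_true": athlete.vlamax,
                "vo2max_measured": measured.vo2max_rel,
                "vlamax_measured": measured.vlamax,
                "pmlss_calculated": model_out.pmlss,
                "pmlss_pct_vo2max": model_out.pmlss_pct_vo2max,
                "pmlss_measured": titration.pmlss_measured,
                "mlss_blc": titration.blc_at_mlss,
                "n_trials": len(titration.trials),
                "bracketed": titration.bracketed,
                **details,
            }
        )
    df = pd.DataFrame(rows)

    agreement = validate_pair_set(
        df["pmlss_measured"], df["pmlss_calculated"], subgroups=df["sex"]
    )
    sensitivity = sensitivity_analysis(
        measured_athletes,
        config.constants,
        measured=df["pmlss_measured"].to_numpy(),
    )
    report = StudyReport(
        config=config,
        cohort=cohort,
        per_athlete=df,
        summary=_summarize(df),
        agreement=agreement,
        sensitivity=sensitivity,
        config_hash=config.config_hash(),
    )
    if out_dir is not None:
        _write_artifacts(report, Path(out_dir))
    return report


def _write_artifacts(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = report.config_hash
    report.per_athlete.to_csv(out_dir / f"per_athlete_{tag}.csv", index=False)
    write_json(report.config.to_dict(), out_dir / f"config_{tag}.json")
    write_json(report.summary, out_dir / f"summary_{tag}.json")
    write_json(report.agreement, out_dir / f"agreement_{tag}.json")
    write_json(
        {
            "effects": {k: to_jsonable(v) for k, v in report.sensitivity.effects.items()},
            "base_pmlss": report.sensitivity.base_pmlss,
        },
        out_dir / f"sensitivity_{tag}.json",
    )
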