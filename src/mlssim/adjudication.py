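"""Gold-standard measured PMLSS: steady-state assessment and 10 W titration.

A constant-load trial shows a lactate steady state when the BLC rises by
less than 0.2 mmol·L⁻¹ over the final 10 min (a change within the accuracy
of the lactate analyzer).  The measured PMLSS is found by titration: after a
steady trial the load is raised by 10 W for the next trial, after a
non-steady trial it is lowered by 10 W, until a steady load with a failed
load one step above brackets the MLSS; two to five trials are needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import DataError, TitrationError
from .types import LactateSeries

__all__ = ["TrialVerdict", "TitrationResult", "assess_trial", "titrate"]

STEADY_CRITERION = 0.2  # mmol·L⁻¹ over the final 10 min
RATE_CRITERION_10 = 0.02  # mmol·L⁻¹·min⁻¹ over the final 10 min
RATE_CRITERION_20 = 0.05  # mmol·L⁻¹·min⁻¹ over the final 20 min


@dataclass(frozen=True)
class TrialVerdict:
    """Steady-state verdict for one constant-load trial."""

    load: float  # W
    steady: bool
    last10_rise: float  # mmol·L⁻¹
    end_blc: float  # mmol·L⁻¹


@dataclass(frozen=True)
class TitrationResult:
    """Outcome of a 2–5 trial titration."""

    pmlss_measured: float  # W, highest steady load
    trials: list[TrialVerdict]
    bracketed: bool  # a failed trial exists exactly one step above
    blc_at_mlss: float  # end BLC of the highest steady trial


def _blc_at(series: LactateSeries, t: float) -> float:
    """BLC at minute ``t``, interpolating between samples if needed."""
    times = series.sample_times
    if t < times[0] - 1e-6 or t > times[-1] + 1e-6:
        raise DataError(
            f"trial at {series.load:.0f} W has no sample coverage at {t:g} min"
        )
    return float(np.interp(t, times, series.blc))


def assess_trial(
    series: LactateSeries,
    criterion: float = STEADY_CRITERION,
    mode: str = "delta_last10",
    strict_boundary: bool = True,
    min_duration: float = None,
) -> TrialVerdict:
    """Steady-state verdict for one trial.

    ``delta_last10`` (default) compares the BLC rise over the final 10 min
    against ``criterion``; a rise of exactly the criterion counts as
    non-steady when ``strict_boundary`` (the protocol defines steady as a
    rise *below* 0.2 and failure as a rise *above* 0.2, leaving exactly 0.2
    undefined).  ``rate_based`` instead applies least-squares slopes: steady
    if < 0.02 mmol·L⁻¹·min⁻¹ over the final 10 min or < 0.05 over the final
    20 min.

    A trial abandoned before ``min_duration`` minutes (e.g. exhaustion at a
    load above the aerobic ceiling) cannot demonstrate a steady state and is
    judged non-steady regardless of its lactate course.
    """
    duration = series.duration
    if min_duration is not None and duration < min_duration - 1e-6:
        t_end = min(duration, float(series.sample_times[-1]))
        start = max(t_end - 10.0, float(series.sample_times[0]))
        end_blc = _blc_at(series, t_end)
        return TrialVerdict(
            load=series.load,
            steady=False,
            last10_rise=end_blc - _blc_at(series, start),
            end_blc=end_blc,
        )
    end_blc = _blc_at(series, duration)
    # nanoscale float noise must not flip the 0.2 boundary verdict
    last10_rise = float(np.round(end_blc - _blc_at(series, duration - 10.0), 9))

    if mode == "delta_last10":
        steady = last10_rise < criterion if strict_boundary else last10_rise <= criterion
    elif mode == "rate_based":
        steady = _window_slope(series, 10.0) < RATE_CRITERION_10
        if not steady and duration >= 20.0:
            steady = _window_slope(series, 20.0) < RATE_CRITERION_20
    else:
        raise ValueError(f"unknown assessment mode {mode!r}")
    return TrialVerdict(
        load=series.load, steady=bool(steady), last10_rise=last10_rise, end_blc=end_blc
    )


def _window_slope(series: LactateSeries, window: float) -> float:
    mask = series.sample_times >= series.duration - window - 1e-9
    if mask.sum() < 2:
        raise DataError(f"fewer than two samples in the final {window:g} min")
    t, b = series.sample_times[mask], series.blc[mask]
    return float(np.polyfit(t, b, 1)[0])


def titrate(
    trial_source: Callable[[float], LactateSeries],
    start_load: float,
    step: float = 10.0,
    max_trials: int = 5,
    **assess_kwargs,
) -> TitrationResult:
    """Bracket the measured PMLSS by ±``step`` W constant-load trials.

    Runs ``trial_source(load)`` at ``start_load``, stepping up while trials
    are steady and down while they are not, until a steady load with a failed
    load exactly one step above exists (``bracketed``) or ``max_trials`` is
    reached.  No load is ever tested twice.  Raises
    :class:`TitrationError` if no steady trial is found within the budget.
    """
    if start_load <= 0:
        raise ValueError("start_load must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if max_trials < 2:
        raise ValueError("the protocol needs at least two trials")

    verdicts: dict[float, TrialVerdict] = {}
    load = float(start_load)
    while len(verdicts) < max_trials:
        verdict = assess_trial(trial_source(load), **assess_kwargs)
        verdict = TrialVerdict(
            load=load,
            steady=verdict.steady,
            last10_rise=verdict.last10_rise,
            end_blc=verdict.end_blc,
        )
        verdicts[load] = verdict
        steady_loads = [v.load for v in verdicts.values() if v.steady]
        failed_loads = {v.load for v in verdicts.values() if not v.steady}
        if steady_loads and (max(steady_loads) + step) in failed_loads:
            break  # bracketed
        load = load + step if verdict.steady else load - step
        if load in verdicts or load <= 0:
            break

    trials = list(verdicts.values())
    steady = [v for v in trials if v.steady]
    if not steady:
        raise TitrationError("MLSS below tested range", verdicts=trials)
    best = max(steady, key=lambda v: v.load)
    bracketed = any(
        (not v.steady) and abs(v.load - (best.load + step)) < 1e-9 for v in trials
    )
    return TitrationResult(
        pmlss_measured=best.load,
        trials=trials,
        bracketed=bracketed,
        blc_at_mlss=best.end_blc,
    )
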