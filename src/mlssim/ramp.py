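"""Ramp-test protocol and VO2max analysis.

The protocol: 12 min warm-up at 1.5 or 2 W·kg⁻¹, an initial load for 120 s
chosen from sex, rider class and body mass, then +25 W every 30 s to
exhaustion.  VO2max is the highest 30 s average of the breath-by-breath VO2;
the test counts as maximal when the peak RQ reaches 1.1 and the final VO2
increment between consecutive 30 s averages stays below 150 ml·min⁻¹
(a plateau despite increasing load).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NoProtocolError
from .types import BreathSeries

__all__ = [
    "RampResult",
    "RampProfile",
    "initial_ramp_load",
    "build_ramp_profile",
    "compute_vo2max",
    "INITIAL_LOADS",
    "FEMALE_INITIAL_LOAD",
]

#: Initial ramp load (W) for male riders by (mass band, rider class); bands
#: are half-open: lower < mass ≤ upper.
INITIAL_LOADS: list[tuple[float, float, dict]] = [
    (60.0, 70.0, {"recreational": 150.0, "amateur": 180.0, "professional": 240.0}),
    (70.0, 80.0, {"recreational": 175.0, "amateur": 210.0, "professional": 280.0}),
    (80.0, 90.0, {"recreational": 200.0, "amateur": 240.0, "professional": 320.0}),
    (90.0, 100.0, {"recreational": 225.0, "amateur": 270.0, "professional": 360.0}),
    (100.0, 110.0, {"recreational": 250.0, "amateur": 300.0, "professional": 400.0}),
]

#: Female riders start at 100 W regardless of class and mass.
FEMALE_INITIAL_LOAD = 100.0


def initial_ramp_load(sex: str, rider_class: str, body_mass: float) -> float:
    """Load for the first 120 s of the ramp test (W)."""
    if sex == "female":
        return FEMALE_INITIAL_LOAD
    if sex != "male":
        raise ValueError(f"unknown sex {sex!r}")
    for lower, upper, by_class in INITIAL_LOADS:
        if lower < body_mass <= upper:
            try:
                return by_class[rider_class]
            except KeyError:
                raise ValueError(f"unknown rider class {rider_class!r}") from None
    raise NoProtocolError(
        f"no ramp protocol defined for a {body_mass:g} kg male rider"
    )


@dataclass(frozen=True)
class RampProfile:
    """Open-ended load schedule of a ramp session.

    Time 0 is the start of the warm-up; the ramp proper starts at
    ``warmup_duration`` with ``initial_load`` held for ``initial_duration``
    seconds, then ``step`` W added every ``step_duration`` seconds.
    """

    initial_load: float
    warmup_load: float
    warmup_duration: float = 720.0  # s
    initial_duration: float = 120.0  # s
    step: float = 25.0  # W
    step_duration: float = 30.0  # s

    @property
    def ramp_start(self) -> float:
        return self.warmup_duration

    def load_at(self, t):
        """Load (W) at session time(s) ``t`` in seconds (vectorised)."""
        t = np.asarray(t, dtype=float)
        s = t - self.warmup_duration
        n_steps = np.floor((s - self.initial_duration) / self.step_duration) + 1
        load = np.where(
            s < 0,
            self.warmup_load,
            np.where(
                s < self.initial_duration,
                self.initial_load,
                self.initial_load + self.step * n_steps,
            ),
        )
        return load if load.ndim else float(load)


def build_ramp_profile(
    initial_load: float,
    warmup_intensity: float,
    body_mass: float,
    warmup_duration: float = 720.0,
    step: float = 25.0,
    step_duration: float = 30.0,
) -> RampProfile:
    """Ramp schedule: 12 min warm-up at ``warmup_intensity`` (W·kg⁻¹), then
    ``initial_load`` for 120 s, then +25 W every 30 s, open-ended."""
    if initial_load <= 0:
        raise ValueError("initial_load must be positive")
    return RampProfile(
        initial_load=float(initial_load),
        warmup_load=float(warmup_intensity * body_mass),
        warmup_duration=warmup_duration,
        step=step,
        step_duration=step_duration,
    )


@dataclass(frozen=True)
class RampResult:
    """VO2max and maximality flags of one ramp test."""

    vo2max_abs: float  # ml·min⁻¹
    vo2max_rel: float  # ml·kg⁻¹·min⁻¹
    max_rq: float
    plateau_delta: float  # ml·min⁻¹, last minus second-to-last 30 s average
    is_maximal: bool
    peak_load: float  # W


def _binned_means(times: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """Time-weighted means of ``values`` over consecutive complete windows.

    Each breath is weighted by its duration (gap to the previous breath) so
    that irregular breath intervals do not bias the averages.  Only bins whose
    end falls within the sampled span are returned.
    """
    weights = np.diff(times, prepend=times[0] - np.median(np.diff(times)))
    bins = np.floor(times / window).astype(int)
    n_complete = int(times[-1] // window)
    means = np.empty(n_complete)
    for b in range(n_complete):
        mask = bins == b
        if not mask.any():  # no breath in this bin — carry the neighbourhood
            means[b] = means[b - 1] if b else values[0]
            continue
        means[b] = np.average(values[mask], weights=weights[mask])
    return means


def compute_vo2max(
    breaths: BreathSeries, body_mass: float, window: float = 30.0
) -> RampResult:
    """VO2max as the highest 30 s (time-weighted, fixed-bin) VO2 average.

    ``plateau_delta`` is the difference between the final two complete 30 s
    bin averages; together with a peak RQ ≥ 1.1 it decides maximality.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    span = breaths.sample_times[-1] - breaths.sample_times[0]
    if span < window:
        raise ValueError("breath series must span at least one averaging window")

    means = _binned_means(breaths.sample_times, breaths.vo2, window)
    vo2max_abs = float(means.max())
    plateau_delta = float(means[-1] - means[-2]) if means.size >= 2 else float("nan")
    max_rq = float(np.max(breaths.rq))
    is_maximal = bool(max_rq >= 1.1 and plateau_delta < 150.0)
    return RampResult(
        vo2max_abs=vo2max_abs,
        vo2max_rel=vo2max_abs / body_mass,
        max_rq=max_rq,
        plateau_delta=plateau_delta,
        is_maximal=is_maximal,
        peak_load=float(np.max(breaths.load)),
    )
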