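"""Core data containers.

All time-series containers hold plain numpy arrays and validate their
invariants on construction.  Units follow the conventions of the exercise
physiology literature: power in W, oxygen uptake in ml·min⁻¹ (absolute) or
ml·kg⁻¹·min⁻¹ (relative to body mass), blood lactate concentration (BLC) in
mmol·L⁻¹ and the maximal glycolytic rate VLa_max in mmol·L⁻¹·s⁻¹.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Athlete", "PowerTrace", "BreathSeries", "LactateSeries"]

_SEXES = ("male", "female")
_RIDER_CLASSES = ("recreational", "amateur", "professional")


@dataclass(frozen=True)
class Athlete:
    """Anthropometrics and latent physiological capacities of one cyclist.

    ``vo2max_rel`` and ``vlamax`` are the *true* underlying capacities; test
    simulators add measurement noise on top of them.

    Attributes
    ----------
    id : str
        Free-form identifier.
    sex : {"male", "female"}
    body_mass : float
        kg, > 0.
    body_fat : float
        Fraction of body mass, in (0, 0.6).
    rider_class : {"recreational", "amateur", "professional"}
        Drives the initial ramp-test load.
    vo2max_rel : float
        Maximal oxygen uptake, ml·kg⁻¹·min⁻¹.
    vlamax : float
        Maximal glycolytic (lactate formation) rate, mmol·L⁻¹·s⁻¹.
    """

    id: str
    sex: str
    body_mass: float
    body_fat: float
    rider_class: str
    vo2max_rel: float
    vlamax: float

    def __post_init__(self):
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.rider_class not in _RIDER_CLASSES:
            raise ValueError(
                f"rider_class must be one of {_RIDER_CLASSES}, got {self.rider_class!r}"
            )
        if not self.body_mass > 0:
            raise ValueError("body_mass must be positive")
        if not 0 < self.body_fat < 0.6:
            raise ValueError("body_fat must lie in (0, 0.6)")
        if not self.vo2max_rel > 0:
            raise ValueError("vo2max_rel must be positive")
        if not self.vlamax > 0:
            raise ValueError("vlamax must be positive")

    @property
    def vo2max_abs(self) -> float:
        """Absolute maximal oxygen uptake in ml·min⁻¹."""
        return self.vo2max_rel * self.body_mass

    def replace(self, **changes) -> "Athlete":
        return dataclasses.replace(self, **changes)


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class PowerTrace:
    """A uniformly sampled ergometer power trace (0.1 s spacing for sprints)."""

    sample_times: np.ndarray  # s
    power: np.ndarray  # W

    def __post_init__(self):
        object.__setattr__(self, "sample_times", _as_float_array(self.sample_times))
        object.__setattr__(self, "power", _as_float_array(self.power))
        if self.sample_times.shape != self.power.shape or self.sample_times.ndim != 1:
            raise ValueError("sample_times and power must be 1-D arrays of equal length")
        if self.sample_times.size < 2:
            raise ValueError("a power trace needs at least two samples")
        dts = np.diff(self.sample_times)
        if not np.allclose(dts, dts[0], rtol=0, atol=1e-9):
            raise ValueError("sample_times must be uniformly spaced")
        if dts[0] <= 0:
            raise ValueError("sample_times must be increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])

    @property
    def duration(self) -> float:
        return float(self.sample_times[-1] - self.sample_times[0]) + self.dt


@dataclass(frozen=True)
class BreathSeries:
    """Breath-by-breath gas exchange during a (ramp) test.

    Times are seconds from the start of the session; ``load`` is the ergometer
    load at each breath.  The respiratory quotient RQ is ``vco2 / vo2``.
    """

    sample_times: np.ndarray  # s
    vo2: np.ndarray  # ml·min⁻¹
    vco2: np.ndarray  # ml·min⁻¹
    load: np.ndarray  # W

    def __post_init__(self):
        for name in ("sample_times", "vo2", "vco2", "load"):
            object.__setattr__(self, name, _as_float_array(getattr(self, name)))
        n = self.sample_times.size
        if any(getattr(self, name).shape != (n,) for name in ("vo2", "vco2", "load")):
            raise ValueError("all BreathSeries arrays must be 1-D of equal length")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if np.any(self.vo2 <= 0) or np.any(self.vco2 <= 0):
            raise ValueError("vo2 and vco2 must be positive")

    @property
    def rq(self) -> np.ndarray:
        return self.vco2 / self.vo2


@dataclass(frozen=True)
class LactateSeries:
    """Timed capillary blood lactate samples for one constant-load trial.

    ``sample_times`` are minutes from the trial start, ``load`` is the single
    constant load of the trial (0 for resting samples) and ``duration`` the
    nominal trial duration in minutes.
    """

    sample_times: np.ndarray  # min
    blc: np.ndarray  # mmol·L⁻¹
    load: float = 0.0  # W
    duration: float = field(default=None)  # min

    def __post_init__(self):
        object.__setattr__(self, "sample_times", _as_float_array(self.sample_times))
        object.__setattr__(self, "blc", _as_float_array(self.blc))
        if self.duration is None:
            dur = float(self.sample_times[-1]) if self.sample_times.size else 0.0
            object.__setattr__(self, "duration", dur)
        if self.sample_times.shape != self.blc.shape or self.sample_times.ndim != 1:
            raise ValueError("sample_times and blc must be 1-D arrays of equal length")
        if np.any(self.blc <= 0):
            raise ValueError("blc must be positive")
        if self.sample_times.size and (
            self.sample_times[0] < -1e-9 or self.sample_times[-1] > self.duration + 1e-9
        ):
            raise ValueError("sample_times must lie within [0, duration]")

    def __len__(self) -> int:
        return self.sample_times.size
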