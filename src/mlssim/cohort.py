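"""Synthetic athletes and raw test signals.

This module generates everything the analysis stages consume: cohorts of
athletes with sex-specific VO2max / VLa_max / body-mass distributions,
noisy 10 Hz sprint power traces with pre/post lactate samples, breath-by-
breath ramp sessions, and constant-load lactate time courses obtained by
integrating the equilibrium model forward in time.

Determinism: every generator takes a :class:`numpy.random.Generator` (or is
driven by the seed in :class:`CohortParams`); per-athlete substreams are
spawned from the master seed so that extending a cohort does not reshuffle
existing athletes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import truncnorm

from . import model as _model
from .model import ModelConstants, net_lactate_rate
from .ramp import build_ramp_profile, initial_ramp_load
from .types import Athlete, BreathSeries, LactateSeries, PowerTrace

__all__ = [
    "SexParams",
    "CohortParams",
    "sample_cohort",
    "standard_cohort",
    "generate_sprint_trace",
    "generate_ramp_session",
    "simulate_constant_load_trial",
    "apply_day_to_day",
    "STANDARD_COHORT_SEED",
]

#: Seed of the standard reference cohort used for calibration and validation.
STANDARD_COHORT_SEED = 1812


@dataclass(frozen=True)
class SexParams:
    """Latent-trait distribution for one sex (means ± SD, truncated ±3 SD)."""

    vo2max_mean: float
    vo2max_sd: float
    vlamax_mean: float
    vlamax_sd: float
    mass_mean: float
    mass_sd: float
    body_fat_mean: float
    body_fat_sd: float  # 0 means a fixed body-fat fraction


#: Defaults reproduce the study cohort: 19 men (VO2max 64.9 ± 7.3
#: ml·kg⁻¹·min⁻¹, VLa_max 0.59 ± 0.15 mmol·L⁻¹·s⁻¹, mass 76.0 ± 7.0 kg) and
#: 10 women (49.1 ± 5.0, 0.50 ± 0.15, 60.7 ± 5.6).  Male body fat is drawn
#: (bio-impedance-like); female body fat is fixed at 20 %.
MALE_DEFAULTS = SexParams(64.9, 7.3, 0.59, 0.15, 76.0, 7.0, 0.15, 0.03)
FEMALE_DEFAULTS = SexParams(49.1, 5.0, 0.50, 0.15, 60.7, 5.6, 0.20, 0.0)


@dataclass(frozen=True)
class CohortParams:
    """Cohort distributions plus instrument and day-to-day noise settings.

    ``power_cv`` is the multiplicative SRM crank noise (~2.5 %),
    ``lactate_sd`` the analyzer noise (mmol·L⁻¹), ``breath_noise_sd`` the
    additive breath-by-breath VO2/VCO2 noise (ml·min⁻¹), and the day-to-day
    SDs the between-visit variability of the two capacities.
    """

    male: SexParams = MALE_DEFAULTS
    female: SexParams = FEMALE_DEFAULTS
    power_cv: float = 0.025
    lactate_sd: float = 0.1
    breath_noise_sd: float = 120.0
    day_to_day_vo2max_sd: float = 3.3  # ml·kg⁻¹·min⁻¹
    day_to_day_vlamax_sd: float = 0.11  # mmol·L⁻¹·s⁻¹
    baseline_blc: float = 1.2  # mmol·L⁻¹, common resting BLC
    seed: int = 0

    def __post_init__(self):
        for name in (
            "power_cv",
            "lactate_sd",
            "breath_noise_sd",
            "day_to_day_vo2max_sd",
            "day_to_day_vlamax_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def for_sex(self, sex: str) -> SexParams:
        return self.male if sex == "male" else self.female

    def replace(self, **changes) -> "CohortParams":
        return dataclasses.replace(self, **changes)


def _trunc_draw(rng: np.random.Generator, mean: float, sd: float, lo_abs: float = 0.0) -> float:
    """Draw from a normal truncated at mean ± 3 SD and below at ``lo_abs``."""
    if sd == 0:
        return mean
    lo = max(mean - 3 * sd, lo_abs)
    hi = mean + 3 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


# rider class assigned from relative VO2max so that initial ramp loads track
# fitness; thresholds roughly reproduce the study's 17/10/4 class split
_CLASS_CUTS = {"male": (63.0, 73.0), "female": (49.5, 56.0)}


def _rider_class(sex: str, vo2max_rel: float) -> str:
    rec_cut, pro_cut = _CLASS_CUTS[sex]
    if vo2max_rel < rec_cut:
        return "recreational"
    if vo2max_rel < pro_cut:
        return "amateur"
    return "professional"


def athlete_rng(params: CohortParams, index: int, purpose: int = 0) -> np.random.Generator:
    """Deterministic per-athlete random stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(index, purpose))
    )


def sample_cohort(n_male: int, n_female: int, params: CohortParams = None) -> list[Athlete]:
    """Draw a cohort of synthetic athletes.

    Latent VO2max, VLa_max and body mass come from sex-specific truncated
    normal distributions; male body fat is drawn, female body fat is fixed.
    Deterministic given ``params.seed``; athlete ``i`` is identical no matter
    how many athletes follow.
    """
    if n_male < 0 or n_female < 0:
        raise ValueError("athlete counts must be non-negative")
    if params is None:
        params = CohortParams()
    cohort: list[Athlete] = []
    specs = [("male", i, f"M{i + 1:02d}") for i in range(n_male)]
    specs += [("female", n_male + i, f"F{i + 1:02d}") for i in range(n_female)]
    for sex, index, ident in specs:
        rng = athlete_rng(params, index)
        sp = params.for_sex(sex)
        vo2 = _trunc_draw(rng, sp.vo2max_mean, sp.vo2max_sd, lo_abs=1.0)
        vla = _trunc_draw(rng, sp.vlamax_mean, sp.vlamax_sd, lo_abs=0.05)
        mass = _trunc_draw(rng, sp.mass_mean, sp.mass_sd, lo_abs=30.0)
        fat = _trunc_draw(rng, sp.body_fat_mean, sp.body_fat_sd, lo_abs=0.03)
        cohort.append(
            Athlete(
                id=ident,
                sex=sex,
                body_mass=mass,
                body_fat=min(fat, 0.59),
                rider_class=_rider_class(sex, vo2),
                vo2max_rel=vo2,
                vlamax=vla,
            )
        )
    return cohort


def standard_cohort() -> list[Athlete]:
    """The fixed 29-athlete reference cohort (19 men, 10 women)."""
    return sample_cohort(19, 10, CohortParams(seed=STANDARD_COHORT_SEED))


# ---------------------------------------------------------------------------
# Sprint test signals
# ---------------------------------------------------------------------------

SPRINT_DURATION = 15.0  # s
SPRINT_DT = 0.1  # s
#: fractional power drop at the first declining sample: the decline must
#: immediately exceed the 3.5 % detection criterion so that, noise-free, the
#: detector localises t_alac to within one sample
_INITIAL_DROP = 0.036
_DECLINE_RATE = 0.03  # fraction of peak power per second after the drop
_LACTATE_PEAK_MIN = 5.0  # post-sprint BLC curve peaks at this recovery minute


def _sprint_peak_power(athlete: Athlete) -> float:
    # crude allometry: stronger glycolytic systems sprint harder
    return athlete.body_mass * (12.0 + 5.0 * athlete.vlamax)


def generate_sprint_trace(
    athlete: Athlete,
    true_t_alac: float,
    params: CohortParams = None,
    rng: np.random.Generator = None,
    decline_rate: float = _DECLINE_RATE,
) -> tuple[PowerTrace, LactateSeries, LactateSeries]:
    """Synthetic 15 s sprint: power trace plus pre/post lactate samples.

    The noise-free trace holds peak power up to ``true_t_alac`` and then
    declines linearly, crossing the 96.5 % detection level within the first
    declining sample.  The noise-free maximum of the post-sprint lactate
    curve equals ``baseline + vlamax · (15 − true_t_alac)``, i.e. the exact
    inversion of the VLa_max estimator.
    """
    if not 0 < true_t_alac < SPRINT_DURATION:
        raise ValueError("true_t_alac must lie strictly inside (0, 15) s")
    if params is None:
        params = CohortParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    times = np.arange(0.0, SPRINT_DURATION - SPRINT_DT / 2, SPRINT_DT)
    peak = _sprint_peak_power(athlete)
    decline = np.clip(
        1.0 - _INITIAL_DROP - decline_rate * (times - true_t_alac), 0.0, None
    )
    power = peak * np.where(times <= true_t_alac + 1e-9, 1.0, decline)
    if params.power_cv > 0:
        power = power * (1.0 + params.power_cv * rng.standard_normal(times.size))
    power = np.clip(power, 0.0, None)

    base = params.baseline_blc
    pre_times = np.array([0.0, 2.0, 4.0])
    pre_blc = base + params.lactate_sd * rng.standard_normal(3)
    post_times = np.arange(0.0, 11.0)
    amp = athlete.vlamax * (SPRINT_DURATION - true_t_alac)
    shape = (post_times / _LACTATE_PEAK_MIN) * np.exp(1.0 - post_times / _LACTATE_PEAK_MIN)
    post_blc = base + amp * shape**2
    post_blc = post_blc + params.lactate_sd * rng.standard_normal(post_times.size)

    pre = LactateSeries(pre_times, np.clip(pre_blc, 0.05, None), load=0.0, duration=10.0)
    post = LactateSeries(post_times, np.clip(post_blc, 0.05, None), load=0.0, duration=10.0)
    return PowerTrace(times, power), pre, post


# ---------------------------------------------------------------------------
# Ramp test signals
# ---------------------------------------------------------------------------

#: Anaerobic work capacity used to time exhaustion: once the oxygen demand of
#: the load exceeds VO2max, the energy shortfall is paid from a finite store
#: of ~280 J per kg body mass (a typical W′ for trained cyclists).
W_PRIME_PER_KG = 280.0
VO2_TAU = 30.0  # s, mono-exponential VO2 on-kinetics


def generate_ramp_session(
    athlete: Athlete,
    params: CohortParams = None,
    rng: np.random.Generator = None,
    constants: ModelConstants = None,
    warmup_intensity: float = 1.5,
    tau: float = VO2_TAU,
    w_prime_per_kg: float = W_PRIME_PER_KG,
) -> BreathSeries:
    """Breath-by-breath gas exchange of a ramp test to exhaustion.

    VO2 follows the linear oxygen demand of the load schedule with
    mono-exponential lag ``tau``, saturating at the athlete's VO2max.  Once
    the demand exceeds VO2max the shortfall depletes an anaerobic work
    capacity of ``w_prime_per_kg`` J·kg⁻¹; the test terminates when it is
    exhausted.  The RQ rises with relative intensity and exceeds 1.1 well
    before termination.
    """
    if params is None:
        params = CohortParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if constants is None:
        constants = _model.DEFAULT_CONSTANTS

    m = athlete.body_mass
    vo2max_abs = athlete.vo2max_abs
    profile = build_ramp_profile(
        initial_ramp_load(athlete.sex, athlete.rider_class, m), warmup_intensity, m
    )

    dt = 0.5
    t_grid = [0.0]
    v_grid = []
    w_prime = w_prime_per_kg * m
    deficit = 0.0
    t = 0.0
    v = m * constants.a + constants.e * profile.load_at(0.0)  # start on-demand
    v_grid.append(v)
    decay = np.exp(-dt / tau)
    max_t = profile.warmup_duration + 3600.0
    while t < max_t:
        t += dt
        load = profile.load_at(t)
        demand = m * constants.a + constants.e * load
        target = min(demand, vo2max_abs)
        v = target + (v - target) * decay
        t_grid.append(t)
        v_grid.append(v)
        if demand > vo2max_abs:
            deficit += (demand - vo2max_abs) / constants.e * dt  # J
            if deficit >= w_prime:
                break
    t_grid = np.asarray(t_grid)
    v_grid = np.asarray(v_grid)

    # breath timestamps: breathing frequency rises with relative intensity
    breath_times = []
    bt = 1.0
    while bt < t_grid[-1]:
        breath_times.append(bt)
        demand_ratio = (m * constants.a + constants.e * profile.load_at(bt)) / vo2max_abs
        rr = 12.0 + 28.0 * min(demand_ratio, 1.2) / 1.2  # breaths·min⁻¹
        gap = 60.0 / rr
        if params.breath_noise_sd > 0:
            gap *= float(np.clip(1.0 + 0.1 * rng.standard_normal(), 0.6, 1.4))
        bt += gap
    breath_times = np.asarray(breath_times)

    vo2 = np.interp(breath_times, t_grid, v_grid)
    demand_ratio = (
        m * constants.a + constants.e * profile.load_at(breath_times)
    ) / vo2max_abs
    rq = np.clip(0.82 + 0.33 * demand_ratio, None, 1.30)
    vco2 = rq * vo2
    if params.breath_noise_sd > 0:
        vo2 = vo2 + params.breath_noise_sd * rng.standard_normal(vo2.size)
        vco2 = vco2 + params.breath_noise_sd * rng.standard_normal(vco2.size)
    return BreathSeries(
        sample_times=breath_times,
        vo2=np.clip(vo2, 50.0, None),
        vco2=np.clip(vco2, 50.0, None),
        load=profile.load_at(breath_times),
    )


# ---------------------------------------------------------------------------
# Constant-load trials
# ---------------------------------------------------------------------------


def simulate_constant_load_trial(
    athlete: Athlete,
    load: float,
    duration: float,
    constants: ModelConstants = None,
    params: CohortParams = None,
    rng: np.random.Generator = None,
    sample_interval: float = 5.0,
    w_prime_per_kg: float = W_PRIME_PER_KG,
) -> LactateSeries:
    """Blood lactate time course of a constant-load trial.

    Integrates the equilibrium model forward in time from the resting
    baseline, ``d[La]/dt = production(load) − capacity(load)·s([La])`` with
    the saturating combustion closure, and samples the solution every
    ``sample_interval`` minutes with analyzer noise.  Standard durations are
    20 or 30 min.

    Loads above the athlete's aerobic ceiling are not sustainable for the
    full trial: the oxygen shortfall depletes the anaerobic work capacity
    and the trial is abandoned at exhaustion, returning a series truncated
    to the achievable duration.
    """
    if load <= 0:
        raise ValueError("load must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if constants is None:
        constants = _model.DEFAULT_CONSTANTS
    if params is None:
        params = CohortParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    t_end = duration * 60.0
    map_w = _model.max_aerobic_power(athlete, constants)
    if load > map_w and w_prime_per_kg > 0:
        t_exhaustion = w_prime_per_kg * athlete.body_mass / (load - map_w)
        t_end = min(t_end, t_exhaustion)
    t_eval = np.arange(0.0, duration + sample_interval / 2, sample_interval) * 60.0
    if t_end < duration * 60.0:
        t_eval = np.append(t_eval[t_eval < t_end], t_end)
    sol = solve_ivp(
        lambda _t, b: [net_lactate_rate(b[0], load, athlete, constants)],
        (0.0, t_end),
        [params.baseline_blc],
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-7,
        atol=1e-9,
    )
    if not sol.success:  # pragma: no cover - smooth scalar ODE
        raise RuntimeError(f"lactate ODE integration failed: {sol.message}")
    blc = sol.y[0]
    if params.lactate_sd > 0:
        blc = blc + params.lactate_sd * rng.standard_normal(blc.size)
    return LactateSeries(
        sample_times=t_eval / 60.0,
        blc=np.clip(blc, 0.05, None),
        load=float(load),
        duration=float(min(duration, t_end / 60.0)),
    )


def apply_day_to_day(
    athlete: Athlete, params: CohortParams = None, rng: np.random.Generator = None
) -> Athlete:
    """Copy of ``athlete`` with VO2max and VLa_max jittered by their
    day-to-day variability (zero-mean Gaussian, redrawn until positive)."""
    if params is None:
        params = CohortParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    def jitter(value: float, sd: float) -> float:
        if sd == 0:
            return value
        for _ in range(100):
            new = value + sd * rng.standard_normal()
            if new > 0:
                return float(new)
        raise RuntimeError("could not draw a positive perturbed value")

    return athlete.replace(
        vo2max_rel=jitter(athlete.vo2max_rel, params.day_to_day_vo2max_sd),
        vlamax=jitter(athlete.vlamax, params.day_to_day_vlamax_sd),
    )
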