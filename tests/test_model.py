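"""Equilibrium model: rate curves, PMLSS crossing, equilibrium BLC, calibration."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mlssim.cohort import CohortParams, sample_cohort
from mlssim.exceptions import NoSteadyStateError
from mlssim.model import (
    DEFAULT_CONSTANTS,
    CalibrationAnchors,
    ModelConstants,
    calibrate_constants,
    cohort_statistics,
    combustion_capacity,
    compute_pmlss,
    effective_vlamax,
    equilibrium_blc,
    max_aerobic_power,
    production_rate,
    vo2_steady,
)
from mlssim.types import Athlete


def make_athlete(**kw):
    defaults = dict(
        id="T01",
        sex="male",
        body_mass=76.0,
        body_fat=0.15,
        rider_class="amateur",
        vo2max_rel=64.9,
        vlamax=0.59,
    )
    defaults.update(kw)
    return Athlete(**defaults)


class TestVo2Steady:
    def test_intercept_at_zero_load(self, constants):
        assert vo2_steady(0.0, make_athlete(), constants) == pytest.approx(constants.a)

    def test_linear_oxygen_cost(self):
        c = ModelConstants(e=10.8, a=7.0)
        athlete = make_athlete()
        assert vo2_steady(300.0, athlete, c) == pytest.approx(7 + 10.8 * 300 / 76, abs=0.01)

    def test_capped_at_vo2max(self, constants):
        athlete = make_athlete()
        assert vo2_steady(2000.0, athlete, constants) == athlete.vo2max_rel


class TestProductionRate:
    def test_negligible_at_rest(self, constants):
        athlete = make_athlete()
        assert production_rate(0.0, athlete, constants) < 5e-3 * athlete.vlamax

    def test_half_activation_at_hill_constant(self, constants):
        # the load at which the saturation odds cubed equal K yields
        # exactly half of the effective VLa_max, by construction
        athlete = make_athlete()
        u = constants.K ** (1.0 / constants.hill_exponent)
        x = u / (1.0 + u)
        load = (x * athlete.vo2max_rel - constants.a) * athlete.body_mass / constants.e
        expected = effective_vlamax(athlete, constants) / 2
        assert production_rate(load, athlete, constants) == pytest.approx(expected, rel=1e-9)

    def test_strictly_increasing_in_load(self, cohort29, constants):
        grid = np.arange(0.0, 501.0, 1.0)
        for athlete in cohort29:
            rates = [production_rate(p, athlete, constants) for p in grid]
            assert np.all(np.diff(rates) > 0)


class TestCombustionCapacity:
    def test_baseline(self, constants):
        athlete = make_athlete()
        assert combustion_capacity(0.0, athlete, constants) == pytest.approx(
            constants.k_ox * constants.a
        )

    def test_linear_in_vo2(self, constants):
        athlete = make_athlete()
        v1 = vo2_steady(100.0, athlete, constants)
        load2 = (2 * v1 - constants.a) * athlete.body_mass / constants.e
        assert vo2_steady(load2, athlete, constants) == pytest.approx(2 * v1)
        assert combustion_capacity(load2, athlete, constants) == pytest.approx(
            2 * combustion_capacity(100.0, athlete, constants)
        )

    def test_capped_at_vo2max(self, cohort29, constants):
        for athlete in cohort29:
            assert combustion_capacity(5000.0, athlete, constants) == pytest.approx(
                constants.k_ox * athlete.vo2max_rel
            )


def grid_scan_pmlss(athlete, constants):
    """Independent oracle: exhaustive 1 W scan for the highest sub-ceiling
    load at which production does not exceed combustion capacity."""
    top = int(np.floor(max_aerobic_power(athlete, constants)))
    best = None
    for load in range(1, top + 1):
        if production_rate(load, athlete, constants) <= combustion_capacity(
            load, athlete, constants
        ):
            best = load
    return float(best)


class TestComputePmlss:
    def test_matches_grid_scan_oracle(self, cohort29, constants):
        extra = sample_cohort(15, 15, CohortParams(seed=99))
        for athlete in cohort29 + extra:
            out = compute_pmlss(athlete, constants)
            assert out.pmlss == pytest.approx(grid_scan_pmlss(athlete, constants))

    def test_vanishing_vlamax_limit_is_maximal_aerobic_power(self, constants):
        athlete = make_athlete(vlamax=1e-6)
        out = compute_pmlss(athlete, constants)
        assert out.aerobic_limited
        assert out.pmlss == pytest.approx(
            np.floor(max_aerobic_power(athlete, constants))
        )

    def test_crossing_invariant(self, cohort29, constants):
        for athlete in cohort29:
            out = compute_pmlss(athlete, constants)
            prod = production_rate(out.pmlss, athlete, constants)
            cap = combustion_capacity(out.pmlss, athlete, constants)
            assert prod <= cap
            if not out.aerobic_limited:
                assert production_rate(out.pmlss + 1.0, athlete, constants) > \
                    combustion_capacity(out.pmlss + 1.0, athlete, constants)

    def test_fraction_of_vo2max_in_physiologic_band(self, cohort29, constants):
        for athlete in cohort29:
            out = compute_pmlss(athlete, constants)
            assert 60.0 < out.pmlss_pct_vo2max <= 100.0
            if not out.aerobic_limited:
                assert out.pmlss_pct_vo2max < 90.0

    def test_monotone_in_vo2max_and_vlamax(self, constants):
        base = make_athlete()
        pmlss = [
            compute_pmlss(base.replace(vo2max_rel=v), constants).pmlss
            for v in np.arange(55.0, 75.0, 2.0)
        ]
        assert np.all(np.diff(pmlss) > 0)
        pmlss = [
            compute_pmlss(base.replace(vlamax=v), constants).pmlss
            for v in np.arange(0.35, 0.95, 0.06)
        ]
        assert np.all(np.diff(pmlss) < 0)

    def test_percent_vo2max_definition(self, constants):
        athlete = make_athlete()
        out = compute_pmlss(athlete, constants)
        expected = 100 * vo2_steady(out.pmlss, athlete, constants) / athlete.vo2max_rel
        assert out.pmlss_pct_vo2max == pytest.approx(expected)


class TestEquilibriumBlc:
    def test_floor_at_baseline(self, constants):
        athlete = make_athlete()
        assert equilibrium_blc(athlete, 1e-6, constants) == constants.b0

    def test_michaelis_midpoint(self, constants):
        # at the load where production is half of capacity the equilibrium
        # sits exactly at the half-saturation concentration Km
        athlete = make_athlete()

        def ratio(load):
            return production_rate(load, athlete, constants) / combustion_capacity(
                load, athlete, constants
            )

        load_half = brentq(lambda p: ratio(p) - 0.5, 1.0, max_aerobic_power(athlete, constants))
        assert equilibrium_blc(athlete, load_half, constants) == pytest.approx(
            constants.Km, rel=1e-6
        )

    def test_diverges_towards_pmlss(self, constants):
        athlete = make_athlete()
        pmlss = compute_pmlss(athlete, constants).pmlss
        loads = pmlss - np.array([40.0, 20.0, 10.0, 5.0, 2.0, 1.0])
        blcs = [equilibrium_blc(athlete, p, constants) for p in loads]
        assert np.all(np.diff(blcs) > 0)
        assert blcs[-1] > 2 * constants.Km

    def test_no_steady_state_above_pmlss(self, constants):
        athlete = make_athlete()
        pmlss = compute_pmlss(athlete, constants).pmlss
        with pytest.raises(NoSteadyStateError):
            equilibrium_blc(athlete, pmlss + 10.0, constants)


class TestCalibration:
    def test_forward_constructed_anchors_give_zero_residual(self):
        # anchors generated by a forward run of known constants must be
        # (near-)exactly reproducible starting from those constants
        cohort = sample_cohort(2, 1, CohortParams(seed=5))
        truth = DEFAULT_CONSTANTS
        stats = cohort_statistics(cohort, truth, resolution=0.05)
        anchors = CalibrationAnchors(
            pct_vo2max_mean=stats["pct_vo2max_mean"],
            delta_vo2_up=stats["delta_vo2_up"],
            delta_vo2_down=stats["delta_vo2_down"],
            delta_vla_up=stats["delta_vla_up"],
            delta_vla_down=stats["delta_vla_down"],
            fat_w_per_pct=stats["fat_w_per_pct"],
        )
        calibrated = calibrate_constants(cohort, anchors, start=truth, max_nfev=40)
        refit = cohort_statistics(cohort, calibrated, anchors, resolution=0.05)
        for key, target in stats.items():
            assert refit[key] == pytest.approx(target, abs=0.15)

    def test_deterministic(self):
        # anchors taken from a forward run so the fit converges immediately;
        # two identical calls must return bit-identical constants
        cohort = sample_cohort(2, 1, CohortParams(seed=5))
        stats = cohort_statistics(cohort, DEFAULT_CONSTANTS, resolution=0.05)
        anchors = CalibrationAnchors(
            pct_vo2max_mean=stats["pct_vo2max_mean"],
            delta_vo2_up=stats["delta_vo2_up"],
            delta_vo2_down=stats["delta_vo2_down"],
            delta_vla_up=stats["delta_vla_up"],
            delta_vla_down=stats["delta_vla_down"],
            fat_w_per_pct=stats["fat_w_per_pct"],
        )
        a = calibrate_constants(cohort, anchors)
        b = calibrate_constants(cohort, anchors)
        assert a == b

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            calibrate_constants([])
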