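"""Bland–Altman, Fisher-z correlation intervals, pair validation, sensitivity."""

import numpy as np
import pytest

from mlssim.agreement import (
    bland_altman,
    correlation_label,
    pearson_ci,
    sensitivity_analysis,
    validate_pair_set,
)
from mlssim.exceptions import DataError
from mlssim.model import compute_pmlss


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman([200.0, 250.0, 300.0], [200.0, 250.0, 300.0])
        assert ba.bias == 0.0
        assert ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_offset(self):
        measured = np.array([200.0, 250.0, 300.0])
        ba = bland_altman(measured, measured + 5.0)
        assert ba.bias == pytest.approx(5.0)
        assert ba.loa_low == pytest.approx(5.0)
        assert ba.loa_high == pytest.approx(5.0)

    def test_matches_direct_formula(self, rng):
        measured = 250.0 + 40.0 * rng.standard_normal(20)
        calculated = measured + 5.0 + 8.0 * rng.standard_normal(20)
        ba = bland_altman(measured, calculated)
        diffs = calculated - measured
        mean = sum(diffs) / len(diffs)
        sd = (sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)) ** 0.5
        assert ba.bias == pytest.approx(mean)
        assert ba.loa_low == pytest.approx(mean - 1.96 * sd)
        assert ba.loa_high == pytest.approx(mean + 1.96 * sd)

    def test_translation_equivariance(self, rng):
        measured = 250.0 + 40.0 * rng.standard_normal(15)
        calculated = measured + 8.0 * rng.standard_normal(15)
        base = bland_altman(measured, calculated)
        shifted = bland_altman(measured, calculated + 12.5)
        assert shifted.bias == pytest.approx(base.bias + 12.5)
        assert shifted.loa_low == pytest.approx(base.loa_low + 12.5)
        assert shifted.loa_high == pytest.approx(base.loa_high + 12.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPearsonCi:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, ci = pearson_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert ci == (r, r)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(25)
        y = x + 0.3 * rng.standard_normal(25)
        r1, ci1 = pearson_ci(x, y)
        r2, ci2 = pearson_ci(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert r1 == pytest.approx(r2)
        assert ci1 == pytest.approx(ci2)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # n < 4
        with pytest.raises(DataError):
            pearson_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @pytest.mark.parametrize(
        "r, n, expected",
        [(0.992, 29, (0.982, 0.996)), (0.984, 10, (0.931, 0.996))],
    )
    def test_reference_intervals(self, r, n, expected):
        # synthesise a pair set with this exact correlation, then check the CI
        x = np.arange(float(n))
        x = (x - x.mean()) / x.std()
        resid = np.zeros(n)
        resid[::2], resid[1::2] = 1.0, -1.0
        resid -= resid.mean()
        resid -= x * (resid @ x) / (x @ x)
        resid /= np.linalg.norm(resid)
        y = r * x / np.linalg.norm(x) + np.sqrt(1 - r * r) * resid
        got_r, (lo, hi) = pearson_ci(x, y)
        assert got_r == pytest.approx(r, abs=1e-12)
        assert abs(lo - expected[0]) < 1e-3
        assert abs(hi - expected[1]) < 1e-3


def test_correlation_labels():
    assert correlation_label(0.2) == "small"
    assert correlation_label(0.45) == "moderate"
    assert correlation_label(-0.5) == "moderate"
    assert correlation_label(0.85) == "high"


class TestValidatePairSet:
    def test_identical_methods_are_interchangeable(self):
        measured = np.linspace(180.0, 350.0, 12)
        report = validate_pair_set(measured, measured.copy())
        assert report.bias == 0.0
        assert report.p_value == pytest.approx(1.0)
        assert np.all(report.pct_bias_per_subject == 0.0)
        assert report.n_exceeding_3pct == 0
        assert report.interchangeable

    def test_counts_subjects_beyond_three_percent(self, rng):
        measured = np.linspace(180.0, 350.0, 29)
        pct = np.zeros(29)
        pct[:12] = rng.uniform(3.1, 7.3, 12)  # twelve subjects biased 3.1-7.3 %
        pct[12:] = rng.uniform(0.0, 2.5, 17)
        calculated = measured * (1 + pct / 100.0)
        report = validate_pair_set(measured, calculated)
        assert report.n_exceeding_3pct == 12

    def test_regression_matches_normal_equations(self):
        calculated = np.array([150.0, 200.0, 250.0, 300.0, 350.0])
        measured = np.array([160.0, 195.0, 240.0, 310.0, 330.0])
        report = validate_pair_set(measured, calculated)
        x = np.column_stack([calculated, np.ones(5)])
        slope, intercept = np.linalg.solve(x.T @ x, x.T @ measured)
        assert report.slope == pytest.approx(slope)
        assert report.intercept == pytest.approx(intercept)

    def test_subgroup_reports(self, rng):
        measured = np.concatenate([280 + 30 * rng.standard_normal(19),
                                   180 + 20 * rng.standard_normal(10)])
        calculated = measured + 5 + 6 * rng.standard_normal(29)
        labels = np.array(["male"] * 19 + ["female"] * 10)
        report = validate_pair_set(measured, calculated, subgroups=labels)
        assert set(report.subgroups) == {"male", "female"}
        assert report.subgroups["male"].n == 19
        assert report.subgroups["female"].n == 10
        male = report.subgroups["male"]
        ba = bland_altman(measured[:19], calculated[:19])
        assert male.bias == pytest.approx(ba.bias)

    def test_loa_rule_variants(self):
        measured = np.linspace(200.0, 320.0, 10)
        calculated = measured + 2.0
        strict = validate_pair_set(measured, calculated, loa_rule="halfwidth")
        bounds = validate_pair_set(measured, calculated, loa_rule="bounds")
        assert strict.interchangeable
        assert bounds.interchangeable


class TestSensitivity:
    def test_zero_perturbation_gives_zero_deltas(self, cohort29, constants):
        report = sensitivity_analysis(
            cohort29[:6], constants, perturbations=[("null", "vlamax", 0.0)]
        )
        assert report.effects["null"].delta_mean == 0.0
        assert report.effects["null"].delta_sd == 0.0

    def test_perturbation_signs_follow_model_monotonicity(self, cohort29, constants):
        report = sensitivity_analysis(
            cohort29,
            constants,
            perturbations=[
                ("vo2up", "vo2max_rel", 3.3),
                ("vlaup", "vlamax", 0.11),
            ],
        )
        base = report.base_pmlss
        limited = np.array(
            [compute_pmlss(a, constants).aerobic_limited for a in cohort29]
        )
        vo2_deltas = report.effects["vo2up"].delta_mean
        assert vo2_deltas > 0
        per_subject = []
        for athlete, b in zip(cohort29, base):
            shifted = athlete.replace(vo2max_rel=athlete.vo2max_rel + 3.3)
            per_subject.append(compute_pmlss(shifted, constants).pmlss - b)
        assert np.all(np.asarray(per_subject) > 0)
        # raising VLa_max lowers PMLSS wherever the crossing (not the
        # aerobic ceiling) is binding
        for athlete, b, lim in zip(cohort29, base, limited):
            shifted = athlete.replace(vlamax=athlete.vlamax + 0.11)
            delta = compute_pmlss(shifted, constants).pmlss - b
            assert delta <= 0
            if not lim:
                assert delta < 0

    def test_asymmetry_is_preserved(self, cohort29, constants):
        report = sensitivity_analysis(cohort29, constants)
        up = report.effects["vlamax+0.11"].delta_mean
        down = report.effects["vlamax-0.11"].delta_mean
        assert up < 0 < down
        assert abs(up + down) > 1e-6  # signed values are not mirrored

    def test_by_sex_split(self, cohort29, constants):
        report = sensitivity_analysis(
            cohort29, constants, perturbations=[("vo2up", "vo2max_rel", 3.3)]
        )
        eff = report.effects["vo2up"]
        assert set(eff.delta_by_sex) == {"male", "female"}
        n_m = sum(a.sex == "male" for a in cohort29)
        total = (
            eff.delta_by_sex["male"][0] * n_m
            + eff.delta_by_sex["female"][0] * (len(cohort29) - n_m)
        ) / len(cohort29)
        assert total == pytest.approx(eff.delta_mean)
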