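"""Method-agreement and sensitivity statistics.

Implements the statistical layer used to compare measured and calculated
PMLSS: Bland–Altman bias and 95 % limits of agreement, Pearson correlations
with Fisher-z confidence intervals and magnitude labels, a paired t-test,
ordinary least-squares regression of measured on calculated PMLSS,
per-subject percent bias, a Shapiro–Wilk normality check, and the
single-input perturbation sensitivity analysis (day-to-day variability of
VO2max and VLa_max, body-fat uncertainty).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DataError, ModelDegenerateError
from .model import ModelConstants, compute_pmlss
from .types import Athlete

__all__ = [
    "BlandAltman",
    "AgreementReport",
    "PerturbationEffect",
    "SensitivityReport",
    "bland_altman",
    "fisher_interval",
    "pearson_ci",
    "correlation_label",
    "validate_pair_set",
    "sensitivity_analysis",
    "DEFAULT_PERTURBATIONS",
]


@dataclass(frozen=True)
class BlandAltman:
    """Mean bias and 95 % limits of agreement of paired differences."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    differences: np.ndarray


def bland_altman(measured, calculated) -> BlandAltman:
    """Bland–Altman analysis of calculated − measured differences (W).

    A positive bias means the calculation overestimates the measured value.
    Limits of agreement are bias ± 1.96 · SD (sample SD, n − 1 degrees of
    freedom).
    """
    measured = np.asarray(measured, dtype=float)
    calculated = np.asarray(calculated, dtype=float)
    if measured.shape != calculated.shape or measured.ndim != 1:
        raise ValueError("measured and calculated must be 1-D arrays of equal length")
    if measured.size < 2:
        raise ValueError("at least two pairs are required")
    diffs = calculated - measured
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd=sd,
        differences=diffs,
    )


def fisher_interval(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation of ``r`` at sample size
    ``n``: ``tanh(atanh(r) ± z / sqrt(n − 3))``."""
    if n < 4:
        raise ValueError("at least four pairs are required for a Fisher-z interval")
    if abs(r) >= 1.0 - 1e-15:
        return (r, r)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z / np.sqrt(n - 3)
    return (
        float(np.tanh(np.arctanh(r) - half)),
        float(np.tanh(np.arctanh(r) + half)),
    )


def pearson_ci(x, y, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Pearson r with a Fisher-z confidence interval.

    The interval is ``tanh(atanh(r) ± z / sqrt(n − 3))``; for |r| = 1 it
    degenerates to the point itself.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("at least four pairs are required for a Fisher-z interval")
    if x.std() == 0 or y.std() == 0:
        raise DataError("correlation undefined: one input has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, fisher_interval(r, n, level)


def correlation_label(r: float) -> str:
    """Magnitude label: small (r < 0.4), moderate (0.40–0.59), high (> 0.6)."""
    r = abs(r)
    if r < 0.4:
        return "small"
    if r < 0.6:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary between measured and calculated PMLSS."""

    n: int
    bias: float  # W
    bias_ci95: tuple[float, float]  # W, t-based
    loa_low: float
    loa_high: float
    r: float
    r_ci95: tuple[float, float]
    r_label: str
    t_stat: float
    p_value: float
    slope: float  # measured ≈ slope · calculated + intercept
    intercept: float
    pct_bias_per_subject: np.ndarray  # %
    n_exceeding_3pct: int
    shapiro_p: float
    interchangeable: bool
    subgroups: dict = field(default_factory=dict)


def _single_report(measured: np.ndarray, calculated: np.ndarray, loa_rule: str) -> AgreementReport:
    ba = bland_altman(measured, calculated)
    n = measured.size
    se = ba.sd / np.sqrt(n)
    t_crit = stats.t.ppf(0.975, n - 1)
    bias_ci = (ba.bias - t_crit * se, ba.bias + t_crit * se)
    if n >= 4 and measured.std() > 0 and calculated.std() > 0:
        r, r_ci = pearson_ci(measured, calculated)
    else:  # too few pairs (or no variance) for a Fisher-z interval
        if n >= 2 and measured.std() > 0 and calculated.std() > 0:
            r = float(np.corrcoef(measured, calculated)[0, 1])
        else:
            r = float("nan")
        r_ci = (float("nan"), float("nan"))
    if ba.sd == 0.0:  # identical differences: the paired test is degenerate
        t_stat = 0.0 if ba.bias == 0.0 else float("inf") * np.sign(ba.bias)
        p_value = 1.0 if ba.bias == 0.0 else 0.0
        shapiro_p = 1.0
    else:
        t_stat, p_value = stats.ttest_rel(calculated, measured)
        shapiro_p = (
            float(stats.shapiro(ba.differences).pvalue) if n >= 3 else float("nan")
        )
    if n >= 3 and calculated.std() > 0:
        reg = stats.linregress(calculated, measured)
        slope, intercept = float(reg.slope), float(reg.intercept)
    else:
        slope, intercept = float("nan"), float("nan")
    pct_bias = 100.0 * np.abs(ba.differences) / measured
    mean_measured = float(measured.mean())
    if loa_rule == "halfwidth":
        interchangeable = 1.96 * ba.sd < 0.03 * mean_measured
    elif loa_rule == "bounds":
        interchangeable = max(abs(ba.loa_low), abs(ba.loa_high)) < 0.03 * mean_measured
    else:
        raise ValueError(f"unknown loa_rule {loa_rule!r}")
    return AgreementReport(
        n=int(n),
        bias=ba.bias,
        bias_ci95=(float(bias_ci[0]), float(bias_ci[1])),
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        r=r,
        r_ci95=r_ci,
        r_label=correlation_label(r),
        t_stat=float(t_stat),
        p_value=float(p_value),
        slope=slope,
        intercept=intercept,
        pct_bias_per_subject=pct_bias,
        n_exceeding_3pct=int(np.sum(pct_bias > 3.0)),
        shapiro_p=shapiro_p,
        interchangeable=bool(interchangeable),
    )


def validate_pair_set(
    measured, calculated, subgroups=None, loa_rule: str = "halfwidth"
) -> AgreementReport:
    """Agreement report overall and, optionally, per subgroup.

    ``subgroups`` is a label per subject (e.g. sex).  The calculated method
    counts as interchangeable with the measured one when the limits of
    agreement stay within 3 % of the mean measured PMLSS — by default the LoA
    half-width (1.96 · SD) is compared against 3 %, with ``loa_rule="bounds"``
    both bounds are.
    """
    measured = np.asarray(measured, dtype=float)
    calculated = np.asarray(calculated, dtype=float)
    report = _single_report(measured, calculated, loa_rule)
    if subgroups is not None:
        labels = np.asarray(subgroups)
        if labels.shape != measured.shape:
            raise ValueError("subgroup labels must cover all subjects")
        sub = {}
        for label in dict.fromkeys(labels.tolist()):  # preserve order
            mask = labels == label
            sub[label] = _single_report(measured[mask], calculated[mask], loa_rule)
        report = AgreementReport(**{**report.__dict__, "subgroups": sub})
    return report


# ---------------------------------------------------------------------------
# Perturbation sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationEffect:
    """Signed PMLSS response to one single-input perturbation."""

    name: str
    attribute: str
    shift: float
    delta_mean: float  # W
    delta_sd: float  # W
    delta_by_sex: dict  # sex -> (mean, sd) in W
    pct_by_sex: dict  # sex -> (mean, sd) in % of unperturbed PMLSS
    r_after: float  # correlation of perturbed values vs reference
    excluded: tuple = ()


@dataclass(frozen=True)
class SensitivityReport:
    effects: dict  # name -> PerturbationEffect
    base_pmlss: np.ndarray


#: day-to-day variability of the inputs plus the body-fat uncertainty band
DEFAULT_PERTURBATIONS: list[tuple[str, str, float]] = (
    [("vo2max+3.3", "vo2max_rel", 3.3), ("vo2max-3.3", "vo2max_rel", -3.3)]
    + [("vlamax+0.11", "vlamax", 0.11), ("vlamax-0.11", "vlamax", -0.11)]
    + [(f"fat{s:+d}pct", "body_fat", s / 100.0) for s in range(-6, 7) if s]
)


def sensitivity_analysis(
    cohort: list[Athlete],
    constants: ModelConstants = None,
    perturbations=None,
    measured=None,
) -> SensitivityReport:
    """Recompute PMLSS with single inputs shifted, one perturbation at a time.

    Reports the signed mean ± SD change overall and by sex, the change as a
    percentage of each athlete's unperturbed PMLSS, and the correlation of
    the perturbed values against ``measured`` (or, if not given, against the
    unperturbed calculated values).  Athletes whose perturbed model becomes
    degenerate are excluded from that perturbation with a warning.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if perturbations is None:
        perturbations = DEFAULT_PERTURBATIONS
    base = np.asarray([compute_pmlss(a, constants).pmlss for a in cohort])
    reference = np.asarray(measured, dtype=float) if measured is not None else base
    sexes = np.asarray([a.sex for a in cohort])

    effects = {}
    for name, attr, shift in perturbations:
        perturbed = np.full(len(cohort), np.nan)
        excluded = []
        for i, ath in enumerate(cohort):
            try:
                shifted = ath.replace(**{attr: getattr(ath, attr) + shift})
                perturbed[i] = compute_pmlss(shifted, constants).pmlss
            except (ModelDegenerateError, ValueError):
                excluded.append(ath.id)
                warnings.warn(
                    f"athlete {ath.id} excluded from perturbation {name}: "
                    "degenerate model",
                    stacklevel=2,
                )
        ok = ~np.isnan(perturbed)
        delta = perturbed[ok] - base[ok]
        pct = 100.0 * delta / base[ok]
        by_sex, pct_by_sex = {}, {}
        for sex in ("male", "female"):
            mask = sexes[ok] == sex
            if mask.any():
                by_sex[sex] = (float(delta[mask].mean()), float(delta[mask].std(ddof=1)) if mask.sum() > 1 else 0.0)
                pct_by_sex[sex] = (float(pct[mask].mean()), float(pct[mask].std(ddof=1)) if mask.sum() > 1 else 0.0)
        if ok.sum() >= 4 and np.std(perturbed[ok]) > 0 and np.std(reference[ok]) > 0:
            r_after, _ = pearson_ci(reference[ok], perturbed[ok])
        else:
            r_after = float("nan")
        effects[name] = PerturbationEffect(
            name=name,
            attribute=attr,
            shift=shift,
            delta_mean=float(delta.mean()),
            delta_sd=float(delta.std(ddof=1)) if delta.size > 1 else 0.0,
            delta_by_sex=by_sex,
            pct_by_sex=pct_by_sex,
            r_after=r_after,
            excluded=tuple(excluded),
        )
    return SensitivityReport(effects=effects, base_pmlss=base)
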