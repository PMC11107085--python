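# Methods

`mlssim` models the determination of the maximal lactate steady state
(MLSS) in cyclists: it simulates the three laboratory tests involved (a
15 s all-out sprint, a ramp test to exhaustion, and a series of 20–30 min
constant-load trials), computes the power at the MLSS (PMLSS) from a
metabolic equilibrium model fed by the sprint- and ramp-derived capacities,
and quantifies how well the calculated PMLSS agrees with the
constant-load-derived one.

## The equilibrium model

The model follows the Mader tradition of treating the blood lactate
concentration (BLC) as the balance of a glycolytic production term and an
oxidative combustion term, both functions of exercise intensity.

**Oxygen cost.** The steady-state oxygen demand of pedalling at power `P`
for an athlete of mass `m` is linear,

```
vo2_ss(P) = a + e·P/m      [ml·kg⁻¹·min⁻¹],  capped at VO2max
```

with baseline cost `a = 7 ml·kg⁻¹·min⁻¹` (fixed) and an oxygen cost per
watt `e` (calibrated within ±15 % of the textbook 10.8 ml·min⁻¹·W⁻¹).
`x = vo2_ss / VO2max` is the fractional aerobic utilisation and
`MAP = (VO2max − a)·m/e` the maximal aerobic power.

**Production.** Glycolytic lactate production is a Hill function of the
aerobic saturation odds `u = x/(1−x)`,

```
production(P) = VLa_max_eff · u^h / (K + u^h)      [mmol·L⁻¹·s⁻¹]
```

rising from ~0 at rest to the athlete's effective maximal glycolytic rate.
Both the exponent `h` and the half-activation constant `K` are calibrated
(see below). The calibrated optimum operates the drive far from saturation
at MLSS intensity (~25–30 % activation), which keeps the model's response
to VLa_max changes smooth across the whole cohort; forcing a steep cubic
drive instead pins part of any realistic cohort against the saturation
boundary and makes the VLa_max sensitivity statistics bimodal and unstable.
Above the aerobic ceiling (`x ≥ 1`) the drive is fully activated and the
unmet oxygen demand is additionally converted into obligatory production at
the classic oxygen equivalent of lactate accumulation
(3 ml O2·kg⁻¹ per mmol·L⁻¹), so supra-ceiling loads can never be
lactate-steady.

**Combustion.** The maximal (BLC-saturated) combustion rate is proportional
to the steady-state oxygen uptake, `capacity(P) = k_ox · vo2_ss(P)` with
`k_ox` calibrated. Actual combustion saturates with concentration as
`b⁴/(b⁴ + Km⁴)`; `Km = 2.2 mmol·L⁻¹` (design choice, see *Constant-load
trials*).

**PMLSS.** The calculated PMLSS is the highest power on a 1 W grid at which
production does not exceed the combustion capacity. The two curves can be
near-tangent, so the crossing is located by evaluating the gap on the whole
grid rather than by a single bracketing. When production saturates below
capacity everywhere (very low VLa_max), the binding limit is the aerobic
ceiling itself and PMLSS equals MAP, flagged `aerobic_limited`; consistent
with this, the `%VO2max` at PMLSS equals 100 for such athletes while it
stays in the 60–90 % band for crossing-limited ones. Below PMLSS the
equilibrium BLC is `Km·(r/(1−r))^{1/4}` with `r = production/capacity`,
floored at the resting baseline `b0 = 1.2 mmol·L⁻¹`; it diverges as the
load approaches PMLSS, which is why the *measured* MLSS BLC (a finite-trial
quantity, see below) is the statistic comparable to published values.

**Body composition.** A two-compartment rule normalises VLa_max to the
glycolytically active (lean) compartment:
`VLa_max_eff = VLa_max · ((1−f)/(1−f_ref))^γ` with sex-specific reference
fat fractions (`0.15` male, `0.20` female) and a calibrated exponent `γ`.
More body fat therefore lowers the effective glycolytic rate and raises the
calculated PMLSS by ~1 W per percentage point, the magnitude reported for
the software being emulated; the direction is a model outcome, not an
assumption, and is noted in the output metadata.

## Calibration

The equations above are a stand-in for unpublished proprietary algorithms;
no claim of numerical identity is made. Their free constants
`(K, h, k_ox, e, γ)` are fixed by deterministic least squares against six
published cohort-level anchors: mean PMLSS at 76.6 %VO2max; mean PMLSS
changes of +19 / −17 W under ±3.3 ml·kg⁻¹·min⁻¹ VO2max shifts and −12 /
+15 W under ±0.11 mmol·L⁻¹·s⁻¹ VLa_max shifts (each weighted by its printed
SD); and ~1 W per 1 % body fat. The shipped defaults were calibrated
against a large synthetic population sample (228 men, 120 women, seed 505)
drawn from the same distributions as the study cohort, so the anchors hold
in expectation over fresh cohorts rather than only on one lucky draw; the
29-athlete reference cohort reproduces all six anchors within one printed
SD. During calibration the PMLSS is evaluated on a fine (0.05–0.1 W) grid
so the objective is smooth for finite differences; athletes whose shifted
input would be unphysiological (e.g. VLa_max driven non-positive) are
excluded from that shift, as in the sensitivity analysis. The calibrated
values are

| constant | value | meaning |
|---|---|---|
| `e` | 11.83 | ml O2·min⁻¹ per W |
| `K` | 21.04 | half-activation of the glycolytic drive |
| `h` | 1.78 | Hill exponent of the drive |
| `k_ox` | 3.42 × 10⁻³ | (mmol·L⁻¹·s⁻¹) per (ml·kg⁻¹·min⁻¹) |
| `γ` | 1.87 | body-fat exponent |

## Synthetic cohorts and signals

`cohort_sim` draws athletes from sex-specific truncated normals (±3 SD,
positive) matching the study cohort: men VO2max 64.9 ± 7.3 ml·kg⁻¹·min⁻¹,
VLa_max 0.59 ± 0.15 mmol·L⁻¹·s⁻¹, mass 76.0 ± 7.0 kg; women 49.1 ± 5.0,
0.50 ± 0.15, 60.7 ± 5.6. Male body fat is drawn from a truncated normal
(0.15 ± 0.03, a bio-impedance-like spread); female body fat is fixed at
0.20, as in the study. Rider class is assigned from relative VO2max with
cuts that roughly reproduce the study's 17/10/4
recreational/amateur/professional split. Every random quantity derives from
the master seed through per-athlete substreams, so cohorts are extensible
without reshuffling.

**Sprint traces** (10 Hz, 15 s) hold peak power until the true alactic time
`t_alac`, then drop immediately past the 3.5 % detection criterion and
decline at 3 %·s⁻¹ — the 96.5 % level is crossed within the first declining
sample, so the detector recovers `t_alac` to one sample noise-free.
Multiplicative 2.5 % crank noise is applied per sample. The post-sprint
lactate curve is a squared gamma-like pulse peaking at recovery minute 5
whose noise-free maximum is exactly
`baseline + VLa_max·(15 − t_alac)`, i.e. the inversion of the VLa_max
estimator; analyzer noise is additive with SD 0.1 mmol·L⁻¹.

**Ramp sessions** follow the published protocol (12 min warm-up at
1.5–2 W·kg⁻¹, a sex/class/mass-specific initial load for 120 s, +25 W
every 30 s). VO2 tracks the linear demand with a 30 s mono-exponential lag
and saturates at VO2max; RQ rises with relative intensity and exceeds 1.1
before exhaustion. Exhaustion occurs when the oxygen shortfall above the
ceiling has depleted an anaerobic work capacity of 280 J·kg⁻¹ (a typical
W′ for trained cyclists). Under this model the loaded portion lasts about
7–11 min for the default cohort (median within the 8–12 min window the
protocol aims for); light, low-VO2max riders on the fixed 100 W female
start finish faster — a property of the protocol arithmetic itself, since
a 50 W·min⁻¹ ramp from 100 W reaches such a rider's maximal aerobic power
in only a few minutes.

**Constant-load trials** integrate the model's net lactate rate
(`solve_ivp`, LSODA) from the resting baseline and sample every 5 min with
analyzer noise; the publication behind the protocol does not state the
sampling schedule, so 5 min was chosen as the coarsest grid that still
resolves the final-10-min criterion from stored samples. Loads above the
aerobic ceiling deplete the same 280 J·kg⁻¹ anaerobic capacity and the
trial is abandoned at exhaustion; an abandoned trial cannot demonstrate a
steady state. `Km = 2.2 mmol·L⁻¹` with the quartic closure was chosen so
that (i) trials more than ~1 W below PMLSS converge within 30 min (the
steady/non-steady boundary sits essentially at PMLSS, keeping the 10 W
titration within one step of the model value), and (ii) the end-trial BLC
at the adjudicated MLSS averages ≈4 mmol·L⁻¹ over the reference cohort,
matching the published 4.06 ± 1.42 range.

## Adjudication and statistics

A trial is steady when the BLC rises less than 0.2 mmol·L⁻¹ over the final
10 min; a rise of exactly 0.2 counts as non-steady (the protocol defines
steady as `< 0.2` and failure as `> 0.2`, leaving the boundary undefined;
the strict reading is the default and a flag selects the lenient one). The
titration steps ±10 W from an informed start (model PMLSS rounded down to
the step) until a steady load is bracketed by a failed one, within 2–5
trials. Rate-based assessment (0.02 mmol·L⁻¹·min⁻¹ over the final 10 min,
0.05 over the final 20) is available as an alternative mode.

The agreement layer reports the Bland–Altman bias and 95 % limits of
agreement of calculated − measured differences (positive bias ⇒ the
calculation overestimates), a t-based 95 % CI for the bias, paired t-test,
Shapiro–Wilk normality of the differences, Pearson r with Fisher-z CIs
(small < 0.4 ≤ moderate < 0.6 ≤ high), the regression of measured on
calculated PMLSS, per-subject percent bias with a count of subjects beyond
3 %, and an interchangeability verdict (LoA half-width below 3 % of the
mean measured PMLSS; a flag switches to comparing both LoA bounds). The
sensitivity analysis recomputes PMLSS with one input shifted at a time
(VO2max ±3.3, VLa_max ±0.11, body fat ±1…6 %), preserving signed
asymmetric responses, splitting by sex, and excluding (with a warning) any
athlete whose perturbed model is degenerate.

## What the simulations do and do not show

The generator reproduces the cohort's distributional structure, instrument
noise magnitudes, and day-to-day variability figures, so passing tests
demonstrate internal consistency of the measurement chain, the calibrated
model, and the statistics — not external validity on real athletes. Real
sprint traces have cadence-dependent structure, real gas exchange drifts
and has outlier breaths, real lactate kinetics include distribution-space
delays, and real MLSS trials end for many reasons other than W′ depletion;
none of that is modelled. Because the measured PMLSS is produced by the
same metabolic model that the calculated PMLSS uses (with measurement
noise and the titration grid in between), the near-unity correlations of a
replication run are an upper bound of self-consistency, not evidence about
the emulated software.

## Numerical choices and degenerate inputs

PMLSS resolution is 1 W (finer than the 5–10 W steps of comparable
protocols); the grid search raises `ModelDegenerateError` when no positive
equilibrium exists (VO2max at or below the baseline cost, or production
exceeding combustion at rest). The steady-state check rounds the
final-10-min rise at 10⁻⁹ mmol·L⁻¹ so float noise cannot flip the 0.2
boundary. Breath binning weights each breath by the interval since the
previous one (first breath: median interval) and uses only complete 30 s
bins. Truncated-normal draws use `scipy.stats.truncnorm` driven by
per-athlete `numpy` substreams. The ODE tolerances are rtol 10⁻⁷ /
atol 10⁻⁹, small enough that the noise-free titration boundary is
reproducible to well under the 0.1 mmol·L⁻¹ analyzer noise.

## Known limitations

* The equilibrium model is a calibrated surrogate: only the six anchors
  (plus the qualitative monotonicities) are constrained by published
  values; all other behaviour (e.g. the exact shape of the production
  curve, the equilibrium BLC profile) is model-dependent.
* Per-subject sensitivity SDs are larger than the published ones; only the
  cohort means were calibrated.
* VLa_max draws near the truncation floor produce aerobic-limited athletes
  whose PMLSS is pinned at maximal aerobic power; these are rare but
  influence tail statistics.
* A common resting BLC (1.2 mmol·L⁻¹) is used for both sexes; the source
  study does not report sex-specific baselines.
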