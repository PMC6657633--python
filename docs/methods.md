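# Methods

## Kinetic model

The maternal circulation is treated as a single well-mixed compartment
sampled at the blood-circulation cycle *t′* (default 1 min, exposed as a
parameter everywhere). Per cycle, infusion at IR mU/min adds
*k* = IR·2×10⁴·*t′*/*V* pg/ml (unit chain: 1 U of solution = 10 iU,
1 iU = 2 µg, so 1 mU = 2×10⁴ pg), and first-order clearance retains
*r* = exp(−ln 2·*t′*/*t*₁/₂).

The recursion convention is **add-then-decay**:
*C<sub>t</sub>* = (*C*<sub>*t*−1</sub> + *k<sub>t</sub>*)·*r*. This makes
the constant-rate solution the geometric partial sum
*k·r*(1 − *r*ⁿ)/(1 − *r*) with steady state *M·k*, *M* = *r*/(1 − *r*).
The alternative decay-then-add convention would give steady state
*k*/(1 − *r*) and is rejected as inconsistent with *C* = *M·k*. The
series tracks the end-of-cycle **baseline** (lower envelope) of the
intra-cycle fluctuation; time stamps are end-of-cycle, so "the value at
30 minutes" is the 30th iterate. Initial concentration defaults to 0
(endogenous maternal and fetal oxytocin are excluded from the model); a
nonzero initial value is accepted for sensitivity use.

Convergence: the relative gap to the steady state after *n* cycles is
exactly *r*ⁿ. For *t*₁/₂ = 3 min, *r*³⁰ = 2⁻¹⁰ ≈ 0.098%, hence the
"within 0.1% at 30 minutes" statement. For *t*₁/₂ = 6 min the 30-cycle
gap is 2⁻⁵ ≈ 3.1%, so that claim is specific to the 3-minute case; we
treat the 30-minute convergence figure as tied to the worked example's
parameters.

### Units and rounding

All internal quantities are pg, ml, minutes; conversions happen at
construction/IO boundaries only. The pound is 0.45359237 kg exactly.
`rounded_volume=True` rounds the derived blood volume to two significant
figures (160 lb → 4.7×10³ ml, 128 lb → 3.8×10³ ml) before downstream
use; this is the clinical-shorthand arithmetic the reference tables were
produced with, and it is the default in the `report` module (and only
there). Table conventions: *M* to two decimals, *k* to whole pg/ml with
half-up tie-breaking.

The historical 128-lb increment column was evidently derived by scaling
the already-rounded 160-lb column by the weight ratio 1.25 and
re-rounding ({54, 106, 160, 213, 266}); direct computation with
*V* = 3.8×10³ ml gives {53, 105, 158, 211, 263}. Direct recomputation is
the canonical output; `make_table2(scaled_from_reference=True)`
regenerates the scaled variant so both derivations are reproducible. The
drift (≤ 3 pg/ml) is a rounding artifact, not a model difference.

## Schedules

Schedules are piecewise-constant rate sequences quantized to whole
cycles; sub-cycle durations are rejected rather than interpolated, since
the model is defined only at cycle resolution. Builders: constant,
stepped ramp (default 30-minute holds, capped), and pulsatile (rate on
for the first part of each period). Because the system is linear, the
converged period-average of a pulsatile schedule equals duty-cycle ×
constant-infusion steady state — tested as an invariant.

## Desensitization layer

Override concentration = max(0, maternal − *L*), where *L* is the
placental oxytocinase degradation limit. *L* is deliberately a required
parameter with no default: no measurement or even order-of-magnitude
estimate exists, and forcing explicitness prevents silently asserting
unsupported placental transfer. Fetal-brain concentration is taken equal
to the override concentration (no blood–brain-barrier inhibition
assumed).

The threshold is stated for constant concentrations as *T* = *D*/*C*
with *D* = 1.8×10⁶ (pg·min)/ml (from in-vitro rat uterine-explant
exposure data: 10⁴ pg/ml × 180 min). For time-varying trajectories we
accumulate Σ *C*<sub>override</sub>·Δ*t* and flag the first cycle where
the sum reaches *D* (ceiling convention). The integral form is the
unique additive generalization consistent with the constant case and
with *D*'s units; it is an extension, not a measured law. Exposure never
decays — no receptor resensitization kinetics are modelled, so crossing
times are lower bounds relative to any model with recovery. *D* is a
configurable scalar (concentration-dependent *D* is not implemented);
the 50% desensitization level is a global time factor (default 1.4,
i.e. 40% longer exposure), drawn as a second hyperbola *C·T* = 1.4 *D*.

`constant_infusion_exposure` evaluates the cumulative exposure of a
constant-rate labor in closed form (geometric partial sums) and is the
vectorized fast path used by the cohort generator; its equality with
simulate-then-accumulate is asserted by test to 10⁻⁹ relative.

## Synthetic cohorts

Each labor draws weight, half-life, infusion rate and duration; exposed
cases get a constant-rate schedule, their cumulative override exposure is
compared with *D*, and a binary outcome is drawn at risk *p*₁ if the
threshold was crossed, else *p*₀. This is the minimal two-level risk
model: no dose–response above threshold is implemented (no functional
form exists to encode). Association measures are computed from the 2×2
exposure × outcome table via `statsmodels` (`Table2x2`): relative risk
as the headline (cohort sampling), odds ratio for comparability,
log-scale 95% normal CIs, 0.5 continuity correction (flagged) on zero
cells, plus stratified RRs for the crossed/uncrossed exposed strata.

Default distributions (general population, all config-overridable and
illustrative — the sources name ranges, not distributions): weight
truncated normal 150 ± 25 lb on [90, 250]; half-life uniform on the
reported 1–6 min; infusion rate truncated normal 12 ± 5 mU/min on
[1, 36]; infusion duration truncated log-normal, median 8 h, on
[1 h, 48 h]; exposure fraction 0.5; *p*₀ = 0.01, *p*₁ = 0.10. Under
these conditions essentially no labor reaches *D* even at *L* = 0 —
which is the model's central claim about ordinary inductions. Attenuation
experiments that need an appreciable above-threshold fraction therefore
use `high_exposure_config`, representing the at-risk stratum the
threshold mechanism concerns: rate 30 ± 8 mU/min on [10, 48]
(high-dose-protocol range), half-life uniform 3–6 min (reported 3–5 plus
an inefficient-clearance tail), duration log-normal median 30 h on
[12, 48] h. These were chosen once as plausible for that stratum.

`limit_for_crossing_fraction` realizes a prescribed above-threshold
fraction *f*: for each exposed case it solves (vectorized bisection on
the closed-form exposure) the critical limit at which that labor would
just reach *D*, then places *L* between order statistics so exactly
round(*f*·*n*<sub>exposed</sub>) cases cross under the same seed.
Unattainable fractions raise instead of silently degrading.

Reproducibility: a master `SeedSequence` is split into one substream per
variable, and all distributions are sampled by inverse CDF, so runs are
bit-reproducible and growing `n_cases` extends a cohort without
reshuffling earlier cases (rejection sampling would break this).

What the generator does **not** emulate: real exposure is
augmentation/induction protocols with titrated ramps, not constant
rates; covariates (parity, gestational age), confounding, measurement
error and outcome misclassification are absent; outcomes are independent
Bernoulli draws. Passing tests therefore demonstrate the mixture
*mechanism* — that a threshold dilutes a strong stratum effect into a
weak population association — not any empirical effect size, and no
published registry estimate is targeted or reproduced.

## Numerical choices

- Retention is always computed as exp(−ln 2·*t′*/*t*₁/₂), never from
  tabulated percentages; printed removal/retention percentages are
  outputs.
- Geometric partial sums are evaluated via `r**n` directly; near the
  asymptote the series saturates at machine precision (tests assert
  strict monotonicity only while increments are resolvable).
- Crossing times are reported at cycle resolution (first cycle with
  cumulative exposure ≥ *D*); for a constant override *C* this is
  ⌈*D*/*C*⌉ exactly.
- Bisection for critical limits runs 60 iterations on [0, *M·k*],
  far below the 10⁻⁶-relative equivalence asserted elsewhere.
- Degenerate inputs: zero infusion rate is legal everywhere (off-phase);
  zero override returns an infinite desensitization time, distinct from
  the domain error raised for negative inputs.

## Problem sizes

The cohort tests and the attenuation demonstration use 100 000 labors
(three cohorts, one per crossing fraction {0, 0.05, 0.2}), which the
vectorized closed-form path completes in about two seconds; unit tests
use 2 000–40 000. Trajectory-level equivalence checks simulate a few
hundred random labors minute-by-minute.

## Known limitations

- The constant-*D* threshold extrapolates a single in-vitro exposure
  pair across two orders of magnitude of concentration.
- No resensitization, no receptor downregulation kinetics beyond the
  crossing flag, no endogenous oxytocin, no intra-cycle fluctuation
  above the baseline envelope.
- *L* is unknown; every downstream statement about crossing is
  conditional on the supplied *L* (hence the sweep tooling).
- Half-life is a fixed per-labor input; pregnancy-stage dynamics are out
  of scope.
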