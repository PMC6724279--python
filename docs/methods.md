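# Methods

This note documents the model implemented by `t1dcea`, its assumptions,
parameter defaults and numerical conventions, and what its tests do and do
not establish.

## Scope and honesty about inputs

The package re-implements the *pipeline* of a published IMSS evaluation of
insulin-pump therapy (CSII) versus multiple daily injections (MDI) in adult
type 1 diabetes: synthetic cohort → annual-cycle complication
microsimulation → 2016-MXN costing and utility weighting → discounted
cost/QALY aggregation, ICERs, scenario analyses, acceptability curve.

Two classes of inputs must be distinguished:

* **Published inputs, transcribed exactly** — the baseline cohort marginals
  (n = 192; HbA1c 9.2 ± 2.2%, age 32.3 ± 10.8 y, 29.2% male, 22.4 severe
  hypoglycaemic events/100 patient-years, 19 complication prevalences, 3
  medication shares), the two intervention-effect regressions
  (−3.60 [SE 0.62] + 0.52 [SE 0.077]·HbA1c; 0.5·rate + 0.016·age − 1.18),
  the unit-cost table (therapy 53,568 / 22,884.97 MXN per year; DRG event
  costs; the one-ninth maintenance rule; 0.0865 DRG inflation 2014→2016;
  18.390 MXN/USD), the human-capital inputs (salaries 333.76/292.88 MXN/day,
  255 workdays, working age [18, 60)), the utility catalogue (baseline
  0.785; one-off and chronic decrements; post-event states), 5%/5%
  discounting and the 70-year horizon.
* **Unpublished internals, replaced by configuration** — complication onset
  hazards, HbA1c relative risks, fatality probabilities, background
  mortality and disability-leave durations live inside the proprietary
  disease model used by the source evaluation.  `data/disease_params.yaml`
  ships clearly-labelled synthetic defaults of plausible magnitude; nothing
  in this repository should be read as those proprietary values, and the
  published lifetime totals (absolute costs, complication-free times, the
  CEAC's headline probability) are consequently *not* reproduction targets.
  What is reproduced exactly is every piece of printed arithmetic, and the
  engine is verified against independent closed-form oracles instead.

## Synthetic cohort

Only univariate summaries of the IMSS cohort are public, so marginals are
sampled independently (a documented simplification; no correlation structure
is available):

* Continuous traits: truncated normals.  The underlying location/scale are
  solved numerically (scipy `truncnorm` moments + root solver) so the
  *truncated* distribution reproduces the published mean and SD exactly;
  naive truncation would shift, e.g., the HbA1c mean by ≈ +0.05 at the [4,20]
  bounds and the age mean by ≈ +2 y at the ≥18 bound.
* Triglycerides (145.7 ± 185.2 mg/dl, SD > mean): moment-matched log-normal,
  since a normal would yield many negative values.
* Diabetes duration: truncated normal, resampled per patient until duration
  ≤ age.  This per-patient constraint biases the duration marginal downward
  by roughly 3.5 years at the IMSS parameters; the alternative (matching the
  printed mean) would require durations exceeding age.  Logical consistency
  was preferred; the bias is asserted, one-sidedly, in the tests.
* eGFR is printed without an SD; the default SD is 20 ml/min/1.73 m²
  (configurable, field `egfr_sd`).
* Binary traits: independent Bernoulli at the printed prevalences.

Bounds: age [18, 100], HbA1c [4, 20], duration [0, age], plus physiological
bounds on BMI, blood pressure and lipids.  Same spec + seed ⇒ bit-identical
cohort; cohorts round-trip through CSV at full precision.

## Intervention effects

The HbA1c difference regression and the severe-hypoglycaemia rate-ratio
regression are evaluated at the *cohort's own* means (so subgroup analyses
automatically receive subgroup-specific effects — the mechanism behind the
divergence of subgroup ICERs).  The sign convention (negative = CSII lowers
HbA1c) is owned in one function.  Full precision is kept internally; the
printed one-decimal figures (−1.2, 10.5, 2.1) arise via
round-half-away-from-zero.  The source text divides 22.4 by the *rounded*
ratio 10.5; this package divides by the full-precision 10.5368 — both round
to 2.1.  Second-order uncertainty propagates only the two printed SEs
(normal draws); the rate-ratio coefficients have no published uncertainty
and are held fixed.

## Disease engine

Annual cycles, no half-cycle correction (consistent with annual DRG costs).
Within a cycle: complication onsets (predecessor states evaluated at cycle
start, so no same-cycle cascades), acute-event Poisson counts, then death —
event fatality before background mortality, so a fatal-event year still
accrues that event's costs (the cost table prices a stroke death within 30
days separately, and that price is used when a stroke is fatal in its
cycle).  The death cycle counts as a lived year.  The treatment effect is an
immediate, sustained HbA1c shift from the first cycle (floored at 4%).

HbA1c adjustment uses the standard log-linear form
`h = h_ref · rr^(HbA1c − ref)`, cycle probability `1 − exp(−h)`.

End-stage renal disease carries a treatment-modality split (default
hemodialysis 0.5 / peritoneal dialysis 0.3 / transplant 0.2) assigned at
onset; prevalent baseline ESRD is split between the dialysis modalities,
prevalent transplant maps to the transplant state.  A healed ulcer ends the
active-ulcer states.  Depression, atrial fibrillation and left-ventricular
hypertrophy are static baseline flags (no dynamics).  Complications are
absorbing: recurrence (second MI, second stroke) is not modelled.

**Common random numbers.** Every cycle consumes a fixed-size uniform block
regardless of who is alive or eligible; fatality verdicts are
time-invariant per (patient, complication) uniforms drawn up front; acute
counts use inverse-CDF Poisson draws.  Consequences, proved by construction
and asserted in tests: a zero-effect contrast makes the two arms identical
bit for bit (ΔQALY exactly 0 per patient); lowering any hazard can only
remove or delay events and can never shorten a life.  Per-patient
*complication-count* dominance additionally requires that death cannot
censor the comparator arm earlier (the survivor paradox), so that property
is tested under a zero-mortality configuration.

Default mortality is a Gompertz table (`1 − exp(−a·e^{b(age−18)})`,
a = 0.0022/0.0018 male/female, b = 0.075), a compact synthetic stand-in for
a national life table; it yields an undiscounted life expectancy of ≈ 30
years at the cohort's mean age under the default hazards.

`time_free_of` reports mean years to first onset; patients who die or reach
the horizon without the complication contribute their observed lifetime,
patients with it at baseline contribute 0, and onset in the first cycle
counts as one year.

## Costing

All amounts are carried in 2016 MXN; USD appears only at reporting time via
the fixed 18.390 rate.  Per cycle and patient: therapy (arm-specific) +
management (monthly medications ×12 for the patient's baseline medication
flags, antidepressants for prevalent depression, and four annual screening
procedures applied to all alive patients — the screening schedule is not
published) + event-year costs for incident states + subsequent-year costs
for active states + per-event acute costs (severe hypoglycaemia 37,000.53;
minor 990).  Categories (treatment, management, cardiovascular, renal,
ulcer/amputation/neuropathy, eye, hypoglycaemia, other acute) always sum to
the total.

The subsequent-year rule is implemented as event/9 rounded to the centavo:
the printed footnote's wording (10% of an acute cost that is 90% of the DRG)
is ambiguous, but all five printed maintenance rows agree with event/9
exactly, so the table wins.  DRG inflation 2014→2016 is a single
application of 0.0865 (the source states one rate, not an annual compound).
"Amputation prosthesis: not covered" is a zero cost (the event itself is
still simulated and costed at its event-year DRG).  Every edema adverse
event is costed at the onset price; the follow-up consultation price is
carried in the table but first-vs-later edema events are not distinguished
(the default edema rate is zero).

Indirect costs are strictly opt-in: disability-leave durations per
event/state-year are configuration with an all-zero default (the source took
them from its unpublished disease model, and inventing clinical numbers and
presenting them as published values would be worse than a neutral default).
When enabled, lost workdays (event days for incident states and acute
events, `<state>_annual` days for prevalent states) are valued at the
sex-specific daily salary inside the working-age window [18, 60), capped at
255 days/year.

## Utilities

Base utility of a cycle = minimum over active conditions of the condition
utility (0.785 if none); one-off disutilities of the cycle's events are then
subtracted; the result is clamped to [0, 1] (the clamp matters only under
adversarial event stacking).  Conditions with post-event state values
(post-MI 0.73, post-stroke 0.621, transplant 0.762, post-amputation 0.505)
contribute those values from the cycle after the event; the event cycle
itself takes the one-off decrement.  Chronic states listed with decrements
(dialysis included) apply every active cycle through the minimum rule — the
published column split is ambiguous for chronic states, and the "lowest
utility value" rule is the literal reading.  The "background retinopathy
wrongly treated" row has no defined trigger and is exposed as a config state
only, never auto-triggered.

## Economics

Cycle-end discounting, cycle 0 undiscounted: weight `(1+r)^(−t)`; separate
rates for costs and effects (base 5%/5%).  ICER = ΔC/ΔE with flags instead
of numbers for dominance (ΔC<0, ΔE>0), dominatedness (ΔC>0, ΔE≤0) and the
undefined south-west quadrant.  NMB = WTP·ΔE − ΔC.  The CEAC repeats: draw
second-order parameters (normal coefficients at printed SEs; gamma
multipliers with mean 1 and CV 0.2 — a conventional choice, configurable —
on therapy/event/acute unit costs), generate a fresh inner cohort
(first-order variability), simulate both arms with common random numbers,
record (ΔC, ΔE); probability at a threshold is the fraction of draws with
positive NMB.  The study-condition sizes are 1000 outer × 1000 inner; the
test suite exercises a 100 × 100 curve and a closed-form Gaussian oracle.
WTP grid: 0–600,000 MXN/QALY in 10,000 steps, with the 2016 Mexican 1- and
3-GDP-per-capita anchors (153,000 and 459,000) marked.

## Scenarios

Nine declarative scenarios mirror the published sensitivity set: base case;
direct + indirect costs; HbA1c benefit forced to −0.6; discount pairs
3% costs + 0% benefits and 7% + 7%; and the four subgroups (HbA1c ≤ 9 / > 9,
duration ≤ 10 / > 10 years).  Subgroups re-derive the effects from their own
baseline means.  Scenario runs are reproducible given seeds; duplicate names
are suffixed.

## Problem sizes and verification

The test suite verifies: printed arithmetic exactly (effects, currency,
insulin chain, the five maintenance rows, the ICER identity from the
published increments at 0.1%); engine behaviour against independent oracles
(two-state chain occupancy vs enumeration at n = 10⁵ within 3 MC SEs;
geometric onset times; Poisson event means; Gompertz-free trivial cases);
coupling properties (exact null-effect equality, hazard monotonicity at
n = 5000, count dominance without mortality at n = 3000); cohort marginal
fidelity at n = 2×10⁴ within 4 SEs; and a monotone 100×100 CEAC.  These
sizes give comfortable statistical power for the asserted tolerances while
keeping the default suite fast.

## Limitations

Independent marginals (no published correlations); absorbing complications
without recurrence; constant post-treatment HbA1c (no drift); synthetic
progression hazards and mortality (all headline lifetime magnitudes depend
on them); screening applied uniformly; minor-hypoglycaemia/ketoacidosis/
edema rates default to zero and arm-independent (not reported by arm).
Passing tests therefore demonstrate the *correctness of the machinery and
the printed arithmetic*, not the clinical accuracy of the default disease
parameters on real cohorts.
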