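# t1dcea

Patient-level cost-effectiveness microsimulation of **continuous subcutaneous
insulin infusion (CSII, "insulin-pump therapy") versus multiple daily
injections (MDI)** in adult type 1 diabetes, from the single-payer
perspective of the Mexican Institute of Social Security (IMSS).

The package is aimed at health economists and modellers who want a fully
open, tested re-implementation of the published IMSS evaluation's pipeline:
a synthetic cohort matching the published baseline characteristics of 192
IMSS T1D adults is pushed through an annual-cycle stochastic complication
model, every state and event is costed in 2016 MXN and utility-weighted, and
the outcomes are summarized as discounted costs, QALYs, ICERs, deterministic
sensitivity scenarios and a cost-effectiveness acceptability curve (CEAC).

## The model

**Intervention effects.** Two effects of CSII relative to MDI, from published
meta-analysis regressions:

```
ΔHbA1c      = −(−3.60 + 0.52 · HbA1c_baseline)          (percentage points)
rate ratio  = 0.5 · r_MDI + 0.016 · age_mean − 1.18     (severe hypos, MDI/CSII)
```

At the IMSS baseline (HbA1c 9.2%, 22.4 severe hypoglycaemic events per 100
patient-years, mean age 32.3 y) these give ΔHbA1c = −1.2 points, a rate
ratio of 10.5 and a CSII rate of 22.4/10.5 ≈ 2.1 events/100 patient-years.

**Disease progression.** Each patient advances in 1-year Markov cycles until
death or a 70-year horizon.  Complication onset hazards scale log-linearly in
HbA1c, `h = h_ref · rr^(HbA1c − HbA1c_ref)`, converted per cycle to
`1 − exp(−h)`; onset respects predecessor states (e.g. proliferative
retinopathy requires background retinopathy), acute events are Poisson
counts, and death combines event fatality with an age/sex background
mortality table.  The hazards themselves are **synthetic, configurable
defaults** — the proprietary disease-model internals behind the published
lifetime totals are not public, and this package does not pretend to them.

**Economics.** Costs follow the published 2016 IMSS unit-cost table
(DRG-based; maintenance years at one ninth of the event-year cost; USD at
18.390 MXN/USD), utilities follow the published catalogue with the
minimum rule across coexisting conditions plus one-off event disutilities,
and both costs and effects are discounted at 5%/year (cycle 0 undiscounted).
ICER = ΔC/ΔE with dominance flags; the CEAC reports
`P(WTP · ΔQALY − ΔC > 0)` over first- and second-order Monte Carlo draws,
with both arms paired by common random numbers.

## Worked example

```python
import t1dcea as t

model = t.CEAModel.from_spec(n=192, seed=1)   # synthetic IMSS-like cohort
print(model.effects)
res = model.fit(seed=2)                        # both arms, common random numbers
print(res)
print(res.summary().round(3).iloc[:6, :3])
```

prints (with the packaged synthetic disease parameters):

```
TreatmentEffects(delta_hba1c=-1.2832..., hypo_rate_ratio=10.5156..., csii_hypo_rate=2.1301...)
<CEAResults 'base_case': n=192, dC=319,812 MXN, dQALY=0.209, ICER=1,530,626 MXN/QALY>
                                           CSII          MDI  difference
outcome
life_expectancy_discounted_years         14.613       14.549       0.064
life_expectancy_undiscounted_years       30.094       29.865       0.229
qalys                                     9.946        9.737       0.209
total_cost_mxn                      1847293.668  1527481.609  319812.059
cost_cardiovascular_mxn              154198.663   160522.420   -6323.758
cost_eye_mxn                          11906.191    13167.215   -1261.024
```

The effects are evaluated at this synthetic cohort's own means (hence
−1.28 rather than the population −1.2); CSII costs more in total (therapy
dominates) but saves complication costs in every clinical category, and the
QALY gain is positive — the structure of the published base case.  The
absolute totals depend on the synthetic progression hazards and are *not*
estimates of the published lifetime figures.

Scenario analyses and the CEAC hang off the same objects:

```python
results = t.run_suite(t.default_suite(), model.cohort)
curve = model.ceac(n_outer=100, n_inner=100, seed=3)
curve.plot(path="ceac.png")
```

A `t1dcea` command-line tool wraps the pipeline
(`t1dcea run --config config.yaml`; subcommands `generate-cohort`,
`simulate`, `scenarios`, `ceac`).

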