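# demcea

A dependence-based Markov cohort cost-effectiveness model for
independence-preserving interventions in people with dementia.

## The problem

Loss of independence in activities of daily living (ADL) is one of the most
consequential aspects of dementia progression: it drives quality of life,
informal-carer burden, and health and social care costs, including
transitions into residential care. Many interventions (sensory support,
assistive technology, occupational therapy) aim to preserve independence,
but few have been costed. This package answers the design question such
interventions face: **how effective does an intervention that keeps people at
a lower level of dependence need to be, at a given per-person cost, to be
cost-effective for the NHS in England?**

## The model

A cohort state-transition (Markov) model with four health states defined by
Bristol Activities of Daily Living Scale (BADLS, 0–60) bands:

* **low dependence** (BADLS 0–14), **moderate** (15–29), **high** (30+), and
  **dead** (absorbing).

Progression is stepwise and irreversible (low → moderate → high, any alive
state → dead) with a 3-month cycle over a 10-year horizon. Writing the
occupancy row vector at cycle *t* as **x**ₜ and the per-cycle transition
matrix as **P**,

```
xₜ = xₜ₋₁ P,      P = | 1−p_LM−p_dL   p_LM        0          p_dL |
                      | 0             1−p_MH−p_dM p_MH       p_dM |
                      | 0             0           1−p_dH     p_dH |
                      | 0             0           0          1    |
```

Per-person discounted costs and QALYs are accumulated over the trace:

```
Cost  = Σₜ δc(t) [ xₜ · c  +  dₜ · c_death ]  (+ intervention cost at entry)
QALYs = Σₜ δq(t) [ xₜ · u ] Δ
```

where `c` is the per-cycle care-cost vector, `c_death` a one-off
admission cost applied to the flow of new deaths `dₜ`, `u` the state utility
vector (EQ-5D-5L indices; dead = 0), `Δ` = 0.25 years, and `δ(t)` the
discount factor (3.5 %/year for costs and QALYs, applied beyond the first
model year).

The hypothetical intervention acts **once, at model entry**: a sample-level
effect *e* moves a fraction *e* of the moderate-dependence occupancy into low
dependence and a fraction *e* of the high-dependence occupancy into moderate
dependence (or only the first move, for the moderate-subgroup scenario).
Comparing the shifted and unshifted cohorts gives incremental costs ΔC and
QALYs ΔQ, an ICER = ΔC/ΔQ, and a verdict against the £20,000/QALY
willingness-to-pay threshold used in England.

The base case enters a cohort aged 80 distributed 60/24/10/6 %
(low/moderate/high/dead), with per-cycle progression probabilities
0.15 (low→moderate) and 0.07 (moderate→high), death probabilities
0.02/0.038/0.05 by state, care costs £1,738/£3,239/£8,510 per cycle,
a £3,519 death admission, utilities 0.788/0.750/0.714, and a £570
intervention.

Beyond the engine the package provides the parameter-derivation stages
(BADLS banding, interval-censored progression estimation from irregular
panel data under constant hazard, survival→cycle-probability conversion,
state-utility estimation), synthetic generators for both source-data shapes,
a deterministic sensitivity suite (effect × horizon × intervention-cost ×
subgroup × perspective), a threshold-effect search, and a calibration
routine that fixes under-documented accounting conventions against published
anchor values.

## Worked example

```sh
$ demcea run --effect 0.075
effect 7.5%  cost/person £104,480  net cost £106  QALYs/person 3.525  net QALYs 0.0125  ICER £8,464
```

A 7.5 % sample-level effect costs £106 extra per person over ten years
(the £570 intervention minus downstream care savings) and gains 0.0125
QALYs, i.e. £8,464 per QALY — cost-effective at the £20,000/QALY threshold.
`demcea suite` renders the full grid; the 10-year base-case block:

```
10-year horizon, intervention £570
  Effect    Cost/person   Net cost  QALYs/person  Net QALYs                     ICER
      0%       £104,374          —         3.513          —                        —
    2.5%       £104,790       £415         3.517     0.0042                  £99,719
      5%       £104,635       £260         3.521     0.0083                  £31,278
    7.5%       £104,480       £106         3.525     0.0125                   £8,464
     10%       £104,325       £-49         3.530     0.0167   Intervention dominates
```

At 10 % the intervention saves money *and* gains QALYs, dominating no
intervention. (QALYs per person are shown without an age-decrement
schedule; a schedule can be supplied in the configuration.)

Other entry points: `demcea estimate` derives progression probabilities and
state utilities from CSV panel/utility data; `demcea synth` generates
synthetic datasets; `demcea calibrate` reports the accounting-convention
search. The same functionality is available as a library
(`demcea.run_model`, `demcea.evaluate_intervention`,
`demcea.run_scenario_suite`, ...).

## Layout

```
src/demcea/parameters.py   domain types, validation, YAML config I/O
src/demcea/engine.py       transition matrix, cohort trace, discounting, accounting
src/demcea/cea.py          effect operator, ICER/dominance, threshold search, suite
src/demcea/derivation.py   BADLS banding, panel/utility estimators, hazard conversion
src/demcea/synthetic.py    trial-cohort and longitudinal-panel generators
src/demcea/calibrate.py    accounting-convention calibration
src/demcea/reporting.py    publication-style tables, run manifests
src/demcea/cli.py          command-line interface
docs/methods.md            model assumptions, conventions, and limitations
```
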