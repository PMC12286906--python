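# Methods

## Model structure and assumptions

The model is a four-state cohort state-transition (Markov) model of people
with dementia, stratified by dependence in activities of daily living rather
than by cognition alone. States are BADLS bands — low (0–14), moderate
(15–29), high (30+) — plus an absorbing dead state. The cycle length is
3 months and the base-case horizon 10 years (40 cycles), which approximates
a lifetime horizon at an entry age of 80. Transition probabilities are
constant over time and identical in both arms; the only difference between
the intervention and control cohorts is the entry distribution (and the
one-off intervention cost). Key structural assumptions:

* **Irreversible stepwise progression.** No backward transitions and no
  within-cycle two-level jumps (low→high). This reflects the observation
  that abilities lost to dementia are generally not regained.
* **Entry-only intervention effect.** The intervention shifts the entry
  distribution and is then withdrawn; subsequent progression is identical in
  both arms. This is a conservative effect model: any durable effect would
  improve cost-effectiveness.
* **State-constant costs and utilities.** Each alive state carries a fixed
  per-cycle health/social-care cost and a fixed utility; deaths are preceded
  by one costed non-elective admission. Members entering dead accrue nothing.
* **No carer outcomes.** Informal-care *costs* can be added per state under
  the societal perspective, but carer quality of life is out of scope.

## Parameters

| Parameter | Default | Units / notes |
|---|---|---|
| Entry distribution (L/M/H/D) | 0.60 / 0.24 / 0.10 / 0.06 | end-of-trial cohort shares |
| p(low→moderate), p(moderate→high) | 0.15, 0.07 | per 3-month cycle |
| p(death) by L/M/H | 0.02 / 0.038 / 0.05 | per cycle, survival-derived |
| Care cost by L/M/H | £1,738 / £3,239 / £8,510 | GBP per cycle, 2019/20 |
| Death admission | £3,519 | one-off at death |
| Utility by L/M/H | 0.788 / 0.750 / 0.714 | EQ-5D-5L index; dead = 0 |
| Intervention cost | £570 | per person, at entry, undiscounted |
| Sample-level effect *e* | 0.025 (base) | relative share of donor state moved |
| Discount rates | 0.035 / 0.035 | per year, costs / QALYs, beyond year 1 |
| Horizon, cycle | 10 y, 0.25 y | 40 cycles |
| Age decrement schedule | empty | age → additive utility decrement |

The sample-level effect is interpreted **relatively**: *e* scales the donor
state's occupancy (moving `e·m` from moderate to low and `e·h` from high to
moderate, both computed from pre-intervention shares). The absolute
interpretation (percentage points of the whole sample) is available behind a
flag but is infeasible for effects above the high-dependence share and
breaks the linear structure of the published results the relative reading
reproduces. Both moves are applied simultaneously from pre-intervention
proportions, which makes the operator order-independent and exactly additive
over donor states.

The age-decrement schedule defaults to zero because no values are packaged;
incremental results are nearly insensitive to any state-independent additive
decrement (asserted numerically in the test suite), but absolute QALYs per
person are not — with zero decrements the model reports 3.513 (10 y) and
2.595 (5 y) discounted QALYs per person.

## Accounting conventions and calibration

Cohort models leave several accounting details implicit. They are explicit
flags here, and `demcea calibrate` fixes them by exhaustive search (48
combinations) against two anchor values of the published base case: the
no-intervention 10-year cost per person (£104,371) and the net cost at a
2.5 % effect (£415). The calibrated defaults:

1. **Discounting: annual step with a per-cycle-equivalent rate.** Factor
   `(1+r)^(−y·Δ)` for a cycle in completed year `y` (year 0 undiscounted),
   i.e. the annual rate converted to its quarterly equivalent
   `(1.035)^{1/4}−1 ≈ 0.864 %` and compounded once per elapsed year. This
   convention was recovered independently from the 10-year and 5-year
   published costs (implied annual rates 0.00864 and 0.00876) and explains
   why alternative discount rates barely move the published results.
   Textbook annual-step (`(1+r)^{−y}`) and per-cycle compounding are
   selectable; both discount far more heavily (≈ £93–96k for the 10-year
   cost).
2. **41 valued occupancy points per 40-cycle run** (entry state plus every
   post-transition state), no half-cycle correction.
3. **Intervention cost charged to the whole entering cohort**, including the
   6 % who enter dead (alive-only charging gives a net cost of £381 rather
   than £415).
4. **Death-event costs on the reference mortality schedule.** Each arm's
   absolute cost includes the admission cost on the flow of new deaths, but
   in comparisons the flow is taken from the no-intervention trace, so
   end-of-life admission costs cancel in increments. The published
   incremental costs imply a care-cost slope of 6,183 GBP per unit effect;
   arm-specific death-cost differencing yields 6,232 while the common
   schedule yields 6,190 and matches the published 5-year slope to 0.01 %.
   Arm-specific differencing remains selectable.

Death events are charged at their completion-cycle discount factor; a death
during the final cycle is valued only when its completion index is among the
valued points.

With these conventions the model reproduces the published 10-year
no-intervention cost to £3 (0.003 %), the 5-year cost to £17 (0.03 %), all
full-effect net QALYs to the 4th decimal, and the base-case and cost-grid
ICERs to well under 1 % — except the published 12.5 %-effect and
moderate-subgroup cells, which are internally inconsistent with the
published full-effect rows themselves (those rows pin the linear net-cost
and net-QALY slopes to four significant figures; the 12.5 % and subgroup
cells deviate from the values those slopes imply by ~1–3 %). The residual
few-pound differences in absolute costs indicate one further unrecoverable
detail of the source implementation; no convention in the searched grid
removes them.

## Derivation stages

* **BADLS banding** partitions 0–60 into the three dependence bands.
* **Progression estimation** uses consecutive within-subject assessment
  pairs from an irregular longitudinal panel. Pairs are stratified by
  interval length (rounded to the month); each stratum's empirical
  proportion moving to a higher band is rescaled to the 3-month cycle under
  a constant hazard, `p₃ = 1 − (1−p_Δ)^{3/Δ}`, and strata are combined by
  exposure (pair-months) weighting. Backward moves count as non-transitions
  (consistent with the irreversible model) and are reported; two-level jumps
  count as events for the start state's stratum and are tallied separately.
  Deaths simply truncate follow-up — mortality is estimated from survival
  data, not from the panel. This is deliberately not a full multi-state
  interval-censored MLE; it reproduces the direct proportion exactly when
  visits are 3 months apart and recovers generating probabilities within
  ±0.02 at 2,000 subjects.
* **Mortality conversion** maps an interval survival probability to a
  per-cycle death probability under constant hazard,
  `p = 1 − S^{Δ/interval}`, with an exact inverse.
* **State utilities** are arithmetic means of individual utility indices by
  state.

## Synthetic data

Two generators emulate the statistical shape of the (non-deposited) source
datasets so the whole pipeline is testable offline:

* **Trial cohort** (default n = 354): states drawn from the 60/24/10/6
  target (multinomial, or exact largest-remainder quotas), BADLS scores
  uniform within the state's band, utilities drawn from a truncated normal
  (sd 0.15 on the EQ-5D-5L index range) whose location is shifted so the
  truncated mean equals the state target — the dispersion is a generator
  choice, not a source value.
* **Longitudinal panel** (default n = 565, 55-month follow-up): each
  subject's latent state evolves on the model's own 3-month clock
  (including state-specific mortality); visits occur at jittered intervals
  (mean 6 ± 2 months, a stand-in — the source's visit-interval distribution
  is unpublished) with 5 % per-visit dropout, and scores are drawn within
  the current band.

What passing recovery tests show: the estimators are consistent for data
generated by the model's own process. What they do not show: robustness to
real-data features absent from the generators — measurement error across
band boundaries, state-dependent visit timing or dropout, or genuine
backward fluctuation in BADLS.

The end-to-end self-consistency test (parameters re-estimated from synthetic
data reproduce base-case net QALYs within 15 %) runs at 4,000 panel and
20,000 trial subjects: at the default (emulated-study) sizes the sampling
noise of the small utility gaps (≈ 0.038) exceeds the band, so the larger
sizes test the pipeline claim at a scale where the band is informative.

## Numerical choices

* Row sums and occupancy conservation enforced to 1e-12; trace invariants
  (dead share non-decreasing, low share non-increasing) checked on
  construction.
* ICERs are computed from unrounded increments; tables round costs to the
  pound and net QALYs to 4 decimals for display only.
* The threshold-effect search exploits no closed form: grid mode returns the
  smallest cost-effective grid multiple (the published answers use a 2.5 %
  grid); continuous mode bisects the cost-effectiveness boundary to 1e-4 on
  *e*, asserting ICER monotonicity over the probed range. With linear net
  outcomes the continuous boundary is `e* = C/(s + λu)`; at £1,000 and
  λ = £20,000/QALY this is ≈ 10.5 %, two grid steps below the grid answer
  of 12.5 %.
* Dominance verdicts use exact sign tests on increments; a zero QALY
  difference yields no ICER and an "undefined" threshold classification.
* The microsimulation oracle replays the same conventions person-by-person;
  agreement with the cohort trace is required within 3 standard errors at
  100,000 individuals.

## Limitations

Time-constant transition probabilities (no age- or duration-dependence
beyond the utility decrement); no tunnel states; no probabilistic
sensitivity analysis (none in the source analysis); informal-care costs have
no packaged values and carer quality of life is not modelled; the EQ-5D-5L
valuation itself is out of scope (the model consumes index values).
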