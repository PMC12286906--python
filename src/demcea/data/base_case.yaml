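# Base-case parameter set for the dependence-based Markov cohort model.
# Cohort entry distribution and utilities derive from end-of-trial data of a
# sensory-support trial in people with mild-moderate dementia; progression
# probabilities from secondary analysis of longitudinal BADLS panel data;
# mortality from published survival by dependence level; costs are GBP,
# cost-year 2019/20.
entry_distribution:
  low: 0.60
  moderate: 0.24
  high: 0.10
  dead: 0.06
transitions:
  low_to_moderate: 0.15
  moderate_to_high: 0.07
  death_low: 0.02
  death_moderate: 0.038
  death_high: 0.05
costs:
  care:
    low: 1738.0
    moderate: 3239.0
    high: 8510.0
  death_event: 3519.0
  # informal_care: {low: ..., moderate: ..., high: ...}  # required for societal runs
utilities:
  low: 0.788
  moderate: 0.750
  high: 0.714
  decrement_schedule: {}   # age -> additive utility decrement; default none
settings:
  horizon_years: 10
  cycle_length_years: 0.25
  discount_rate_costs: 0.035
  discount_rate_qalys: 0.035
  entry_age: 80
  cohort_size: 1000
  first_year_undiscounted: true
  # accounting conventions fixed by `demcea calibrate` against the anchors below
  discounting: cycle_rate_annual_step
  include_terminal_cycle: true
  half_cycle_correction: false
  intervention_cost_alive_only: false
  death_cost_schedule: reference
intervention:
  per_person_cost: 570.0
  effect: 0.025
  subgroup_only: false
  relative: true
scenarios:
  effects: [0.025, 0.05, 0.075, 0.10]
  horizons_years: [10, 5]
  intervention_costs: [100, 250, 570, 1000, 2500]
  wtp: 20000
calibration:
  # published base-case anchor values used to fix the accounting conventions
  anchors:
    cost_per_person_no_intervention_10y: 104371
    net_cost_effect_2p5_10y: 415
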