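# Default lifetime-model parameter file (schema pedometer-cea-markov/1).
#
# SYNTHETIC PLACEHOLDERS: the disease epidemiology (incidence, excess
# mortality), state costs and state utilities below are order-of-magnitude
# placeholder values chosen to be clinically plausible for a UK cohort aged
# 59-88 and to reproduce the qualitative pattern of the published
# evaluation (postal delivery dominant against usual care; nurse delivery
# costlier with a positive ICER; nurse dominated by postal). They are NOT
# the source model's calibrated inputs and absolute outputs should not be
# read as estimates. Trial-derived entries (arm activity relative risks,
# year-1 per-person costs, annuitised year-2 intervention costs) follow the
# published within-trial results.
#
# Units: probabilities are annual; costs GBP at 2013/14 prices; utilities
# on the EQ-5D index scale.
schema: pedometer-cea-markov/1
cohort_size: 100000
start_age: 59
end_age: 88
p_active_control: 0.35
rr_active_by_arm:
  control: 1.0
  postal: 1.40
  nurse: 1.35
rr_disease_given_active:
  chd: 0.73
  stroke: 0.75
  t2d: 0.67
effect_duration_years: 10
incidence_bands:  # annual incidence for inactive people
  - {from_age: 59, chd: 0.006, stroke: 0.004, t2d: 0.008}
  - {from_age: 65, chd: 0.009, stroke: 0.006, t2d: 0.009}
  - {from_age: 75, chd: 0.013, stroke: 0.011, t2d: 0.010}
  - {from_age: 85, chd: 0.018, stroke: 0.018, t2d: 0.010}
mortality_bands:  # abridged life-table-style background mortality
  - {from_age: 59, all_cause: 0.007, cvd_fraction: 0.30}
  - {from_age: 65, all_cause: 0.011, cvd_fraction: 0.30}
  - {from_age: 70, all_cause: 0.018, cvd_fraction: 0.32}
  - {from_age: 75, all_cause: 0.030, cvd_fraction: 0.34}
  - {from_age: 80, all_cause: 0.055, cvd_fraction: 0.36}
  - {from_age: 85, all_cause: 0.100, cvd_fraction: 0.38}
excess_mortality:  # added annual death probability by state
  chd_year1: 0.050
  chd_post: 0.015
  stroke_year1: 0.100
  stroke_post: 0.030
  t2d: 0.008
state_costs:  # annual treatment cost by state, first event year vs subsequent
  chd_first: 4000.0
  chd_subsequent: 400.0
  stroke_first: 9500.0
  stroke_subsequent: 2500.0
  t2d_annual: 1400.0
state_utilities:
  event_free: 0.84
  chd: 0.76
  stroke: 0.63
  t2d: 0.78
one_off_utility_gain: 0.01
year1_cost_per_person:  # trial-based adjusted 12-month total cost per person
  control: 467.0
  postal: 376.0
  nurse: 593.0
intervention_cost_year1:  # intervention components only (set-up + delivery)
  control: 0.0
  postal: 55.0
  nurse: 157.0
intervention_cost_year2:  # annuitised second-year intervention cost
  control: 0.0
  postal: 5.03
  nurse: 4.14
participant_cost_per_person:  # participant-borne costs, year 1 (placeholder)
  control: 23.0
  postal: 60.0
  nurse: 65.0
discount_rate_costs: 0.035
discount_rate_qalys: 0.035
include_year1_hsu_costs: true
include_psych_benefit: true
include_participant_costs: false
half_cycle_correction: false
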