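# Default model configuration: heart-failure virtual ward vs standard inpatient care.
# Unit costs are NHS reference costs held at 2021/22 prices; staff per-minute
# rates follow PSSRU conventions (annual employment cost / annual working hours).

unit_costs:
  home_visit:
    amount: 102.0
    currency_year: "2021/22"
    source: "NHS Cost Collection reference cost per home visit"
  ed_attendance:
    amount: 158.0
    currency_year: "2021/22"
    source: "NHS Cost Collection, emergency department attendance"
  nhs111_contact:
    amount: 11.0
    currency_year: "2021/22"
    source: "published unit cost per NHS 111 contact"
  outpatient_appointment:
    amount: 213.0
    currency_year: "2021/22"
    source: "NHS Cost Collection, outpatient appointment"
  admission:
    amount: 2587.0
    currency_year: "2021/22"
    source: "NHS Cost Collection, non-elective HF admission (all HF/shock HRGs)"
  excess_bed_day:
    amount: 338.0
    currency_year: "2021/22"
    source: "NHS cost collection excess bed day, inflated from 2017/18 via PSSRU index"
  poc_test:
    amount: 49.0
    currency_year: "2021/22"
    source: "assumed per-test point-of-care panel cost"
  home_monitoring:
    amount: 34.0
    currency_year: "2021/22"
    source: "monitoring equipment cost per onboarded admission"
  home_setup:
    amount: 30.0
    currency_year: "2021/22"
    source: "home set-up cost per onboarded admission"

# PSSRU-style inflation index; opaque fiscal-year labels.  The shipped unit
# costs are already at 2021/22 so the default index is the identity year plus
# the 2017/18 base used for excess bed days.
inflation_index:
  "2017/18": 1.000
  "2021/22": 1.094

staff_roles:
  # Annual costs back-derived from the blended per-minute rates actually used
  # (1553 h/yr nurse, 2142 h/yr consultant working-time assumptions).
  band_7_nurse:
    annual_cost: 95043.60      # -> 1.02 GBP/min
    annual_hours: 1553
  consultant:
    annual_cost: 230047.80     # -> 1.79 GBP/min
    annual_hours: 2142

activities:
  home_visit:
    duration_min: 45
    cost_per_minute: 1.02      # blended band 5/7 rate; override wins over staff mix
  virtual_call:
    duration_min: 10
    cost_per_minute: 1.79      # blended band 7/consultant rate

fixed_costs:
  # Aggregate on-going annual cost of running the ward: telehealth hub,
  # equipment/licence, overheads, non-pay, pharmacy, clinical leadership and
  # programme management.  Sub-categories may be itemised; only the total is
  # used by the model.
  vw_platform: 308113.0

setup_costs:
  communications: 4685.0

cohort:
  size: 648                    # annualized cohort
  observed_months: 6

horizon_days: 30
dsa_fraction: 0.15

# Per-patient component cost targets used to calibrate synthetic event rates
# (rate = target cost / unit cost per event).
calibration_targets:
  vw:
    home_visits: 154.0
    calls: 140.0
    poc_testing: 98.0
    home_monitoring: 34.0
    home_setup: 30.0
    ed_visits: 14.0
    readmission: 326.0
    excess_bed_day_savings: 558.0
    nhs111: 1.0
  sc:
    outpatient: 117.0
    ed_visits: 19.0
    initial_admission: 1164.0
    readmission: 556.0
    nhs111: 1.0

synthetic:
  age_mean: 76.0
  age_sd: 11.0
  age_min: 40.0
  age_max: 99.0
  female_probability: 0.47
  diagnoses:
    "I50.0": 0.35
    "I50.1": 0.25
    "I50.9": 0.40
  control_pool_ratio: 2.0
  control_age_shift: 2.0       # mean-age offset of the control pool, gives matching signal
  event_day_max: 45            # event days uniform on 0..max, so tails exercise the horizon
  mean_vw_length_of_stay: 7.0
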