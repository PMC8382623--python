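arm_a:
  arm_name: Zilver PTX
  r12: 0.0896551724137931
  r24: 0.201
  m12_perc: 0.96
  m12_open: 0.04
  m24_perc: 0.971
  m24_open: 0.029
  a12: 0.0
  a24: 0.007
  h12: 1.2480769504889653
  h24: 2.7782999734724534
  stent_price: 0.0
arm_b:
  arm_name: Eluvia
  r12: 0.04529616724738676
  r24: 0.127
  m12_perc: 0.967
  m12_open: 0.033
  m24_perc: 0.957
  m24_open: 0.043
  a12: 0.003484320557491289
  a24: 0.015
  h12: 0.5398058182377473
  h24: 2.235999966668163
  stent_price: 0.0
costs:
  c_percutaneous: 5495.0
  c_open: 16411.0
  c_amputation: 35354.0
  c_bed_day: 2003.0
  c_primary: 5495.0
  c_primary_calibrated: false
population:
  kind: explicit
  cohorts:
  - 5674.0
  - 6060.0
  - 6474.0
  - 6915.0
  - 7386.0
  - 7890.0
  evp_eligibility: 0.8
  des_use_rate: 0.28
n_years: 6
start_year: 2019
second_cycle_mode: cumulative_recount
rounding: half_up_display
state_shares:
  NSW & ACT: 0.33112205747667023
  VIC: 0.2529765588257135
  SA: 0.06898685611029975
  WA: 0.10307185821431224
  NT: 0.00987648209114087
  QLD: 0.19725735785539247
  TAS: 0.02091635931582465
scenario_ranges:
  evp_eligibility:
  - 0.7
  - 0.99
  des_use_rate:
  - 0.1
  - 0.4
  stent_price_multiplier:
  - 0.9
  - 1.1
  bed_day_cost_multiplier:
  - 0.9
  - 1.1
  enforce_bounds: true
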