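# Bench-test controller configuration: a 14-day flock of 20,000 broilers in
# a building with seven blind positions.  Blind and fan maps are the sample
# values of the experimental stage; cycle time is pinned at 5 minutes and
# the emergency blind opening at position 4, matching the recorded test run.
tick: 1
timers:
  ts2_minutes: 5
  ts3: 30
  ts4: 10
flock:
  n_birds: 20000
  age_days: 14
blinds:
  n_positions: 7
  transitional_offset: 1
  emergency_mode: fixed
  emergency_fixed_pos: 4
  map:
    dt1_breakpoints: [0, 5, 15]
    weight_breakpoints: [0.0]
    positions: [[4, 3, 2]]
fans:
  power_map: {1: 15, 2: 25, 3: 40, 4: 50, 5: 65, 6: 80, 7: 100}
  saf_at_full_power: 2.5
dp:
  band: [17.5, 30]
gas:
  NH3_max: 15
  CO2_max: 3000
  CO_max: 4.4
  H2S_eps: 0.1
  warn_fraction: 0.8
heater:
  gain: 20.0
  emergency_floor: 50.0
control:
  dt3_max: 3.0
  saf_tolerance: 0.10
evap:
  rhout_cutoff: 80.0
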