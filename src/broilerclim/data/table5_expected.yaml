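# Expectations encoding the published bench-test narrative, minute by
# minute.  Windows are in seconds.  Blind-position numbers follow the
# sample maps packaged in table5_config.yaml.
#
# minute 0: minimum ventilation M1 — blind 2, ventilation on, heater 100 %
- {window: [0, 30], kind: mode, name: mode, equals: M1}
- {window: [0, 30], kind: actuator, name: blind_pos, equals: 2}
- {window: [0, 30], kind: actuator, name: heater, equals: 100}
- {window: [0, 30], kind: actuator, name: vent_power, ge: 1}
# after 30 s: ventilation off, blind closed, circulation fan on
- {window: [25, 40], kind: actuator, name: vent_power, equals: 0}
- {window: [25, 40], kind: actuator, name: blind_pos, equals: 0}
- {window: [25, 40], kind: actuator, name: circ_fan, equals: true}
# minute 5: new minimum-ventilation cycle, blind 3, heater still full
- {window: [295, 330], kind: actuator, name: blind_pos, equals: 3}
- {window: [295, 330], kind: actuator, name: circ_fan, equals: false}
# minute 10: transitional ventilation — heater off, blind 4, fan continuous
- {window: [595, 630], kind: mode, name: mode, equals: TR}
- {window: [595, 630], kind: actuator, name: heater, equals: 0}
- {window: [595, 630], kind: actuator, name: blind_pos, equals: 4}
# minute 15: back to minimum ventilation M2 — heater PWM 10 %, blind 3
- {window: [895, 930], kind: mode, name: mode, equals: M2}
- {window: [895, 930], kind: actuator, name: heater, equals: 10}
- {window: [895, 930], kind: actuator, name: blind_pos, equals: 3}
- {window: [920, 940], kind: actuator, name: circ_fan, equals: true}
# minute 20: CO2 above 80 % of the limit — blind one step wider (4)
- {window: [1195, 1230], kind: actuator, name: blind_pos, equals: 4}
# minute 25: CO2 above the limit — emergency mode, CO2 alert, heater 50 %
- {window: [1495, 1530], kind: mode, name: emergency, equals: true}
- {window: [1495, 1530], kind: alert, contains: CO2}
- {window: [1495, 1530], kind: actuator, name: heater, equals: 50}
- {window: [1495, 1530], kind: actuator, name: blind_pos, equals: 4}
# minute 28: reading cleared — emergency exit, blind 3, heater back to 10 %
- {window: [1675, 1700], kind: mode, name: emergency, equals: false}
- {window: [1675, 1700], kind: actuator, name: blind_pos, equals: 3}
- {window: [1675, 1700], kind: actuator, name: heater, equals: 10}
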