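# Methods

## The felt-temperature model

The controller's central quantity is the felt temperature

```
tf = ti − tcw + tcRH
```

with both corrections taken from empirical lookup grids rather than a
psychrometric formula; the package deliberately contains no dew-point or
enthalpy computation, because the control logic is defined entirely over
the printed grids.

**Wind chill `tcw(ti, SAF)`.** The adult (7-week) grid covers air
temperatures 18–38 °C (1 °C rows) and air speeds 0.5–2.5 m/s (0.25 m/s
columns). Lookups use bilinear interpolation; inputs are clamped to the
grid hull; `tcw = 0` for `SAF ≤ 0.5 m/s` (neutral air movement) and for
`ti ≥ 38 °C`. The cold-and-fast corner of the grid is undefined — those
are air speeds a controller must never command at those temperatures. A
query that lands there is evaluated at the nearest defined speed of each
bounding temperature row and flagged (`wind_chill_ex`), rather than
raising: during replay a flagged value is more useful than a crash.

**Age scaling.** Grids for younger birds exist in practice but only the
adult one is tabulated here. The default stand-in attenuates the adult
grid by a factor interpolated linearly from 0.3 at day 1 to 1.0 at day 35.
This is an explicit, documented invention: users with real age-specific
grids should supply them (all of `ComfortTables` is replaceable, and
`age_scale_points` is a constructor argument). Conclusions that depend on
the *young-bird* wind-chill magnitude should not rest on the default.

**Humidity correction `tcRH(ti, ΔRH)`.** Active only when indoor RH
exceeds the age band's upper value by more than 1 point. ΔRH is binned
exactly as printed — half-open 5-point bins, the last bin open-ended above
25 — and the correction is interpolated linearly in `ti` between the 1 °C
rows (18–35 °C, clamped). The threshold is the setpoint band's `RHmax`;
the alternative reading (a separate "optimal RH") is noted as an open
interpretation, and the band value is used because it is the only RH
reference the schedule provides.

**Setpoints.** The age schedule stores `(tmax, tmin)` per band with
`topt = (tmin + tmax)/2` (this midpoint reproduces the 14-day flock's
25.5 °C exactly). The final band is open-ended; it prints a single
temperature, so `tmin = tmax = topt = 18 °C` there by default.

**Inverse problem.** `optimal_airspeed` scans a 0.05 m/s grid from
0.5 m/s up to the age-dependent maximum `Zmax` (default: 0.8 m/s through
day 7, linearly to 2.5 m/s at day 49) and returns the smallest speed with
`tf ≤ topt`, or `(Zmax, saturated)` when even maximum wind cannot reach
the optimum. 0.05 m/s is finer than any fan-bank actuation step yet
coarse enough that the scan is exhaustively testable.

## The controller

A discrete-tick state machine (default tick 1 s; all timers are integer
ticks; sensor frames are sampled-and-held between updates). Each cycle
starts by re-measuring `ti` and classifying:

| condition | branch |
|---|---|
| `ti < tmin` | M1 (minimum ventilation, heater 100 %) |
| `tmin ≤ ti ≤ topt` | M2 (minimum ventilation, proportional heater) |
| `topt < ti ≤ tmax` | Tr (transitional) |
| `ti > tmax` | Tu (tunnel family) |

The M1/M2 boundary is not stated anywhere explicitly; `tmin` is the choice
that reproduces the recorded heater behaviour (100 % at `ti = 22 °C`,
10 % PWM at `ti = 25 °C` for the 14-day band).

**Minimum ventilation (M1/M2).** Cycle length `ts2` defaults to an age
schedule — 7 min during brooding (≤ 14 days, to save heating energy),
5 min after — and is overridable (`timers.ts2_minutes`); the packaged
bench fixture pins 5 min because that is what the recorded run used.
Within a cycle: gas check → tunnel/evaporative hardware off → heater set
(M2 law: `clamp(gain · Δt2, 0, 100)` with the default gain 20 %/°C chosen
so Δt2 = 0.5 °C gives 10 %) → blinds to position X from the blind map →
ventilation at the power matched to the blind position → after the ts4
settling time (10 s) the differential pressure is regulated → fans stop at
`ts3` (30 s; bounds 10–60 s) → circulation fans run iff the under-roof
stratification `Δt3 = tih − ti` exceeds 3 °C → at cycle end the RH check
nudges the next cycle's `ts3` by ±5 s (low RH → shorter ventilation) and
emits one-time messages.

**Blind map.** Position X is a 2-D lookup on `Δt1 = ti − to` and total
live weight, monotone nonincreasing in Δt1, clamping to fully open below
the lowest breakpoint. Transitional mode opens one configurable step wider
than the map (`blinds.transitional_offset`, default 1): the recorded trace
cannot be produced by a single Δt1-monotone map (position 3 at Δt1 = 10 °C
in minimum ventilation but 4 at Δt1 = 11 °C in transitional), and a wider
transitional opening matches the regime's larger air volume. Live weight
uses a Gompertz growth curve fitted to ~45 g at day 1, ~0.45 kg at day 14
and 2.0 kg at day 35 (overridable per flock).

**Gas safety.** Limits: NH₃ 15 ppm, CO₂ 3000 ppm, CO 4.4 ppm; H₂S may not
be present at all, so any reading above a 0.1 ppm detection floor is an
exceedance. At 80 % of a limit (pre-warning) the blinds widen one step
with no message. At the limit the controller — in M1, M2 or Tr — enters
emergency: cycle shortened to 3 min, ventilation running the whole cycle,
heater floored at 50 % in M2, blinds opened per `blinds.emergency_mode`
(`max` per the flowcharts by default; `x_plus_2` in M1 always, to avoid
chilling chicks; the bench fixture uses `fixed: 4` to match the recorded
run). Alerts are one-time per condition episode: a latch clears only after
the condition has been absent for one full cycle. The alert text reports
both the limit and the measured value (the recorded message quoted the
limit). In tunnel mode a gas exceedance alerts but is not an emergency —
tunnel air volumes are so large that an exceedance there indicates
hardware failure, not a ventilation shortfall.

**Tunnel family.** `tf` is evaluated at `Zmax`. Below `tmin` the wind is
throttled to `Zopt`; inside the band it runs at `Zmax`; above `tmax` the
evaporative pads engage provided outdoor RH is below 80 % and the pads are
not in their drying hold. After a wet cycle the controller re-evaluates
`tf` and either starts the shutdown (below `tmin`) or enters the closed
monitoring cycle `TU_EVAP_HOLD` — the only state that does not re-measure
and re-classify on `ti`; it watches only `tf`, the air speed, the gases
and outdoor RH, and can be left exclusively through `EVAP_SHUTDOWN`.
Shutdown throttles to `Zopt`, switches the pads off and holds for the full
drying time (default 30 min — the timer is named in the source material
but unvalued) before the pads may ever re-enable; this is the anti-mold
interlock and it is property-tested. Measured air speed deviating more
than 10 % from target trims fan power multiplicatively, with the per-step
factor bounded in [0.5, 1.5] and a 5 % power floor so that a wild sensor
reading can never stall the airflow under wet pads.

**Building preparation.** Before housing, a purge ventilation flush
(default 10 min) followed by a thermostat holding `ti` in the configured
`[tpmin, tpmax]`: heater below, duty-cycle ventilation above, idle inside.
The exact preparation sequence is the least-specified part of the source
flowcharts; purge-then-thermostat is this package's reading.

**Determinism.** The controller is a pure function of (state, frame,
config, tables): identical traces and configs give byte-identical event
logs, which the replay tests assert.

## The plant simulator

A deliberately coarse test double, not a building-physics model. Single
thermal node: flock heat (11.6 kJ/h/kg of live weight — the 20,000 × 2 kg
reference flock releases 129 kW, printed as 130) plus heater, minus
envelope UA losses, ventilation air exchange, and evaporative cooling of
the tunnel stream (effectiveness 0.75 toward the Stull wet-bulb
approximation; the pad stream is humidified along the same line). Moisture
is a humidity-ratio balance (reference flock evaporates 4000 L/day →
0.1 L/day per kg); CO₂ a dilution balance (0.0008 m³/h/kg, ambient
420 ppm); the under-roof temperature is the zone temperature plus a
stratification offset relaxing toward 4 °C in still air and 0.5 °C when
stirred. Differential pressure follows an orifice law
`Δp = k (Q/A)²` with `k = 1.67 Pa·s²/m²` (≈ ρ/2Cd² for Cd ≈ 0.6),
calibrated together with the default fan-power map so blind position 3
lands mid-band (~23 Pa); a blocked building caps at `dp_max` with a fault
flag.

Integration is explicit Euler at the controller tick, guarded by a
stability check at simulation start (`tick` must be well under the
fastest thermal time constant with all fans at maximum). The zone heat
capacity is the air mass times a thermal-mass factor (default 5) standing
in for litter and structure; without it a single transitional cycle at
Δt1 ≈ 20 °C would swing the zone by over 6 °C, which no real house does.

**What the simulator does not capture:** spatial gradients beyond the one
stratification offset, litter chemistry (NH₃ generation is not modelled —
gas logic is exercised through trace injection instead), bird behaviour,
solar load, and sensor noise. Closed-loop tests passing therefore show
that the *control logic* is coherent under a plausible plant, not that the
plant parameters describe any particular building.

## Scenarios, fixtures, tests

`make_scenario` produces deterministic traces: `table5` is the published
bench-test input sequence (seven input states over 33 minutes,
sample-and-hold at the 30 s transmission interval; channels the bench did
not exercise are filled with in-band constants — RH 72 %, RHout 50 %,
SAF 0.25 m/s, other gases zero). `cold_day`, `hot_day` and `gas_spike`
are seeded synthetic weather days (sinusoidal diurnal cycle plus small
noise) used for closed-loop and emergency tests.

Problem sizes used by the test suite and the acceptance script: grid
checks cover every defined cell (168 wind-chill + 108 humidity cells);
the interpolation oracle uses 1,000 random points against an independent
`scipy` regular-grid interpolator at 1e−9 °C; plant steady-state checks
use small test buildings (V ≈ 10 m³) so equilibria are reached within
simulated minutes; closed-loop runs are three simulated hours with a
two-hour burn-in. The full suite runs in a few seconds on one CPU.

## Known limitations

* The age scaling of wind chill and the `Zmax` schedule between day 7 and
  adulthood are documented inventions inside stated ranges.
* The blind map, fan-power map and all building parameters are sample
  values for a synthetic seven-position building; every deployment must
  calibrate its own (the configuration schema exists for exactly this).
* Field-scale outcomes (mortality, productivity, heating-energy savings)
  are outside what a desk-scale simulation can establish and are not
  claimed by any test.
* MQTT transport, hardware drivers and dashboard integration are out of
  scope; the CSV trace is the transport-neutral equivalent of a live feed.
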