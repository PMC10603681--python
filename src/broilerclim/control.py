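"""The autonomous ventilation controller.

A discrete-time finite-state machine that re-measures the house each cycle,
classifies the indoor temperature against the flock's age-dependent comfort
band and runs one of four regimes:

* **M1 / M2 — minimum ventilation** (cold weather): short fan pulses
  (ts3 ≈ 30 s) through inlet blinds every 5–7 min with heating on; M1 is
  the sub-band regime (ti below tmin, heater pinned at 100 %), M2 the
  in-band regime (proportional heating up to topt).
* **Tr — transitional ventilation**: continuous blind-fed ventilation to
  dump the flock's surplus heat, no heating, no circulation fans.
* **Tu — tunnel ventilation**: end-to-end airflow producing a cooling wind
  over the birds, regulated on *felt* temperature rather than air
  temperature, with optional evaporative-pad cooling and closed monitoring
  cycles while the pads are wet.

Gas safety wraps every cycle: at 80 % of a limit the blinds widen one step
(pre-warning); at the limit the controller enters emergency mode — 3-minute
cycles, wide-open blinds, ventilation running the whole cycle — until the
reading clears.  Alerts are one-time per condition episode.

The controller is purely functional over (state, sensor frame, config,
tables): identical traces yield byte-identical event logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

from .comfort import (
    ComfortTables,
    Setpoints,
    felt_temperature,
    max_airspeed,
    optimal_airspeed,
    setpoints,
)
from .config import ConfigError, ControllerConfig, DpConfig, GasLimits, gompertz_weight

__all__ = [
    "Mode",
    "GasLevel",
    "SensorFrame",
    "ActuatorState",
    "ControllerState",
    "Event",
    "classify_mode",
    "gas_status",
    "blind_position",
    "heater_power",
    "regulate_dp",
    "controller_step",
    "run_min_vent_cycle",
    "run_transitional_cycle",
    "run_tunnel_cycle",
    "run_prep",
    "run_cycle",
    "new_state",
    "held_frames",
]


class Mode(str, Enum):
    PREP = "PREP"
    M1 = "M1"
    M2 = "M2"
    TR = "TR"
    TU = "TU"
    TU_EVAP = "TU_EVAP"
    TU_EVAP_HOLD = "TU_EVAP_HOLD"
    EVAP_SHUTDOWN = "EVAP_SHUTDOWN"


class GasLevel(str, Enum):
    NORMAL = "NORMAL"
    WARN = "WARN"
    EXCEED = "EXCEED"


#: regimes in which the gas-exceedance emergency applies (tunnel air volumes
#: are large enough that exceedances there signal hardware faults instead).
EMERGENCY_MODES = (Mode.M1, Mode.M2, Mode.TR)


@dataclass(frozen=True)
class SensorFrame:
    """One timestamped reading of every monitored variable."""

    t: int                 # seconds since start
    ti: float              # indoor temperature at broiler level, °C
    to: float              # outdoor temperature, °C
    tih: float             # indoor temperature below the roof, °C
    RH: float              # indoor relative humidity, %
    RHout: float           # outdoor relative humidity, %
    dp: float              # differential pressure, Pa
    SAF: float             # speed of air flow at bird level, m/s
    NH3: float = 0.0       # ppm
    CO2: float = 0.0       # ppm
    CO: float = 0.0        # ppm
    H2S: float = 0.0       # ppm

    def __post_init__(self) -> None:
        if min(self.NH3, self.CO2, self.CO, self.H2S) < 0:
            raise ValueError("gas readings must be >= 0")
        if not (0 <= self.RH <= 100 and 0 <= self.RHout <= 100):
            raise ValueError("RH readings must be in [0, 100]")


@dataclass
class ActuatorState:
    heater: float = 0.0          # %
    blind_pos: int = 0           # 0 = closed
    vent_power: float = 0.0      # %
    circ_fan: bool = False
    tunnel_inlets: bool = False
    tunnel_power: float = 0.0    # %
    evap_pads: bool = False


@dataclass(frozen=True)
class Event:
    """One log record: an actuator change, a mode change or an alert."""

    t: int
    kind: str   # "actuator" | "mode" | "alert"
    name: str
    value: object

    def to_json(self) -> str:
        return json.dumps(
            {"t": self.t, "kind": self.kind, "name": self.name, "value": self.value},
            separators=(",", ":"), sort_keys=True)


@dataclass
class ControllerState:
    mode: Mode = Mode.M2
    emergency: bool = False
    t: int = 0
    last_frame_t: int = -1
    started: bool = False
    cycle_done: bool = False
    cycle_start: int = 0
    cycle_len: int = 300
    cycle_index: int = -1
    ts3: int = 30
    ts3_next: int = 30
    actuators: ActuatorState = field(default_factory=ActuatorState)
    latches: set[str] = field(default_factory=set)
    conds_this_cycle: set[str] = field(default_factory=set)
    conds_prev_cycle: set[str] = field(default_factory=set)
    dp_steps: int = 0
    saf_steps: int = 0
    saf_target: float = 0.0
    drying_until: int = -1       # pads must stay off before this time (anti-mold)
    prep_purged: bool = False
    prep_venting: bool = False


def new_state(cfg: ControllerConfig, mode: Mode = Mode.M2) -> ControllerState:
    return ControllerState(mode=mode, ts3=cfg.timers.ts3, ts3_next=cfg.timers.ts3)


# ---------------------------------------------------------------------------
# elementary decision rules


def classify_mode(ti: float, sp: Setpoints) -> Mode:
    """Partition the temperature axis into the four ventilation branches."""
    if ti < sp.tmin:
        return Mode.M1
    if ti <= sp.topt:
        return Mode.M2
    if ti <= sp.tmax:
        return Mode.TR
    return Mode.TU


def gas_status(frame: SensorFrame, limits: GasLimits) -> tuple[GasLevel, list[str]]:
    """Classify air quality: EXCEED at a limit, WARN at the pre-warning
    fraction of it, NORMAL otherwise; H2S exceeds whenever detectable."""
    checks = [("NH3", frame.NH3, limits.NH3_max),
              ("CO2", frame.CO2, limits.CO2_max),
              ("CO", frame.CO, limits.CO_max)]
    exceed = [g for g, v, lim in checks if v >= lim]
    if frame.H2S > limits.H2S_eps:
        exceed.append("H2S")
    if exceed:
        return GasLevel.EXCEED, exceed
    warn = [g for g, v, lim in checks if v >= limits.warn_fraction * lim]
    if warn:
        return GasLevel.WARN, warn
    return GasLevel.NORMAL, []


def blind_position(dt1: float, ts1: float, n_birds: int,
                   cfg: ControllerConfig) -> int:
    """Fresh-air blind position X from the indoor/outdoor difference
    Δt1 = ti - to and the flock's total live weight (age x headcount).

    Δt1 below every breakpoint clamps to the fully-open position."""
    m = cfg.blinds.map
    if not m.positions:
        raise ConfigError("blind map is empty")
    weight = cfg.flock.weight_kg if cfg.flock.weight_kg is not None \
        else gompertz_weight(ts1)
    total = n_birds * weight
    wi = 0
    for k, edge in enumerate(m.weight_breakpoints):
        if total >= edge:
            wi = k
    di = -1
    for k, edge in enumerate(m.dt1_breakpoints):
        if dt1 >= edge:
            di = k
    if di < 0:
        return cfg.blinds.n_positions
    pos = m.positions[wi][di]
    return max(1, min(cfg.blinds.n_positions, pos))


def heater_power(dt2: float, mode: Mode, emergency: bool,
                 cfg: ControllerConfig) -> float:
    """Heating power (%) from the optimum shortfall Δt2 = topt - ti.

    M1 always heats at full power; M2 heats proportionally, with a floor
    (default 50 %) in emergency mode when ventilation runs the whole cycle.
    """
    if mode == Mode.M1:
        return 100.0
    p = max(0.0, min(100.0, cfg.heater.gain * dt2))
    if emergency:
        p = max(p, cfg.heater.emergency_floor)
    return round(p, 1)


def regulate_dp(dp: float, vent_power: float, dpcfg: DpConfig,
                steps: int = 0) -> tuple[float, bool]:
    """One proportional correction of fan power toward the Δp band.

    Returns the adjusted power and a fault flag that raises once ``steps``
    corrections have already been spent without reaching the band.
    """
    lo, hi = dpcfg.band
    if lo <= dp <= hi:
        return vent_power, False
    err = (lo + hi) / 2.0 - dp
    power = max(0.0, min(100.0, vent_power + dpcfg.gain * err))
    return round(power, 1), steps + 1 >= dpcfg.max_iter


# ---------------------------------------------------------------------------
# event plumbing


def _set(state: ControllerState, events: list[Event], name: str, value) -> None:
    if getattr(state.actuators, name) != value:
        setattr(state.actuators, name, value)
        events.append(Event(state.t, "actuator", name, value))


def _alert_once(state: ControllerState, events: list[Event], key: str,
                message: str) -> None:
    """One-time message per condition episode: re-emitted only after the
    condition has been absent for a full cycle."""
    state.conds_this_cycle.add(key)
    if key not in state.latches:
        state.latches.add(key)
        events.append(Event(state.t, "alert", key, message))


def _set_mode(state: ControllerState, events: list[Event], mode: Mode) -> None:
    if state.mode != mode:
        state.mode = mode
        events.append(Event(state.t, "mode", "mode", mode.value))


# ---------------------------------------------------------------------------
# cycle phases


def _gas_alerts(state: ControllerState, events: list[Event], frame: SensorFrame,
                level: GasLevel, offending: Sequence[str],
                cfg: ControllerConfig) -> None:
    if level != GasLevel.EXCEED:
        return
    limits = {"NH3": cfg.gas.NH3_max, "CO2": cfg.gas.CO2_max,
              "CO": cfg.gas.CO_max, "H2S": cfg.gas.H2S_eps}
    for g in offending:
        measured = getattr(frame, g)
        _alert_once(state, events, f"gas_exceed_{g}",
                    f"Warning: High {g} level—{limits[g]:g} ppm "
                    f"(measured {measured:g} ppm)")


def _all_heating_cooling_off(state: ControllerState, events: list[Event]) -> None:
    _set(state, events, "tunnel_power", 0.0)
    _set(state, events, "tunnel_inlets", False)
    _set(state, events, "evap_pads", False)


def _begin_min_vent(state: ControllerState, events: list[Event],
                    frame: SensorFrame, sp: Setpoints, level: GasLevel,
                    cfg: ControllerConfig) -> None:
    ts2 = cfg.timers.ts2_emergency_minutes if state.emergency \
        else cfg.timers.ts2_for_age(cfg.flock.age_days)
    state.cycle_len = int(round(ts2 * 60))
    state.ts3 = state.ts3_next
    _all_heating_cooling_off(state, events)
    _set(state, events, "circ_fan", False)
    _set(state, events, "heater",
         heater_power(sp.topt - frame.ti, state.mode, state.emergency, cfg))
    x = blind_position(frame.ti - frame.to, cfg.flock.age_days,
                       cfg.flock.n_birds, cfg)
    n = cfg.blinds.n_positions
    if state.emergency:
        if state.mode == Mode.M1:
            pos = min(x + 2, n)   # never fully open with cold chicks inside
        elif cfg.blinds.emergency_mode == "max":
            pos = n
        elif cfg.blinds.emergency_mode == "x_plus_2":
            pos = min(x + 2, n)
        else:
            pos = min(cfg.blinds.emergency_fixed_pos, n)
    elif level == GasLevel.WARN:
        pos = min(x + 1, n)
    else:
        pos = x
    _set(state, events, "blind_pos", pos)
    _set(state, events, "vent_power", cfg.fans.power_for(pos))


def _begin_transitional(state: ControllerState, events: list[Event],
                        frame: SensorFrame, sp: Setpoints, level: GasLevel,
                        cfg: ControllerConfig) -> None:
    ts2 = cfg.timers.ts2_emergency_minutes if state.emergency \
        else cfg.timers.ts2_transitional_minutes
    state.cycle_len = int(round(ts2 * 60))
    _all_heating_cooling_off(state, events)
    _set(state, events, "circ_fan", False)
    _set(state, events, "heater", 0.0)
    x = blind_position(frame.ti - frame.to, cfg.flock.age_days,
                       cfg.flock.n_birds, cfg)
    n = cfg.blinds.n_positions
    if state.emergency:
        pos = n
    else:
        pos = min(x + cfg.blinds.transitional_offset, n)
        if level == GasLevel.WARN:
            pos = min(pos + 1, n)
    _set(state, events, "blind_pos", pos)
    _set(state, events, "vent_power", cfg.fans.power_for(pos))


def _set_tunnel(state: ControllerState, events: list[Event], target: float,
                pads: bool, cfg: ControllerConfig) -> None:
    _set(state, events, "heater", 0.0)
    _set(state, events, "circ_fan", False)
    _set(state, events, "vent_power", 0.0)
    _set(state, events, "blind_pos", 0)
    _set(state, events, "tunnel_inlets", True)
    _set(state, events, "tunnel_power", round(cfg.fans.power_for_speed(target), 1))
    _set(state, events, "evap_pads", pads)
    state.saf_target = target


def _begin_tunnel(state: ControllerState, events: list[Event],
                  frame: SensorFrame, sp: Setpoints,
                  cfg: ControllerConfig, tables: ComfortTables) -> None:
    """Fresh tunnel cycle entered from the ti classification."""
    age = cfg.flock.age_days
    zmax = max_airspeed(age, tables)
    tf = felt_temperature(frame.ti, zmax, frame.RH, age, tables)
    state.cycle_len = int(round(cfg.timers.ts2_tunnel_minutes * 60))
    if tf < sp.tmin:
        zopt, _ = optimal_airspeed(frame.ti, frame.RH, age, tables)
        _set_mode(state, events, Mode.TU)
        _set_tunnel(state, events, zopt, False, cfg)
    elif tf <= sp.tmax:
        _set_mode(state, events, Mode.TU)
        _set_tunnel(state, events, zmax, False, cfg)
    else:
        if frame.RHout < cfg.evap.rhout_cutoff and state.t >= state.drying_until:
            _set_mode(state, events, Mode.TU_EVAP)
            _set_tunnel(state, events, zmax, True, cfg)
        else:
            # too humid outside (or pads still drying): run flat out instead
            _set_mode(state, events, Mode.TU)
            _set_tunnel(state, events, zmax, False, cfg)


def _begin_evap_shutdown(state: ControllerState, events: list[Event],
                         frame: SensorFrame, cfg: ControllerConfig,
                         tables: ComfortTables) -> None:
    """Pads off, wind back to Zopt, and a full drying hold before the pads
    may ever re-enable (mold prevention)."""
    age = cfg.flock.age_days
    zopt, _ = optimal_airspeed(frame.ti, frame.RH, age, tables)
    _set_mode(state, events, Mode.EVAP_SHUTDOWN)
    state.cycle_len = int(round(cfg.timers.ts_drying_minutes * 60))
    state.drying_until = state.t + state.cycle_len
    _set_tunnel(state, events, zopt, False, cfg)


def _begin_hold(state: ControllerState, events: list[Event],
                frame: SensorFrame, sp: Setpoints, cfg: ControllerConfig,
                tables: ComfortTables) -> None:
    """Closed evaporative-cooling cycle: monitors tf, SAF, gases and RHout
    only — deliberately never re-classifies on ti."""
    age = cfg.flock.age_days
    if frame.RHout >= cfg.evap.rhout_cutoff:
        _begin_evap_shutdown(state, events, frame, cfg, tables)
        return
    zmax = max_airspeed(age, tables)
    tf = felt_temperature(frame.ti, zmax, frame.RH, age, tables)
    if tf < sp.tmin:
        _begin_evap_shutdown(state, events, frame, cfg, tables)
        return
    state.cycle_len = int(round(cfg.timers.ts2_tunnel_minutes * 60))
    if tf <= sp.tmax:
        zopt, _ = optimal_airspeed(frame.ti, frame.RH, age, tables)
        _set_tunnel(state, events, zopt, True, cfg)
    else:
        _set_tunnel(state, events, zmax, True, cfg)


def _begin_prep(state: ControllerState, events: list[Event],
                frame: SensorFrame, cfg: ControllerConfig) -> None:
    tpmin, tpmax = cfg.prep.require_band()
    _all_heating_cooling_off(state, events)
    _set(state, events, "circ_fan", False)
    if not state.prep_purged:
        # initial purge: flush disinfection smells before any temperature hold
        state.cycle_len = int(round(cfg.prep.purge_minutes * 60))
        state.prep_purged = True
        state.prep_venting = True
        pos = cfg.blinds.n_positions
        _set(state, events, "heater", 0.0)
        _set(state, events, "blind_pos", pos)
        _set(state, events, "vent_power", cfg.fans.power_for(pos))
        return
    state.cycle_len = int(round(cfg.timers.ts2_grown_minutes * 60))
    state.prep_venting = False
    if frame.ti < tpmin:
        _set(state, events, "heater", 100.0)
        _set(state, events, "blind_pos", 0)
        _set(state, events, "vent_power", 0.0)
    elif frame.ti > tpmax:
        state.prep_venting = True
        state.ts3 = cfg.timers.ts3
        x = blind_position(frame.ti - frame.to, 1, 1, cfg)
        _set(state, events, "heater", 0.0)
        _set(state, events, "blind_pos", x)
        _set(state, events, "vent_power", cfg.fans.power_for(x))
    else:
        _set(state, events, "heater", 0.0)
        _set(state, events, "blind_pos", 0)
        _set(state, events, "vent_power", 0.0)


def _begin_cycle(state: ControllerState, events: list[Event],
                 frame: SensorFrame, cfg: ControllerConfig,
                 tables: ComfortTables) -> None:
    state.cycle_start = state.t
    state.cycle_index += 1
    state.dp_steps = 0
    state.saf_steps = 0
    # close condition episodes that stayed silent for the whole previous cycle
    state.latches &= state.conds_this_cycle
    state.conds_prev_cycle = state.conds_this_cycle
    state.conds_this_cycle = set()

    age = cfg.flock.age_days
    sp = setpoints(age, tables)
    level, offending = gas_status(frame, cfg.gas)

    if state.mode == Mode.PREP:
        _begin_prep(state, events, frame, cfg)
        return

    if state.mode == Mode.TU_EVAP_HOLD:
        _gas_alerts(state, events, frame, level, offending, cfg)
        _begin_hold(state, events, frame, sp, cfg, tables)
        return

    if state.mode == Mode.TU_EVAP:
        # the first wet cycle just ended: decide shutdown vs closed cycle
        _gas_alerts(state, events, frame, level, offending, cfg)
        zmax = max_airspeed(age, tables)
        tf = felt_temperature(frame.ti, zmax, frame.RH, age, tables)
        if tf < sp.tmin:
            _begin_evap_shutdown(state, events, frame, cfg, tables)
        else:
            _set_mode(state, events, Mode.TU_EVAP_HOLD)
            _begin_hold(state, events, frame, sp, cfg, tables)
        return

    # every other state re-measures ti and classifies afresh
    branch = classify_mode(frame.ti, sp)
    was_emergency = state.emergency
    state.emergency = level == GasLevel.EXCEED and branch in EMERGENCY_MODES
    prev_mode = state.mode
    _set_mode(state, events, branch)
    if state.emergency != was_emergency:
        events.append(Event(state.t, "mode", "emergency", state.emergency))
    if branch == Mode.M1 and prev_mode != Mode.M1:
        _alert_once(state, events, "low_temperature",
                    f"Entering minimum ventilation M1: ti {frame.ti:g} °C "
                    f"below tmin {sp.tmin:g} °C")
    if branch in EMERGENCY_MODES:
        _gas_alerts(state, events, frame, level, offending, cfg)

    if branch in (Mode.M1, Mode.M2):
        _begin_min_vent(state, events, frame, sp, level, cfg)
    elif branch == Mode.TR:
        _begin_transitional(state, events, frame, sp, level, cfg)
    else:
        _gas_alerts(state, events, frame, level, offending, cfg)
        _begin_tunnel(state, events, frame, sp, cfg, tables)


def _dp_regulation(state: ControllerState, events: list[Event],
                   frame: SensorFrame, cfg: ControllerConfig) -> None:
    lo, hi = cfg.dp.band
    if lo <= frame.dp <= hi:
        return
    if state.dp_steps >= cfg.dp.max_iter:
        _alert_once(state, events, "dp_fault",
                    f"Differential pressure {frame.dp:g} Pa still outside "
                    f"[{lo:g}, {hi:g}] Pa after {cfg.dp.max_iter} corrections")
        return
    power, fault = regulate_dp(frame.dp, state.actuators.vent_power,
                               cfg.dp, state.dp_steps)
    state.dp_steps += 1
    _set(state, events, "vent_power", power)
    if fault:
        _alert_once(state, events, "dp_fault",
                    f"Differential pressure {frame.dp:g} Pa still outside "
                    f"[{lo:g}, {hi:g}] Pa after {cfg.dp.max_iter} corrections")


def _saf_regulation(state: ControllerState, events: list[Event],
                    frame: SensorFrame, cfg: ControllerConfig) -> None:
    target = state.saf_target
    if target <= 0:
        return
    if abs(frame.SAF - target) <= cfg.control.saf_tolerance * target:
        return
    if state.saf_steps >= cfg.dp.max_iter:
        _alert_once(state, events, "saf_fault",
                    f"Air speed {frame.SAF:g} m/s stuck away from target "
                    f"{target:g} m/s; check inlets and pads for fouling")
        return
    state.saf_steps += 1
    factor = 1.0 + cfg.control.saf_gain * (target - frame.SAF) / target
    factor = max(0.5, min(1.5, factor))  # bounded step: a wild reading must
    p = state.actuators.tunnel_power * factor       # not kill the airflow
    _set(state, events, "tunnel_power", round(max(5.0, min(100.0, p)), 1))


def _mid_cycle(state: ControllerState, events: list[Event],
               frame: SensorFrame, cfg: ControllerConfig,
               tables: ComfortTables, elapsed: int) -> None:
    mode = state.mode
    if mode in (Mode.M1, Mode.M2):
        if not state.emergency and elapsed == state.ts3:
            _set(state, events, "vent_power", 0.0)
            _set(state, events, "blind_pos", 0)
            if frame.tih - frame.ti > cfg.control.dt3_max:
                _set(state, events, "circ_fan", True)
        if state.actuators.vent_power > 0 and elapsed >= cfg.timers.ts4:
            _dp_regulation(state, events, frame, cfg)
    elif mode == Mode.TR:
        if elapsed >= cfg.timers.ts4:
            _dp_regulation(state, events, frame, cfg)
    elif mode in (Mode.TU, Mode.TU_EVAP, Mode.TU_EVAP_HOLD, Mode.EVAP_SHUTDOWN):
        if elapsed >= cfg.timers.ts4:
            _saf_regulation(state, events, frame, cfg)
    elif mode == Mode.PREP:
        if state.prep_venting and state.prep_purged \
                and elapsed == state.ts3 and state.cycle_len > state.ts3 * 2:
            _set(state, events, "vent_power", 0.0)
            _set(state, events, "blind_pos", 0)


def _rh_check(state: ControllerState, events: list[Event], frame: SensorFrame,
              sp: Setpoints, cfg: ControllerConfig, adjust: bool) -> None:
    step = cfg.timers.ts3_step
    if frame.RH < sp.rh_min:
        _alert_once(state, events, "rh_low",
                    f"RH {frame.RH:g}% below minimum {sp.rh_min:g}%")
        if adjust:
            state.ts3_next = max(cfg.timers.ts3_min, state.ts3 - step)
    elif frame.RH > sp.rh_max:
        _alert_once(state, events, "rh_high",
                    f"RH {frame.RH:g}% above maximum {sp.rh_max:g}%")
        if adjust:
            state.ts3_next = min(cfg.timers.ts3_max, state.ts3 + step)
    else:
        state.ts3_next = state.ts3


def _end_cycle(state: ControllerState, events: list[Event],
               frame: SensorFrame, cfg: ControllerConfig,
               tables: ComfortTables) -> None:
    sp = setpoints(cfg.flock.age_days, tables)
    if state.mode in (Mode.M1, Mode.M2):
        _set(state, events, "circ_fan", False)
        _rh_check(state, events, frame, sp, cfg, adjust=not state.emergency)
    elif state.mode == Mode.TR:
        _rh_check(state, events, frame, sp, cfg, adjust=False)
    # tunnel-family and PREP cycles have no end-of-cycle bookkeeping


# ---------------------------------------------------------------------------
# the tick


def controller_step(state: ControllerState, frame: SensorFrame | None,
                    cfg: ControllerConfig, tables: ComfortTables,
                    ) -> tuple[ControllerState, ActuatorState, list[Event]]:
    """Advance the controller by one tick.

    At a cycle boundary the house is re-measured and the branch dispatched;
    inside a cycle the phase actions run (fan-off at ts3, Δp / air-speed
    regulation after the ts4 settling time); the last tick of a cycle runs
    the end-of-cycle RH bookkeeping.  A missing frame holds all actuators
    and raises a one-time alert.  Mutates and returns *state*.
    """
    events: list[Event] = []
    if frame is None:
        _alert_once(state, events, "sensor_missing",
                    "No sensor frame available; actuators held")
        state.t += cfg.tick
        return state, replace(state.actuators), events
    if frame.t < state.last_frame_t:
        raise ValueError(f"sensor time went backwards: {frame.t} < {state.last_frame_t}")
    state.last_frame_t = frame.t

    if not state.started or state.cycle_done:
        state.started = True
        state.cycle_done = False
        _begin_cycle(state, events, frame, cfg, tables)
    else:
        _mid_cycle(state, events, frame, cfg, tables, state.t - state.cycle_start)

    if state.t - state.cycle_start >= state.cycle_len - cfg.tick:
        _end_cycle(state, events, frame, cfg, tables)
        state.cycle_done = True

    state.t += cfg.tick
    return state, replace(state.actuators), events


# ---------------------------------------------------------------------------
# cycle-level drivers

FrameSource = Callable[[int], SensorFrame | None]


def held_frames(frames: Iterable[SensorFrame]) -> FrameSource:
    """Sample-and-hold frame source: at time t, the latest frame with
    timestamp <= t (None before the first frame)."""
    ordered = sorted(frames, key=lambda f: f.t)

    def source(t: int) -> SensorFrame | None:
        latest = None
        for f in ordered:
            if f.t <= t:
                latest = f
            else:
                break
        return latest

    return source


def run_cycle(state: ControllerState, frame_source: FrameSource,
              cfg: ControllerConfig, tables: ComfortTables,
              ) -> tuple[ControllerState, list[Event]]:
    """Run exactly one full controller cycle (begin through end-of-cycle)."""
    events: list[Event] = []
    while True:
        _, _, ev = controller_step(state, frame_source(state.t), cfg, tables)
        events.extend(ev)
        if state.cycle_done:
            return state, events


def _run_expected(state: ControllerState, frame_source: FrameSource,
                  cfg: ControllerConfig, tables: ComfortTables,
                  allowed: tuple[Mode, ...]) -> tuple[ControllerState, list[Event]]:
    state, events = run_cycle(state, frame_source, cfg, tables)
    if state.mode not in allowed:
        raise RuntimeError(f"classified branch {state.mode}, expected one of {allowed}")
    return state, events


def run_min_vent_cycle(state, frame_source, cfg, tables):
    """One minimum-ventilation (M1/M2) cycle; raises if the temperature
    classification lands elsewhere."""
    return _run_expected(state, frame_source, cfg, tables, (Mode.M1, Mode.M2))


def run_transitional_cycle(state, frame_source, cfg, tables):
    """One transitional (Tr) cycle; raises on a different classification."""
    return _run_expected(state, frame_source, cfg, tables, (Mode.TR,))


def run_tunnel_cycle(state, frame_source, cfg, tables):
    """One tunnel-family cycle (Tu / evaporative variants)."""
    return _run_expected(state, frame_source, cfg, tables,
                         (Mode.TU, Mode.TU_EVAP, Mode.TU_EVAP_HOLD,
                          Mode.EVAP_SHUTDOWN))


def run_prep(state, frame_source, cfg, tables):
    """One building-preparation cycle (purge, then thermostat hold)."""
    if state.mode != Mode.PREP:
        raise RuntimeError("run_prep requires PREP mode")
    cfg.prep.require_band()
    return run_cycle(state, frame_source, cfg, tables)
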