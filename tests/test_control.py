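"""Ventilation state machine: branch classification, gas logic, duty cycle,
emergency and latch semantics, safety interlocks, evaporative closed cycles."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from broilerclim.comfort import setpoints
from broilerclim.config import ControllerConfig, default_config
from broilerclim.control import (GasLevel, Mode, SensorFrame, blind_position,
                                 classify_mode, controller_step, gas_status,
                                 heater_power, held_frames, new_state,
                                 regulate_dp, run_cycle, run_min_vent_cycle,
                                 run_prep, run_transitional_cycle,
                                 run_tunnel_cycle)


def frame(t=0, ti=25.0, to=15.0, tih=25.0, rh=72.0, rhout=50.0, dp=25.0,
          saf=0.25, nh3=0.0, co2=500.0, co=0.0, h2s=0.0):
    return SensorFrame(t=t, ti=ti, to=to, tih=tih, RH=rh, RHout=rhout,
                       dp=dp, SAF=saf, NH3=nh3, CO2=co2, CO=co, H2S=h2s)


def constant_source(**kw):
    return lambda t: frame(t=t, **kw)


@pytest.fixture
def cfg():
    return default_config(timers={"ts2_minutes": 5})


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize("ti, expected", [
    (22.0, Mode.M1),    # bench test minute 0: heater at 100 %
    (23.99, Mode.M1),
    (24.0, Mode.M2),
    (25.0, Mode.M2),    # minute 15: heater PWM 10 %
    (25.5, Mode.M2),
    (26.0, Mode.TR),    # minute 10
    (27.0, Mode.TR),
    (27.01, Mode.TU),
])
def test_classify_mode_branches(tables, ti, expected):
    assert classify_mode(ti, setpoints(14, tables)) is expected


@given(ti=st.floats(-20, 60))
def test_classify_mode_is_a_partition(tables, ti):
    sp = setpoints(14, tables)
    mode = classify_mode(ti, sp)
    ranges = {
        Mode.M1: ti < sp.tmin,
        Mode.M2: sp.tmin <= ti <= sp.topt,
        Mode.TR: sp.topt < ti <= sp.tmax,
        Mode.TU: ti > sp.tmax,
    }
    assert sum(ranges.values()) == 1 and ranges[mode]


# ---------------------------------------------------------------------------
# gas status


def test_gas_status_levels(cfg):
    assert gas_status(frame(co2=2500), cfg.gas) == (GasLevel.WARN, ["CO2"])
    assert gas_status(frame(co2=3500), cfg.gas) == (GasLevel.EXCEED, ["CO2"])
    assert gas_status(frame(co2=0), cfg.gas) == (GasLevel.NORMAL, [])
    assert gas_status(frame(nh3=15), cfg.gas)[0] is GasLevel.EXCEED
    assert gas_status(frame(nh3=12.5), cfg.gas)[0] is GasLevel.WARN
    assert gas_status(frame(co=4.4), cfg.gas)[0] is GasLevel.EXCEED
    # hydrogen sulfide may not be present at all
    assert gas_status(frame(h2s=0.2), cfg.gas)[0] is GasLevel.EXCEED
    assert gas_status(frame(h2s=0.05), cfg.gas)[0] is GasLevel.NORMAL


def test_gas_status_reports_all_offenders(cfg):
    level, gases = gas_status(frame(co2=3500, nh3=20), cfg.gas)
    assert level is GasLevel.EXCEED and set(gases) == {"CO2", "NH3"}


# ---------------------------------------------------------------------------
# blind position and heater law


def test_blind_position_bench_map(cfg):
    assert blind_position(17.0, 14, 20000, cfg) == 2   # minute 0: 22-5 °C
    assert blind_position(7.0, 14, 20000, cfg) == 3    # minute 5: 22-15 °C
    assert blind_position(10.0, 14, 20000, cfg) == 3
    # below every breakpoint: clamp to fully open
    assert blind_position(-1.0, 14, 20000, cfg) == cfg.blinds.n_positions


def test_blind_map_rejects_nonmonotone():
    with pytest.raises(Exception):
        default_config(blinds={
            "n_positions": 7,
            "map": {"dt1_breakpoints": [0, 5], "weight_breakpoints": [0.0],
                    "positions": [[3, 4]]}})


def test_heater_law(cfg):
    assert heater_power(5.0, Mode.M1, False, cfg) == 100.0
    assert heater_power(0.5, Mode.M2, False, cfg) == 10.0
    assert heater_power(0.5, Mode.M2, True, cfg) == 50.0   # emergency floor
    assert heater_power(10.0, Mode.M2, False, cfg) == 100.0  # clamp
    assert heater_power(-1.0, Mode.M2, False, cfg) == 0.0


# ---------------------------------------------------------------------------
# differential-pressure regulation


def test_regulate_dp_in_band_unchanged(cfg):
    assert regulate_dp(20.0, 40.0, cfg.dp) == (40.0, False)


def test_regulate_dp_steps_toward_band(cfg):
    low, _ = regulate_dp(10.0, 40.0, cfg.dp)
    high, _ = regulate_dp(40.0, 40.0, cfg.dp)
    assert low > 40.0 > high


def test_regulate_dp_fault_after_max_iter(cfg):
    _, fault = regulate_dp(5.0, 40.0, cfg.dp, steps=cfg.dp.max_iter - 1)
    assert fault
    _, fault = regulate_dp(5.0, 40.0, cfg.dp, steps=0)
    assert not fault


def test_dp_fault_alert_on_stuck_pressure(cfg, tables):
    """A pressure stuck far out of band exhausts the correction budget and
    raises exactly one fault alert per episode."""
    state = new_state(cfg)
    _, events = run_cycle(state, constant_source(ti=26.0, dp=5.0), cfg, tables)
    faults = [e for e in events if e.name == "dp_fault"]
    assert len(faults) == 1


# ---------------------------------------------------------------------------
# cycle execution


def test_min_vent_cycle_duty_and_actions(cfg, tables):
    """Bench-test first cycle: blind 2, fan on, heater 100 %; after ts3 the
    fan stops, the blind closes and the stir fan starts (Δt3 > 3 °C)."""
    state = new_state(cfg)
    src = constant_source(ti=22.0, to=5.0, tih=26.0)
    state, events = run_min_vent_cycle(state, src, cfg, tables)
    assert state.mode is Mode.M1
    by_name = lambda n: [(e.t, e.value) for e in events
                         if e.kind == "actuator" and e.name == n]
    assert by_name("heater")[0] == (0, 100.0)
    assert by_name("blind_pos") == [(0, 2), (30, 0)]
    on, off = by_name("vent_power")[:2]
    assert off[0] - on[0] == cfg.timers.ts3   # fan-on time is exactly ts3
    assert (30, True) in by_name("circ_fan")
    # stir fan off again by the end of the cycle
    assert state.actuators.circ_fan is False


def test_circ_fan_stays_off_without_stratification(cfg, tables):
    state = new_state(cfg)
    state, events = run_min_vent_cycle(
        state, constant_source(ti=25.0, tih=25.0), cfg, tables)
    assert all(not (e.name == "circ_fan" and e.value) for e in events)


def test_transitional_cycle_continuous_ventilation(cfg, tables):
    state = new_state(cfg)
    state, events = run_transitional_cycle(
        state, constant_source(ti=26.0, to=15.0), cfg, tables)
    assert state.mode is Mode.TR
    assert state.actuators.heater == 0.0
    assert state.actuators.vent_power > 0           # still running at cycle end
    assert state.actuators.blind_pos == 4           # map(11 °C)=3, +1 offset
    assert state.actuators.circ_fan is False


def test_transitional_rh_message_without_ts3_change(cfg, tables):
    state = new_state(cfg)
    before = state.ts3_next
    state, events = run_transitional_cycle(
        state, constant_source(ti=26.0, rh=85.0), cfg, tables)
    assert any(e.name == "rh_high" for e in events)
    assert state.ts3_next == before


def test_min_vent_rh_adjusts_ts3(cfg, tables):
    state = new_state(cfg)
    state, events = run_min_vent_cycle(
        state, constant_source(ti=25.0, rh=60.0), cfg, tables)
    assert any(e.name == "rh_low" for e in events)
    assert state.ts3_next == cfg.timers.ts3 - cfg.timers.ts3_step
    # and the step is bounded below over many wet-side cycles
    for _ in range(20):
        state, _ = run_min_vent_cycle(
            state, constant_source(ti=25.0, rh=60.0), cfg, tables)
    assert state.ts3_next == cfg.timers.ts3_min


def test_min_vent_rh_increase_bounded_above(cfg, tables):
    state = new_state(cfg)
    for _ in range(20):
        state, _ = run_min_vent_cycle(
            state, constant_source(ti=25.0, rh=90.0), cfg, tables)
    assert state.ts3_next == cfg.timers.ts3_max


def test_warn_widens_blind_one_step(cfg, tables):
    state = new_state(cfg)
    state, events = run_min_vent_cycle(
        state, constant_source(ti=25.0, co2=2500.0), cfg, tables)
    blinds = [e.value for e in events if e.name == "blind_pos"]
    assert blinds[0] == 4   # map gives 3, pre-warning adds one
    assert not any(e.kind == "alert" and "CO2" in str(e.value) for e in events)


def test_emergency_semantics(cfg, tables):
    """Gas exceedance: 3-minute cycle, one-time alert, ventilation running
    the whole cycle, heater floored at 50 % in M2."""
    state = new_state(cfg)
    state, events = run_min_vent_cycle(
        state, constant_source(ti=25.0, co2=3500.0), cfg, tables)
    assert state.emergency
    assert state.cycle_len == 180
    alerts = [e for e in events if e.kind == "alert" and "CO2" in str(e.value)]
    assert len(alerts) == 1
    assert "3000" in str(alerts[0].value) and "3500" in str(alerts[0].value)
    assert state.actuators.vent_power > 0   # never switched off mid-cycle
    assert state.actuators.heater == 50.0


def test_emergency_blind_modes(tables):
    for mode_name, expected in [("max", 7), ("x_plus_2", 5), ("fixed", 4)]:
        cfg = default_config(
            timers={"ts2_minutes": 5},
            blinds={"n_positions": 7, "emergency_mode": mode_name,
                    "emergency_fixed_pos": 4,
                    "map": {"dt1_breakpoints": [0, 5, 15],
                            "weight_breakpoints": [0.0],
                            "positions": [[4, 3, 2]]}})
        state = new_state(cfg)
        state, events = run_min_vent_cycle(
            state, constant_source(ti=25.0, co2=3500.0), cfg, tables)
        assert state.actuators.blind_pos == expected, mode_name


def test_emergency_in_m1_opens_x_plus_2_not_max(cfg, tables):
    state = new_state(cfg)
    state, _ = run_min_vent_cycle(
        state, constant_source(ti=22.0, to=5.0, co2=3500.0), cfg, tables)
    assert state.mode is Mode.M1
    assert state.actuators.blind_pos == 4   # X=2, +2; never fully open


def test_alert_latch_two_episodes(cfg, tables):
    """Two exceedance episodes separated by a clean cycle produce exactly
    two alerts; consecutive exceedance cycles produce only one."""
    def co2_at(t):
        # episode 1: two emergency cycles, then clean air, then episode 2
        if t < 360:
            return 3500.0
        if t < 1000:
            return 500.0
        return 3500.0
    src = lambda t: frame(t=t, ti=25.0, co2=co2_at(t))
    state = new_state(cfg)
    events = []
    for _ in range(8):
        state, ev = run_cycle(state, src, cfg, tables)
        events.extend(ev)
    alerts = [e for e in events if e.name == "gas_exceed_CO2"]
    assert len(alerts) == 2
    flips = [e.value for e in events if e.name == "emergency"]
    assert flips == [True, False, True, False] or flips[:3] == [True, False, True]


def test_normal_gas_never_emergency(cfg, tables):
    state = new_state(cfg)
    for _ in range(5):
        state, _ = run_cycle(state, constant_source(ti=25.0), cfg, tables)
        assert not state.emergency


# ---------------------------------------------------------------------------
# tunnel branch


@pytest.fixture
def adult_cfg():
    return default_config(timers={"ts2_minutes": 5},
                          flock={"n_birds": 20000, "age_days": 49})


def test_tunnel_runs_at_zmax_between_tmin_tmax(adult_cfg, tables):
    # adults: band [18,18]; ti=23 gives tf(2.5 m/s) ~ 18.4 — above the band,
    # but outdoor air too humid for the pads
    state = new_state(adult_cfg)
    state, events = run_tunnel_cycle(
        state, constant_source(ti=23.0, rhout=85.0, saf=2.5), adult_cfg, tables)
    assert state.mode is Mode.TU
    assert state.actuators.tunnel_inlets and state.actuators.tunnel_power > 0
    assert state.actuators.evap_pads is False
    assert state.actuators.blind_pos == 0 and state.actuators.heater == 0


def test_tunnel_saf_correction(adult_cfg, tables):
    """A measured air speed >10 % away from target trims the fan power."""
    state = new_state(adult_cfg)
    state, events = run_tunnel_cycle(
        state, constant_source(ti=23.0, rhout=85.0, saf=1.5), adult_cfg, tables)
    assert state.saf_target > 0
    tp = [e.value for e in events if e.name == "tunnel_power"]
    assert len(tp) > 1 and tp[-1] > tp[0]   # speed too low -> power raised


def test_evaporative_cycle_and_drying_interlock(adult_cfg, tables):
    """Pads engage on a hot dry day, the controller enters the closed
    monitoring cycle, and shutdown enforces the full drying hold before the
    pads may re-enable."""
    tdry = int(adult_cfg.timers.ts_drying_minutes * 60)

    state = new_state(adult_cfg)
    # hot cycle: tf(Zmax) above tmax, dry outside -> pads on
    state, ev1 = run_tunnel_cycle(
        state, constant_source(ti=30.0, rhout=50.0, saf=2.5), adult_cfg, tables)
    assert state.mode is Mode.TU_EVAP and state.actuators.evap_pads

    # still warm: drop into the closed monitoring cycle, pads stay on
    state, ev2 = run_tunnel_cycle(
        state, constant_source(ti=26.0, rhout=50.0, saf=2.5), adult_cfg, tables)
    assert state.mode is Mode.TU_EVAP_HOLD and state.actuators.evap_pads

    # cooled below tmin: shutdown — pads off, Zopt, drying hold
    state, ev3 = run_tunnel_cycle(
        state, constant_source(ti=18.0, rhout=50.0, saf=2.5), adult_cfg, tables)
    assert state.mode is Mode.EVAP_SHUTDOWN
    assert state.actuators.evap_pads is False
    assert state.cycle_len == tdry
    shutdown_t = state.cycle_start

    # hot again immediately after drying: pads may only re-enable once the
    # drying time has fully elapsed
    state, ev4 = run_tunnel_cycle(
        state, constant_source(ti=30.0, rhout=50.0, saf=2.5), adult_cfg, tables)
    pad_on = [e for e in ev4 if e.name == "evap_pads" and e.value]
    assert pad_on and pad_on[0].t - shutdown_t >= tdry


def test_hold_exits_on_humid_outdoor_air(adult_cfg, tables):
    state = new_state(adult_cfg)
    state, _ = run_tunnel_cycle(
        state, constant_source(ti=30.0, rhout=50.0, saf=2.5), adult_cfg, tables)
    state, _ = run_tunnel_cycle(
        state, constant_source(ti=26.0, rhout=50.0, saf=2.5), adult_cfg, tables)
    assert state.mode is Mode.TU_EVAP_HOLD
    state, _ = run_tunnel_cycle(
        state, constant_source(ti=26.0, rhout=90.0, saf=2.5), adult_cfg, tables)
    assert state.mode is Mode.EVAP_SHUTDOWN


def test_gas_exceed_in_tunnel_alerts_without_emergency(adult_cfg, tables):
    state = new_state(adult_cfg)
    state, events = run_tunnel_cycle(
        state, constant_source(ti=23.0, rhout=85.0, saf=2.5, co2=3500.0),
        adult_cfg, tables)
    assert any(e.name == "gas_exceed_CO2" for e in events)
    assert not state.emergency


# ---------------------------------------------------------------------------
# building preparation


def test_prep_thermostat(tables):
    cfg = default_config(prep={"tpmin": 28.0, "tpmax": 32.0,
                               "purge_minutes": 2.0})
    state = new_state(cfg, mode=Mode.PREP)
    # initial purge ventilates regardless of temperature
    state, ev = run_prep(state, constant_source(ti=30.0), cfg, tables)
    assert any(e.name == "vent_power" and e.value > 0 for e in ev)
    # cold: heater on
    state, _ = run_prep(state, constant_source(ti=25.0), cfg, tables)
    assert state.actuators.heater == 100.0 and state.actuators.vent_power == 0
    # hot: ventilation duty cycle
    state, ev = run_prep(state, constant_source(ti=34.0), cfg, tables)
    assert state.actuators.heater == 0.0
    assert any(e.name == "vent_power" and e.value > 0 for e in ev)
    # in band: idle hold
    state, _ = run_prep(state, constant_source(ti=30.0), cfg, tables)
    assert state.actuators.heater == 0.0 and state.actuators.vent_power == 0.0


def test_prep_requires_band():
    from broilerclim.config import ConfigError
    cfg = default_config()
    state = new_state(cfg, mode=Mode.PREP)
    with pytest.raises(ConfigError):
        run_prep(state, constant_source(), cfg, load_tables_cached())


def load_tables_cached():
    from broilerclim.comfort import load_tables
    return load_tables()


# ---------------------------------------------------------------------------
# step-level contracts


def test_missing_frame_holds_and_alerts(cfg, tables):
    state = new_state(cfg)
    state, _, _ = controller_step(state, frame(ti=25.0), cfg, tables)
    held = state.actuators.blind_pos
    state, act, ev = controller_step(state, None, cfg, tables)
    assert act.blind_pos == held
    assert any(e.name == "sensor_missing" for e in ev)


def test_time_going_backwards_rejected(cfg, tables):
    state = new_state(cfg)
    controller_step(state, frame(t=100, ti=25.0), cfg, tables)
    with pytest.raises(ValueError):
        controller_step(state, frame(t=50, ti=25.0), cfg, tables)


def _interlocks_ok(state):
    a = state.actuators
    if a.evap_pads and not (a.tunnel_inlets and a.tunnel_power > 0):
        return False
    if a.heater > 0 and state.mode not in (Mode.PREP, Mode.M1, Mode.M2):
        return False
    if a.blind_pos > 0 and a.tunnel_inlets:
        return False
    return True


_PROP_CFG = default_config(timers={"ts2_minutes": 5})


@given(seed=st.integers(0, 999))
def test_safety_interlocks_hold_under_random_traces(tables, seed):
    cfg = _PROP_CFG
    """Whatever the sensors report, the pads never run without tunnel air,
    the heater never runs in a cooling regime, and blinds and tunnel inlets
    are never open together."""
    import random
    rng = random.Random(seed)
    state = new_state(cfg)
    t = 0
    for _ in range(12):
        f = frame(t=t, ti=rng.uniform(10, 40), to=rng.uniform(-5, 35),
                  tih=rng.uniform(10, 45), rh=rng.uniform(30, 95),
                  rhout=rng.uniform(20, 95), dp=rng.uniform(5, 40),
                  saf=rng.uniform(0.1, 3.0), co2=rng.uniform(0, 4000))
        # hold each random frame for a whole cycle
        state, _ = run_cycle(state, lambda tt, f=f: frame(
            t=tt, ti=f.ti, to=f.to, tih=f.tih, rh=f.RH, rhout=f.RHout,
            dp=f.dp, saf=f.SAF, co2=f.CO2), cfg, tables)
        assert _interlocks_ok(state)
        assert state.emergency == (state.cycle_len == 180) or not state.emergency
        if state.emergency:
            assert state.mode in (Mode.M1, Mode.M2, Mode.TR)
        t = state.t
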