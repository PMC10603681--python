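"""Lumped-parameter broiler-house plant model.

A single-zone synthetic building + flock so the controller can be exercised
closed-loop without hardware.  The flock is a heat, moisture and CO2 source
scaled by total live weight; the building is a first-order thermal node with
envelope losses, ventilation air exchange, heater input and (when the pads
run) evaporative cooling of the tunnel air stream.  Differential pressure
follows an orifice law over the open inlet area; near-roof temperature is
the zone temperature plus a stratification offset that decays when air is
stirred.  Integration is explicit Euler at the controller tick.

All of this is deliberately coarse plumbing around the controller — a test
double for a building, not a building-physics model.  Constants are
calibrated so the reference flock (20,000 birds at 2 kg) releases ~130 kW
and ~4000 L of water per day, and so the default blind/fan pairing lands
the differential pressure mid-band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .config import gompertz_weight
from .control import ActuatorState

__all__ = [
    "FlockParams",
    "BuildingParams",
    "PlantState",
    "flock_heat",
    "pressure_model",
    "plant_step",
    "make_scenario",
    "SCENARIO_KINDS",
]

RHO_AIR = 1.206      # kg/m3
CP_AIR = 1005.0      # J/(kg K)
CO2_AMBIENT = 420.0  # ppm


# ---------------------------------------------------------------------------
# moist-air helpers (plant-side only)


def _p_sat(t: float) -> float:
    """Magnus saturation vapour pressure, Pa."""
    return 610.94 * math.exp(17.625 * t / (t + 243.04))


def _w_sat(t: float, p_tot: float = 101325.0) -> float:
    ps = _p_sat(t)
    return 0.622 * ps / (p_tot - ps)


def _rh_to_w(t: float, rh: float) -> float:
    return rh / 100.0 * _w_sat(t)


def _w_to_rh(t: float, w: float) -> float:
    return float(np.clip(100.0 * w / _w_sat(t), 0.5, 100.0))


def _wet_bulb(t: float, rh: float) -> float:
    """Stull (2011) wet-bulb approximation, °C (valid for ordinary ranges)."""
    return (t * math.atan(0.151977 * math.sqrt(rh + 8.313659))
            + math.atan(t + rh) - math.atan(rh - 1.676331)
            + 0.00391838 * rh ** 1.5 * math.atan(0.023101 * rh)
            - 4.686035)


# ---------------------------------------------------------------------------
# parameters and state


@dataclass(frozen=True)
class FlockParams:
    """The birds as a source term.

    heat_rate is the specific sensible+latent heat release (kJ/h per kg of
    live weight); water_rate_per_kg the evaporated water (L/day per kg —
    the reference flock of 20,000 x 2 kg birds evaporates ~4000 L/day);
    co2_rate the exhaled CO2 (m3/h per kg).
    """

    n_birds: int = 20000
    age_days: float = 14.0
    weight_curve: Callable[[float], float] = gompertz_weight
    heat_rate: float = 11.6
    water_rate_per_kg: float = 0.1
    co2_rate: float = 0.0008

    def bird_weight(self) -> float:
        w = self.weight_curve(self.age_days)
        if w <= 0:
            raise ValueError("weight curve must be positive")
        return w

    def total_weight(self) -> float:
        return self.n_birds * self.bird_weight()


@dataclass(frozen=True)
class BuildingParams:
    """Envelope, inlets and machinery of the synthetic building.

    ``thermal_mass_factor`` scales the air heat capacity to stand in for
    litter and structure mass (a bare-air zone would swing several °C per
    ventilation cycle, which real houses do not).
    """

    volume: float = 6000.0            # m3
    envelope_ua: float = 600.0        # W/°C
    cross_section: float = 60.0       # m2 (tunnel flow cross-section)
    blind_area_per_pos: float = 0.8   # m2 per blind position step
    tunnel_inlet_area: float = 40.0   # m2
    vent_flow_max: float = 80000.0    # m3/h at 100 % ventilation power
    tunnel_flow_max: float = 540000.0  # m3/h at 100 % tunnel power
    heater_capacity: float = 120.0    # kW
    evap_effectiveness: float = 0.75  # 0..1
    orifice_k: float = 1.67           # Pa/(m/s)^2, ~rho/(2 Cd^2)
    dp_max: float = 100.0             # Pa cap when inlets are blocked
    thermal_mass_factor: float = 5.0
    strat_offset_max: float = 4.0     # °C tih-ti with still air
    strat_tau: float = 300.0          # s
    saf_baseline: float = 0.25        # m/s bird-level air movement, no tunnel

    def __post_init__(self) -> None:
        for name in ("volume", "envelope_ua", "cross_section",
                     "blind_area_per_pos", "tunnel_inlet_area",
                     "vent_flow_max", "tunnel_flow_max", "heater_capacity",
                     "orifice_k", "thermal_mass_factor", "strat_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.evap_effectiveness <= 1:
            raise ValueError("evap_effectiveness must be in [0, 1]")

    def heat_capacity(self) -> float:
        """Effective zone heat capacity, J/°C."""
        return RHO_AIR * CP_AIR * self.volume * self.thermal_mass_factor

    def vent_flow(self, power_pct: float) -> float:
        return self.vent_flow_max * power_pct / 100.0

    def tunnel_flow(self, power_pct: float) -> float:
        return self.tunnel_flow_max * power_pct / 100.0

    def euler_stable(self, dt: float) -> bool:
        """Explicit Euler stays stable when dt is well below the fastest
        thermal time constant (all fans flat out)."""
        g_max = self.envelope_ua + RHO_AIR * CP_AIR * (
            self.vent_flow_max + self.tunnel_flow_max) / 3600.0
        return dt < 0.5 * self.heat_capacity() / g_max


@dataclass
class PlantState:
    ti: float = 25.0
    tih: float = 29.0
    RH: float = 70.0
    CO2: float = 800.0
    dp: float = 0.0
    SAF: float = 0.25
    w: float = field(default=0.0)          # humidity ratio kg/kg (0 = derive)
    strat: float = field(default=-1.0)     # tih-ti offset (<0 = derive)
    dp_fault: bool = False

    def __post_init__(self) -> None:
        if self.w == 0.0:
            self.w = _rh_to_w(self.ti, self.RH)
        if self.strat < 0:
            self.strat = self.tih - self.ti


# ---------------------------------------------------------------------------
# operations


def flock_heat(n_birds: int, weight_kg: float, heat_rate: float = 11.6) -> float:
    """Total flock heat release in kW (heat_rate in kJ/h per kg)."""
    if n_birds < 0 or weight_kg < 0:
        raise ValueError("bird count and weight must be >= 0")
    return n_birds * weight_kg * heat_rate / 3600.0


def pressure_model(vent_flow: float, open_area: float, k: float,
                   dp_max: float = math.inf) -> float:
    """Orifice differential pressure: dp = k (Q/A)^2 with Q in m3/h, A in m2.

    Zero open area with nonzero flow is a blocked building: the result is
    capped at ``dp_max`` (callers should treat that as a fault)."""
    if vent_flow <= 0:
        return 0.0
    if open_area <= 0:
        return dp_max
    v = vent_flow / 3600.0 / open_area
    return min(k * v * v, dp_max)


def plant_step(state: PlantState, act: ActuatorState,
               weather: tuple[float, float], flock: FlockParams,
               bldg: BuildingParams, dt: float) -> PlantState:
    """One explicit-Euler step of the building balance over *dt* seconds.

    *weather* is ``(to, RHout)``.  Returns a new :class:`PlantState`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    to, rhout = weather
    w_out = _rh_to_w(to, rhout)

    q_vent = bldg.vent_flow(act.vent_power) if act.blind_pos > 0 else 0.0
    q_tun = bldg.tunnel_flow(act.tunnel_power) if act.tunnel_inlets else 0.0

    # tunnel supply condition, optionally evaporatively cooled
    t_sup, w_sup = to, w_out
    if act.evap_pads and q_tun > 0:
        twb = _wet_bulb(to, rhout)
        eff = bldg.evap_effectiveness
        t_sup = to - eff * (to - twb)
        w_sup = w_out + eff * (_w_sat(twb) - w_out)

    mdot_v = RHO_AIR * q_vent / 3600.0
    mdot_t = RHO_AIR * q_tun / 3600.0

    p_source = (flock_heat(flock.n_birds, flock.bird_weight(), flock.heat_rate)
                + act.heater / 100.0 * bldg.heater_capacity) * 1000.0  # W
    p_loss = (bldg.envelope_ua * (state.ti - to)
              + mdot_v * CP_AIR * (state.ti - to)
              + mdot_t * CP_AIR * (state.ti - t_sup))
    ti = state.ti + (p_source - p_loss) / bldg.heat_capacity() * dt

    # moisture balance on the humidity ratio
    m_air = RHO_AIR * bldg.volume
    water_kgps = flock.total_weight() * flock.water_rate_per_kg / 86400.0
    dw = (water_kgps - mdot_v * (state.w - w_out)
          - mdot_t * (state.w - w_sup)) / m_air
    w = max(1e-5, state.w + dw * dt)

    # CO2 dilution balance (ppm)
    s_co2 = flock.total_weight() * flock.co2_rate  # m3/h
    q_tot = q_vent + q_tun
    dc = (s_co2 / bldg.volume * 1e6 - q_tot * (state.CO2 - CO2_AMBIENT)
          / bldg.volume) / 3600.0
    co2 = max(CO2_AMBIENT, state.CO2 + dc * dt)

    # stratification offset relaxes toward still-air maximum; stirring
    # (circulation fans or tunnel flow) collapses it
    stirred = act.circ_fan or q_tun > 0
    target = 0.5 if stirred else bldg.strat_offset_max
    strat = state.strat + (target - state.strat) / bldg.strat_tau * dt

    open_area = (act.blind_pos * bldg.blind_area_per_pos
                 + (bldg.tunnel_inlet_area if act.tunnel_inlets else 0.0))
    dp = pressure_model(q_tot, open_area, bldg.orifice_k, bldg.dp_max)
    dp_fault = q_tot > 0 and open_area <= 0

    saf = (q_tun / 3600.0 / bldg.cross_section if act.tunnel_inlets and q_tun > 0
           else bldg.saf_baseline)

    return PlantState(ti=ti, tih=ti + strat, RH=_w_to_rh(ti, w), CO2=co2,
                      dp=dp, SAF=saf, w=w, strat=strat, dp_fault=dp_fault)


# ---------------------------------------------------------------------------
# scenario generation

SCENARIO_KINDS = ("table5", "cold_day", "hot_day", "gas_spike")

#: the published bench-test input rows: minute -> (ti, to, tih, dp, CO2);
#: the remaining channels were not exercised and are filled with in-band
#: constants (RH 72 %, RHout 50 %, SAF 0.25 m/s, other gases zero).
TABLE5_ROWS: tuple[tuple[int, float, float, float, float, float], ...] = (
    (0, 22.0, 5.0, 26.0, 25.0, 500.0),
    (4, 22.0, 15.0, 22.0, 25.0, 500.0),
    (8, 26.0, 15.0, 30.0, 25.0, 500.0),
    (14, 25.0, 15.0, 30.0, 25.0, 500.0),
    (19, 25.0, 15.0, 25.0, 25.0, 2500.0),
    (24, 24.5, 15.0, 25.0, 25.0, 3500.0),
    (27, 25.0, 15.0, 25.0, 25.0, 500.0),
)

TRACE_COLUMNS = ["time", "ti", "to", "tih", "RH", "RHout", "dp", "SAF",
                 "NH3", "CO2", "CO", "H2S"]


def _table5_frame_values(t_s: float) -> tuple[float, float, float, float, float]:
    row = TABLE5_ROWS[0]
    for r in TABLE5_ROWS:
        if r[0] * 60 <= t_s:
            row = r
    return row[1], row[2], row[3], row[4], row[5]


def make_scenario(kind: str, seed: int = 0, duration_s: int | None = None,
                  sample_s: int = 30) -> pd.DataFrame:
    """Build a deterministic sensor trace as a DataFrame (canonical columns).

    ``table5`` reproduces the published bench-test inputs sample-and-hold at
    the 30 s send interval; the other kinds are seeded synthetic weather
    days (cold, hot, and a cold day with a CO2 excursion).
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}; choose from {SCENARIO_KINDS}")
    if kind == "table5":
        dur = 1980 if duration_s is None else duration_s
        rows = []
        for t in range(0, dur + 1, sample_s):
            ti, to, tih, dp, co2 = _table5_frame_values(t)
            rows.append((t, ti, to, tih, 72.0, 50.0, dp, 0.25,
                         0.0, co2, 0.0, 0.0))
        return pd.DataFrame(rows, columns=TRACE_COLUMNS)

    rng = np.random.default_rng(seed)
    dur = 86400 if duration_s is None else duration_s
    t = np.arange(0, dur + 1, sample_s, dtype=float)
    day = 2 * np.pi * t / 86400.0
    if kind == "hot_day":
        to = 31.0 + 5.0 * np.sin(day - np.pi / 2) + rng.normal(0, 0.2, t.size)
        rhout = np.clip(55.0 - 15.0 * np.sin(day - np.pi / 2)
                        + rng.normal(0, 2.0, t.size), 20, 95)
        ti_base, co2_base = 29.0, 900.0
    else:  # cold_day and gas_spike share the cold weather
        to = 6.0 + 4.0 * np.sin(day - np.pi / 2) + rng.normal(0, 0.2, t.size)
        rhout = np.clip(75.0 + 10.0 * np.sin(day) + rng.normal(0, 2.0, t.size),
                        30, 98)
        ti_base, co2_base = 25.0, 1200.0
    ti = ti_base + rng.normal(0, 0.1, t.size)
    co2 = np.full(t.size, co2_base)
    if kind == "gas_spike":
        spike = (t >= 1200) & (t < 1800)
        co2 = co2 + np.where(spike, 2600.0, 0.0)
    df = pd.DataFrame({
        "time": t.astype(int), "ti": np.round(ti, 2), "to": np.round(to, 2),
        "tih": np.round(ti + 3.5, 2), "RH": 72.0,
        "RHout": np.round(rhout, 1), "dp": 25.0, "SAF": 0.25,
        "NH3": 0.0, "CO2": np.round(co2, 0), "CO": 0.0, "H2S": 0.0,
    })
    return df[TRACE_COLUMNS]
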