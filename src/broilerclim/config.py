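"""Controller configuration schema.

Per-farm data the algorithm cannot know by itself: building blind/fan
hardware, the blind-position map, timer defaults, gas limits and the flock.
Loaded from a nested YAML document (sections mirror the model names below);
see ``broilerclim validate-config`` for schema checking from the shell.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class ConfigError(ValueError):
    pass


class GasLimits(BaseModel):
    """Regulatory air-quality limits (ppm).

    Hydrogen sulfide may not be present at all, so it has no limit — any
    reading above the ``H2S_eps`` detection floor is an exceedance.
    ``warn_fraction`` is the pre-warning threshold as a fraction of each
    limit (default 80 %).
    """

    NH3_max: float = 15.0
    CO2_max: float = 3000.0
    CO_max: float = 4.4
    H2S_eps: float = Field(default=0.1, ge=0)
    warn_fraction: float = Field(default=0.8, gt=0, lt=1)

    @model_validator(mode="after")
    def _positive(self) -> "GasLimits":
        if min(self.NH3_max, self.CO2_max, self.CO_max) <= 0:
            raise ValueError("gas limits must be positive")
        return self


class TimerConfig(BaseModel):
    """Duty-cycle timers.

    ts2 (cycle length, minutes) defaults to an age schedule — 7 min during
    brooding (<= 14 days) to save heating energy, 5 min after — unless
    ``ts2_minutes`` pins it.  ts3 is the fan-on time per cycle (s), nudged
    by ``ts3_step`` within [ts3_min, ts3_max] when RH drifts out of band.
    ts4 is the actuator settling time (s).  The remaining-on time
    ts5 = ts3 - ts4 and off time ts6 = ts2*60 - ts3 are derived, never
    stored.
    """

    ts2_minutes: float | None = None
    ts2_brooding_minutes: float = 7.0
    ts2_grown_minutes: float = 5.0
    ts2_emergency_minutes: float = 3.0
    ts2_transitional_minutes: float = 5.0
    ts2_tunnel_minutes: float = 5.0
    ts3: int = 30
    ts3_min: int = 10
    ts3_max: int = 60
    ts3_step: int = 5
    ts4: int = 10
    ts_drying_minutes: float = 30.0

    @model_validator(mode="after")
    def _consistent(self) -> "TimerConfig":
        if not (0 < self.ts3_min <= self.ts3 <= self.ts3_max):
            raise ValueError("require ts3_min <= ts3 <= ts3_max")
        if self.ts4 > self.ts3_min:
            raise ValueError("settling time ts4 must not exceed ts3_min")
        return self

    def ts2_for_age(self, age_days: float) -> float:
        if self.ts2_minutes is not None:
            return self.ts2_minutes
        return self.ts2_brooding_minutes if age_days <= 14 else self.ts2_grown_minutes


class BlindMap(BaseModel):
    """2-D lookup (Δt1 = ti - to) x (total live weight) -> blind position.

    ``positions[w][d]`` is the position for the w-th weight band and d-th
    Δt1 band; breakpoints are lower band edges, ascending.  Positions must
    not increase with Δt1 (colder outside -> smaller opening).  A Δt1 below
    every breakpoint clamps to the fully-open position.
    """

    dt1_breakpoints: list[float]
    weight_breakpoints: list[float] = Field(default_factory=lambda: [0.0])
    positions: list[list[int]]

    @model_validator(mode="after")
    def _check(self) -> "BlindMap":
        if not self.dt1_breakpoints or not self.positions:
            raise ValueError("blind map must not be empty")
        if sorted(self.dt1_breakpoints) != self.dt1_breakpoints:
            raise ValueError("dt1_breakpoints must be ascending")
        if sorted(self.weight_breakpoints) != self.weight_breakpoints:
            raise ValueError("weight_breakpoints must be ascending")
        if len(self.positions) != len(self.weight_breakpoints):
            raise ValueError("one position row per weight band required")
        for row in self.positions:
            if len(row) != len(self.dt1_breakpoints):
                raise ValueError("one position per dt1 band required")
            if any(a < b for a, b in zip(row, row[1:])):
                raise ValueError("positions must be nonincreasing in dt1")
        return self


class BlindConfig(BaseModel):
    n_positions: int = Field(default=7, ge=1)
    map: BlindMap
    #: transitional ventilation opens this many steps wider than the map.
    transitional_offset: int = 1
    #: emergency opening in branch M2: flowchart maximum, X+2, or a fixed
    #: position (branch M1 always uses X+2 to avoid chilling the birds).
    emergency_mode: Literal["max", "x_plus_2", "fixed"] = "max"
    emergency_fixed_pos: int = 4


class FanConfig(BaseModel):
    """power_map: blind position -> ventilation fan power (%), matched so
    each position lands the differential pressure inside its band."""

    power_map: dict[int, float]
    #: tunnel air speed achieved at 100 % tunnel fan power (m/s).
    saf_at_full_power: float = Field(default=2.5, gt=0)

    def power_for(self, position: int) -> float:
        if not self.power_map:
            raise ConfigError("fan power map is empty")
        if position in self.power_map:
            return self.power_map[position]
        nearest = min(self.power_map, key=lambda p: abs(p - position))
        return self.power_map[nearest]

    def power_for_speed(self, saf: float) -> float:
        return float(min(100.0, max(0.0, 100.0 * saf / self.saf_at_full_power)))


class DpConfig(BaseModel):
    """Differential-pressure regulation: band (Pa), proportional gain
    (% fan power per Pa of error) and the step cap before a fault alert."""

    band: tuple[float, float] = (17.5, 30.0)
    gain: float = Field(default=0.5, gt=0)
    max_iter: int = Field(default=20, ge=1)

    @model_validator(mode="after")
    def _band(self) -> "DpConfig":
        if self.band[0] >= self.band[1]:
            raise ValueError("dp band lower bound must be below upper bound")
        return self


class HeaterConfig(BaseModel):
    """In branch M2 heater power is proportional to Δt2 = topt - ti;
    the default gain gives 10 % at half a degree below optimum."""

    gain: float = Field(default=20.0, gt=0)  # % per °C
    emergency_floor: float = 50.0


class FlockConfig(BaseModel):
    n_birds: int = Field(default=20000, ge=1)
    age_days: float = Field(default=14.0, ge=1)
    #: per-bird weight override (kg); default follows the growth curve.
    weight_kg: float | None = None

    def bird_weight(self) -> float:
        if self.weight_kg is not None:
            return self.weight_kg
        return gompertz_weight(self.age_days)

    def total_weight(self) -> float:
        return self.n_birds * self.bird_weight()


def gompertz_weight(age_days: float) -> float:
    """Default broiler growth curve (kg/bird): Gompertz fitted to ~45 g at
    day 1, ~0.45 kg at day 14 and 2.0 kg at day 35."""
    return 4.0 * math.exp(-4.74 * math.exp(-0.055 * age_days))


class PrepConfig(BaseModel):
    """Building-preparation thermostat band and initial purge length."""

    tpmin: float | None = None
    tpmax: float | None = None
    purge_minutes: float = 10.0

    def require_band(self) -> tuple[float, float]:
        if self.tpmin is None or self.tpmax is None or self.tpmin >= self.tpmax:
            raise ConfigError("preparation mode needs tpmin < tpmax")
        return self.tpmin, self.tpmax


class EvapConfig(BaseModel):
    #: outdoor RH above which evaporative pads stay off (%).
    rhout_cutoff: float = 80.0


class ControlMisc(BaseModel):
    #: stratification threshold Δt3 = tih - ti for the circulation fans (°C).
    dt3_max: float = 3.0
    #: relative air-speed deviation triggering tunnel fan correction.
    saf_tolerance: float = 0.10
    #: fractional power step per tick when correcting tunnel air speed.
    saf_gain: float = 0.2


class ControllerConfig(BaseModel):
    """Top-level configuration; every section has working defaults except
    the building-specific blind map."""

    tick: int = Field(default=1, ge=1)
    timers: TimerConfig = TimerConfig()
    gas: GasLimits = GasLimits()
    blinds: BlindConfig
    fans: FanConfig
    dp: DpConfig = DpConfig()
    heater: HeaterConfig = HeaterConfig()
    flock: FlockConfig = FlockConfig()
    prep: PrepConfig = PrepConfig()
    evap: EvapConfig = EvapConfig()
    control: ControlMisc = ControlMisc()


def default_config(**overrides) -> ControllerConfig:
    """A working configuration for the sample seven-position building
    (the experimental-stage blind and fan maps); keyword overrides are
    merged into the top level."""
    base: dict = {
        "blinds": {
            "n_positions": 7,
            "map": {
                "dt1_breakpoints": [0.0, 5.0, 15.0],
                "weight_breakpoints": [0.0],
                "positions": [[4, 3, 2]],
            },
        },
        "fans": {
            "power_map": {1: 15, 2: 25, 3: 40, 4: 50, 5: 65, 6: 80, 7: 100},
            "saf_at_full_power": 2.5,
        },
    }
    base.update(overrides)
    return ControllerConfig.model_validate(base)


def load_config(path: str | Path) -> ControllerConfig:
    """Load and validate a YAML controller configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return ControllerConfig.model_validate(raw)
    except Exception as exc:  # surface pydantic detail with the file name
        raise ConfigError(f"{path}: {exc}") from exc
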