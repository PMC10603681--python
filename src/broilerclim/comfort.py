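"""Felt-temperature model for broilers.

The temperature a broiler effectively experiences (the *felt temperature*
``tf``) differs from the measured air temperature ``ti``: moving air cools
the bird (wind-chill correction ``tcw``), while excess humidity impedes
evaporative heat loss and makes the air feel warmer (humidity correction
``tcRH``)::

    tf = ti - tcw + tcRH

Both corrections come from empirical lookup grids — a wind-chill table for
adult (7-week-old) birds over air temperature x air speed, and a humidity
table over air temperature x excess-RH bin.  Younger birds feel wind chill
less strongly; a dimensionless age-scale factor attenuates ``tcw`` for them.
The age-dependent comfort band (``tmin``/``topt``/``tmax`` plus an RH band)
comes from a schedule of rearing setpoints.

All knowledge lives in :class:`ComfortTables`, loaded from the packaged CSV
grids by :func:`load_tables`; every grid is user-overridable.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Setpoints",
    "WindChillGrid",
    "RHCorrectionGrid",
    "ComfortTables",
    "load_tables",
    "setpoints",
    "wind_chill",
    "wind_chill_ex",
    "rh_correction",
    "felt_temperature",
    "felt_temperature_parts",
    "optimal_airspeed",
    "max_airspeed",
    "ZOPT_GRID_STEP",
]

#: resolution of the air-speed search grid used by :func:`optimal_airspeed`,
#: in m/s — finer than any real fan-bank actuator step.
ZOPT_GRID_STEP = 0.05

#: air speeds at or below this value do not affect the felt temperature.
SAF_NEUTRAL = 0.5


class ComfortInputError(ValueError):
    """Raised for physically impossible sensor inputs (negative air speed,
    RH outside [0, 100])."""


@dataclass(frozen=True)
class Setpoints:
    """Comfort band for one age: temperatures in °C, RH band in percent."""

    tmin: float
    tmax: float
    topt: float
    rh_min: float
    rh_max: float

    def __post_init__(self) -> None:
        if not (self.tmin <= self.topt <= self.tmax):
            raise ValueError(f"require tmin <= topt <= tmax, got {self}")
        if not (0 < self.rh_min <= self.rh_max <= 100):
            raise ValueError(f"require 0 < rh_min <= rh_max <= 100, got {self}")


@dataclass(frozen=True)
class AgeBand:
    """One row of the setpoint schedule; ``age_max=None`` means open-ended."""

    age_min: int
    age_max: int | None
    setpoints: Setpoints

    def contains(self, ts1: float) -> bool:
        return ts1 >= self.age_min and (self.age_max is None or ts1 <= self.age_max)


@dataclass(frozen=True)
class WindChillGrid:
    """Wind-chill corrections tcw(ti, SAF) for 7-week-old broilers.

    ``values`` is indexed [ti ascending, SAF ascending]; undefined
    (never-commanded) cells hold NaN.
    """

    ti_axis: np.ndarray       # ascending, °C
    saf_axis: np.ndarray      # ascending, m/s
    values: np.ndarray        # shape (len(ti_axis), len(saf_axis)), NaN = undefined

    def max_defined_saf(self, row: int) -> float:
        """Largest air speed with a defined cell in grid row *row*."""
        defined = np.where(~np.isnan(self.values[row]))[0]
        return float(self.saf_axis[defined[-1]])

    def lookup(self, ti: float, saf: float) -> float:
        """Exact cell lookup; both coordinates must be on-grid and defined."""
        i = int(np.argmin(np.abs(self.ti_axis - ti)))
        j = int(np.argmin(np.abs(self.saf_axis - saf)))
        v = self.values[i, j]
        if math.isnan(v):
            raise KeyError(f"cell (ti={ti}, SAF={saf}) is undefined")
        return float(v)


@dataclass(frozen=True)
class RHCorrectionGrid:
    """Humidity corrections tcRH(ti, ΔRH-bin).

    Bins are half-open intervals on the RH excess ΔRH = RH - RHmax(age):
    (1, 5], (5, 10], ..., (25, inf).  ``bin_edges`` stores the upper edges
    with ``inf`` for the last, open-ended bin.
    """

    ti_axis: np.ndarray       # ascending, °C
    bin_edges: np.ndarray     # upper edges, last = inf
    values: np.ndarray        # shape (len(ti_axis), len(bin_edges))

    def bin_index(self, drh: float) -> int:
        for j, edge in enumerate(self.bin_edges):
            if drh <= edge:
                return j
        return len(self.bin_edges) - 1

    def lookup(self, ti: float, drh: float) -> float:
        """Exact row lookup (ti must be on-grid)."""
        i = int(np.argmin(np.abs(self.ti_axis - ti)))
        return float(self.values[i, self.bin_index(drh)])


def _interp_breakpoints(x: float, pts: Sequence[tuple[float, float]]) -> float:
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    return float(np.interp(x, xs, ys))


# Younger birds have sparser plumage yet much smaller bodies; the net effect
# is a weaker wind-chill response.  The true age-specific grids are not
# published, so by default the adult grid is attenuated linearly from 0.3 at
# day 1 to 1.0 at day 35.  Supply your own breakpoints (or full grids) to
# override this stand-in.
DEFAULT_AGE_SCALE: tuple[tuple[float, float], ...] = ((1, 0.3), (35, 1.0))

# Maximum permissible tunnel air speed by age: 0.8 m/s through the first
# week, rising linearly to 2.5 m/s for adults (7 weeks on).
DEFAULT_ZMAX: tuple[tuple[float, float], ...] = ((1, 0.8), (7, 0.8), (49, 2.5))


@dataclass(frozen=True)
class ComfortTables:
    """The complete felt-temperature knowledge base."""

    setpoint_schedule: tuple[AgeBand, ...]
    wind_chill: WindChillGrid
    rh_correction: RHCorrectionGrid
    age_scale_points: tuple[tuple[float, float], ...] = DEFAULT_AGE_SCALE
    zmax_points: tuple[tuple[float, float], ...] = DEFAULT_ZMAX

    def age_scale(self, ts1: float) -> float:
        """Dimensionless attenuation of the adult wind-chill grid."""
        return _interp_breakpoints(ts1, self.age_scale_points)

    def zmax(self, ts1: float) -> float:
        """Maximum permissible air speed (m/s) for age *ts1* (days)."""
        return _interp_breakpoints(ts1, self.zmax_points)


# ---------------------------------------------------------------------------
# loading


def _read_rows(path_or_trav) -> list[list[str]]:
    if hasattr(path_or_trav, "open"):
        with path_or_trav.open("r", encoding="utf-8") as fh:
            return [row for row in csv.reader(fh)]
    with open(path_or_trav, encoding="utf-8") as fh:
        return [row for row in csv.reader(fh)]


def _parse_setpoints(rows: list[list[str]]) -> tuple[AgeBand, ...]:
    bands = []
    for row in rows[1:]:
        age_min = int(row[0])
        age_max = int(row[1]) if row[1].strip() else None
        tmax, tmin = float(row[2]), float(row[3])
        rh_min, rh_max = float(row[4]), float(row[5])
        sp = Setpoints(tmin=tmin, tmax=tmax, topt=(tmin + tmax) / 2.0,
                       rh_min=rh_min, rh_max=rh_max)
        bands.append(AgeBand(age_min, age_max, sp))
    bands.sort(key=lambda b: b.age_min)
    for a, b in zip(bands, bands[1:]):
        if a.age_max is None or b.age_min != a.age_max + 1:
            raise ValueError("setpoint schedule age bands must tile 1..inf")
    if bands[-1].age_max is not None:
        raise ValueError("last setpoint band must be open-ended")
    return tuple(bands)


def _parse_wind_chill(rows: list[list[str]]) -> WindChillGrid:
    saf_axis = np.array([float(x) for x in rows[0][1:]])
    ti, vals = [], []
    for row in rows[1:]:
        ti.append(float(row[0]))
        vals.append([float(x) if x.strip() else math.nan for x in row[1:]])
    ti_arr = np.array(ti)
    order = np.argsort(ti_arr)
    return WindChillGrid(ti_axis=ti_arr[order], saf_axis=saf_axis,
                         values=np.array(vals)[order])


def _parse_rh_correction(rows: list[list[str]]) -> RHCorrectionGrid:
    edges = np.array([math.inf if x == "inf" else float(x) for x in rows[0][1:]])
    ti, vals = [], []
    for row in rows[1:]:
        ti.append(float(row[0]))
        vals.append([float(x) for x in row[1:]])
    ti_arr = np.array(ti)
    order = np.argsort(ti_arr)
    return RHCorrectionGrid(ti_axis=ti_arr[order], bin_edges=edges,
                            values=np.array(vals)[order])


def load_tables(directory: str | Path | None = None) -> ComfortTables:
    """Load the comfort knowledge base.

    With no argument, loads the packaged grids; pass a directory containing
    ``table1_setpoints.csv``, ``table2_wind_chill.csv`` and
    ``table3_rh_correction.csv`` (same dialect: comma-separated, header row,
    empty field = undefined cell) to substitute your own.
    """
    if directory is None:
        root = resources.files("broilerclim").joinpath("data")
    else:
        root = Path(directory)
    sched = _parse_setpoints(_read_rows(root.joinpath("table1_setpoints.csv")))
    wc = _parse_wind_chill(_read_rows(root.joinpath("table2_wind_chill.csv")))
    rh = _parse_rh_correction(_read_rows(root.joinpath("table3_rh_correction.csv")))
    return ComfortTables(setpoint_schedule=sched, wind_chill=wc, rh_correction=rh)


# ---------------------------------------------------------------------------
# operations


def setpoints(ts1: float, tables: ComfortTables) -> Setpoints:
    """Comfort band for a flock aged *ts1* days.

    Ages beyond the last tabulated band use the open-ended final row.
    """
    if ts1 < 1:
        raise ComfortInputError(f"broiler age must be >= 1 day, got {ts1}")
    for band in tables.setpoint_schedule:
        if band.contains(ts1):
            return band.setpoints
    return tables.setpoint_schedule[-1].setpoints  # pragma: no cover


def wind_chill_ex(ti: float, saf: float, ts1: float,
                  tables: ComfortTables) -> tuple[float, bool]:
    """Wind-chill correction tcw in °C plus an out-of-envelope flag.

    Bilinear interpolation on the adult grid, attenuated by the age scale.
    Inputs are clamped to the grid hull.  Cold-and-fast combinations fall in
    the grid's undefined region (speeds a controller must never command at
    that temperature); these are evaluated at the nearest defined speed for
    each bounding temperature row and flagged ``True``.
    """
    if saf < 0:
        raise ComfortInputError(f"air speed must be >= 0, got {saf}")
    grid = tables.wind_chill
    if saf <= SAF_NEUTRAL or ti >= grid.ti_axis[-1]:
        return 0.0, False

    ti_c = float(np.clip(ti, grid.ti_axis[0], grid.ti_axis[-1]))
    saf_c = float(np.clip(saf, grid.saf_axis[0], grid.saf_axis[-1]))

    i1 = int(np.searchsorted(grid.ti_axis, ti_c, side="right"))
    i1 = min(max(i1, 1), len(grid.ti_axis) - 1)
    i0 = i1 - 1

    flagged = False
    row_vals = []
    for i in (i0, i1):
        saf_max = grid.max_defined_saf(i)
        s = saf_c
        if s > saf_max:
            s = saf_max
            flagged = True
        row = grid.values[i]
        defined = ~np.isnan(row)
        row_vals.append(float(np.interp(s, grid.saf_axis[defined], row[defined])))

    t0, t1 = grid.ti_axis[i0], grid.ti_axis[i1]
    w = 0.0 if t1 == t0 else (ti_c - t0) / (t1 - t0)
    tcw = (1 - w) * row_vals[0] + w * row_vals[1]
    return tcw * tables.age_scale(ts1), flagged


def wind_chill(ti: float, saf: float, ts1: float, tables: ComfortTables) -> float:
    """Wind-chill correction tcw in °C (see :func:`wind_chill_ex`)."""
    return wind_chill_ex(ti, saf, ts1, tables)[0]


def rh_correction(ti: float, rh: float, ts1: float, tables: ComfortTables) -> float:
    """Humidity correction tcRH in °C.

    The excess ΔRH = RH - RHmax(age) selects a column bin (no effect for
    ΔRH <= 1); the correction is interpolated linearly in ti between the
    grid's 1 °C rows, with ti clamped to the grid range.
    """
    if not 0 <= rh <= 100:
        raise ComfortInputError(f"RH must be in [0, 100], got {rh}")
    sp = setpoints(ts1, tables)
    drh = rh - sp.rh_max
    if drh <= 1:
        return 0.0
    grid = tables.rh_correction
    j = grid.bin_index(drh)
    ti_c = float(np.clip(ti, grid.ti_axis[0], grid.ti_axis[-1]))
    return float(np.interp(ti_c, grid.ti_axis, grid.values[:, j]))


def felt_temperature(ti: float, saf: float, rh: float, ts1: float,
                     tables: ComfortTables) -> float:
    """Felt temperature tf = ti - tcw + tcRH, in °C."""
    return ti - wind_chill(ti, saf, ts1, tables) + rh_correction(ti, rh, ts1, tables)


def felt_temperature_parts(ti: float, saf: float, rh: float, ts1: float,
                           tables: ComfortTables) -> dict[str, float]:
    """``{"tf": ..., "tcw": ..., "tcRH": ...}`` for diagnostics and the CLI."""
    tcw = wind_chill(ti, saf, ts1, tables)
    tcrh = rh_correction(ti, rh, ts1, tables)
    return {"tf": ti - tcw + tcrh, "tcw": tcw, "tcRH": tcrh}


def max_airspeed(ts1: float, tables: ComfortTables) -> float:
    """Maximum permissible air speed Zmax (m/s) for age *ts1*."""
    if ts1 < 1:
        raise ComfortInputError(f"broiler age must be >= 1 day, got {ts1}")
    return tables.zmax(ts1)


def optimal_airspeed(ti: float, rh: float, ts1: float,
                     tables: ComfortTables) -> tuple[float, bool]:
    """Smallest air speed Zopt whose felt temperature is at or below topt.

    Scans a 0.05 m/s grid from the neutral speed (0.5 m/s) up to the
    age-dependent maximum.  Returns ``(zopt, saturated)``: when even Zmax
    cannot pull tf down to topt the pair is ``(zmax, True)``.
    """
    sp = setpoints(ts1, tables)
    zmax = tables.zmax(ts1)
    n = int(round((zmax - SAF_NEUTRAL) / ZOPT_GRID_STEP))
    for k in range(n + 1):
        z = min(SAF_NEUTRAL + k * ZOPT_GRID_STEP, zmax)
        if felt_temperature(ti, z, rh, ts1, tables) <= sp.topt:
            return z, False
    return zmax, True
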