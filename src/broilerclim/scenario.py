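"""Trace files, event logs, replay and the expectations comparator.

The transport-neutral equivalent of the live sensor feed is a CSV trace
(comma separator, header row, '.' decimal, UTF-8, time in seconds).  The
controller replays a trace into a JSON-lines event log; an expectations
file (YAML) encodes what a correct controller must have done — mode
transitions, actuator values, alert texts — inside time windows, and
:func:`compare_events` grades the log against it.

The packaged bench-test fixture (``table5_trace.csv`` + matching config and
expectations) turns the published minute-by-minute test narrative into an
executable regression test.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .comfort import ComfortTables, load_tables, setpoints
from .config import ControllerConfig, load_config
from .control import (ActuatorState, ControllerState, Event, Mode, SensorFrame,
                      controller_step, held_frames, new_state)
from .plant import (TRACE_COLUMNS, BuildingParams, FlockParams, PlantState,
                    make_scenario, plant_step)

__all__ = [
    "read_trace",
    "write_trace",
    "frames_to_dataframe",
    "replay_trace",
    "write_events",
    "read_events",
    "ExpectedEvent",
    "CompareReport",
    "load_expectations",
    "compare_events",
    "fixture_path",
    "load_fixture_config",
    "simulate_closed_loop",
]

REQUIRED_COLUMNS = ["time", "ti", "to", "tih", "RH", "RHout", "dp", "SAF"]
GAS_COLUMNS = ["NH3", "CO2", "CO", "H2S"]


class TraceError(ValueError):
    pass


def _fmt(x: float) -> str:
    return f"{x:g}"


def read_trace(path: str | Path) -> list[SensorFrame]:
    """Read and validate a sensor trace CSV.

    Missing gas columns default to zero (with a warning); times must be
    strictly increasing; malformed rows are reported with their line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise TraceError(f"{path}: empty trace file") from None
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise TraceError(f"{path}: missing required columns {missing}")
        absent_gas = [c for c in GAS_COLUMNS if c not in header]
        if absent_gas:
            warnings.warn(f"{path}: gas columns {absent_gas} absent, assuming 0",
                          stacklevel=2)
        idx = {c: header.index(c) for c in header}
        frames: list[SensorFrame] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                vals = {c: float(row[idx[c]].strip()) for c in header}
            except (ValueError, IndexError) as exc:
                raise TraceError(f"{path}:{lineno}: malformed row: {exc}") from None
            frames.append(SensorFrame(
                t=int(vals["time"]), ti=vals["ti"], to=vals["to"],
                tih=vals["tih"], RH=vals["RH"], RHout=vals["RHout"],
                dp=vals["dp"], SAF=vals["SAF"],
                **{g: vals.get(g, 0.0) for g in GAS_COLUMNS}))
    if not frames:
        raise TraceError(f"{path}: trace contains no data rows")
    for a, b in zip(frames, frames[1:]):
        if b.t <= a.t:
            raise TraceError(f"{path}: time not strictly increasing at t={b.t}")
    return frames


def frames_to_dataframe(frames: Sequence[SensorFrame]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.t, f.ti, f.to, f.tih, f.RH, f.RHout, f.dp, f.SAF,
          f.NH3, f.CO2, f.CO, f.H2S) for f in frames],
        columns=TRACE_COLUMNS)


def write_trace(data: pd.DataFrame | Sequence[SensorFrame],
                path: str | Path) -> None:
    """Write a trace in the canonical dialect (stable float formatting, so
    read -> write round-trips byte-identically)."""
    df = data if isinstance(data, pd.DataFrame) else frames_to_dataframe(data)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for row in df[TRACE_COLUMNS].itertuples(index=False):
            fh.write(",".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# replay


def replay_trace(frames: Sequence[SensorFrame], cfg: ControllerConfig,
                 tables: ComfortTables | None = None,
                 initial_mode: Mode = Mode.M2) -> list[Event]:
    """Drive the controller over a recorded trace (sample-and-hold between
    frames) and return the full event log.  Deterministic: the same trace
    and config always produce an identical log."""
    if tables is None:
        tables = load_tables()
    source = held_frames(frames)
    state = new_state(cfg, mode=initial_mode)
    state.t = frames[0].t
    t_end = frames[-1].t
    events: list[Event] = []
    while state.t <= t_end - cfg.tick:
        _, _, ev = controller_step(state, source(state.t), cfg, tables)
        events.extend(ev)
    return events


def write_events(events: Iterable[Event], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def read_events(path: str | Path) -> list[Event]:
    events = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                events.append(Event(t=d["t"], kind=d["kind"], name=d["name"],
                                    value=d["value"]))
    return events


# ---------------------------------------------------------------------------
# expectations


@dataclass(frozen=True)
class ExpectedEvent:
    """One graded expectation: some event inside ``window`` (seconds,
    inclusive) of the given kind/name must satisfy every stated predicate."""

    window: tuple[float, float]
    kind: str
    name: str | None = None
    equals: object = None
    contains: str | None = None
    ge: float | None = None
    le: float | None = None

    def __post_init__(self) -> None:
        if self.window[0] < 0 or self.window[1] < self.window[0]:
            raise ValueError(f"bad expectation window {self.window}")

    def matches(self, ev: Event) -> bool:
        if ev.kind != self.kind:
            return False
        if self.name is not None and ev.name != self.name:
            return False
        if self.equals is not None:
            a, b = ev.value, self.equals
            if isinstance(a, bool) or isinstance(b, bool):
                if bool(a) != bool(b):
                    return False
            elif isinstance(a, (int, float)) and isinstance(b, (int, float)):
                if float(a) != float(b):
                    return False
            elif str(a) != str(b):
                return False
        if self.contains is not None and self.contains not in str(ev.value):
            return False
        if self.ge is not None and not float(ev.value) >= self.ge:
            return False
        if self.le is not None and not float(ev.value) <= self.le:
            return False
        return True

    def describe(self) -> str:
        preds = []
        if self.equals is not None:
            preds.append(f"== {self.equals!r}")
        if self.contains is not None:
            preds.append(f"contains {self.contains!r}")
        if self.ge is not None:
            preds.append(f">= {self.ge}")
        if self.le is not None:
            preds.append(f"<= {self.le}")
        what = self.kind if self.name is None else f"{self.kind}:{self.name}"
        return f"[{self.window[0]:g}-{self.window[1]:g}s] {what} {' '.join(preds)}"


def load_expectations(path: str | Path) -> list[ExpectedEvent]:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or []
    out = []
    for item in raw:
        out.append(ExpectedEvent(
            window=(float(item["window"][0]), float(item["window"][1])),
            kind=item["kind"], name=item.get("name"),
            equals=item.get("equals"), contains=item.get("contains"),
            ge=item.get("ge"), le=item.get("le")))
    return out


@dataclass(frozen=True)
class CompareReport:
    entries: tuple[tuple[ExpectedEvent, bool, str], ...]

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.entries)

    @property
    def n_failed(self) -> int:
        return sum(not passed for _, passed, _ in self.entries)

    def render(self) -> str:
        lines = []
        for exp, passed, detail in self.entries:
            mark = "PASS" if passed else "FAIL"
            lines.append(f"{mark}  {exp.describe()}" + (f"  ({detail})" if detail else ""))
        lines.append(f"{len(self.entries) - self.n_failed}/{len(self.entries)} expectations met")
        return "\n".join(lines)


def compare_events(actual: Sequence[Event], expected: Sequence[ExpectedEvent],
                   t_max: float | None = None) -> CompareReport:
    """Grade an event log against expectations.  ``t_max`` (normally the
    trace end) turns expectations whose window starts later into explicit
    failures rather than silent vacuous ones."""
    entries = []
    for exp in expected:
        if t_max is not None and exp.window[0] > t_max:
            entries.append((exp, False, "window beyond trace"))
            continue
        hits = [ev for ev in actual if exp.window[0] <= ev.t <= exp.window[1]]
        if any(exp.matches(ev) for ev in hits):
            entries.append((exp, True, ""))
        else:
            near = "; ".join(f"{ev.t}s {ev.kind}:{ev.name}={ev.value}"
                             for ev in hits[:4]) or "no events in window"
            entries.append((exp, False, near))
    return CompareReport(entries=tuple(entries))


# ---------------------------------------------------------------------------
# packaged fixtures


def fixture_path(name: str) -> Path:
    """Path to a packaged data/fixture file (e.g. ``table5_trace.csv``)."""
    return Path(str(resources.files("broilerclim").joinpath("data", name)))


def load_fixture_config() -> ControllerConfig:
    """The bench-test controller configuration (14-day flock, seven blind
    positions, the sample blind/fan maps of the experimental stage)."""
    return load_config(fixture_path("table5_config.yaml"))


# ---------------------------------------------------------------------------
# closed loop


def simulate_closed_loop(cfg: ControllerConfig,
                         weather: pd.DataFrame,
                         flock: FlockParams,
                         bldg: BuildingParams,
                         duration_s: int,
                         tables: ComfortTables | None = None,
                         initial: PlantState | None = None,
                         record_every: int = 30,
                         ) -> tuple[pd.DataFrame, list[Event], dict]:
    """Run controller and plant against each other.

    *weather* supplies outdoor conditions (columns ``time``, ``to``,
    ``RHout``; sample-and-hold).  Returns the recorded sensor trace, the
    event log and a run summary (band occupancy, mode seconds, alerts).
    """
    if tables is None:
        tables = load_tables()
    if not bldg.euler_stable(cfg.tick):
        raise ValueError("tick too long for stable integration of this building")
    wt = weather["time"].to_numpy(dtype=float)
    wto = weather["to"].to_numpy(dtype=float)
    wrh = weather["RHout"].to_numpy(dtype=float)

    plant = initial if initial is not None else PlantState()
    state = new_state(cfg)
    events: list[Event] = []
    rows = []
    mode_seconds: dict[str, int] = {}
    sp = setpoints(cfg.flock.age_days, tables)
    in_band = 0

    for t in range(0, duration_s, cfg.tick):
        k = int(np.searchsorted(wt, t, side="right")) - 1
        k = max(k, 0)
        to, rhout = float(wto[k]), float(min(max(wrh[k], 0.0), 100.0))
        frame = SensorFrame(t=t, ti=plant.ti, to=to, tih=plant.tih,
                            RH=plant.RH, RHout=rhout, dp=plant.dp,
                            SAF=plant.SAF, CO2=plant.CO2)
        state, act, ev = controller_step(state, frame, cfg, tables)
        events.extend(ev)
        mode_seconds[state.mode.value] = mode_seconds.get(state.mode.value, 0) + cfg.tick
        if sp.tmin <= plant.ti <= sp.tmax:
            in_band += cfg.tick
        if t % record_every == 0:
            rows.append((t, plant.ti, to, plant.tih, plant.RH, rhout,
                         plant.dp, plant.SAF, 0.0, plant.CO2, 0.0, 0.0))
        plant = plant_step(plant, act, (to, rhout), flock, bldg, cfg.tick)

    trace = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    summary = {
        "duration_s": duration_s,
        "fraction_in_band": round(in_band / max(duration_s, 1), 4),
        "mode_seconds": mode_seconds,
        "n_alerts": sum(1 for e in events if e.kind == "alert"),
        "final_ti": round(plant.ti, 2),
        "final_RH": round(plant.RH, 1),
        "final_CO2": round(plant.CO2, 0),
    }
    return trace, events, summary
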