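"""Session files: one JSONL document per participant per test.

The first line is the header (schema version, participant, calibration,
grid, full schedules, seed, parameter hash); every following line is one
event with its millisecond timestamp, kind, trial index, and payload.
Floats round-trip exactly (shortest-repr JSON encoding), so a written
session re-reads byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Union

from .geometry import Calibration, LocationGrid, MotionSpec, Vec3
from .protocol import TaskSchedule, TrialSpec
from .simulant import Event, EventLog

SCHEMA_VERSION = "reachtime-session/1"


class SessionFormatError(ValueError):
    """Unparseable or schema-violating session file; names the line."""


def _vec_to_list(v: Vec3) -> list[float]:
    return [v.x, v.y, v.z]


def _vec_from_list(x: Any) -> Vec3:
    return Vec3(float(x[0]), float(x[1]), float(x[2]))


def _motion_to_dict(m: MotionSpec) -> dict[str, Any]:
    return {"origin_index": m.origin_index, "target_index": m.target_index, "speed": m.speed}


def _motion_from_dict(d: dict[str, Any]) -> MotionSpec:
    return MotionSpec(
        origin_index=int(d["origin_index"]),
        target_index=int(d["target_index"]),
        speed=float(d["speed"]),
    )


def _trial_to_dict(t: TrialSpec) -> dict[str, Any]:
    d: dict[str, Any] = {
        "task": t.task,
        "index": t.index,
        "is_training": t.is_training,
        "color": t.color,
        "is_go": t.is_go,
        "display_ms": t.display_ms,
        "isi_ms": t.isi_ms,
    }
    if t.location_index is not None:
        d["location_index"] = t.location_index
    if t.motion is not None:
        d["motion"] = _motion_to_dict(t.motion)
    return d


def _trial_from_dict(d: dict[str, Any]) -> TrialSpec:
    return TrialSpec(
        task=d["task"],
        index=int(d["index"]),
        is_training=bool(d["is_training"]),
        color=d["color"],
        is_go=bool(d["is_go"]),
        display_ms=float(d["display_ms"]),
        isi_ms=float(d["isi_ms"]),
        location_index=d.get("location_index"),
        motion=_motion_from_dict(d["motion"]) if "motion" in d else None,
    )


def _header_dict(log: EventLog) -> dict[str, Any]:
    return {
        "schema": SCHEMA_VERSION,
        "participant": log.participant,
        "seed": log.seed,
        "params_hash": log.params_hash,
        "calibration": {
            "location_b": _vec_to_list(log.calibration.location_b),
            "location_r": _vec_to_list(log.calibration.location_r),
            "distance_d": log.calibration.distance_d,
        },
        "grid": {
            "locations": [_vec_to_list(p) for p in log.grid.locations],
            "elevation_deg": log.grid.elevation_deg,
            "azimuth_deg": log.grid.azimuth_deg,
        },
        "schedules": [
            {
                "task": s.task,
                "rng_seed": s.rng_seed,
                "trials": [_trial_to_dict(t) for t in s.trials],
            }
            for s in log.schedules
        ],
    }


def _event_dict(e: Event) -> dict[str, Any]:
    d: dict[str, Any] = {"t": e.t, "kind": e.kind, "trial": e.trial_index}
    if e.payload:
        d["payload"] = dict(e.payload)
    return d


def dumps_session(log: EventLog) -> str:
    """Serialize a session to its JSONL text (deterministic key order)."""
    lines = [json.dumps(_header_dict(log), sort_keys=True)]
    lines.extend(json.dumps(_event_dict(e), sort_keys=True) for e in log.events)
    return "\n".join(lines) + "\n"


def write_session(log: EventLog, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(dumps_session(log))
    return path


def _parse_line(raw: str, lineno: int) -> dict[str, Any]:
    try:
        obj = json.loads(raw)
    except json.JSONDecodeError as err:
        raise SessionFormatError(
            f"line {lineno}: invalid JSON (last valid line is {lineno - 1}): {err}"
        ) from err
    if not isinstance(obj, dict):
        raise SessionFormatError(f"line {lineno}: expected a JSON object")
    return obj


def loads_session(text: str) -> EventLog:
    """Parse a session document, validating schema and event ordering."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SessionFormatError("line 1: empty file, header missing")
    head = _parse_line(lines[0], 1)
    if head.get("schema") != SCHEMA_VERSION:
        raise SessionFormatError(
            f"line 1: schema {head.get('schema')!r} != {SCHEMA_VERSION!r}"
        )
    cal = Calibration(
        location_b=_vec_from_list(head["calibration"]["location_b"]),
        location_r=_vec_from_list(head["calibration"]["location_r"]),
        distance_d=float(head["calibration"]["distance_d"]),
    )
    grid = LocationGrid(
        locations=tuple(_vec_from_list(p) for p in head["grid"]["locations"]),
        elevation_deg=float(head["grid"]["elevation_deg"]),
        azimuth_deg=float(head["grid"]["azimuth_deg"]),
    )
    schedules = tuple(
        TaskSchedule(
            task=s["task"],
            rng_seed=int(s["rng_seed"]),
            trials=tuple(_trial_from_dict(t) for t in s["trials"]),
        )
        for s in head["schedules"]
    )
    n_trials = sum(len(s.trials) for s in schedules)

    events: list[Event] = []
    prev_t: Optional[float] = None
    for lineno, raw in enumerate(lines[1:], start=2):
        obj = _parse_line(raw, lineno)
        try:
            ev = Event(
                t=float(obj["t"]),
                kind=obj["kind"],
                trial_index=int(obj["trial"]),
                payload=obj.get("payload", {}),
            )
        except (KeyError, ValueError) as err:
            raise SessionFormatError(f"line {lineno}: bad event: {err}") from err
        if prev_t is not None and ev.t < prev_t:
            raise SessionFormatError(
                f"line {lineno}: timestamps not monotone ({ev.t} < {prev_t})"
            )
        if not 0 <= ev.trial_index < n_trials:
            raise SessionFormatError(
                f"line {lineno}: trial {ev.trial_index} not in header schedules"
            )
        prev_t = ev.t
        events.append(ev)

    return EventLog(
        participant=head["participant"],
        calibration=cal,
        grid=grid,
        schedules=schedules,
        seed=int(head["seed"]),
        params_hash=head["params_hash"],
        events=tuple(events),
    )


def read_session(path: Union[str, Path]) -> EventLog:
    return loads_session(Path(path).read_text())
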