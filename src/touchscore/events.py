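"""Touch-event stream I/O.

Defines the raw capture model of a multi-touch assessment: timestamped
pointer ``down``/``move``/``up`` events in screen pixels, the device
profile that converts pixels to centimetres, the session wrapper (one
participant x exercise x attempt), and the tidy outcome table written by
the scorers.

Event logs are JSONL, one object per event::

    {"t_ms": 0, "pointer_id": 0, "phase": "down", "x_px": 512.0, "y_px": 300.0}

with ``t_ms`` counted from the start signal of the exercise.  A session
manifest (JSON) carries the metadata: participant, exercise, hand,
session index, rater, timing window, optional calibration point (cm) and
the device profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import StreamParseError, StreamValidationError

PHASES = ("down", "move", "up")

FINGERS = ("thumb", "index", "middle", "ring", "little")
PINCER_FINGERS = ("index", "middle", "ring", "little")
GRAPHO_FIGURES = ("M", "3", "S", "spiral")
OCULO_CONDITIONS = ("finger", "pen", "pen_drop")

ISO_TAP_IDS = tuple(f"iso_tap_{f}" for f in FINGERS)
PINCER_IDS = tuple(f"pincer_{f}" for f in PINCER_FINGERS)
GRAPHO_IDS = tuple(f"grapho_{f}" for f in GRAPHO_FIGURES)
OCULO_IDS = tuple(f"oculo_{c}" for c in OCULO_CONDITIONS)

EXERCISE_IDS = frozenset(
    ("tapping", "open_close") + ISO_TAP_IDS + PINCER_IDS + GRAPHO_IDS + OCULO_IDS
)

#: canonical units per outcome measure
MEASURE_UNITS = {
    "tap_count": "n",
    "valid_tap_count": "n",
    "pincer_max_cm": "cm",
    "pincer_min_cm": "cm",
    "area_max_cm2": "cm2",
    "area_min_cm2": "cm2",
    "dissimilarity_cm": "cm",
    "completion_s": "s",
}

OUTCOME_COLUMNS = [
    "participant_id",
    "exercise_id",
    "measure_name",
    "value",
    "units",
    "session_idx",
    "rater_id",
]


@dataclass(frozen=True)
class TouchEvent:
    """A single pointer event in screen pixels, time in ms from start."""

    t_ms: int
    pointer_id: int
    phase: str
    x_px: float
    y_px: float

    def __post_init__(self):
        if self.t_ms < 0:
            raise StreamValidationError(f"negative t_ms {self.t_ms}")
        if self.pointer_id < 0:
            raise StreamValidationError(f"negative pointer_id {self.pointer_id}")
        if self.phase not in PHASES:
            raise StreamValidationError(f"unknown phase {self.phase!r}")
        if not (math.isfinite(self.x_px) and math.isfinite(self.y_px)):
            raise StreamValidationError("non-finite coordinates")


@dataclass(frozen=True)
class DeviceProfile:
    """Screen geometry and pixel density of the capture device.

    Pixel density is per axis because real panels are not perfectly
    isotropic.  There is deliberately no default: density must come from
    the hardware, never be guessed.
    """

    screen_w_px: int
    screen_h_px: int
    px_per_cm_x: float
    px_per_cm_y: float

    def __post_init__(self):
        for name in ("screen_w_px", "screen_h_px", "px_per_cm_x", "px_per_cm_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def width_cm(self) -> float:
        return self.screen_w_px / self.px_per_cm_x

    @property
    def height_cm(self) -> float:
        return self.screen_h_px / self.px_per_cm_y


def to_cm(event: TouchEvent, device: DeviceProfile) -> tuple[float, float]:
    """Convert an event's pixel coordinates to centimetres."""
    return (event.x_px / device.px_per_cm_x, event.y_px / device.px_per_cm_y)


def cm_to_px(x_cm: float, y_cm: float, device: DeviceProfile) -> tuple[float, float]:
    """Inverse of :func:`to_cm` for a bare point."""
    return (x_cm * device.px_per_cm_x, y_cm * device.px_per_cm_y)


@dataclass(frozen=True)
class ExerciseSession:
    """One participant x exercise x attempt: events plus metadata."""

    participant_id: str
    exercise_id: str
    hand: str
    session_idx: int
    rater_id: str
    events: tuple[TouchEvent, ...]
    device: DeviceProfile
    duration_s: float | None = None
    calibration: tuple[float, float] | None = None  # spot centre, cm

    def __post_init__(self):
        if self.exercise_id not in EXERCISE_IDS:
            raise ValueError(f"unknown exercise_id {self.exercise_id!r}")
        if self.hand not in ("left", "right"):
            raise ValueError(f"hand must be left/right, got {self.hand!r}")
        if self.session_idx < 1:
            raise ValueError("session_idx must be >= 1")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be > 0 when given")
        object.__setattr__(self, "events", tuple(self.events))
        validate_events(self.events, self.device)


@dataclass(frozen=True)
class OutcomeRecord:
    """One scored outcome measure for one session."""

    participant_id: str
    exercise_id: str
    measure_name: str
    value: float
    units: str
    session_idx: int
    rater_id: str

    def __post_init__(self):
        expected = MEASURE_UNITS.get(self.measure_name)
        if expected is not None and self.units != expected:
            raise ValueError(
                f"measure {self.measure_name!r} expects units {expected!r}, "
                f"got {self.units!r}"
            )
        if self.units == "n":
            if self.value < 0 or self.value != int(self.value):
                raise ValueError("count measures must be non-negative integers")
        elif self.value < 0:
            raise ValueError("distances, areas and times must be non-negative")


def sort_events(events: Iterable[TouchEvent]) -> tuple[TouchEvent, ...]:
    """Sort by t_ms, stable on ties (preserves input order at equal t)."""
    return tuple(sorted(events, key=lambda e: e.t_ms))


def validate_events(
    events: Sequence[TouchEvent], device: DeviceProfile | None = None
) -> None:
    """Check the per-pointer phase grammar and screen bounds.

    Per pointer lifetime the phase sequence must be exactly
    ``down (move)* up``; pointer ids may be reused after ``up``.  Raises
    :class:`StreamValidationError` on the first violation.
    """
    last_t = None
    active: set[int] = set()
    for ev in events:
        if last_t is not None and ev.t_ms < last_t:
            raise StreamValidationError(
                f"events not sorted by t_ms at t={ev.t_ms}", ev.pointer_id
            )
        last_t = ev.t_ms
        if ev.phase == "down":
            if ev.pointer_id in active:
                raise StreamValidationError(
                    "down while pointer already in contact", ev.pointer_id
                )
            active.add(ev.pointer_id)
        else:
            if ev.pointer_id not in active:
                raise StreamValidationError(
                    f"{ev.phase} without preceding down", ev.pointer_id
                )
            if ev.phase == "up":
                active.remove(ev.pointer_id)
        if device is not None:
            if not (0 <= ev.x_px <= device.screen_w_px) or not (
                0 <= ev.y_px <= device.screen_h_px
            ):
                raise StreamValidationError(
                    f"coordinates ({ev.x_px}, {ev.y_px}) outside screen bounds",
                    ev.pointer_id,
                )
    if active:
        pid = sorted(active)[0]
        raise StreamValidationError("pointer never lifted (missing up)", pid)


# ---------------------------------------------------------------------------
# JSONL event logs


def read_events(path: str | Path) -> tuple[TouchEvent, ...]:
    """Parse a JSONL event log; events are returned sorted by t_ms."""
    events = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                ev = TouchEvent(
                    t_ms=int(obj["t_ms"]),
                    pointer_id=int(obj["pointer_id"]),
                    phase=str(obj["phase"]),
                    x_px=float(obj["x_px"]),
                    y_px=float(obj["y_px"]),
                )
            except StreamValidationError:
                raise
            except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
                raise StreamParseError(str(exc), line_no) from exc
            events.append(ev)
    return sort_events(events)


def write_events(events: Sequence[TouchEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(json.dumps(asdict(ev)) + "\n")


def read_stream(
    path: str | Path,
    device: DeviceProfile,
    *,
    participant_id: str = "unknown",
    exercise_id: str = "tapping",
    hand: str = "right",
    session_idx: int = 1,
    rater_id: str = "unknown",
    duration_s: float | None = None,
    calibration: tuple[float, float] | None = None,
) -> ExerciseSession:
    """Read a JSONL event log into a validated :class:`ExerciseSession`.

    Session metadata not present in the log itself is supplied by keyword
    (or use :func:`read_session` with a manifest file).
    """
    events = read_events(path)
    return ExerciseSession(
        participant_id=participant_id,
        exercise_id=exercise_id,
        hand=hand,
        session_idx=session_idx,
        rater_id=rater_id,
        events=events,
        device=device,
        duration_s=duration_s,
        calibration=calibration,
    )


# ---------------------------------------------------------------------------
# manifests and device profiles


def device_to_dict(device: DeviceProfile) -> dict:
    return asdict(device)


def device_from_dict(obj: dict) -> DeviceProfile:
    return DeviceProfile(
        screen_w_px=int(obj["screen_w_px"]),
        screen_h_px=int(obj["screen_h_px"]),
        px_per_cm_x=float(obj["px_per_cm_x"]),
        px_per_cm_y=float(obj["px_per_cm_y"]),
    )


def load_device(path: str | Path) -> DeviceProfile:
    with open(path, encoding="utf-8") as fh:
        return device_from_dict(json.load(fh))


def write_manifest(session: ExerciseSession, path: str | Path) -> None:
    obj = {
        "participant_id": session.participant_id,
        "exercise_id": session.exercise_id,
        "hand": session.hand,
        "session_idx": session.session_idx,
        "rater_id": session.rater_id,
        "duration_s": session.duration_s,
        "calibration": list(session.calibration) if session.calibration else None,
        "device": device_to_dict(session.device),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)


def read_session(
    events_path: str | Path,
    manifest_path: str | Path,
    device: DeviceProfile | None = None,
) -> ExerciseSession:
    """Assemble a session from an event log plus its manifest.

    The manifest's embedded device profile is used unless ``device``
    overrides it.
    """
    with open(manifest_path, encoding="utf-8") as fh:
        man = json.load(fh)
    dev = device or device_from_dict(man["device"])
    calib = man.get("calibration")
    return read_stream(
        events_path,
        dev,
        participant_id=str(man["participant_id"]),
        exercise_id=str(man["exercise_id"]),
        hand=str(man["hand"]),
        session_idx=int(man["session_idx"]),
        rater_id=str(man["rater_id"]),
        duration_s=man.get("duration_s"),
        calibration=tuple(calib) if calib else None,
    )


def write_session(session: ExerciseSession, events_path, manifest_path) -> None:
    write_events(session.events, events_path)
    write_manifest(session, manifest_path)


# ---------------------------------------------------------------------------
# outcome tables


def outcomes_frame(records: Sequence[OutcomeRecord]) -> pd.DataFrame:
    """Records as a tidy long DataFrame with stable column order."""
    rows = [asdict(r) for r in records]
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def write_outcomes(records: Sequence[OutcomeRecord], path: str | Path) -> None:
    outcomes_frame(records).to_csv(path, index=False)


def read_outcomes(path: str | Path) -> list[OutcomeRecord]:
    df = pd.read_csv(path, dtype={"participant_id": str, "rater_id": str})
    if list(df.columns) != OUTCOME_COLUMNS:
        raise ValueError(f"unexpected outcome columns in {path}: {list(df.columns)}")
    return [
        OutcomeRecord(
            participant_id=str(row.participant_id),
            exercise_id=str(row.exercise_id),
            measure_name=str(row.measure_name),
            value=float(row.value),
            units=str(row.units),
            session_idx=int(row.session_idx),
            rater_id=str(row.rater_id),
        )
        for row in df.itertuples(index=False)
    ]
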