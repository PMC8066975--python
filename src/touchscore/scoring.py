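"""Scorers: turn an :class:`ExerciseSession` into outcome records.

One scorer per subtest family:

* tapping — taps in a 10-s window;
* isolated tapping — taps on a calibrated spot while the other digits
  stay in contact with the screen (weight-bearing);
* pincer grasp — max/min thumb-finger distance over two-contact frames;
* hand opening/closing — max/min convex-hull area over >=3-contact frames;
* graphomotricity — symmetric nearest-neighbour dissimilarity between
  the traced line and the template figure;
* oculo-manual coordination — time to acquire all 32 grid targets.

Frame semantics: a pointer is "in contact" at every instant of its
[down, up] interval, inclusive; its position is the most recent
coordinate at or before the instant.  Positions are piecewise-constant
between events, so evaluating extrema at every event timestamp is exact.
All scorers are pure functions of (session, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import groupby
from typing import Mapping, Sequence

import numpy as np

from .errors import IncompleteTrialError, UnscorableError
from .events import (
    ExerciseSession,
    GRAPHO_IDS,
    ISO_TAP_IDS,
    MEASURE_UNITS,
    OCULO_IDS,
    OutcomeRecord,
    PINCER_IDS,
)
from .geometry import Polyline, convex_hull_area, nearest_distances, resample
from .templates import default_target_grid, default_templates


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable scoring parameters, all in physical units.

    ``tap_window_s`` and the 4x8 target grid come from the assessment's
    protocol; spot radius, resting-contact count, resample density,
    target radius and timeout are configuration (the protocol does not
    pin them down) with defaults chosen for a 12-inch tablet.
    """

    tap_window_s: float = 10.0
    spot_radius_cm: float = 1.25
    required_resting_contacts: int = 4
    min_area_contacts: int = 3
    grapho_resample_n: int = 200
    oculo_n_targets: int = 32
    target_radius_cm: float = 1.0
    oculo_timeout_s: float = 120.0

    def __post_init__(self):
        for name in (
            "tap_window_s",
            "spot_radius_cm",
            "required_resting_contacts",
            "min_area_contacts",
            "grapho_resample_n",
            "oculo_n_targets",
            "target_radius_cm",
            "oculo_timeout_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_CONFIG = ScoringConfig()


def _require(session: ExerciseSession, allowed) -> None:
    if session.exercise_id not in allowed:
        raise ValueError(
            f"scorer expects exercise in {sorted(allowed)}, "
            f"got {session.exercise_id!r}"
        )


def _events_cm(session: ExerciseSession):
    """Events as (t_ms, pointer_id, phase, x_cm, y_cm) tuples."""
    sx, sy = session.device.px_per_cm_x, session.device.px_per_cm_y
    return [
        (e.t_ms, e.pointer_id, e.phase, e.x_px / sx, e.y_px / sy)
        for e in session.events
    ]


def _frames(session: ExerciseSession):
    """Yield (t_ms, {pointer_id: (x_cm, y_cm)}) at each event timestamp.

    All events sharing a timestamp are applied first; pointers lifting at
    t are still included in the frame at t (the up instant counts as
    contact) and removed afterwards.
    """
    active: dict[int, tuple[float, float]] = {}
    evs = _events_cm(session)
    for t, group in groupby(evs, key=lambda e: e[0]):
        ups = []
        for _, pid, phase, x, y in group:
            if phase == "up":
                ups.append(pid)
            else:
                active[pid] = (x, y)
        yield t, dict(active)
        for pid in ups:
            active.pop(pid, None)


def _lifetimes(session: ExerciseSession):
    """Per-pointer contact intervals: (pointer_id, t_down, t_up, x0_cm, y0_cm)."""
    open_at: dict[int, tuple[int, float, float]] = {}
    out = []
    for t, pid, phase, x, y in _events_cm(session):
        if phase == "down":
            open_at[pid] = (t, x, y)
        elif phase == "up":
            t0, x0, y0 = open_at.pop(pid)
            out.append((pid, t0, t, x0, y0))
    return out


# ---------------------------------------------------------------------------
# tapping


def score_tapping(session: ExerciseSession, config: ScoringConfig = DEFAULT_CONFIG) -> int:
    """Number of finger touches in the tap window (down events count)."""
    _require(session, {"tapping"})
    limit = config.tap_window_s * 1000.0
    return sum(1 for e in session.events if e.phase == "down" and 0 <= e.t_ms < limit)


def score_isolated_tapping(
    session: ExerciseSession, config: ScoringConfig = DEFAULT_CONFIG
) -> int:
    """Valid taps on the calibrated spot with the other digits weight-bearing.

    A down event inside the window counts iff (a) it lies within
    ``spot_radius_cm`` of the calibration centre and (b) at its instant at
    least ``required_resting_contacts`` *other* pointers are in contact.
    """
    _require(session, set(ISO_TAP_IDS))
    if session.calibration is None:
        raise ValueError("isolated tapping requires a calibration spot centre")
    cx, cy = session.calibration
    limit = config.tap_window_s * 1000.0
    lifetimes = _lifetimes(session)
    count = 0
    for key, (pid, t0, t1, x0, y0) in enumerate(lifetimes):
        if not (0 <= t0 < limit):
            continue
        if math.hypot(x0 - cx, y0 - cy) > config.spot_radius_cm:
            continue
        resting = sum(
            1
            for other, (opid, ot0, ot1, _, _) in enumerate(lifetimes)
            if other != key and ot0 <= t0 <= ot1
        )
        if resting >= config.required_resting_contacts:
            count += 1
    return count


# ---------------------------------------------------------------------------
# pincer grasp and hand area


def score_pincer(
    session: ExerciseSession, config: ScoringConfig = DEFAULT_CONFIG
) -> tuple[float, float]:
    """(max, min) thumb-finger distance in cm over two-contact instants.

    Frames with any other number of concurrent contacts (transient palm
    or nail contacts) are excluded rather than failing the trial.
    """
    _require(session, set(PINCER_IDS))
    dmax, dmin = -math.inf, math.inf
    for _, positions in _frames(session):
        if len(positions) != 2:
            continue
        (x1, y1), (x2, y2) = positions.values()
        d = math.hypot(x1 - x2, y1 - y2)
        dmax = max(dmax, d)
        dmin = min(dmin, d)
    if not math.isfinite(dmax):
        raise UnscorableError(
            "no instant with exactly two concurrent contacts in pincer trial"
        )
    return dmax, dmin


def score_hand_area(
    session: ExerciseSession, config: ScoringConfig = DEFAULT_CONFIG
) -> tuple[float, float]:
    """(max, min) convex-hull area in cm^2 over frames with >=3 contacts."""
    _require(session, {"open_close"})
    amax, amin = -math.inf, math.inf
    for _, positions in _frames(session):
        if len(positions) < config.min_area_contacts:
            continue
        a = convex_hull_area(list(positions.values()))
        amax = max(amax, a)
        amin = min(amin, a)
    if not math.isfinite(amax):
        raise UnscorableError(
            f"no instant with >= {config.min_area_contacts} concurrent contacts"
        )
    return amax, amin


# ---------------------------------------------------------------------------
# graphomotricity


def trace_polyline(session: ExerciseSession) -> Polyline:
    """The traced line in cm: event positions in time order.

    Multi-stroke traces are concatenated; positions are piecewise-linear
    between samples for the purposes of the dissimilarity metric.
    """
    pts = [(x, y) for _, _, _, x, y in _events_cm(session)]
    if len(pts) < 2:
        raise UnscorableError("trace has fewer than 2 points")
    return Polyline(pts)


def dissimilarity(trace: Polyline, template: Polyline, n: int = 200) -> float:
    """Symmetric summed nearest-neighbour distance between two curves (cm).

    Both curves are resampled to ``n`` arc-length-equidistant points;
    the score is ``0.5 * (sum_i d(trace_i, template) +
    sum_j d(template_j, trace))`` with distances taken to the full
    polylines.  Zero iff the curves coincide; symmetric; invariant under
    a simultaneous rigid motion of both curves.
    """
    if trace.is_degenerate or template.is_degenerate:
        raise UnscorableError("degenerate curve in dissimilarity")
    tr = resample(trace, n)
    te = resample(template, n)
    fwd = nearest_distances(tr, template).sum()
    bwd = nearest_distances(te, trace).sum()
    return 0.5 * float(fwd + bwd)


def score_graphomotricity(
    session: ExerciseSession,
    template: Polyline,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Trace-template dissimilarity in cm for one graphomotricity trial."""
    _require(session, set(GRAPHO_IDS))
    trace = trace_polyline(session)
    if trace.is_degenerate:
        raise UnscorableError("trace has fewer than 2 distinct points")
    return dissimilarity(trace, template, config.grapho_resample_n)


# ---------------------------------------------------------------------------
# oculo-manual coordination


def score_oculomanual(
    session: ExerciseSession,
    layout: np.ndarray | None = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Seconds until all targets are acquired, in any order.

    A target is acquired by the first down event within
    ``target_radius_cm`` of its centre; re-touching an acquired target
    does not advance completion.  Raises :class:`IncompleteTrialError`
    (reporting the acquired count) if any target is still unacquired at
    ``oculo_timeout_s`` or at the end of the stream.
    """
    _require(session, set(OCULO_IDS))
    centers = np.asarray(
        layout if layout is not None else default_target_grid(session.device)
    )
    n_targets = len(centers)
    acquired = np.zeros(n_targets, dtype=bool)
    limit = config.oculo_timeout_s * 1000.0
    for t, pid, phase, x, y in _events_cm(session):
        if phase != "down" or t > limit:
            continue
        d = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
        hit = (d <= config.target_radius_cm) & ~acquired
        if hit.any():
            acquired |= hit
            if acquired.all():
                return t / 1000.0
    raise IncompleteTrialError(int(acquired.sum()), n_targets)


# ---------------------------------------------------------------------------
# dispatcher


def score_session(
    session: ExerciseSession,
    config: ScoringConfig = DEFAULT_CONFIG,
    templates: Mapping[str, Polyline] | None = None,
    target_grid: np.ndarray | None = None,
) -> list[OutcomeRecord]:
    """Score one session, dispatching on exercise_id.

    Returns fully populated outcome records (one per measure the subtest
    defines).  Scorer errors propagate with the session identity attached
    to the message.
    """
    ex = session.exercise_id

    def rec(measure: str, value: float) -> OutcomeRecord:
        return OutcomeRecord(
            participant_id=session.participant_id,
            exercise_id=ex,
            measure_name=measure,
            value=value,
            units=MEASURE_UNITS[measure],
            session_idx=session.session_idx,
            rater_id=session.rater_id,
        )

    try:
        if ex == "tapping":
            return [rec("tap_count", score_tapping(session, config))]
        if ex in ISO_TAP_IDS:
            return [rec("valid_tap_count", score_isolated_tapping(session, config))]
        if ex in PINCER_IDS:
            dmax, dmin = score_pincer(session, config)
            return [rec("pincer_max_cm", dmax), rec("pincer_min_cm", dmin)]
        if ex == "open_close":
            amax, amin = score_hand_area(session, config)
            return [rec("area_max_cm2", amax), rec("area_min_cm2", amin)]
        if ex in GRAPHO_IDS:
            tpl = (templates or default_templates())[ex]
            return [rec("dissimilarity_cm", score_graphomotricity(session, tpl, config))]
        if ex in OCULO_IDS:
            return [rec("completion_s", score_oculomanual(session, target_grid, config))]
    except (UnscorableError, ValueError) as exc:
        ident = f"{session.participant_id}/{ex}/session {session.session_idx}"
        if isinstance(exc, IncompleteTrialError):
            raise IncompleteTrialError(
                exc.acquired, exc.total, f"{ident}: {exc}"
            ) from exc
        raise type(exc)(f"{ident}: {exc}") from exc
    raise ValueError(f"unknown exercise_id {ex!r}")


def score_sessions(
    sessions: Sequence[ExerciseSession],
    config: ScoringConfig = DEFAULT_CONFIG,
    templates: Mapping[str, Polyline] | None = None,
) -> list[OutcomeRecord]:
    """Score a batch of sessions; templates are resolved once."""
    templates = templates or default_templates()
    out: list[OutcomeRecord] = []
    for s in sessions:
        out.extend(score_session(s, config, templates))
    return out
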