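"""Synthetic touch-stream and cohort generator.

No public dataset of multi-touch assessment streams exists, so every
scorer and statistic in this package is exercised against synthetic
data.  Two levels are generated:

* **streams** — event-level sessions obeying the capture grammar, whose
  *scored* outcome is drawn from the configured impairment profile.  The
  kinematics are phenomenological (renewal tap trains, radial pincer
  trajectories, pentagon open-close cycles, jittered template
  traversals, timed target sweeps): just enough structure to drive the
  scorers, with the outcome value attained exactly.
* **cohorts** — outcome-level tables for the statistics stage: two
  severity groups whose per-measure distributions default to published
  group summaries for this assessment (e.g. tapping mild 43.97 (14.47)
  counts/10 s vs moderate 25.26 (13.51)), FMA-UE scores uniform within
  each group's range, clinical columns with configurable correlation to
  an anchor measure, and two-way (participant x session) reliability
  matrices with controllable variance components.

Outcome noise is normal with truncation at physical bounds by
resampling; all randomness flows from explicit integer seeds.  Each
stream's primary outcome consumes the *first* normal variate of its
RNG, so sessions simulated with the same seed share that variate across
exercises (common random numbers, which stabilises Monte-Carlo
comparisons between exercises).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import (
    DeviceProfile,
    ExerciseSession,
    FINGERS,
    GRAPHO_FIGURES,
    ISO_TAP_IDS,
    MEASURE_UNITS,
    OCULO_CONDITIONS,
    OutcomeRecord,
    PINCER_FINGERS,
    PINCER_IDS,
    TouchEvent,
    sort_events,
)
from .geometry import Polyline
from .templates import default_target_grid, default_templates

#: 12-inch 3:2 tablet, 2160 x 1440 px (25.4 x 16.9 cm active area)
DEFAULT_DEVICE = DeviceProfile(
    screen_w_px=2160, screen_h_px=1440, px_per_cm_x=85.0, px_per_cm_y=85.0
)

MeanSD = tuple[float, float]


@dataclass(frozen=True)
class ImpairmentProfile:
    """Outcome distributions (mean, SD) for one severity group.

    Count distributions are per 10-s window; distances in cm, areas in
    cm^2, completion times in s.  ``trace_jitter_cm`` is the per-vertex
    positional noise of graphomotricity traces at stream level;
    ``grapho_dissimilarity_cm`` gives the cohort-level outcome
    distributions of the four figures.
    """

    label: str
    tap_count: MeanSD
    iso_tap_count: Mapping[str, MeanSD]
    pincer_max_cm: Mapping[str, MeanSD]
    pincer_min_cm: Mapping[str, MeanSD]
    hand_area_open_cm2: MeanSD
    hand_area_close_cm2: MeanSD
    grapho_dissimilarity_cm: Mapping[str, MeanSD]
    oculo_completion_s: Mapping[str, MeanSD]
    trace_jitter_cm: float
    fma_range: tuple[int, int]


MILD_PROFILE = ImpairmentProfile(
    label="mild",
    tap_count=(43.97, 14.47),
    iso_tap_count={
        "thumb": (34.44, 11.46),
        "index": (37.65, 12.43),
        "middle": (34.34, 11.24),
        "ring": (28.18, 9.10),
        "little": (28.86, 9.92),
    },
    pincer_max_cm={
        "index": (13.05, 2.04),
        "middle": (17.94, 2.28),
        "ring": (15.81, 2.35),
        "little": (15.59, 2.87),
    },
    pincer_min_cm={
        "index": (1.32, 0.70),
        "middle": (1.25, 0.74),
        "ring": (1.17, 0.85),
        "little": (1.39, 0.92),
    },
    hand_area_open_cm2=(95.47, 23.84),
    hand_area_close_cm2=(2.48, 0.73),
    grapho_dissimilarity_cm={
        "M": (58.25, 34.76),
        "S": (33.82, 16.62),
        "3": (34.19, 21.41),
        "spiral": (129.30, 77.22),
    },
    oculo_completion_s={
        "finger": (28.37, 12.60),
        "pen": (29.79, 11.91),
        "pen_drop": (80.52, 32.34),
    },
    trace_jitter_cm=0.15,
    fma_range=(47, 66),
)

MODERATE_PROFILE = ImpairmentProfile(
    label="moderate",
    tap_count=(25.26, 13.51),
    iso_tap_count={
        "thumb": (17.71, 11.08),
        "index": (18.31, 11.21),
        "middle": (17.50, 9.29),
        "ring": (12.00, 9.01),
        "little": (13.50, 8.50),
    },
    pincer_max_cm={
        "index": (10.31, 2.29),
        "middle": (12.39, 2.48),
        "ring": (12.13, 2.49),
        "little": (12.69, 4.24),
    },
    pincer_min_cm={
        "index": (1.73, 1.20),
        "middle": (1.59, 0.71),
        "ring": (2.12, 1.43),
        "little": (2.128, 0.953),
    },
    hand_area_open_cm2=(67.88, 25.60),
    hand_area_close_cm2=(2.47, 0.54),
    grapho_dissimilarity_cm={
        "M": (82.57, 37.71),
        "S": (40.01, 9.92),
        "3": (52.09, 23.39),
        "spiral": (145.26, 64.58),
    },
    oculo_completion_s={
        "finger": (35.87, 10.58),
        "pen": (39.45, 11.18),
        "pen_drop": (163.07, 87.81),
    },
    trace_jitter_cm=0.30,
    fma_range=(19, 46),
)

PROFILES = {"mild": MILD_PROFILE, "moderate": MODERATE_PROFILE}


def outcome_distribution(
    profile: ImpairmentProfile, exercise_id: str, measure_name: str
) -> MeanSD:
    """(mean, SD) the profile assigns to one exercise/measure pair."""
    if exercise_id == "tapping" and measure_name == "tap_count":
        return profile.tap_count
    if exercise_id.startswith("iso_tap_") and measure_name == "valid_tap_count":
        return profile.iso_tap_count[exercise_id.removeprefix("iso_tap_")]
    if exercise_id.startswith("pincer_"):
        finger = exercise_id.removeprefix("pincer_")
        if measure_name == "pincer_max_cm":
            return profile.pincer_max_cm[finger]
        if measure_name == "pincer_min_cm":
            return profile.pincer_min_cm[finger]
    if exercise_id == "open_close":
        if measure_name == "area_max_cm2":
            return profile.hand_area_open_cm2
        if measure_name == "area_min_cm2":
            return profile.hand_area_close_cm2
    if exercise_id.startswith("grapho_") and measure_name == "dissimilarity_cm":
        return profile.grapho_dissimilarity_cm[exercise_id.removeprefix("grapho_")]
    if exercise_id.startswith("oculo_") and measure_name == "completion_s":
        return profile.oculo_completion_s[exercise_id.removeprefix("oculo_")]
    raise KeyError(f"no configured distribution for {exercise_id}/{measure_name}")


#: every (exercise_id, measure_name) pair a cohort table carries
COHORT_MEASURES: list[tuple[str, str]] = (
    [("tapping", "tap_count")]
    + [(e, "valid_tap_count") for e in ISO_TAP_IDS]
    + [(e, m) for e in PINCER_IDS for m in ("pincer_max_cm", "pincer_min_cm")]
    + [("open_close", "area_max_cm2"), ("open_close", "area_min_cm2")]
    + [(f"grapho_{f}", "dissimilarity_cm") for f in GRAPHO_FIGURES]
    + [(f"oculo_{c}", "completion_s") for c in OCULO_CONDITIONS]
)


def measure_key(exercise_id: str, measure_name: str) -> str:
    return f"{exercise_id}:{measure_name}"


# ---------------------------------------------------------------------------
# draws


def _draw(rng, mean: float, sd: float, z: float, low: float = 0.0, high=None) -> float:
    """mean + sd*z, resampled (fresh variates) while outside (low, high)."""
    v = mean + sd * z
    tries = 0
    while v <= low or (high is not None and v >= high):
        v = mean + sd * rng.standard_normal()
        tries += 1
        if tries > 1000:
            raise RuntimeError("truncated draw failed to converge")
    return v


def truncated_mean(mean: float, sd: float, low: float = 0.0) -> float:
    """Analytic mean of N(mean, sd) truncated below at ``low``.

    The generator's outcome distribution under resampling; used as the
    exact recovery target in end-to-end checks.
    """
    from scipy import stats

    if sd == 0:
        return mean
    a = (low - mean) / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd))


# ---------------------------------------------------------------------------
# stream builders (positions in cm, converted to px on emission)


def _ev(t_ms, pid, phase, x_cm, y_cm, device) -> TouchEvent:
    x = min(max(x_cm * device.px_per_cm_x, 0.0), device.screen_w_px)
    y = min(max(y_cm * device.px_per_cm_y, 0.0), device.screen_h_px)
    return TouchEvent(t_ms=int(round(t_ms)), pointer_id=pid, phase=phase, x_px=x, y_px=y)


def _tap_train(n_taps: int, center, device, pid=0, jitter=None, rng=None, window_ms=10000):
    """Down/up pairs of one pointer, evenly spread inside the window."""
    events = []
    if n_taps <= 0:
        return events
    spacing = 9500.0 / n_taps
    for i in range(n_taps):
        t0 = i * spacing
        x, y = center
        if jitter and rng is not None:
            x += rng.normal(0, jitter)
            y += rng.normal(0, jitter)
        events.append(_ev(t0, pid, "down", x, y, device))
        events.append(_ev(t0 + min(30.0, spacing / 2), pid, "up", x, y, device))
    return events


def _simulate_tapping(rng, z, profile, device):
    mean, sd = profile.tap_count
    n = max(0, int(round(_draw(rng, mean, sd, z, low=-0.5))))
    center = (device.width_cm / 2, device.height_cm / 2)
    return _tap_train(n, center, device, jitter=0.15, rng=rng), None, 10.0


def _simulate_iso_tap(rng, z, profile, device, finger: str):
    mean, sd = profile.iso_tap_count[finger]
    n = max(0, int(round(_draw(rng, mean, sd, z, low=-0.5))))
    spot = (device.width_cm * 0.5, device.height_cm * 0.3)
    events = []
    # four weight-bearing digits held down for the whole window
    for j in range(4):
        rx = device.width_cm * 0.3 + j * 1.8
        ry = device.height_cm * 0.65
        events.append(_ev(0, j, "down", rx, ry, device))
        events.append(_ev(10400, j, "up", rx, ry, device))
    for ev in _tap_train(n, spot, device, pid=4):
        events.append(ev)
    return events, spot, 10.0


def _pincer_axis(device, reach: float):
    """Anchor point and unit direction giving at least ``reach`` cm on screen."""
    a = np.array([2.0, 2.5])
    b = np.array([device.width_cm - 1.0, device.height_cm - 2.0])
    u = b - a
    span = float(np.linalg.norm(u))
    return a, u / span, span


def _simulate_pincer(rng, z, profile, device, finger: str):
    mmax, smax = profile.pincer_max_cm[finger]
    mmin, smin = profile.pincer_min_cm[finger]
    a, u, span = _pincer_axis(device, 0.0)
    dmax = _draw(rng, mmax, smax, z, low=0.3, high=span - 0.1)
    dmin = _draw(rng, mmin, smin, z, low=0.05, high=dmax)
    d0 = (dmax + dmin) / 2
    thumb = a
    events = [_ev(0, 0, "down", thumb[0], thumb[1], device)]

    def finger_at(t, d, phase):
        p = a + u * d
        return _ev(t, 1, phase, p[0], p[1], device)

    events.append(finger_at(10, d0, "down"))
    events.append(finger_at(500, dmax, "move"))
    events.append(finger_at(1000, dmin, "move"))
    events.append(finger_at(1500, d0, "move"))
    events.append(finger_at(1600, d0, "up"))
    events.append(_ev(1650, 0, "up", thumb[0], thumb[1], device))
    return events, None, None


_PENTAGON_UNIT_AREA = 2.5 * math.sin(2 * math.pi / 5)  # area of unit-circumradius pentagon


def _simulate_open_close(rng, z, profile, device):
    momax, somax = profile.hand_area_open_cm2
    momin, somin = profile.hand_area_close_cm2
    r_cap = min(device.width_cm, device.height_cm) / 2 - 0.3
    area_cap = _PENTAGON_UNIT_AREA * r_cap**2
    amax = _draw(rng, momax, somax, z, low=0.3, high=area_cap)
    amin = _draw(rng, momin, somin, z, low=0.05, high=amax)
    r_of = lambda area: math.sqrt(area / _PENTAGON_UNIT_AREA)
    cx, cy = device.width_cm / 2, device.height_cm / 2
    angles = 2 * math.pi * np.arange(5) / 5
    r0 = r_of((amax + amin) / 2)

    def ring(t, r, phase):
        return [
            _ev(t, j, phase, cx + r * math.cos(a), cy + r * math.sin(a), device)
            for j, a in enumerate(angles)
        ]

    events = (
        ring(0, r0, "down")
        + ring(500, r_of(amax), "move")
        + ring(1000, r_of(amin), "move")
        + ring(1100, r_of(amin), "up")
    )
    return events, None, None


def _simulate_grapho(rng, z, profile, device, figure: str, jitter=None):
    tpl = default_templates()[f"grapho_{figure}"]
    pts = tpl.points.copy()
    j = profile.trace_jitter_cm if jitter is None else jitter
    if j > 0:
        pts = pts + rng.normal(0.0, j, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0.0, device.width_cm)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, device.height_cm)
    events = [_ev(0, 0, "down", pts[0, 0], pts[0, 1], device)]
    for i, (x, y) in enumerate(pts[1:-1], start=1):
        events.append(_ev(i * 20, 0, "move", x, y, device))
    events.append(_ev(len(pts) * 20, 0, "up", pts[-1, 0], pts[-1, 1], device))
    return events, None, None


def _simulate_oculo(rng, z, profile, device, condition: str):
    mean, sd = profile.oculo_completion_s[condition]
    total_s = _draw(rng, mean, sd, z, low=1.0)
    grid = default_target_grid(device)
    order = rng.permutation(len(grid))
    events = []
    n = len(grid)
    for k, idx in enumerate(order):
        t = total_s * 1000.0 * (k + 1) / n
        x, y = grid[idx]
        events.append(_ev(t, 0, "down", x, y, device))
        events.append(_ev(t + 10, 0, "up", x, y, device))
    return events, None, None


def simulate_stream(
    exercise_id: str,
    profile: ImpairmentProfile,
    device: DeviceProfile = DEFAULT_DEVICE,
    seed: int = 0,
    *,
    participant_id: str = "sim",
    hand: str = "right",
    session_idx: int = 1,
    rater_id: str = "R1",
    trace_jitter_cm: float | None = None,
) -> ExerciseSession:
    """Simulate one session whose scored outcome follows the profile.

    Deterministic given ``seed``.  The session passes full event-grammar
    validation and scores to the drawn outcome exactly (up to millisecond
    rounding for times), so scoring o simulation recovers the configured
    distributions.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal()  # primary outcome variate, shared across exercises
    if exercise_id == "tapping":
        events, calib, dur = _simulate_tapping(rng, z, profile, device)
    elif exercise_id.startswith("iso_tap_"):
        finger = exercise_id.removeprefix("iso_tap_")
        if finger not in FINGERS:
            raise ValueError(f"unknown exercise_id {exercise_id!r}")
        events, calib, dur = _simulate_iso_tap(rng, z, profile, device, finger)
    elif exercise_id.startswith("pincer_"):
        finger = exercise_id.removeprefix("pincer_")
        if finger not in PINCER_FINGERS:
            raise ValueError(f"unknown exercise_id {exercise_id!r}")
        events, calib, dur = _simulate_pincer(rng, z, profile, device, finger)
    elif exercise_id == "open_close":
        events, calib, dur = _simulate_open_close(rng, z, profile, device)
    elif exercise_id.startswith("grapho_"):
        figure = exercise_id.removeprefix("grapho_")
        if figure not in GRAPHO_FIGURES:
            raise ValueError(f"unknown exercise_id {exercise_id!r}")
        events, calib, dur = _simulate_grapho(
            rng, z, profile, device, figure, jitter=trace_jitter_cm
        )
    elif exercise_id.startswith("oculo_"):
        condition = exercise_id.removeprefix("oculo_")
        if condition not in OCULO_CONDITIONS:
            raise ValueError(f"unknown exercise_id {exercise_id!r}")
        events, calib, dur = _simulate_oculo(rng, z, profile, device, condition)
    else:
        raise ValueError(f"unknown exercise_id {exercise_id!r}")
    return ExerciseSession(
        participant_id=participant_id,
        exercise_id=exercise_id,
        hand=hand,
        session_idx=session_idx,
        rater_id=rater_id,
        events=sort_events(events),
        device=device,
        duration_s=dur,
        calibration=calib,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class ClinicalSpec:
    """One synthetic clinical column: correlated with an anchor measure."""

    name: str
    anchor: str  # measure key, e.g. "tapping:tap_count"
    rho: float
    mean: float
    sd: float


DEFAULT_CLINICAL_SPECS = (
    ClinicalSpec("box_block_n", "tapping:tap_count", 0.70, 35.0, 15.0),
    ClinicalSpec("nine_hole_peg_s", "tapping:tap_count", -0.53, 60.0, 30.0),
    ClinicalSpec("fma_hand", "tapping:tap_count", 0.64, 10.0, 3.0),
)


@dataclass
class CohortTables:
    """Output bundle of :func:`simulate_cohort`."""

    outcomes: pd.DataFrame  # wide, indexed by participant_id
    groups: pd.Series  # participant -> "mild"/"moderate"
    fma: pd.DataFrame  # participant_id, fma_ue
    clinical: pd.DataFrame  # wide, indexed by participant_id
    outcomes_long: pd.DataFrame | None = None  # repeated sessions, if requested


def simulate_cohort(
    n_mild: int,
    n_moderate: int,
    profiles: Mapping[str, ImpairmentProfile] = PROFILES,
    seed: int = 0,
    *,
    measures: Sequence[tuple[str, str]] | None = None,
    clinical_specs: Sequence[ClinicalSpec] = DEFAULT_CLINICAL_SPECS,
    n_sessions: int = 1,
    reliability_icc: float = 0.85,
) -> CohortTables:
    """Outcome-level cohort for the statistics stage.

    Per participant and measure the session-1 value is drawn from the
    group profile (normal, truncated at zero by resampling).  With
    ``n_sessions`` >= 2, a long table is also produced under a two-way
    model: participant effect variance ``reliability_icc`` * sigma^2 and
    independent session residuals carrying the rest (sessions 1-2 rater
    R1, session 3 rater R2).  Clinical columns are built to correlate
    ``rho`` with their anchor measure.
    """
    if n_mild < 1 or n_moderate < 1:
        raise ValueError("need at least one participant per group")
    rng = np.random.default_rng(seed)
    measures = list(measures if measures is not None else COHORT_MEASURES)
    pids = [f"P{i:03d}" for i in range(n_mild + n_moderate)]
    labels = ["mild"] * n_mild + ["moderate"] * n_moderate
    groups = pd.Series(labels, index=pd.Index(pids, name="participant_id"))

    true_vals = pd.DataFrame(index=groups.index, dtype=float)
    for ex, meas in measures:
        col = np.empty(len(pids))
        for g, prof in profiles.items():
            mean, sd = outcome_distribution(prof, ex, meas)
            mask = groups.to_numpy() == g
            m = int(mask.sum())
            p_sd = sd * math.sqrt(reliability_icc) if n_sessions >= 2 else sd
            draws = mean + p_sd * rng.standard_normal(m)
            bad = draws <= 0
            while bad.any():
                draws[bad] = mean + p_sd * rng.standard_normal(int(bad.sum()))
                bad = draws <= 0
            col[mask] = draws
        true_vals[measure_key(ex, meas)] = col

    long_rows = []
    outcomes = true_vals.copy()
    if n_sessions >= 2:
        for ex, meas in measures:
            key = measure_key(ex, meas)
            for g, prof in profiles.items():
                mean, sd = outcome_distribution(prof, ex, meas)
                e_sd = sd * math.sqrt(max(0.0, 1.0 - reliability_icc))
                mask = groups == g
                base = true_vals.loc[mask, key]
                for s_idx in range(1, n_sessions + 1):
                    noise = e_sd * rng.standard_normal(len(base))
                    vals = np.maximum(base.to_numpy() + noise, 0.0)
                    if s_idx == 1:
                        outcomes.loc[mask, key] = vals
                    rater = "R1" if s_idx <= 2 else "R2"
                    for pid, v in zip(base.index, vals):
                        long_rows.append(
                            dict(
                                participant_id=pid,
                                exercise_id=ex,
                                measure_name=meas,
                                value=float(v),
                                units=MEASURE_UNITS[meas],
                                session_idx=s_idx,
                                rater_id=rater,
                            )
                        )
    outcomes_long = pd.DataFrame(long_rows) if long_rows else None

    fma_vals = np.empty(len(pids), dtype=int)
    for g, prof in profiles.items():
        mask = groups.to_numpy() == g
        lo, hi = prof.fma_range
        fma_vals[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    fma = pd.DataFrame({"participant_id": pids, "fma_ue": fma_vals}).set_index(
        "participant_id"
    )

    clinical = pd.DataFrame(index=groups.index, dtype=float)
    for spec in clinical_specs:
        anchor = outcomes[spec.anchor].to_numpy()
        zs = (anchor - anchor.mean()) / anchor.std(ddof=0)
        eps = rng.standard_normal(len(pids))
        clinical[spec.name] = spec.mean + spec.sd * (
            spec.rho * zs + math.sqrt(1.0 - spec.rho**2) * eps
        )
    return CohortTables(
        outcomes=outcomes,
        groups=groups,
        fma=fma,
        clinical=clinical,
        outcomes_long=outcomes_long,
    )


# ---------------------------------------------------------------------------
# reliability matrices


@dataclass(frozen=True)
class VarianceComponents:
    """Two-way random-effects variance components behind ICC(2,1)."""

    sigma2_participant: float
    sigma2_session: float
    sigma2_error: float

    def __post_init__(self):
        if min(self.sigma2_participant, self.sigma2_session, self.sigma2_error) < 0:
            raise ValueError("variance components must be >= 0")
        if self.sigma2_participant + self.sigma2_session + self.sigma2_error == 0:
            raise ValueError("variance components cannot all be zero")

    @property
    def theoretical_icc(self) -> float:
        tot = self.sigma2_participant + self.sigma2_session + self.sigma2_error
        return self.sigma2_participant / tot


def simulate_reliability(
    n: int,
    k: int,
    mu: float,
    vc: VarianceComponents,
    seed: int = 0,
    measure_name: str = "measure",
):
    """y_ij = mu + p_i + s_j + e_ij with independent normal components.

    The population ICC(2,1) of this model is
    sigma2_p / (sigma2_p + sigma2_s + sigma2_e).
    """
    from .psychometrics import ReliabilityInput

    if n < 2 or k < 2:
        raise ValueError("need n >= 2 participants and k >= 2 sessions")
    rng = np.random.default_rng(seed)
    p = rng.normal(0.0, math.sqrt(vc.sigma2_participant), size=(n, 1))
    s = rng.normal(0.0, math.sqrt(vc.sigma2_session), size=(1, k))
    e = rng.normal(0.0, math.sqrt(vc.sigma2_error), size=(n, k))
    return ReliabilityInput(measure_name=measure_name, scores=mu + p + s + e)
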