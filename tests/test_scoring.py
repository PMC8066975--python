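"""Scorers: scripted fixtures, frame semantics, and metric properties."""

import math

import numpy as np
import pytest

from touchscore.errors import IncompleteTrialError, UnscorableError
from touchscore.events import OutcomeRecord
from touchscore.geometry import Polyline, convex_hull_area
from touchscore.scoring import (
    ScoringConfig,
    dissimilarity,
    score_graphomotricity,
    score_hand_area,
    score_isolated_tapping,
    score_oculomanual,
    score_pincer,
    score_session,
    score_tapping,
)
from touchscore.templates import default_target_grid, template_s
from conftest import ev, make_session, tap_pair

CFG = ScoringConfig()


class TestTapping:
    def test_empty_stream_scores_zero(self, device):
        s = make_session([], device)
        assert score_tapping(s) == 0

    def test_counts_down_events_in_window(self, device):
        events = sum((tap_pair(500 + 1200 * i, 5, 5) for i in range(7)), [])
        assert score_tapping(make_session(events, device)) == 7

    def test_taps_after_window_excluded(self, device):
        inside = sum((tap_pair(1000 * i, 5, 5) for i in range(5)), [])
        outside = sum((tap_pair(10_000 + 500 * i, 5, 5) for i in range(2)), [])
        assert score_tapping(make_session(inside + outside, device)) == 5

    def test_down_exactly_at_window_edge_excluded(self, device):
        events = tap_pair(0, 5, 5) + tap_pair(10_000, 5, 5)
        assert score_tapping(make_session(events, device)) == 1

    def test_wrong_exercise_rejected(self, device):
        s = make_session([], device, exercise_id="open_close")
        with pytest.raises(ValueError):
            score_tapping(s)

    def test_inserting_a_tap_never_decreases_count(self, device):
        base = sum((tap_pair(1000 * i, 5, 5) for i in range(4)), [])
        extra = base + tap_pair(4500, 6, 6)
        assert score_tapping(make_session(extra, device)) == score_tapping(
            make_session(base, device)
        ) + 1


def resting_hand(t_up=10_500):
    """Four weight-bearing contacts held from t=0."""
    events = []
    for j in range(4):
        events.append(ev(0, j, "down", 10 + j, 12))
        events.append(ev(t_up, j, "up", 10 + j, 12))
    return events


class TestIsolatedTapping:
    SPOT = (5.0, 5.0)

    def session(self, events, device, **kw):
        return make_session(
            events, device, exercise_id="iso_tap_index", calibration=self.SPOT, **kw
        )

    def test_taps_on_spot_with_resting_hand_all_count(self, device):
        taps = sum((tap_pair(200 + 900 * i, 5, 5, pid=4) for i in range(6)), [])
        assert score_isolated_tapping(self.session(resting_hand() + taps, device)) == 6

    def test_taps_off_spot_not_counted(self, device):
        taps = sum((tap_pair(200 + 900 * i, 7.0, 5.0, pid=4) for i in range(6)), [])
        # 2 cm from a 1.25 cm spot
        assert score_isolated_tapping(self.session(resting_hand() + taps, device)) == 0

    def test_taps_after_resting_hand_lifts_not_counted(self, device):
        taps = sum((tap_pair(1000 * i, 5, 5, pid=4) for i in range(8)), [])
        # hand lifts at 3.5 s: taps at 0,1,2,3 s counted, later ones not
        assert (
            score_isolated_tapping(self.session(resting_hand(t_up=3500) + taps, device))
            == 4
        )

    def test_tap_at_lift_instant_still_counts(self, device):
        taps = tap_pair(3500, 5, 5, pid=4)
        # contact interval is inclusive of the up instant
        assert (
            score_isolated_tapping(self.session(resting_hand(t_up=3500) + taps, device))
            == 1
        )

    def test_three_resting_contacts_insufficient(self, device):
        rest = [e for e in resting_hand() if e.pointer_id < 3]
        taps = tap_pair(500, 5, 5, pid=4)
        assert score_isolated_tapping(self.session(rest + taps, device)) == 0

    def test_missing_calibration_errors(self, device):
        s = make_session(resting_hand(), device, exercise_id="iso_tap_index")
        with pytest.raises(ValueError, match="calibration"):
            score_isolated_tapping(s)


class TestPincer:
    def test_two_static_contacts(self, device):
        events = [
            ev(0, 0, "down", 2, 2), ev(0, 1, "down", 5, 6),
            ev(900, 0, "up", 2, 2), ev(900, 1, "up", 5, 6),
        ]
        s = make_session(events, device, exercise_id="pincer_index")
        dmax, dmin = score_pincer(s)
        assert dmax == pytest.approx(5.0)
        assert dmin == pytest.approx(5.0)

    def test_radial_trajectory_extrema(self, device):
        events = [ev(0, 0, "down", 2, 2), ev(0, 1, "down", 2 + 5, 2)]
        for i, d in enumerate([2, 7, 13, 4], start=1):
            events.append(ev(100 * i, 1, "move", 2 + d, 2))
        events += [ev(600, 1, "up", 6, 2), ev(600, 0, "up", 2, 2)]
        s = make_session(events, device, exercise_id="pincer_index")
        dmax, dmin = score_pincer(s)
        assert dmax == pytest.approx(13.0)
        assert dmin == pytest.approx(2.0)

    def test_third_transient_contact_excludes_frames(self, device):
        events = [
            ev(0, 0, "down", 2, 2), ev(0, 1, "down", 10, 2),
            # while the palm touches, fingers reach an extreme that must be ignored
            ev(100, 2, "down", 5, 10),
            ev(150, 1, "move", 18, 2),
            ev(200, 2, "up", 5, 10),
            ev(300, 1, "move", 12, 2),
            ev(400, 0, "up", 2, 2), ev(400, 1, "up", 12, 2),
        ]
        s = make_session(events, device, exercise_id="pincer_index")
        dmax, dmin = score_pincer(s)
        # the d=16 instant at t=150/200 had 3 contacts (up inclusive at 200)
        assert dmax == pytest.approx(10.0)
        assert dmin == pytest.approx(8.0)

    def test_never_two_contacts_is_unscorable(self, device):
        events = [ev(0, 0, "down", 2, 2), ev(500, 0, "up", 2, 2)]
        s = make_session(events, device, exercise_id="pincer_index")
        with pytest.raises(UnscorableError):
            score_pincer(s)


def pentagon(cx, cy, r):
    ang = 2 * np.pi * np.arange(5) / 5
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


class TestHandArea:
    def test_static_square_plus_center(self, device):
        pts = [(4, 4), (5, 4), (5, 5), (4, 5), (4.5, 4.5)]
        events = [ev(0, j, "down", x, y) for j, (x, y) in enumerate(pts)]
        events += [ev(800, j, "up", x, y) for j, (x, y) in enumerate(pts)]
        s = make_session(events, device, exercise_id="open_close")
        amax, amin = score_hand_area(s)
        assert amax == pytest.approx(1.0)
        assert amin == pytest.approx(1.0)

    def test_radial_contraction_scales_quadratically(self, device):
        p0 = pentagon(7, 7, 4.0)
        p1 = pentagon(7, 7, 2.0)
        events = [ev(0, j, "down", x, y) for j, (x, y) in enumerate(p0)]
        events += [ev(500, j, "move", x, y) for j, (x, y) in enumerate(p1)]
        events += [ev(600, j, "up", x, y) for j, (x, y) in enumerate(p1)]
        s = make_session(events, device, exercise_id="open_close")
        amax, amin = score_hand_area(s)
        assert amin == pytest.approx(0.25 * amax)

    def test_extrema_match_frame_by_frame_oracle(self, device):
        rng = np.random.default_rng(6)
        radii = rng.uniform(1.0, 6.0, size=10)
        events = [ev(0, j, "down", x, y) for j, (x, y) in enumerate(pentagon(7, 7, radii[0]))]
        for i, r in enumerate(radii[1:], start=1):
            events += [ev(100 * i, j, "move", x, y) for j, (x, y) in enumerate(pentagon(7, 7, r))]
        events += [ev(1100, j, "up", x, y) for j, (x, y) in enumerate(pentagon(7, 7, radii[-1]))]
        s = make_session(events, device, exercise_id="open_close")
        amax, amin = score_hand_area(s)
        areas = [convex_hull_area(pentagon(7, 7, r)) for r in radii]
        assert amax == pytest.approx(max(areas))
        assert amin == pytest.approx(min(areas))

    def test_fewer_than_three_contacts_unscorable(self, device):
        events = [ev(0, 0, "down", 2, 2), ev(0, 1, "down", 4, 4),
                  ev(500, 0, "up", 2, 2), ev(500, 1, "up", 4, 4)]
        s = make_session(events, device, exercise_id="open_close")
        with pytest.raises(UnscorableError):
            score_hand_area(s)


class TestGraphomotricity:
    def trace_session(self, pts, device, exercise_id="grapho_S"):
        events = [ev(0, 0, "down", *pts[0])]
        events += [ev(20 * i, 0, "move", *p) for i, p in enumerate(pts[1:-1], start=1)]
        events += [ev(20 * len(pts), 0, "up", *pts[-1])]
        return make_session(events, device, exercise_id=exercise_id)

    def test_identical_trace_scores_zero(self, device):
        tpl = template_s(origin=(8.0, 3.0))
        s = self.trace_session(tpl.points, device)
        assert score_graphomotricity(s, tpl) == pytest.approx(0.0, abs=1e-9)

    def test_parallel_offset_of_straight_template_is_n_times_d(self, device):
        tpl = Polyline([(2.0, 3.0), (12.0, 3.0)])
        d = 0.8
        trace = tpl.points + [0.0, d]
        s = self.trace_session(trace, device)
        n = CFG.grapho_resample_n
        assert score_graphomotricity(s, tpl) == pytest.approx(n * d, rel=1e-9)

    def test_dissimilarity_increases_with_offset(self, device):
        tpl = template_s(origin=(8.0, 3.0))
        scores = []
        for d in [0.0, 0.2, 0.5, 1.0, 2.0]:
            s = self.trace_session(tpl.points + [d, 0.0], device)
            scores.append(score_graphomotricity(s, tpl))
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_symmetric_in_the_two_curves(self):
        rng = np.random.default_rng(7)
        a = Polyline(rng.uniform(0, 10, size=(9, 2)))
        b = Polyline(rng.uniform(0, 10, size=(7, 2)))
        assert dissimilarity(a, b) == pytest.approx(dissimilarity(b, a))

    def test_invariant_under_simultaneous_rigid_motion(self):
        rng = np.random.default_rng(8)
        a = Polyline(rng.uniform(0, 10, size=(9, 2)))
        b = Polyline(rng.uniform(0, 10, size=(7, 2)))
        th = 0.6
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert dissimilarity(
            a.transformed(rot, (1.0, -2.0)), b.transformed(rot, (1.0, -2.0))
        ) == pytest.approx(dissimilarity(a, b), rel=1e-9)

    def test_degenerate_trace_unscorable(self, device):
        events = [ev(0, 0, "down", 5, 5), ev(40, 0, "up", 5, 5)]
        s = make_session(events, device, exercise_id="grapho_M")
        with pytest.raises(UnscorableError):
            score_graphomotricity(s, template_s())


class TestOculomanual:
    def sweep(self, centers, device, last_ms=12_300, skip=0):
        """Touch targets in order, the last one exactly at ``last_ms``."""
        events = []
        n = len(centers) - skip
        for k, (x, y) in enumerate(centers[: len(centers) - skip]):
            t = round(last_ms * (k + 1) / n)
            events += tap_pair(t, x, y, pid=0, hold_ms=5)
        return make_session(events, device, exercise_id="oculo_finger")

    def test_completion_time_of_full_sweep(self, device):
        centers = default_target_grid(device)
        s = self.sweep(centers, device, last_ms=12_300)
        assert score_oculomanual(s) == pytest.approx(12.3)

    def test_retouching_acquired_target_does_not_advance(self, device):
        centers = default_target_grid(device)
        events = list(self.sweep(centers, device, last_ms=10_000).events)
        # re-touch the first target after the sweep: completion stays at 10 s
        events += tap_pair(11_000, *centers[0], pid=0, hold_ms=5)
        s = make_session(events, device, exercise_id="oculo_finger")
        assert score_oculomanual(s) == pytest.approx(10.0)

    def test_missing_target_reports_acquired_count(self, device):
        centers = default_target_grid(device)
        s = self.sweep(centers, device, skip=1)
        with pytest.raises(IncompleteTrialError) as err:
            score_oculomanual(s)
        assert err.value.acquired == 31

    def test_touches_after_timeout_ignored(self, device):
        centers = default_target_grid(device)
        s = self.sweep(centers, device, last_ms=125_000)
        with pytest.raises(IncompleteTrialError):
            score_oculomanual(s)


class TestDispatcher:
    def test_tapping_record_units(self, device):
        s = make_session(tap_pair(100, 5, 5), device)
        (rec,) = score_session(s)
        assert isinstance(rec, OutcomeRecord)
        assert (rec.measure_name, rec.units, rec.value) == ("tap_count", "n", 1)

    def test_pincer_emits_two_cm_records(self, device):
        events = [ev(0, 0, "down", 2, 2), ev(0, 1, "down", 8, 2),
                  ev(500, 0, "up", 2, 2), ev(500, 1, "up", 8, 2)]
        s = make_session(events, device, exercise_id="pincer_middle")
        recs = score_session(s)
        assert [r.measure_name for r in recs] == ["pincer_max_cm", "pincer_min_cm"]
        assert all(r.units == "cm" for r in recs)

    def test_batch_record_count(self, device):
        from touchscore.scoring import score_sessions
        from touchscore.simulator import MILD_PROFILE, simulate_stream

        sessions = [
            simulate_stream(ex, MILD_PROFILE, seed=11)
            for ex in ["tapping", "pincer_index", "open_close", "grapho_M", "oculo_pen"]
        ]
        recs = score_sessions(sessions)
        # 1 + 2 + 2 + 1 + 1 measures
        assert len(recs) == 7

    def test_errors_carry_session_identity(self, device):
        events = [ev(0, 0, "down", 2, 2), ev(500, 0, "up", 2, 2)]
        s = make_session(events, device, exercise_id="pincer_index", participant_id="P9")
        with pytest.raises(UnscorableError, match="P9/pincer_index"):
            score_session(s)

    def test_scorers_are_pure(self, device):
        events = sum((tap_pair(900 * i, 5, 5) for i in range(5)), [])
        s = make_session(events, device)
        assert score_session(s) == score_session(s)

    def test_extrema_invariant_to_tie_order(self, device):
        # two serializations of the same instant: order of equal-t events differs
        a = [ev(0, 0, "down", 2, 2), ev(0, 1, "down", 8, 2),
             ev(300, 0, "move", 3, 2), ev(300, 1, "move", 9, 2),
             ev(600, 0, "up", 3, 2), ev(600, 1, "up", 9, 2)]
        b = [a[1], a[0], a[3], a[2], a[5], a[4]]
        sa = make_session(a, device, exercise_id="pincer_ring")
        sb = make_session(b, device, exercise_id="pincer_ring")
        assert score_pincer(sa) == score_pincer(sb)
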