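import numpy as np
import pytest

from touchscore.events import DeviceProfile, ExerciseSession, TouchEvent, sort_events


@pytest.fixture
def device():
    """Isotropic 100 px/cm panel, 20 x 15 cm, for hand-built fixtures."""
    return DeviceProfile(
        screen_w_px=2000, screen_h_px=1500, px_per_cm_x=100.0, px_per_cm_y=100.0
    )


def ev(t, pid, phase, x_cm, y_cm, ppcm=100.0):
    """Event helper: positions given in cm on an isotropic ppcm panel."""
    return TouchEvent(
        t_ms=t, pointer_id=pid, phase=phase, x_px=x_cm * ppcm, y_px=y_cm * ppcm
    )


def make_session(events, device, exercise_id="tapping", **kwargs):
    defaults = dict(
        participant_id="T01",
        exercise_id=exercise_id,
        hand="right",
        session_idx=1,
        rater_id="R1",
        events=sort_events(events),
        device=device,
    )
    defaults.update(kwargs)
    return ExerciseSession(**defaults)


def tap_pair(t, x_cm, y_cm, pid=0, hold_ms=30):
    """A down/up pair at one spot."""
    return [ev(t, pid, "down", x_cm, y_cm), ev(t + hold_ms, pid, "up", x_cm, y_cm)]
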