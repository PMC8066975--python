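"""Template figures and target layouts.

The graphomotricity subtest shows four figures — an "M", a "3", an "S"
and a spiral — that the participant traces; the oculo-manual subtest
shows 32 circular targets on a 4 x 8 grid.  This module generates those
geometries programmatically, in screen centimetres, so no figure assets
need to ship with the package.  Exact figure proportions in the original
app are unknown; these are smooth, screen-sized stand-ins with the right
topology, and scoring is agnostic to the precise shapes (templates are
an input).
"""

from __future__ import annotations

import numpy as np

from .events import DeviceProfile, GRAPHO_FIGURES
from .geometry import Polyline


def template_m(
    height: float = 8.0,
    width: float = 6.0,
    origin: tuple[float, float] = (9.0, 4.0),
    points_per_segment: int = 40,
) -> Polyline:
    """Four-stroke "M": up, down to the valley, up, down (y grows downward)."""
    ox, oy = origin
    verts = np.array(
        [
            [0.0, height],
            [0.0, 0.0],
            [width / 2, height * 0.6],
            [width, 0.0],
            [width, height],
        ]
    )
    pts = []
    for a, b in zip(verts[:-1], verts[1:]):
        t = np.linspace(0.0, 1.0, points_per_segment, endpoint=False)[:, None]
        pts.append(a + t * (b - a))
    pts.append(verts[-1:])
    return Polyline(np.vstack(pts) + [ox, oy])


def _sine_figure(amplitude_fn, height, origin, n_points):
    ox, oy = origin
    t = np.linspace(0.0, 1.0, n_points)
    x = ox + amplitude_fn(t)
    y = oy + height * t
    return Polyline(np.column_stack([x, y]))


def template_s(
    height: float = 10.0,
    half_width: float = 2.5,
    origin: tuple[float, float] = (11.0, 3.0),
    n_points: int = 160,
) -> Polyline:
    """Smooth S-curve: one full sine period along the vertical axis."""
    return _sine_figure(
        lambda t: half_width * np.sin(2 * np.pi * t), height, origin, n_points
    )


def template_3(
    height: float = 10.0,
    half_width: float = 2.5,
    origin: tuple[float, float] = (11.0, 3.0),
    n_points: int = 160,
) -> Polyline:
    """Two right-bulging arcs meeting mid-height, like the digit 3."""
    return _sine_figure(
        lambda t: half_width * np.abs(np.sin(2 * np.pi * t)), height, origin, n_points
    )


def template_spiral(
    turns: float = 3.0,
    spacing_cm: float = 0.9,
    center: tuple[float, float] = (12.5, 8.5),
    n_points: int = 400,
) -> Polyline:
    """Archimedean spiral, ~``turns`` revolutions, ``spacing_cm`` between arms."""
    theta = np.linspace(0.0, 2 * np.pi * turns, n_points)
    r = (spacing_cm / (2 * np.pi)) * theta
    cx, cy = center
    return Polyline(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))


def default_templates() -> dict[str, Polyline]:
    """Template polylines keyed by graphomotricity exercise id."""
    return {
        "grapho_M": template_m(),
        "grapho_3": template_3(),
        "grapho_S": template_s(),
        "grapho_spiral": template_spiral(),
    }


def default_target_grid(device: DeviceProfile) -> np.ndarray:
    """Centres (cm) of the 32 targets on a 4 x 8 grid, row-major.

    Columns are spread evenly across the screen width, rows across the
    height, with one grid-cell margin on each side.
    """
    w, h = device.width_cm, device.height_cm
    xs = np.arange(1, 9) * w / 9.0
    ys = np.arange(1, 5) * h / 5.0
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def read_template_csv(path) -> Polyline:
    """Read a template polyline from CSV with columns x_cm,y_cm."""
    import pandas as pd

    df = pd.read_csv(path)
    return Polyline(df[["x_cm", "y_cm"]].to_numpy(dtype=float))


def write_template_csv(polyline: Polyline, path) -> None:
    import pandas as pd

    pd.DataFrame(polyline.points, columns=["x_cm", "y_cm"]).to_csv(path, index=False)
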