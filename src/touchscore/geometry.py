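"""Geometric primitives shared by the scorers.

All coordinates are centimetres in the screen plane (origin top-left,
y downward).  Convex hulls serve the hand-area measure, arc-length
resampling and point-to-polyline distance serve the trace-template
dissimilarity measure.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPoint, Point


class Polyline:
    """An ordered sequence of points in cm; consecutive duplicates collapsed.

    Wraps a float array of shape (n, 2) and caches the shapely LineString
    used for distance queries.
    """

    def __init__(self, points):
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError("a polyline needs >= 2 points of shape (n, 2)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("polyline coordinates must be finite")
        keep = np.ones(len(arr), dtype=bool)
        keep[1:] = np.any(arr[1:] != arr[:-1], axis=1)
        self.points = arr[keep]
        self._linestring = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Total arc length in cm."""
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def is_degenerate(self) -> bool:
        return len(self.points) < 2 or self.length <= 0.0

    @property
    def linestring(self) -> LineString:
        if self._linestring is None:
            if self.is_degenerate:
                raise ValueError("degenerate polyline has no LineString")
            self._linestring = LineString(self.points)
        return self._linestring

    def translated(self, dx: float, dy: float) -> "Polyline":
        return Polyline(self.points + np.array([dx, dy]))

    def transformed(self, matrix: np.ndarray, offset=(0.0, 0.0)) -> "Polyline":
        """Apply a 2x2 linear map plus offset (rigid motions in tests)."""
        return Polyline(self.points @ np.asarray(matrix).T + np.asarray(offset))


def convex_hull_area(points) -> float:
    """Area (cm^2) of the convex hull of a point set.

    Returns 0 for fewer than 3 non-collinear points (closed-hand frames
    may be nearly collinear; that is a measurement of 0 area, not an
    error).  An empty point set is an error.
    """
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        raise ValueError("convex_hull_area of empty point set")
    arr = arr.reshape(-1, 2)
    if not np.all(np.isfinite(arr)):
        raise ValueError("points must be finite")
    if len(arr) < 3:
        return 0.0
    return float(MultiPoint(arr).convex_hull.area)


def resample(polyline: Polyline, n: int) -> np.ndarray:
    """``n`` points equally spaced by arc length along the polyline.

    The first and last output points coincide with the polyline's
    endpoints.  Raises on zero total length.
    """
    if n < 2:
        raise ValueError("need n >= 2 resample points")
    pts = polyline.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        raise ValueError("cannot resample a zero-length polyline")
    targets = np.linspace(0.0, total, n)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    out = np.column_stack([x, y])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def nearest_distance(point, polyline: Polyline) -> float:
    """Minimum Euclidean distance (cm) from a point to the polyline.

    Distance to the segments, not only to the vertices.
    """
    return float(polyline.linestring.distance(Point(point)))


def nearest_distances(points: np.ndarray, polyline: Polyline) -> np.ndarray:
    """Vectorised :func:`nearest_distance` for an (n, 2) array of points."""
    geoms = shapely.points(np.asarray(points, dtype=float))
    return shapely.distance(geoms, polyline.linestring)
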