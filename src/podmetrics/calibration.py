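"""Coin-based pixel-to-millimeter calibration.

A coin of known diameter (a 25 mm one-RMB piece by default) is placed at
the far-left edge of every photograph.  Its contour is identified by
position and circularity, its pixel diameter is measured from the edge
midpoints of its minimum-area rotated bounding rectangle, and two
conversion factors are derived::

    diameter_ratio = coin_diameter_true / coin_diameter_pixel   [mm / px]
    area_ratio     = coin_area_true     / coin_area_pixel       [mm^2 / px^2]

with ``coin_area_true = pi * (coin_diameter_true / 2)^2``.  All physical
pod measurements are pixel quantities multiplied by one of these ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .imaging import Contour, contour_area, contour_perimeter

__all__ = [
    "OrderedBox",
    "CalibrationScale",
    "CoinNotFoundError",
    "midpoint",
    "euclidean_distance",
    "order_box_corners",
    "min_area_box",
    "find_coin",
    "coin_pixel_diameter",
    "make_scale",
    "circularity",
]

DEFAULT_COIN_DIAMETER_MM = 25.0
DEFAULT_CIRCULARITY_MIN = 0.8
DEFAULT_COIN_MIN_AREA_PX = 500.0


class CoinNotFoundError(RuntimeError):
    """No contour qualified as the reference coin."""

    def __init__(self, message: str, best_circularity: float | None = None):
        super().__init__(message)
        self.best_circularity = best_circularity


def midpoint(p, q) -> tuple[float, float]:
    """Coordinate-wise mean of two points."""
    return ((p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0)


def euclidean_distance(p, q) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


@dataclass(frozen=True)
class OrderedBox:
    """Four box corners in clockwise screen order starting top-left,
    plus the midpoints of the four edges."""

    top_left: tuple[float, float]
    top_right: tuple[float, float]
    bottom_right: tuple[float, float]
    bottom_left: tuple[float, float]

    @property
    def corners(self):
        return (self.top_left, self.top_right, self.bottom_right, self.bottom_left)

    @property
    def midpoint_top(self):
        return midpoint(self.top_left, self.top_right)

    @property
    def midpoint_bottom(self):
        return midpoint(self.bottom_left, self.bottom_right)

    @property
    def midpoint_left(self):
        return midpoint(self.top_left, self.bottom_left)

    @property
    def midpoint_right(self):
        return midpoint(self.top_right, self.bottom_right)


def order_box_corners(points) -> OrderedBox:
    """Order 4 corner points clockwise (on screen, y pointing down),
    starting from the topmost corner, ties broken toward the left.

    The first corner is labelled top-left and the traversal continues
    top-right -> bottom-right -> bottom-left.  Collinear or duplicated
    input is rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (4, 2):
        raise ValueError("exactly 4 (x, y) points required")
    if len({(round(x, 9), round(y, 9)) for x, y in pts}) < 4:
        raise ValueError("corner points must be distinct")
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    order = np.argsort(ang, kind="stable")  # increasing angle = clockwise on screen
    ring = pts[order]
    # check convexity / non-degeneracy via consistent cross-product signs
    v = np.roll(ring, -1, axis=0) - ring
    cross = v[:, 0] * np.roll(v, -1, axis=0)[:, 1] - v[:, 1] * np.roll(v, -1, axis=0)[:, 0]
    if np.any(np.abs(cross) < 1e-12) or not (np.all(cross > 0) or np.all(cross < 0)):
        raise ValueError("points do not form a convex quadrilateral")
    # rotate the ring so it starts at the topmost (then leftmost) corner
    start = np.lexsort((ring[:, 0], ring[:, 1]))[0]
    ring = np.roll(ring, -start, axis=0)
    tl, tr, br, bl = (tuple(map(float, p)) for p in ring)
    return OrderedBox(tl, tr, br, bl)


def min_area_box(c: Contour) -> OrderedBox:
    """Minimum-area rotated bounding rectangle of a contour, with ordered
    corners."""
    rect = _ShapelyPolygon(c.points).minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:4]
    return order_box_corners(coords)


def circularity(c: Contour) -> float:
    """4*pi*area / perimeter^2; 1 for a circle, < 1 otherwise."""
    p = contour_perimeter(c)
    if p == 0:
        return 0.0
    return 4.0 * math.pi * contour_area(c) / (p * p)


def find_coin(
    contours: list[Contour],
    image_width: float | None = None,
    circularity_min: float = DEFAULT_CIRCULARITY_MIN,
    min_area: float = DEFAULT_COIN_MIN_AREA_PX,
) -> Contour:
    """Pick the coin contour: the leftmost (smallest centroid x) contour
    that is round enough (circularity >= ``circularity_min``) and at least
    ``min_area`` px^2.

    The result does not depend on the order of ``contours``.  Raises
    :class:`CoinNotFoundError` (carrying the best circularity seen) when
    nothing qualifies.
    """
    if not contours:
        raise CoinNotFoundError("no contours supplied")
    best_circ = None
    candidates = []
    for c in contours:
        circ = circularity(c)
        if best_circ is None or circ > best_circ:
            best_circ = circ
        if circ >= circularity_min and contour_area(c) >= min_area:
            candidates.append((c.centroid()[0], c.centroid()[1], c))
    if not candidates:
        raise CoinNotFoundError(
            f"no contour with circularity >= {circularity_min} and area >= "
            f"{min_area} px^2 (best circularity seen: {best_circ:.3f})",
            best_circularity=best_circ,
        )
    candidates.sort(key=lambda t: (t[0], t[1]))
    return candidates[0][2]


def coin_pixel_diameter(coin: Contour) -> float:
    """Coin diameter in pixels: the mean of the two midpoint-to-midpoint
    distances (top-bottom and left-right) of the coin's minimum-area
    rotated bounding rectangle."""
    box = min_area_box(coin)
    d1 = euclidean_distance(box.midpoint_top, box.midpoint_bottom)
    d2 = euclidean_distance(box.midpoint_left, box.midpoint_right)
    return (d1 + d2) / 2.0


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel-to-physical conversion derived from the reference coin."""

    coin_diameter_true: float  # mm
    coin_diameter_pixel: float  # px
    coin_area_true: float  # mm^2
    coin_area_pixel: float  # px^2
    diameter_ratio: float  # mm / px
    area_ratio: float  # mm^2 / px^2

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def make_scale(
    coin_diameter_pixel: float,
    coin_area_pixel: float,
    coin_diameter_true: float = DEFAULT_COIN_DIAMETER_MM,
) -> CalibrationScale:
    """Build the conversion ratios from the coin's pixel measurements.

    ``coin_area_true`` is the area of the ideal disk of the stated true
    diameter.
    """
    if coin_diameter_pixel <= 0 or coin_area_pixel <= 0 or coin_diameter_true <= 0:
        raise ValueError("coin measurements must be positive")
    coin_area_true = math.pi * (coin_diameter_true / 2.0) ** 2
    return CalibrationScale(
        coin_diameter_true=float(coin_diameter_true),
        coin_diameter_pixel=float(coin_diameter_pixel),
        coin_area_true=coin_area_true,
        coin_area_pixel=float(coin_area_pixel),
        diameter_ratio=coin_diameter_true / coin_diameter_pixel,
        area_ratio=coin_area_true / coin_area_pixel,
    )


def calibrate_from_contour(
    coin: Contour, coin_diameter_true: float = DEFAULT_COIN_DIAMETER_MM
) -> CalibrationScale:
    """Measure a coin contour and build the calibration scale."""
    return make_scale(
        coin_pixel_diameter(coin), contour_area(coin), coin_diameter_true
    )
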