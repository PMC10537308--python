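"""Raster preprocessing and contour extraction.

The measurement pipeline photographs pods on near-black velvet, so the
foreground is recovered with a classic grayscale → Gaussian blur →
threshold → small-component removal chain.  Each surviving 8-connected
component is then traced into a closed boundary polygon on which all
geometry (perimeter, area, bounding rectangles) is computed.

Conventions used throughout the package:

* images are ``numpy`` arrays, ``(H, W, 3)`` uint8 RGB or ``(H, W)`` gray;
* binary masks are ``(H, W)`` boolean arrays;
* contour points are ``(x, y)`` pairs with ``x`` = column, ``y`` = row,
  origin at the top-left pixel center, 0-based;
* foreground is 8-connected, background 4-connected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon as _fill_polygon

__all__ = [
    "Contour",
    "to_grayscale",
    "gaussian_blur",
    "binarize",
    "otsu_threshold",
    "remove_small_components",
    "extract_contours",
    "contour_area",
    "contour_perimeter",
    "rasterize_contour",
    "read_image",
    "write_mask",
]

#: ITU-R BT.601 luma weights (R, G, B).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Reference resolution at which the default noise cutoff is specified.
NATIVE_AREA_PX = 2400 * 1600

#: Default minimum component area (px^2) at the native 2400x1600 resolution.
DEFAULT_MIN_AREA_NATIVE = 150.0


@dataclass(frozen=True)
class Contour:
    """Simple closed polygon traced around one foreground component.

    ``points`` is an ``(N, 2)`` float array of ``(x, y)`` vertices; the
    closing edge from the last back to the first vertex is implicit.
    """

    points: np.ndarray
    _signed_area: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("a contour needs at least 3 (x, y) points")
        object.__setattr__(self, "points", pts)
        x, y = pts[:, 0], pts[:, 1]
        s = 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        object.__setattr__(self, "_signed_area", s)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def orientation(self) -> str:
        """'clockwise' or 'counterclockwise' in image coordinates (y down)."""
        # With y pointing down, positive shoelace area means clockwise on
        # screen.
        return "counterclockwise" if self._signed_area > 0 else "clockwise"

    @property
    def signed_area(self) -> float:
        return self._signed_area

    def centroid(self) -> tuple[float, float]:
        """Area centroid of the polygon (falls back to vertex mean when
        the area is numerically zero)."""
        pts = self.points
        x, y = pts[:, 0], pts[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-9:
            return float(x.mean()), float(y.mean())
        cx = float(((x + xn) * cross).sum() / (6.0 * a))
        cy = float(((y + yn) * cross).sum() / (6.0 * a))
        return cx, cy

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.points + np.array([dx, dy]))

    def scaled(self, s: float) -> "Contour":
        return Contour(self.points * s)

    def to_json(self) -> str:
        return json.dumps({"points": self.points.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Contour":
        return cls(np.asarray(json.loads(text)["points"], dtype=float))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale using BT.601 luma weights."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 2:
        return img.astype(float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    return img.astype(float) @ np.asarray(LUMA_WEIGHTS)


def gaussian_blur(img: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Gaussian smoothing with reflect border handling, kernel cut at 4 sigma.

    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(img, dtype=float)
    if sigma == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma=sigma, mode="reflect", truncate=4.0)


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu's threshold on the 256-bin histogram of ``img``.

    Returns the threshold t maximizing between-class variance; foreground
    is defined as intensity > t.
    """
    from skimage.filters import threshold_otsu

    vals = np.clip(np.asarray(img, dtype=float).ravel(), 0, 255)
    return float(threshold_otsu(vals, nbins=256))


def binarize(
    img: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold a gray image to a boolean foreground mask.

    ``method='fixed'`` requires an explicit ``threshold`` in [0, 255];
    ``method='otsu'`` picks it by maximizing between-class variance.
    A pixel is foreground iff its intensity is strictly above the threshold.
    """
    img = np.asarray(img, dtype=float)
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        if not 0 <= threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        t = float(threshold)
    elif method == "otsu":
        t = otsu_threshold(img)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img > t


def remove_small_components(mask: np.ndarray, min_area: float) -> np.ndarray:
    """Zero out every 8-connected foreground component smaller than
    ``min_area`` pixels."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if min_area == 0:
        return mask.copy()
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labels]


def default_min_area(height: int, width: int) -> float:
    """Noise cutoff scaled from the 150 px^2 default at 2400x1600."""
    return DEFAULT_MIN_AREA_NATIVE * (height * width) / NATIVE_AREA_PX


# ---------------------------------------------------------------------------
# boundary tracing
# ---------------------------------------------------------------------------

def _smooth_ring(ring: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average of a closed vertex chain (no endpoint
    duplication)."""
    if window <= 1 or len(ring) <= window:
        return ring
    kernel = np.ones(window) / window
    pad = window // 2
    ext = np.vstack([ring[-pad:], ring, ring[:pad]])
    out = np.column_stack(
        [np.convolve(ext[:, k], kernel, mode="valid") for k in range(2)]
    )
    return out


def extract_contours(
    mask: np.ndarray,
    smooth_window: int = 5,
) -> list[Contour]:
    """Trace the outer boundary polygon of every 8-connected component.

    The boundary follows the mid-crack convention (marching squares at
    level 0.5): vertices sit on pixel-edge midpoints halfway between a
    foreground and a background pixel, so the shoelace area of the
    polygon matches the component's pixel count (a filled 10x10 square
    yields area 100).  The raw marching chain zigzags along oblique
    edges and overestimates their length, so the vertex chain is
    smoothed with a circular moving average of ``smooth_window`` points
    (1 disables smoothing; the window trades corner rounding against
    staircase noise).  Holes are ignored.  Contours are returned in
    descending order of enclosed area.
    """
    from skimage.measure import find_contours

    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    contours: list[Contour] = []
    slices = ndimage.find_objects(labels)
    for i, slc in enumerate(slices, start=1):
        sub = np.pad(labels[slc] == i, 1).astype(float)
        rings = find_contours(sub, 0.5)
        if not rings:
            continue

        def ring_area(r):
            x, y = r[:, 1], r[:, 0]
            return abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2

        ring = max(rings, key=ring_area)  # outer boundary; holes ignored
        if np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        if len(ring) < 3:
            continue
        ring = _smooth_ring(ring, smooth_window)
        # (row, col) -> (x, y), undo padding, back to image coordinates
        xy = ring[:, ::-1] - 1.0 + np.array(
            [slc[1].start, slc[0].start], dtype=float
        )
        contours.append(Contour(xy))
    contours.sort(key=lambda c: -abs(c.signed_area))
    return contours


def contour_area(c: Contour) -> float:
    """Absolute shoelace area of the polygon, in px^2."""
    return abs(c.signed_area)


def contour_perimeter(c: Contour) -> float:
    """Sum of Euclidean edge lengths, closing edge included, in px."""
    pts = c.points
    return float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())


def rasterize_contour(c: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Fill the contour's interior on a pixel grid of the given (H, W)."""
    rr, cc = _fill_polygon(c.points[:, 1], c.points[:, 0], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG image as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)
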