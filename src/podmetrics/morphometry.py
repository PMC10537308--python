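"""Per-pod morphometry, counting, summaries and comparisons.

Pod size is derived from the closed contour alone:

* length  = contour perimeter / 2 ("half-perimeter" length).  For a
  rectangle of sides L x w this gives L + w, i.e. the true length plus
  one width; the estimate degrades further with curvature.
* width   = contour area / length.  For the same rectangle this gives
  L*w / (L + w), slightly below the true width.
* area    = shoelace area of the contour.

The isoperimetric inequality (area <= perimeter^2 / (4*pi)) guarantees
width <= length / pi for every simple contour, so the derived width is
always well below the derived length.

Pixel quantities are converted to millimeters with the coin-derived
:class:`~podmetrics.calibration.CalibrationScale`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .calibration import (
    CalibrationScale,
    calibrate_from_contour,
    find_coin,
)
from .imaging import (
    NATIVE_AREA_PX,
    Contour,
    binarize,
    contour_area,
    contour_perimeter,
    default_min_area,
    extract_contours,
    gaussian_blur,
    remove_small_components,
    to_grayscale,
)

__all__ = [
    "PodMeasurement",
    "MeasurementSummary",
    "ComparisonFit",
    "MeasureConfig",
    "pod_length_px",
    "pod_width_px",
    "measure_pod",
    "measure_image",
    "count_pods",
    "summarize",
    "compare_measurements",
    "annotate_image",
]


def pod_length_px(c: Contour) -> float:
    """Pod length in pixels: half the closed-contour perimeter."""
    return contour_perimeter(c) / 2.0


def pod_width_px(c: Contour) -> float:
    """Pod width in pixels: contour area divided by the half-perimeter
    length."""
    length = pod_length_px(c)
    if length <= 0:
        raise ValueError("degenerate contour with zero length")
    return contour_area(c) / length


@dataclass(frozen=True)
class PodMeasurement:
    """One pod's pixel and physical measurements."""

    pod_id: int
    length_pixel: float  # px
    width_pixel: float  # px
    area_pixel: float  # px^2
    length: float  # mm
    width: float  # mm
    area: float  # mm^2
    contour: Contour


def measure_pod(c: Contour, scale: CalibrationScale, pod_id: int) -> PodMeasurement:
    """Measure one pod contour and convert to physical units."""
    length_px = pod_length_px(c)
    width_px = pod_width_px(c)
    area_px = contour_area(c)
    return PodMeasurement(
        pod_id=pod_id,
        length_pixel=length_px,
        width_pixel=width_px,
        area_pixel=area_px,
        length=length_px * scale.diameter_ratio,
        width=width_px * scale.diameter_ratio,
        area=area_px * scale.area_ratio,
        contour=c,
    )


@dataclass(frozen=True)
class MeasureConfig:
    """Tunables of the measurement pipeline (defaults documented in
    docs/methods.md)."""

    blur_sigma: float | None = None  # None: 1.5 px at 2400x1600, scaled
    threshold_method: str = "otsu"  # 'otsu' | 'fixed'
    threshold_value: float | None = None
    min_noise_area: float | None = None  # None: 150 px^2 scaled from 2400x1600
    coin_diameter_mm: float = 25.0
    circularity_min: float = 0.8
    coin_min_area: float = 500.0
    contour_smooth_window: int = 5
    refine_threshold: bool = True


def _refine_components(gray: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Re-threshold each segmented object at its local midpoint level.

    A single global threshold sits between the background and the mean
    of *all* foreground, so with objects of different brightness (dull
    pods next to a shiny coin) it lands above the pod/background
    midpoint and shaves a fraction of a pixel off thin objects.  For
    each component the threshold is recomputed as the midpoint between
    the component's median intensity and the median of the nearby
    background, which centres the binarized boundary on the true edge.
    """
    from scipy import ndimage

    eight = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(mask, structure=eight)
    if n == 0:
        return mask
    h, w = mask.shape
    occupied = ndimage.binary_dilation(mask, structure=eight, iterations=3)
    out = np.zeros_like(mask)
    margin = 6
    for i, slc in enumerate(ndimage.find_objects(labels), start=1):
        r0, r1 = max(slc[0].start - margin, 0), min(slc[0].stop + margin, h)
        c0, c1 = max(slc[1].start - margin, 0), min(slc[1].stop + margin, w)
        win = gray[r0:r1, c0:c1]
        comp = labels[r0:r1, c0:c1] == i
        bg = ~occupied[r0:r1, c0:c1]
        if not bg.any():
            out[r0:r1, c0:c1] |= comp
            continue
        t = (float(np.median(win[comp])) + float(np.median(win[bg]))) / 2.0
        local = win > t
        relabel, _ = ndimage.label(local, structure=eight)
        keep = np.unique(relabel[comp])
        keep = keep[keep > 0]
        if keep.size:
            out[r0:r1, c0:c1] |= np.isin(relabel, keep)
        else:
            out[r0:r1, c0:c1] |= comp
    return out


def measure_image(
    img: np.ndarray, config: MeasureConfig | None = None
) -> tuple[list[PodMeasurement], CalibrationScale]:
    """Run the full pipeline on one photograph.

    Grayscale -> Gaussian blur -> threshold -> small-component removal ->
    contour extraction -> coin identification and calibration -> one
    measurement per remaining contour.  Pods are numbered 1..n from left
    to right by contour centroid (ties broken top to bottom).

    Raises :class:`~podmetrics.calibration.CoinNotFoundError` when no
    contour qualifies as the coin; an image with a coin but no pods
    yields an empty measurement list.
    """
    cfg = config or MeasureConfig()
    img = np.asarray(img)
    sigma = cfg.blur_sigma
    if sigma is None:
        # keep preprocessing resolution-covariant: the smoothing scale
        # tracks the linear image resolution, like the noise-area cutoff
        sigma = 1.5 * np.sqrt(img.shape[0] * img.shape[1] / NATIVE_AREA_PX)
    gray = gaussian_blur(to_grayscale(img), sigma)
    mask = binarize(gray, method=cfg.threshold_method, threshold=cfg.threshold_value)
    min_area = cfg.min_noise_area
    if min_area is None:
        min_area = default_min_area(*mask.shape)
    mask = remove_small_components(mask, min_area)
    if cfg.refine_threshold:
        mask = _refine_components(gray, mask)
    contours = extract_contours(mask, smooth_window=cfg.contour_smooth_window)
    coin = find_coin(
        contours,
        image_width=mask.shape[1],
        circularity_min=cfg.circularity_min,
        min_area=cfg.coin_min_area,
    )
    scale = calibrate_from_contour(coin, cfg.coin_diameter_mm)
    pods = [c for c in contours if c is not coin]
    pods.sort(key=lambda c: c.centroid())
    measurements = [measure_pod(c, scale, i) for i, c in enumerate(pods, start=1)]
    return measurements, scale


def count_pods(measurements: Sequence[PodMeasurement]) -> int:
    return len(measurements)


@dataclass(frozen=True)
class MeasurementSummary:
    """Descriptive statistics of one trait over a set of pods."""

    n: int
    mean: float
    median: float
    mode: float
    min: float
    max: float


def summarize(values: Sequence[float], rounding: int = 1) -> MeasurementSummary:
    """Mean/median/min/max of the raw values; mode of the values rounded
    to ``rounding`` decimals (ties resolved to the smallest value)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty sample")
    rounded = np.round(vals, rounding)
    counts = Counter(rounded.tolist())
    top = max(counts.values())
    mode = min(v for v, k in counts.items() if k == top)
    return MeasurementSummary(
        n=int(vals.size),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        mode=float(mode),
        min=float(vals.min()),
        max=float(vals.max()),
    )


@dataclass(frozen=True)
class ComparisonFit:
    """Ordinary least-squares fit of one measurement series on another,
    e.g. machine-vision length against manual length."""

    slope: float
    intercept: float
    r_squared: float


def compare_measurements(x: Sequence[float], y: Sequence[float]) -> ComparisonFit:
    """OLS regression of ``y`` on ``x`` with the coefficient of
    determination."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = _stats.linregress(x, y)
    return ComparisonFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def annotate_image(
    img: np.ndarray, measurements: Sequence[PodMeasurement]
) -> np.ndarray:
    """Return a copy of the image with each pod's contour outlined and
    its length/width/area printed near the contour centroid.

    The input array is never modified; an empty measurement list yields a
    pixel-identical copy.
    """
    from PIL import Image, ImageDraw

    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    out = Image.fromarray(img.astype(np.uint8))
    if measurements:
        draw = ImageDraw.Draw(out)
        for m in measurements:
            ring = [tuple(p) for p in m.contour.points] + [tuple(m.contour.points[0])]
            draw.line(ring, fill=(255, 60, 60), width=2)
            cx, cy = m.contour.centroid()
            label = (
                f"#{m.pod_id} L={m.length / 10:.1f}cm "
                f"W={m.width / 10:.2f}cm A={m.area:.0f}mm2"
            )
            draw.text((cx + 4, cy + 4), label, fill=(255, 255, 80))
    return np.asarray(out)
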