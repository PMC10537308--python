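"""Seeded synthetic pod scenes with exact ground truth.

Real measurement photographs — pods scattered on black velvet with a
25 mm coin at the far-left edge — are not redistributable, so the test
and example infrastructure renders look-alike scenes instead: a
near-black background, one bright disk for the coin at the left margin,
and elongated pod silhouettes at intermediate intensity.  Every object
is built as an exact vector shape (shapely polygon), rasterized on pixel
centers, and reported with its analytic length, width and area, which
makes measurement-recovery errors attributable to the pipeline rather
than to the fixture.

Straight pods are exact L x w rectangles (a flat-capped buffer of a
centerline segment); bent pods are constant-half-width tubes around a
quadratic Bezier arc with round caps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .imaging import extract_contours

__all__ = [
    "PodSpec",
    "SceneSpec",
    "SceneGroundTruth",
    "PodTruth",
    "render_scene",
    "random_scene",
    "export_annotations",
]


@dataclass(frozen=True)
class PodSpec:
    """One pod: a straight or quadratically bent constant-width tube.

    ``length_mm`` is the centerline length, ``width_mm`` the full width
    (twice the tube half-width).  ``bend`` is the sagitta of the Bezier
    control point as a fraction of the length; 0 means straight.
    """

    center: tuple[float, float]  # px, (x, y)
    length_mm: float
    width_mm: float
    orientation: float = 0.0  # radians, 0 = horizontal
    bend: float = 0.0

    def __post_init__(self) -> None:
        if self.length_mm <= self.width_mm:
            raise ValueError("pod length must exceed its width")
        if self.bend < 0:
            raise ValueError("bend must be >= 0")

    def geometry(self, mm_per_px: float) -> Polygon:
        """Exact silhouette polygon in pixel coordinates."""
        half_len = self.length_mm / (2.0 * mm_per_px)
        half_w = self.width_mm / (2.0 * mm_per_px)
        if self.bend == 0:
            line = LineString([(-half_len, 0.0), (half_len, 0.0)])
            shape = line.buffer(half_w, cap_style="flat", join_style="mitre")
        else:
            sag = self.bend * 2 * half_len
            # quadratic Bezier through (+-half_len, 0) with apex sagitta
            t = np.linspace(0.0, 1.0, 65)
            p0, p1, p2 = np.array([-half_len, 0.0]), np.array([0.0, -2 * sag]), np.array(
                [half_len, 0.0]
            )
            pts = (
                np.outer((1 - t) ** 2, p0)
                + np.outer(2 * t * (1 - t), p1)
                + np.outer(t**2, p2)
            )
            # rescale the arc so its arc length equals length_mm exactly
            arc = LineString(pts)
            pts *= (2 * half_len) / arc.length
            shape = LineString(pts).buffer(half_w, cap_style="round", quad_segs=32)
        cos, sin = math.cos(self.orientation), math.sin(self.orientation)
        rotated = shapely.transform(
            shape,
            lambda a: a @ np.array([[cos, sin], [-sin, cos]]) + np.asarray(self.center),
        )
        return rotated


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic photograph."""

    height: int = 800
    width: int = 1200
    mm_per_px: float = 0.2
    coin_center: tuple[float, float] = (100.0, 120.0)
    coin_diameter_mm: float = 25.0
    pods: tuple[PodSpec, ...] = ()
    background: int = 15
    pod_intensity: int = 150
    coin_intensity: int = 230
    noise_sigma: float = 0.0
    seed: int = 0

    def coin_geometry(self) -> Polygon:
        r = self.coin_diameter_mm / (2.0 * self.mm_per_px)
        return Point(self.coin_center).buffer(r, quad_segs=128)

    def validate(self) -> None:
        if self.coin_center[0] >= self.width / 4:
            raise ValueError("coin must sit in the left quarter of the image")
        geoms = [self.coin_geometry()] + [p.geometry(self.mm_per_px) for p in self.pods]
        for g in geoms:
            minx, miny, maxx, maxy = g.bounds
            if minx < 0 or miny < 0 or maxx >= self.width or maxy >= self.height:
                raise ValueError("object extends beyond the image")
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                if geoms[i].distance(geoms[j]) < 2.0:
                    raise ValueError(f"objects {i} and {j} overlap or touch")


@dataclass(frozen=True)
class PodTruth:
    """Analytic ground truth for one rendered pod."""

    length_mm: float
    width_mm: float
    area_mm2: float
    length_px: float
    width_px: float
    area_px: float
    mask: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SceneGroundTruth:
    coin_mask: np.ndarray
    coin_diameter_px: float
    pods: tuple[PodTruth, ...]
    mm_per_px: float


def _rasterize(geom: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers fall inside the polygon."""
    h, w = shape
    minx, miny, maxx, maxy = geom.bounds
    x0, x1 = max(0, int(minx) - 1), min(w - 1, int(maxx) + 1)
    y0, y1 = max(0, int(miny) - 1), min(h - 1, int(maxy) + 1)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(xs.shape)
    mask = np.zeros(shape, dtype=bool)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    return mask


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render the scene to an (H, W, 3) uint8 image plus exact ground
    truth.  Identical specs produce byte-identical images."""
    spec.validate()
    shape = (spec.height, spec.width)
    canvas = np.full(shape, float(spec.background))

    coin_geom = spec.coin_geometry()
    coin_mask = _rasterize(coin_geom, shape)
    pods: list[PodTruth] = []
    for pod in spec.pods:
        geom = pod.geometry(spec.mm_per_px)
        mask = _rasterize(geom, shape)
        canvas[mask] = spec.pod_intensity
        area_px = geom.area
        pods.append(
            PodTruth(
                length_mm=pod.length_mm,
                width_mm=pod.width_mm,
                area_mm2=area_px * spec.mm_per_px**2,
                length_px=pod.length_mm / spec.mm_per_px,
                width_px=pod.width_mm / spec.mm_per_px,
                area_px=area_px,
                mask=mask,
            )
        )
    canvas[coin_mask] = spec.coin_intensity

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    img = np.stack([img] * 3, axis=-1)

    gt = SceneGroundTruth(
        coin_mask=coin_mask,
        coin_diameter_px=spec.coin_diameter_mm / spec.mm_per_px,
        pods=tuple(pods),
        mm_per_px=spec.mm_per_px,
    )
    return img, gt


def scaled_spec(spec: SceneSpec, factor: float) -> SceneSpec:
    """The same physical scene rendered at ``factor`` times the pixel
    resolution (e.g. 2 doubles the image dimensions and halves
    mm_per_px)."""
    return replace(
        spec,
        height=int(round(spec.height * factor)),
        width=int(round(spec.width * factor)),
        mm_per_px=spec.mm_per_px / factor,
        coin_center=(spec.coin_center[0] * factor, spec.coin_center[1] * factor),
        pods=tuple(
            replace(p, center=(p.center[0] * factor, p.center[1] * factor))
            for p in spec.pods
        ),
    )


#: manual measurement range of real pods: lengths 47-151 mm, widths 2-5 mm
POD_LENGTH_RANGE_MM = (47.0, 151.0)
POD_WIDTH_RANGE_MM = (2.0, 5.0)


def random_scene(
    n_pods: int,
    seed: int = 0,
    difficulty: str = "easy",
    height: int = 800,
    width: int = 1200,
    mm_per_px: float = 0.2,
    max_attempts: int = 2000,
) -> SceneSpec:
    """Sample a non-overlapping scene layout.

    Pod lengths and widths are drawn uniformly from the ranges observed
    on real pods (4.7-15.1 cm long, 0.2-0.5 cm wide).  ``difficulty``:
    'easy' = straight pods, no noise; 'bent' = curved pods; 'noisy' =
    curved pods plus Gaussian sensor noise (sigma 8).
    """
    if n_pods < 0:
        raise ValueError("n_pods must be >= 0")
    if difficulty not in ("easy", "bent", "noisy"):
        raise ValueError(f"unknown difficulty {difficulty!r}")
    rng = np.random.default_rng(seed)
    coin_r_px = 25.0 / (2 * mm_per_px)
    coin_center = (
        float(rng.uniform(coin_r_px + 5, width / 4 - 5)),
        float(rng.uniform(coin_r_px + 5, height - coin_r_px - 5)),
    )
    base = SceneSpec(
        height=height,
        width=width,
        mm_per_px=mm_per_px,
        coin_center=coin_center,
        noise_sigma=8.0 if difficulty == "noisy" else 0.0,
        seed=seed,
    )
    placed: list[PodSpec] = []
    geoms = [base.coin_geometry()]
    attempts = 0
    while len(placed) < n_pods:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placed only {len(placed)}/{n_pods} pods after {max_attempts} "
                "attempts; try fewer pods or a larger scene"
            )
        attempts += 1
        length = float(rng.uniform(*POD_LENGTH_RANGE_MM))
        width_mm = float(rng.uniform(*POD_WIDTH_RANGE_MM))
        orient = float(rng.uniform(0, math.pi))
        bend = 0.0 if difficulty == "easy" else float(rng.uniform(0.02, 0.08))
        half_span = length / (2 * mm_per_px) + 10
        if 2 * half_span > min(height, width) - 20:
            # long pods are kept mostly horizontal so they fit
            orient = float(rng.uniform(-0.3, 0.3))
        span_x = abs(math.cos(orient)) * half_span + 15
        span_y = abs(math.sin(orient)) * half_span + 15
        lo_x, hi_x = span_x, width - span_x
        lo_y, hi_y = span_y, height - span_y
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        pod = PodSpec(
            center=(float(rng.uniform(lo_x, hi_x)), float(rng.uniform(lo_y, hi_y))),
            length_mm=length,
            width_mm=width_mm,
            orientation=orient,
            bend=bend,
        )
        geom = pod.geometry(mm_per_px)
        minx, miny, maxx, maxy = geom.bounds
        if minx < 1 or miny < 1 or maxx >= width - 1 or maxy >= height - 1:
            continue
        if any(geom.distance(g) < 4.0 for g in geoms):
            continue
        placed.append(pod)
        geoms.append(geom)
    return replace(base, pods=tuple(placed))


def export_annotations(
    gt: SceneGroundTruth,
    format: str = "labelme",
    image_path: str = "scene.png",
    include_coin: bool = True,
):
    """Trace the ground-truth masks into polygon annotations.

    Returns a Labelme-dialect document (dict) or a COCO instances
    document via :mod:`podmetrics.dataset_io`, suitable for round-trip
    tests of the annotation tooling.
    """
    from . import dataset_io

    masks: list[tuple[str, np.ndarray]] = []
    if include_coin:
        masks.append(("coin", gt.coin_mask))
    masks.extend(("pod", p.mask) for p in gt.pods)

    shape = masks[0][1].shape if masks else (0, 0)
    instances = []
    for label, mask in masks:
        contours = extract_contours(mask)
        if not contours:
            continue
        instances.append(
            dataset_io.LabeledInstance(
                label=label,
                polygon=contours[0].points.copy(),
                image_path=image_path,
                image_height=shape[0],
                image_width=shape[1],
            )
        )
    if format == "labelme":
        return dataset_io.to_labelme(instances, image_path, shape[0], shape[1])
    if format == "coco":
        categories = sorted({inst.label for inst in instances}) or ["pod"]
        return dataset_io.to_coco(instances, categories)
    raise ValueError(f"unknown annotation format {format!r}")
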