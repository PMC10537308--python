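"""Annotation formats and annotation-consistent augmentation.

Reads Labelme polygon annotations, converts them to COCO instances
JSON, loads external detector output in COCO results JSON (polygon or
run-length-encoded masks), and applies geometric/photometric
augmentations that keep image and polygons in lockstep.

COCO dialect produced here: polygons as flat ``[x1, y1, x2, y2, ...]``
lists, ``iscrowd = 0``, deterministic ids (images sorted by file name,
annotations by image then polygon order), ``bbox`` the tight axis-aligned
box of the polygon and ``area`` its shoelace area.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon, box as _shapely_box
from skimage.draw import polygon as _fill_polygon

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledInstance",
    "AugmentationSpec",
    "read_labelme",
    "to_labelme",
    "to_coco",
    "write_coco",
    "read_coco",
    "coco_to_instances",
    "load_predictions",
    "rle_decode",
    "rle_encode",
    "polygon_to_mask",
    "apply_augmentation",
    "split_dataset",
]


@dataclass
class LabeledInstance:
    """One polygon annotation tied to its source image."""

    label: str
    polygon: np.ndarray  # (N, 2) float, (x, y) image coordinates
    image_path: str
    image_height: int
    image_width: int

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("polygon needs at least 3 (x, y) points")
        self.polygon = poly

    def clipped(self) -> "LabeledInstance":
        """Copy with vertices clipped into the image bounds."""
        poly = self.polygon.copy()
        poly[:, 0] = np.clip(poly[:, 0], 0, self.image_width - 1)
        poly[:, 1] = np.clip(poly[:, 1], 0, self.image_height - 1)
        return LabeledInstance(
            self.label, poly, self.image_path, self.image_height, self.image_width
        )

    @property
    def area(self) -> float:
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return abs(
            float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0
        )

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(x, y, w, h) tight axis-aligned box."""
        x0, y0 = self.polygon.min(axis=0)
        x1, y1 = self.polygon.max(axis=0)
        return float(x0), float(y0), float(x1 - x0), float(y1 - y0)


# ---------------------------------------------------------------------------
# Labelme
# ---------------------------------------------------------------------------

def read_labelme(path: str | Path) -> list[LabeledInstance]:
    """Read a Labelme JSON file into LabeledInstance records.

    Non-polygon shapes are skipped with a warning.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed Labelme JSON in {path}: {exc}") from exc
    if "imageHeight" not in doc or "imageWidth" not in doc:
        raise ValueError(f"{path}: missing imageHeight/imageWidth")
    h, w = int(doc["imageHeight"]), int(doc["imageWidth"])
    image_path = doc.get("imagePath", path.with_suffix(".png").name)
    out: list[LabeledInstance] = []
    for shape in doc.get("shapes", []):
        if shape.get("shape_type", "polygon") != "polygon":
            logger.warning(
                "%s: skipping non-polygon shape of type %r",
                path,
                shape.get("shape_type"),
            )
            continue
        out.append(
            LabeledInstance(
                label=shape["label"],
                polygon=np.asarray(shape["points"], dtype=float),
                image_path=image_path,
                image_height=h,
                image_width=w,
            ).clipped()
        )
    return out


def to_labelme(
    instances: Sequence[LabeledInstance],
    image_path: str,
    height: int,
    width: int,
) -> dict:
    """Build a Labelme-dialect document for one image."""
    return {
        "version": "5.0.0",
        "flags": {},
        "shapes": [
            {
                "label": inst.label,
                "points": inst.polygon.tolist(),
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
            for inst in instances
        ],
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": int(height),
        "imageWidth": int(width),
    }


# ---------------------------------------------------------------------------
# COCO instances
# ---------------------------------------------------------------------------

def to_coco(
    instances: Iterable[LabeledInstance],
    categories: Sequence[str] = ("pod",),
) -> dict:
    """Convert labeled polygons to a COCO instances document.

    Category ids are assigned 1..k in the given order; an instance whose
    label is missing from ``categories`` is an error.
    """
    instances = list(instances)
    cat_id = {name: i for i, name in enumerate(categories, start=1)}
    unknown = sorted({i.label for i in instances} - set(cat_id))
    if unknown:
        raise ValueError(f"labels not in categories: {unknown}")

    by_image: dict[str, list[LabeledInstance]] = {}
    sizes: dict[str, tuple[int, int]] = {}
    for inst in instances:
        by_image.setdefault(inst.image_path, []).append(inst)
        size = (inst.image_height, inst.image_width)
        if sizes.setdefault(inst.image_path, size) != size:
            raise ValueError(f"inconsistent sizes recorded for {inst.image_path}")

    images, annotations = [], []
    ann_id = 1
    for img_id, name in enumerate(sorted(by_image), start=1):
        h, w = sizes[name]
        images.append({"id": img_id, "file_name": name, "height": h, "width": w})
        for inst in by_image[name]:
            x, y, bw, bh = inst.bbox
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": cat_id[inst.label],
                    "segmentation": [inst.polygon.ravel().tolist()],
                    "bbox": [x, y, bw, bh],
                    "area": inst.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": i, "name": name} for name, i in cat_id.items()
        ],
    }


def write_coco(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"{path}: not a COCO instances document (no {key!r})")
    return doc


def coco_to_instances(doc: dict) -> list[LabeledInstance]:
    """Decode a COCO instances document back to polygon records (first
    polygon part of each segmentation)."""
    images = {im["id"]: im for im in doc["images"]}
    names = {c["id"]: c["name"] for c in doc["categories"]}
    out = []
    for ann in doc["annotations"]:
        im = images[ann["image_id"]]
        seg = ann["segmentation"]
        if not (isinstance(seg, list) and seg and isinstance(seg[0], (list, tuple))):
            raise ValueError(f"annotation {ann['id']}: polygon segmentation required")
        flat = np.asarray(seg[0], dtype=float)
        out.append(
            LabeledInstance(
                label=names[ann["category_id"]],
                polygon=flat.reshape(-1, 2),
                image_path=im["file_name"],
                image_height=im["height"],
                image_width=im["width"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# masks: polygon rasterization and COCO RLE
# ---------------------------------------------------------------------------

def polygon_to_mask(polygon: np.ndarray, height: int, width: int) -> np.ndarray:
    """Rasterize an (N, 2) (x, y) polygon to a boolean mask."""
    polygon = np.asarray(polygon, dtype=float)
    rr, cc = _fill_polygon(polygon[:, 1], polygon[:, 0], shape=(height, width))
    mask = np.zeros((height, width), dtype=bool)
    mask[rr, cc] = True
    return mask


def rle_decode(rle: Mapping) -> np.ndarray:
    """Decode a COCO RLE dict (uncompressed counts list or compressed
    LEB128-style string) to a boolean mask.

    COCO RLE runs are column-major and start with a background run.
    """
    h, w = rle["size"]
    counts = rle["counts"]
    if isinstance(counts, str):
        counts = _rle_string_decode(counts)
    counts = list(counts)
    total = h * w
    flat = np.zeros(total, dtype=bool)
    pos = 0
    val = False
    for run in counts:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    if pos != total:
        raise ValueError(f"RLE runs sum to {pos}, expected {total}")
    return flat.reshape((w, h)).T  # column-major


def rle_encode(mask: np.ndarray, compress: bool = False) -> dict:
    """Encode a boolean mask as COCO RLE (uncompressed by default)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.T.ravel()
    # run lengths, first run is background (possibly length 0)
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate([[0], changes + 1, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat.size and flat[0]:
        runs = [0] + runs
    counts = runs if runs else [0]
    if compress:
        return {"size": [h, w], "counts": _rle_string_encode(counts)}
    return {"size": [h, w], "counts": counts}


def _rle_string_decode(s: str) -> list[int]:
    """COCO's modified-LEB128 RLE string: 6-bit groups, continuation bit,
    sign extension, and delta coding of every run after the second."""
    counts: list[int] = []
    i = 0
    while i < len(s):
        x, k = 0, 0
        more = True
        while more:
            c = ord(s[i]) - 48
            x |= (c & 0x1F) << (5 * k)
            more = bool(c & 0x20)
            i += 1
            if not more and (c & 0x10):
                x |= -1 << (5 * (k + 1))
            k += 1
        if len(counts) > 2:
            x += counts[-2]
        counts.append(x)
    return counts


def _rle_string_encode(counts: Sequence[int]) -> str:
    chars: list[str] = []
    for idx, run in enumerate(counts):
        x = int(run)
        if idx > 2:
            x -= int(counts[idx - 2])
        more = True
        while more:
            c = x & 0x1F
            x >>= 5
            more = not ((x == 0 and not (c & 0x10)) or (x == -1 and (c & 0x10)))
            if more:
                c |= 0x20
            chars.append(chr(c + 48))
    return "".join(chars)


def load_predictions(
    path: str | Path,
    score_threshold: float = 0.0,
    image_sizes: Mapping[int, tuple[int, int]] | None = None,
) -> dict[int, list[tuple[np.ndarray, float]]]:
    """Load a COCO results JSON into per-image (mask, score) lists.

    Segmentations may be polygons (requires ``image_sizes`` mapping
    image_id -> (H, W)) or RLE dicts (carry their own size).  Records
    below ``score_threshold`` are dropped.
    """
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise ValueError(f"{path}: COCO results JSON must be a list")
    out: dict[int, list[tuple[np.ndarray, float]]] = {}
    for rec in records:
        score = float(rec["score"])
        if score < score_threshold:
            continue
        seg = rec["segmentation"]
        if isinstance(seg, Mapping):
            mask = rle_decode(seg)
        elif isinstance(seg, list) and seg and isinstance(seg[0], (list, tuple)):
            if image_sizes is None or rec["image_id"] not in image_sizes:
                raise ValueError(
                    "polygon predictions need image_sizes[image_id] = (H, W)"
                )
            h, w = image_sizes[rec["image_id"]]
            mask = polygon_to_mask(np.asarray(seg[0], dtype=float).reshape(-1, 2), h, w)
        else:
            raise ValueError(
                f"unknown segmentation encoding in record for image "
                f"{rec.get('image_id')}"
            )
        out.setdefault(int(rec["image_id"]), []).append((mask, score))
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUGMENTATION_OPS = (
    "hflip",
    "vflip",
    "rotate",
    "scale",
    "crop",
    "noise",
    "blur",
    "cutout",
    "color_jitter",
    "mosaic",
)

#: fraction of its area an instance must keep after cropping to survive
MIN_VISIBLE_FRACTION = 0.2


@dataclass(frozen=True)
class AugmentationSpec:
    """One augmentation operation; all randomness derives from ``seed``."""

    op: str
    params: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.op not in AUGMENTATION_OPS:
            raise ValueError(f"unknown augmentation op {self.op!r}")


def _transform_polys(instances, matrix: np.ndarray, offset: np.ndarray, h, w):
    out = []
    for inst in instances:
        poly = inst.polygon @ matrix.T + offset
        out.append(
            LabeledInstance(inst.label, poly, inst.image_path, int(h), int(w))
        )
    return out


def apply_augmentation(
    img,
    instances: Sequence[LabeledInstance],
    spec: AugmentationSpec,
):
    """Apply one augmentation to an image and its polygon annotations.

    Geometric ops move image and polygons through the same map;
    photometric ops (noise, blur, color_jitter, cutout) leave the
    polygons untouched.  ``mosaic`` expects ``img`` and ``instances`` to
    be lists of four.  Returns ``(image, instances)``.
    """
    p = dict(spec.params)
    if spec.op == "mosaic":
        return _mosaic(img, instances)
    img = np.asarray(img)
    h, w = img.shape[:2]

    if spec.op == "hflip":
        out = img[:, ::-1].copy()
        m = np.array([[-1.0, 0.0], [0.0, 1.0]])
        return out, _transform_polys(instances, m, np.array([w - 1.0, 0.0]), h, w)
    if spec.op == "vflip":
        out = img[::-1].copy()
        m = np.array([[1.0, 0.0], [0.0, -1.0]])
        return out, _transform_polys(instances, m, np.array([0.0, h - 1.0]), h, w)
    if spec.op == "rotate":
        return _rotate(img, instances, float(p.get("angle", 90.0)))
    if spec.op == "scale":
        return _scale(img, instances, float(p.get("factor", 1.5)))
    if spec.op == "crop":
        return _crop(img, instances, p)
    if spec.op == "noise":
        rng = np.random.default_rng(spec.seed)
        sigma = float(p.get("sigma", 10.0))
        out = np.clip(
            img.astype(float) + rng.normal(0, sigma, img.shape), 0, 255
        ).astype(img.dtype)
        return out, list(instances)
    if spec.op == "blur":
        sigma = float(p.get("sigma", 1.5))
        out = ndimage.gaussian_filter(
            img.astype(float), sigma=(sigma, sigma, 0)[: img.ndim], mode="reflect"
        )
        return out.astype(img.dtype), list(instances)
    if spec.op == "cutout":
        rng = np.random.default_rng(spec.seed)
        n = int(p.get("count", 3))
        size = float(p.get("size_fraction", 0.1))
        out = img.copy()
        for _ in range(n):
            ch = max(1, int(h * size)), max(1, int(w * size))
            r = rng.integers(0, h - ch[0] + 1)
            c = rng.integers(0, w - ch[1] + 1)
            out[r : r + ch[0], c : c + ch[1]] = 0
        return out, list(instances)
    if spec.op == "color_jitter":
        rng = np.random.default_rng(spec.seed)
        brightness = float(p.get("brightness", 0.2))
        contrast = float(p.get("contrast", 0.2))
        saturation = float(p.get("saturation", 0.2))
        out = img.astype(float)
        out = out * float(rng.uniform(1 - contrast, 1 + contrast))
        out = out + float(rng.uniform(-brightness, brightness)) * 255.0
        if out.ndim == 3:
            gray = out.mean(axis=2, keepdims=True)
            s = float(rng.uniform(1 - saturation, 1 + saturation))
            out = gray + (out - gray) * s
        return np.clip(out, 0, 255).astype(img.dtype), list(instances)
    raise AssertionError(f"unhandled op {spec.op}")  # pragma: no cover


def _rotate(img, instances, angle: float):
    h, w = img.shape[:2]
    k = round(angle / 90.0)
    if math.isclose(angle, 90.0 * k, abs_tol=1e-9):
        # exact quarter-turn path: lossless on pixels and polygons
        k %= 4
        out = np.ascontiguousarray(np.rot90(img, k=-k))  # clockwise on screen
        insts = list(instances)
        hh, ww = h, w
        for _ in range(k % 4):
            m = np.array([[0.0, -1.0], [1.0, 0.0]])  # (x,y) -> (-y, x)
            insts = _transform_polys(insts, m, np.array([hh - 1.0, 0.0]), ww, hh)
            hh, ww = ww, hh
        return out, insts

    from skimage.transform import AffineTransform, warp

    theta = math.radians(angle)
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    rot = AffineTransform(rotation=theta)
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    moved = (corners - center) @ rot.params[:2, :2].T
    shift = -moved.min(axis=0)
    out_w = int(math.ceil(np.ptp(moved[:, 0]))) + 1
    out_h = int(math.ceil(np.ptp(moved[:, 1]))) + 1
    tform = AffineTransform(translation=tuple(-center)) + rot + AffineTransform(
        translation=tuple(shift)
    )
    out = warp(
        img.astype(float), tform.inverse, output_shape=(out_h, out_w), order=1, cval=0
    )
    m = tform.params[:2, :2]
    off = tform.params[:2, 2]
    return out.astype(img.dtype), _transform_polys(instances, m, off, out_h, out_w)


def _scale(img, instances, s: float):
    if s <= 0:
        raise ValueError("scale factor must be positive")
    from skimage.transform import resize

    h, w = img.shape[:2]
    out_h, out_w = max(1, round(h * s)), max(1, round(w * s))
    out = resize(
        img.astype(float), (out_h, out_w), order=1, anti_aliasing=s < 1
    ).astype(img.dtype)
    m = np.array([[s, 0.0], [0.0, s]])
    return out, _transform_polys(instances, m, np.zeros(2), out_h, out_w)


def _crop(img, instances, p):
    h, w = img.shape[:2]
    x0 = int(p.get("x", 0))
    y0 = int(p.get("y", 0))
    cw = int(p.get("width", w - x0))
    ch = int(p.get("height", h - y0))
    if not (0 <= x0 < w and 0 <= y0 < h and cw > 0 and ch > 0):
        raise ValueError("invalid crop window")
    cw, ch = min(cw, w - x0), min(ch, h - y0)
    out = img[y0 : y0 + ch, x0 : x0 + cw].copy()
    window = _shapely_box(x0, y0, x0 + cw, y0 + ch)
    kept, dropped = [], 0
    for inst in instances:
        poly = _ShapelyPolygon(inst.polygon)
        if not poly.is_valid:
            poly = poly.buffer(0)
        clipped = poly.intersection(window)
        if clipped.is_empty or clipped.area < MIN_VISIBLE_FRACTION * poly.area:
            dropped += 1
            continue
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        pts = np.asarray(clipped.exterior.coords)[:-1] - np.array([x0, y0])
        kept.append(LabeledInstance(inst.label, pts, inst.image_path, ch, cw))
    if dropped:
        logger.info("crop dropped %d instance(s) below visibility threshold", dropped)
    return out, kept


def _mosaic(imgs, instance_lists):
    if len(imgs) != 4 or len(instance_lists) != 4:
        raise ValueError("mosaic requires exactly 4 images and 4 instance lists")
    imgs = [np.asarray(im) for im in imgs]
    h = max(im.shape[0] for im in imgs)
    w = max(im.shape[1] for im in imgs)
    sample = imgs[0]
    shape = (2 * h, 2 * w) + sample.shape[2:]
    canvas = np.zeros(shape, dtype=sample.dtype)
    origins = [(0, 0), (0, w), (h, 0), (h, w)]
    out_instances = []
    for im, insts, (oy, ox) in zip(imgs, instance_lists, origins):
        ih, iw = im.shape[:2]
        canvas[oy : oy + ih, ox : ox + iw] = im
        for inst in insts:
            out_instances.append(
                LabeledInstance(
                    inst.label,
                    inst.polygon + np.array([ox, oy], dtype=float),
                    inst.image_path,
                    2 * h,
                    2 * w,
                )
            )
    return canvas, out_instances


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

def split_dataset(doc: dict, train_fraction: float = 0.9, seed: int = 0):
    """Split a COCO instances document at the image level.

    The training set receives ``ceil(n * train_fraction)`` images after a
    seeded shuffle; no image appears in both halves.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    images = sorted(doc["images"], key=lambda im: im["file_name"])
    n = len(images)
    if n < 2:
        raise ValueError("need at least 2 images to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = math.ceil(n * train_fraction)
    train_ids = {images[i]["id"] for i in order[:n_train]}

    def subset(keep: set) -> dict:
        return {
            "images": [im for im in doc["images"] if im["id"] in keep],
            "annotations": [
                a for a in doc["annotations"] if a["image_id"] in keep
            ],
            "categories": doc["categories"],
        }

    all_ids = {im["id"] for im in doc["images"]}
    return subset(train_ids), subset(all_ids - train_ids)
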