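"""Annotation schema, dataset splitting, class weighting and augmentation.

Boxes follow one convention everywhere in this package: 0-based pixel
coordinates, x to the right, y down, ``(x, y, w, h)`` half-open (a box
covers columns ``x .. x+w-1``).  Annotation files are COCO-style JSON with
fixed category ids 1..6 for the six stages in maturation order and 7 for
DOUBTFUL.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import filters as _skfilters
from skimage import transform as _sktransform

from .stages import StageClass, stage_from_any

Box = tuple[float, float, float, float]


@dataclass(frozen=True)
class BoxAnnotation:
    """A labeled bounding box on one image."""

    image_id: str
    bbox: Box
    stage: StageClass
    source: str = "manual"  # {manual, inferred}

    def __post_init__(self):
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate box {self.bbox}")

    def clipped(self, width: int, height: int) -> "BoxAnnotation | None":
        """Clip to image bounds; None if nothing remains."""
        x, y, w, h = self.bbox
        x0, y0 = max(x, 0.0), max(y, 0.0)
        x1, y1 = min(x + w, float(width)), min(y + h, float(height))
        if x1 - x0 <= 0 or y1 - y0 <= 0:
            return None
        return replace(self, bbox=(x0, y0, x1 - x0, y1 - y0))


# ---------------------------------------------------------------------------
# COCO-style JSON I/O

CATEGORY_IDS = {s: s.value for s in StageClass}  # 1=T .. 6=MP, 7=DOUBTFUL
CATEGORY_NAMES = {
    StageClass.TETRAD: "tetrad",
    StageClass.YOUNG_MICROSPORE: "young microspore",
    StageClass.MEDIUM_MICROSPORE: "medium microspore",
    StageClass.VACUOLATED_MICROSPORE: "vacuolated microspore",
    StageClass.YOUNG_POLLEN: "young pollen",
    StageClass.MATURE_POLLEN: "mature pollen",
    StageClass.DOUBTFUL: "doubtful",
}


def to_coco(annotations, image_sizes=None) -> dict:
    """Build a COCO-style dict from BoxAnnotations.

    image_sizes: optional mapping image_id -> (width, height).
    """
    image_ids = sorted({a.image_id for a in annotations})
    id_map = {im: i + 1 for i, im in enumerate(image_ids)}
    images = []
    for im in image_ids:
        entry = {"id": id_map[im], "file_name": str(im)}
        if image_sizes and im in image_sizes:
            entry["width"], entry["height"] = image_sizes[im]
        images.append(entry)
    anns = [
        {
            "id": i + 1,
            "image_id": id_map[a.image_id],
            "category_id": CATEGORY_IDS[a.stage],
            "bbox": [float(v) for v in a.bbox],
            "area": float(a.bbox[2] * a.bbox[3]),
            "iscrowd": 0,
            "source": a.source,
        }
        for i, a in enumerate(annotations)
    ]
    categories = [
        {"id": CATEGORY_IDS[s], "name": CATEGORY_NAMES[s], "supercategory": "cell"}
        for s in StageClass
    ]
    return {"images": images, "annotations": anns, "categories": categories}


def write_coco(annotations, path, image_sizes=None) -> None:
    with open(path, "w") as fh:
        json.dump(to_coco(annotations, image_sizes), fh, indent=1)


def from_coco(doc: dict) -> list[BoxAnnotation]:
    names = {im["id"]: im.get("file_name", str(im["id"])) for im in doc["images"]}
    out = []
    for ann in doc["annotations"]:
        out.append(
            BoxAnnotation(
                image_id=names[ann["image_id"]],
                bbox=tuple(ann["bbox"]),
                stage=StageClass(ann["category_id"]),
                source=ann.get("source", "manual"),
            )
        )
    return out


def read_coco(path) -> list[BoxAnnotation]:
    with open(path) as fh:
        return from_coco(json.load(fh))


# ---------------------------------------------------------------------------
# Dataset splitting

PARTITIONS = ("train", "test", "val")


@dataclass
class DatasetSplit:
    """Image-level train/test/val partition stratified by dominant class."""

    proportions: tuple[float, float, float]
    assignment: dict  # image_id -> partition name
    per_class_counts: dict  # partition -> {StageClass: n_images (dominant)}
    max_deviation: float  # worst |class share in partition - global share|
    warnings: list = field(default_factory=list)

    @property
    def sizes(self) -> tuple[int, int, int]:
        c = Counter(self.assignment.values())
        return tuple(c.get(p, 0) for p in PARTITIONS)

    def images(self, partition: str) -> list:
        return sorted(i for i, p in self.assignment.items() if p == partition)


def largest_remainder(n: int, proportions) -> list[int]:
    """Integer apportionment of n by the largest-remainder (Hare) rule."""
    quotas = [n * p for p in proportions]
    base = [math.floor(q) for q in quotas]
    short = n - sum(base)
    order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def dominant_class(boxes) -> StageClass:
    """Most frequent non-DOUBTFUL stage of an image (ties -> earlier stage)."""
    counts = Counter(b.stage for b in boxes if b.stage is not StageClass.DOUBTFUL)
    if not counts:
        return StageClass.DOUBTFUL
    return min(counts, key=lambda s: (-counts[s], s.value))


def make_splits(annotations, proportions=(0.8, 0.1, 0.1), seed=0, tolerance=0.02):
    """Split images into train/test/val, stratified on each image's dominant class.

    Partition sizes follow largest-remainder rounding of ``proportions`` times
    the number of images; within that constraint each dominant-class group is
    spread across partitions so the class mixture of every partition stays
    within ``tolerance`` of the global mixture (deviation reported if not
    attainable).  Deterministic given ``seed``.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    by_image = defaultdict(list)
    for a in annotations:
        by_image[a.image_id].append(a)
    images = sorted(by_image)
    n = len(images)
    if n == 0:
        raise ValueError("no images to split")
    targets = dict(zip(PARTITIONS, largest_remainder(n, proportions)))

    rng = np.random.default_rng(seed)
    groups = defaultdict(list)
    for im in images:
        groups[dominant_class(by_image[im])].append(im)
    warnings = []
    for cls, ims in sorted(groups.items(), key=lambda kv: kv[0].value):
        if len(ims) < 3:
            warnings.append(
                f"class {cls.short} present in only {len(ims)} image(s); "
                "stratification is degenerate"
            )

    # Per-(group, partition) quotas: floors first, then distribute the
    # leftovers by largest fractional remainder subject to partition capacity.
    capacity = dict(targets)
    alloc = {}
    leftover = {}
    cells = []
    for cls in sorted(groups, key=lambda s: s.value):
        ims = groups[cls]
        rng.shuffle(ims)
        n_g = len(ims)
        quota = {p: n_g * prop for p, prop in zip(PARTITIONS, proportions)}
        base = {p: math.floor(quota[p]) for p in PARTITIONS}
        for p in PARTITIONS:
            alloc[cls, p] = base[p]
            capacity[p] -= base[p]
        leftover[cls] = n_g - sum(base.values())
        cells.extend(
            (quota[p] - base[p], p, cls) for p in PARTITIONS
        )
    cells.sort(key=lambda t: (-t[0], PARTITIONS.index(t[1]), t[2].value))
    for frac, p, cls in cells:
        if leftover[cls] > 0 and capacity[p] > 0:
            alloc[cls, p] += 1
            leftover[cls] -= 1
            capacity[p] -= 1
    # Mop up any dead-ends of the greedy pass.
    for cls in sorted(leftover, key=lambda s: s.value):
        while leftover[cls] > 0:
            p = max(PARTITIONS, key=lambda q: capacity[q])
            alloc[cls, p] += 1
            leftover[cls] -= 1
            capacity[p] -= 1

    assignment = {}
    per_class = {p: Counter() for p in PARTITIONS}
    for cls in sorted(groups, key=lambda s: s.value):
        ims = groups[cls]
        i = 0
        for p in PARTITIONS:
            for im in ims[i : i + alloc[cls, p]]:
                assignment[im] = p
                per_class[p][cls] += 1
            i += alloc[cls, p]

    global_share = {cls: len(groups[cls]) / n for cls in groups}
    max_dev = 0.0
    for p in PARTITIONS:
        tot = max(sum(per_class[p].values()), 1)
        for cls in groups:
            dev = abs(per_class[p][cls] / tot - global_share[cls])
            max_dev = max(max_dev, dev)
    if max_dev > tolerance:
        warnings.append(
            f"per-class proportion deviation {max_dev:.3f} exceeds "
            f"tolerance {tolerance}; best split returned"
        )
    return DatasetSplit(
        proportions=tuple(proportions),
        assignment=assignment,
        per_class_counts={p: dict(per_class[p]) for p in PARTITIONS},
        max_deviation=max_dev,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Class-imbalance weights


def class_weights(per_class_counts) -> dict:
    """Inverse-frequency class weights.

    weight_c ∝ 1/count_c, normalized so that sum_c weight_c * count_c equals
    the total count (equal counts therefore give unit weights, and scaling
    every count leaves the weights unchanged).
    """
    counts = {stage_from_any(k): int(v) for k, v in dict(per_class_counts).items()}
    for cls, c in counts.items():
        if c <= 0:
            raise ValueError(f"class {cls.short} has zero count; weight undefined")
    total = sum(counts.values())
    k = total / len(counts)
    return {cls: k / c for cls, c in counts.items()}


# ---------------------------------------------------------------------------
# Augmentation


def _rot90_box(box: Box, width: int) -> Box:
    """Box transform matching one 90° counter-clockwise np.rot90."""
    x, y, w, h = box
    return (y, width - x - w, h, w)


def augment(image, boxes, op_spec, seed=0):
    """Apply geometric/blur augmentations to an image and its boxes.

    ``op_spec`` is a sequence of (name, param) pairs applied in order:

    - ``("rot90", k)``          : k quarter-turns counter-clockwise (exact).
    - ``("rotate", deg)``       : small free rotation; deg may be a (lo, hi)
                                  range sampled with ``seed``.
    - ``("blur", sigma)``       : Gaussian blur; boxes untouched.
    - ``("scale", factor)``     : isotropic rescale; factor may be a range.

    Boxes are transformed consistently with the pixels, re-clipped to the
    output bounds; a box pushed fully outside is dropped (logged in the
    returned ``dropped`` list).
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image)
    was_uint8 = img.dtype == np.uint8
    work = img.astype(float) / 255.0 if was_uint8 else img.astype(float)
    boxes = list(boxes)
    dropped = []

    def _param(p):
        if isinstance(p, (tuple, list)) and len(p) == 2:
            return float(rng.uniform(*p))
        return float(p)

    for name, param in op_spec:
        h, w = work.shape[:2]
        if name == "rot90":
            k = int(param) % 4
            for _ in range(k):
                cur_w = work.shape[1]
                work = np.rot90(work)
                boxes = [replace(b, bbox=_rot90_box(b.bbox, cur_w)) for b in boxes]
        elif name == "rotate":
            deg = _param(param)
            work = _sktransform.rotate(work, deg, resize=False, mode="edge")
            cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
            th = math.radians(deg)  # CCW in image (y-down) convention
            cos, sin = math.cos(th), math.sin(th)
            new_boxes = []
            for b in boxes:
                x, y, bw, bh = b.bbox
                corners = np.array(
                    [[x, y], [x + bw, y], [x, y + bh], [x + bw, y + bh]], float
                )
                dx, dy = corners[:, 0] - cx, corners[:, 1] - cy
                rx = cx + cos * dx + sin * dy
                ry = cy - sin * dx + cos * dy
                nb = replace(
                    b,
                    bbox=(rx.min(), ry.min(), rx.max() - rx.min(), ry.max() - ry.min()),
                )
                nb = nb.clipped(w, h)
                (new_boxes.append(nb) if nb else dropped.append(b))
            boxes = new_boxes
        elif name == "blur":
            sigma = _param(param)
            work = _skfilters.gaussian(work, sigma=sigma, preserve_range=True)
        elif name == "scale":
            s = _param(param)
            work = _sktransform.rescale(
                work, s, anti_aliasing=s < 1, preserve_range=True, channel_axis=None
            )
            nh, nw = work.shape[:2]
            new_boxes = []
            for b in boxes:
                x, y, bw, bh = b.bbox
                nb = replace(b, bbox=(x * s, y * s, bw * s, bh * s)).clipped(nw, nh)
                (new_boxes.append(nb) if nb else dropped.append(b))
            boxes = new_boxes
        else:
            raise ValueError(f"unknown augmentation op {name!r}")

    out = (
        np.clip(np.round(work * 255.0), 0, 255).astype(np.uint8) if was_uint8 else work
    )
    return out, boxes, dropped


def count_events(per_class_counts) -> int:
    """Total labeled cellular events in a per-class count table."""
    return int(sum(int(v) for v in dict(per_class_counts).values()))
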