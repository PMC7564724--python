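"""Stage detection: detector contract plus a morphology-rule baseline.

Any object mapping an image to a list of :class:`Detection` honors the
detector contract (the production system drops a trained neural detector
into the same slot; its training is out of scope here).  The shipped
baseline keeps the pipeline exercisable end to end: candidate cells are
segmented by intensity thresholding against the background mode, their
morphology descriptors measured (size, opacity, circularity, exine rim,
rhomboid fit, vacuole contrast), and each candidate scored against
per-stage trapezoidal membership rules calibrated to the simulator's stage
parameters.  Scores form a proper distribution over the six stages — the
continuous, confidence-weighted assignment used instead of a hard label.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton
from skimage.segmentation import watershed

from .detmetrics import iou
from .geometry import DEFAULT_GEOMETRY
from .stages import DETECTABLE_STAGES, StageClass, stage_from_any

FEATURE_NAMES = (
    "equivalent_diameter",
    "mean_opacity",
    "circularity",
    "rim_thickness",
    "rhomboidness",
    "interior_variance",
    "vacuole_score",
)


@dataclass(frozen=True)
class MorphFeatures:
    """Morphology descriptors of one segmented cell."""

    equivalent_diameter: float  # µm
    mean_opacity: float  # [0,1], 1 = fully dark
    circularity: float  # 4*pi*A/P^2
    rim_thickness: float  # µm
    rhomboidness: float  # 0 disc .. 1 diamond
    interior_variance: float  # intensity² (on [0,1] scale)
    vacuole_score: float  # [0,1] bright-core contrast

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


@dataclass
class Detection:
    """One detected cell: box plus a score distribution over the six stages."""

    bbox: tuple[float, float, float, float]
    scores: np.ndarray  # 6-vector over DETECTABLE_STAGES, sums to 1

    def __post_init__(self):
        self.scores = np.asarray(self.scores, float)
        if self.scores.shape != (6,):
            raise ValueError("scores must be a 6-vector over the six stages")
        if np.any(self.scores < -1e-9) or abs(self.scores.sum() - 1.0) > 1e-6:
            raise ValueError("scores must be a distribution (non-negative, sum 1)")

    @property
    def top_class(self) -> StageClass:
        return DETECTABLE_STAGES[int(np.argmax(self.scores))]

    @property
    def confidence(self) -> float:
        return float(self.scores.max())

    def score_of(self, stage) -> float:
        return float(self.scores[DETECTABLE_STAGES.index(stage_from_any(stage))])


# ---------------------------------------------------------------------------
# Segmentation


def _as_float(img) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim == 3:
        a = a.mean(axis=2)
    return a.astype(float) / 255.0 if a.dtype == np.uint8 else a.astype(float)


def _background_mode(img: np.ndarray) -> float:
    hist, edges = np.histogram(img.ravel(), bins=128)
    i = int(hist.argmax())
    return float((edges[i] + edges[i + 1]) / 2)


def segment_cells(
    image,
    min_diameter_um=10.0,
    max_diameter_um=55.0,
    pixel_pitch=DEFAULT_GEOMETRY.pixel_pitch,
    threshold_drop=0.10,
):
    """Segment candidate cells from a brightfield tile.

    Foreground = pixels darker than the background mode by more than
    ``threshold_drop`` (on a [0,1] intensity scale); holes (bright vacuoles)
    are filled, connected components are gated on equivalent diameter, and a
    component showing two clear distance-transform peaks is split by
    watershed (touching pair).  Returns a list of (mask, bbox) in the input
    frame.
    """
    img = _as_float(image)
    if img.size == 0:
        return []
    bg = _background_mode(img)
    fg = img < bg - threshold_drop
    fg = ndi.binary_fill_holes(ndi.binary_opening(fg, np.ones((3, 3), bool)))
    labeled = cc_label(fg)
    out = []
    min_area = math.pi * (min_diameter_um / pixel_pitch / 2) ** 2
    max_area = math.pi * (max_diameter_um / pixel_pitch / 2) ** 2
    for idx in range(1, labeled.max() + 1):
        comp = labeled == idx
        area = comp.sum()
        if area < min_area:
            continue
        pieces = [comp] if area <= max_area else _watershed_split(comp, min_diameter_um / pixel_pitch)
        if area > max_area and len(pieces) == 1:
            continue  # oversized blob that would not split: reject
        for piece in pieces:
            pa = piece.sum()
            if not (min_area <= pa <= max_area):
                continue
            ys, xs = np.nonzero(piece)
            bbox = (int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))
            out.append((piece, bbox))
    return out


def _watershed_split(mask: np.ndarray, min_diameter_px: float):
    """Split a touching pair by distance-transform watershed (two-peak test)."""
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist,
        min_distance=max(int(min_diameter_px / 2), 3),
        threshold_abs=0.3 * float(dist.max()),
        labels=mask,
    )
    if len(peaks) < 2:
        return [mask]
    markers = np.zeros(mask.shape, int)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    ws = watershed(-dist, markers, mask=mask)
    return [ws == i for i in range(1, len(peaks) + 1)]


# ---------------------------------------------------------------------------
# Feature extraction

_EXTENT_DISC = math.pi / 4.0
_EXTENT_DIAMOND = 0.5


def extract_features(
    mask, image, pixel_pitch=DEFAULT_GEOMETRY.pixel_pitch, background=None
) -> MorphFeatures:
    """Measure morphology descriptors of one segmented cell.

    ``background`` is the reference white level; when omitted it is
    estimated from the pixels around the mask (falling back to the image
    mode).  Opacity is 1 minus the background-normalized mean interior
    intensity, per the brightfield convention that opaque cells are dark.
    """
    mask = np.asarray(mask, bool)
    img = _as_float(image)
    area = int(mask.sum())
    if area < 4:
        raise ValueError("degenerate mask (needs at least a few pixels)")
    if background is None:
        halo = ndi.binary_dilation(mask, iterations=6) & ~mask
        background = float(np.median(img[halo])) if halo.any() else _background_mode(img)
    background = max(background, 1e-6)

    eq_d = 2.0 * math.sqrt(area / math.pi) * pixel_pitch
    perim = perimeter_crofton(mask, directions=4)
    circularity = min(4 * math.pi * area / perim**2, 1.0) if perim > 0 else 0.0
    interior = img[mask]
    mean_opacity = float(np.clip(1.0 - interior.mean() / background, 0.0, 1.0))
    interior_variance = float(interior.var())

    ys, xs = np.nonzero(mask)
    w = int(xs.max() - xs.min() + 1)
    h = int(ys.max() - ys.min() + 1)
    extent = area / (w * h)
    rhomboidness = float(
        np.clip((_EXTENT_DISC - extent) / (_EXTENT_DISC - _EXTENT_DIAMOND), 0.0, 1.0)
    )

    dist = ndi.distance_transform_edt(mask)
    dmax = float(dist.max())
    # exine rim: dark band hugging the boundary, width from pixel counting
    band = mask & (dist <= 0.3 * dmax)
    inner_ref = float(np.median(img[mask & (dist > 0.3 * dmax)])) if (dist > 0.3 * dmax).any() else interior.mean()
    rim_px = (img[band] < inner_ref - 0.08).sum() / max(perim, 1.0)
    rim_thickness = float(rim_px * pixel_pitch)

    core = dist > 0.65 * dmax
    ring = (dist > 0.22 * dmax) & (dist <= 0.38 * dmax)
    if core.any() and ring.any():
        contrast = float((img[core].mean() - img[ring].mean()) / background)
        vacuole_score = float(np.clip(contrast / 0.30, 0.0, 1.0))
    else:
        vacuole_score = 0.0
    return MorphFeatures(
        equivalent_diameter=eq_d,
        mean_opacity=mean_opacity,
        circularity=float(circularity),
        rim_thickness=rim_thickness,
        rhomboidness=rhomboidness,
        interior_variance=interior_variance,
        vacuole_score=vacuole_score,
    )


# ---------------------------------------------------------------------------
# Rule-based classification


@dataclass
class RuleSet:
    """Per-stage trapezoidal membership rules over morphology features.

    ``rules[stage][feature] = (a, b, c, d)``: membership ramps 0→1 over
    [a, b], is 1 on [b, c] and ramps back to 0 over [c, d].  A stage's score
    is the product of its feature memberships; scores are normalized to a
    distribution, and when every stage's raw score is negligible the
    classifier returns a flat (maximum-entropy) distribution instead of
    failing.
    """

    rules: dict  # StageClass -> {feature: (a, b, c, d)}
    version: str = "unversioned"
    score_floor: float = 1e-9

    def membership(self, stage: StageClass, features: dict) -> float:
        m = 1.0
        for feat, (a, b, c, d) in self.rules[stage].items():
            m *= _trapezoid(features[feat], a, b, c, d)
        return m

    @classmethod
    def from_yaml(cls, path_or_stream) -> "RuleSet":
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                doc = yaml.safe_load(fh)
        rules = {
            stage_from_any(k): {f: tuple(float(x) for x in v) for f, v in spec.items()}
            for k, spec in doc["rules"].items()
        }
        return cls(rules=rules, version=str(doc.get("version", "unversioned")))

    def to_yaml(self, path) -> None:
        doc = {
            "version": self.version,
            "rules": {
                s.short: {f: [float(x) for x in v] for f, v in spec.items()}
                for s, spec in self.rules.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _trapezoid(x: float, a: float, b: float, c: float, d: float) -> float:
    if x <= a or x >= d:
        return 0.0
    if b <= x <= c:
        return 1.0
    if x < b:
        return (x - a) / (b - a)
    return (d - x) / (d - c)


def default_ruleset() -> RuleSet:
    """The shipped ruleset, calibrated to the simulator's stage parameters."""
    ref = importlib.resources.files("pollenscan").joinpath("data/default_ruleset.yaml")
    with ref.open() as fh:
        return RuleSet.from_yaml(fh)


def classify_cell(features, rules: RuleSet) -> np.ndarray:
    """Score a cell's stage distribution from its morphology descriptors.

    Returns a normalized 6-vector over the detectable stages (DOUBTFUL is
    never emitted); an out-of-range cell gets the flat distribution.
    """
    fdict = features.as_dict() if isinstance(features, MorphFeatures) else dict(features)
    raw = np.array([rules.membership(s, fdict) for s in DETECTABLE_STAGES], float)
    if raw.max() <= rules.score_floor:
        return np.full(6, 1.0 / 6.0)
    return raw / raw.sum()


def calibrate_ruleset(samples_by_stage, features=None, margin=0.5, version="calibrated"):
    """Fit trapezoidal memberships from per-stage feature samples.

    Plateau spans the 5th–95th percentile of each feature; shoulders extend
    the plateau by ``margin`` of its width (with a floor so degenerate
    features keep a usable ramp).
    """
    features = features or ("equivalent_diameter", "mean_opacity", "rhomboidness", "vacuole_score")
    rules = {}
    for stage, samples in samples_by_stage.items():
        stage = stage_from_any(stage)
        spec = {}
        for feat in features:
            vals = np.asarray(
                [s.as_dict()[feat] if isinstance(s, MorphFeatures) else s[feat] for s in samples],
                float,
            )
            b, c = np.percentile(vals, [5, 95])
            width = max(c - b, 0.05 * max(abs(b), abs(c), 1.0))
            spec[feat] = (b - margin * width, float(b), float(c), c + margin * width)
        rules[stage] = spec
    return RuleSet(rules=rules, version=version)


# ---------------------------------------------------------------------------
# Detector contract


class MorphologyDetector:
    """Baseline detector: segment -> features -> rule classification.

    Deterministic; overlapping detections are suppressed keeping the higher
    confidence (IoU > ``nms_iou``).
    """

    def __init__(
        self,
        ruleset: RuleSet | None = None,
        pixel_pitch=DEFAULT_GEOMETRY.pixel_pitch,
        min_diameter_um=10.0,
        max_diameter_um=55.0,
        threshold_drop=0.10,
        nms_iou=0.6,
    ):
        self.ruleset = ruleset or default_ruleset()
        self.pixel_pitch = pixel_pitch
        self.min_diameter_um = min_diameter_um
        self.max_diameter_um = max_diameter_um
        self.threshold_drop = threshold_drop
        self.nms_iou = nms_iou

    def __call__(self, image):
        img = _as_float(image)
        bg = _background_mode(img)
        dets = []
        for mask, bbox in segment_cells(
            image,
            self.min_diameter_um,
            self.max_diameter_um,
            self.pixel_pitch,
            self.threshold_drop,
        ):
            feats = extract_features(mask, img, self.pixel_pitch, background=bg)
            dets.append(Detection(bbox=bbox, scores=classify_cell(feats, self.ruleset)))
        return _nms(dets, self.nms_iou)


def _nms(detections, iou_threshold):
    """Keep-highest-confidence suppression of overlapping detections."""
    kept = []
    for d in sorted(detections, key=lambda d: -d.confidence):
        if all(iou(d.bbox, k.bbox) <= iou_threshold for k in kept):
            kept.append(d)
    return kept


def detect(image, detector) -> list:
    """Run any contract-honoring detector and validate its output.

    Detections are returned sorted by confidence descending, coordinates in
    the input frame.  Contract violations (malformed score vectors) raise.
    """
    raw = detector(image)
    out = []
    for d in raw:
        if not isinstance(d, Detection):
            d = Detection(bbox=tuple(d.bbox), scores=np.asarray(d.scores, float))
        out.append(d)  # Detection.__post_init__ enforces the contract
    return sorted(out, key=lambda d: -d.confidence)
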