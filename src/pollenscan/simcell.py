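"""Synthetic brightfield slide simulator with ground truth.

Generates microspore/pollen sprites for the six optical stages, composes
them into overlapping scanner tiles with known offsets, boxes and blur
flags, and samples per-anther-range stage-count profiles along a maturation
axis.  Every downstream operation (stitching, QC, detection, evaluation,
range recommendation) is testable against this ground truth without real
slides.

Rendering model: a brightfield background of intensity ``background_level``
(white-ish) attenuated by a per-pixel cell opacity in [0, 1], i.e.
``intensity = background * (1 - opacity)``; opacity 1 is fully dark.  The
stage-conditional defaults encode the qualitative optical contrasts of the
stages: tetrads are rhomboid; young microspores small and faint; medium
microspores intermediate with a thick exine rim; vacuolated microspores
circular with a bright central vacuole; young pollen larger and darker from
early starch accumulation; mature pollen the darkest, packed with granules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import perimeter_crofton

from .antherselect import RANGE_LABELS, AntherRangeCount, parse_range_label
from .geometry import DEFAULT_GEOMETRY, AcquisitionGeometry
from .labelset import BoxAnnotation
from .scanproc import Tile
from .stages import DETECTABLE_STAGES, StageClass

# ---------------------------------------------------------------------------
# Stage-conditional sprite parameters (means/sd; diameters in µm, opacity in
# [0,1]).  Chosen so the stage orderings hold and the pixel-level oracle can
# re-derive the stage (values are implementation defaults, the contrasts are
# the documented biology).

STAGE_PARAMS: dict[StageClass, dict] = {
    StageClass.TETRAD: dict(
        diameter=42.0, diameter_sd=2.5, opacity=0.45, opacity_sd=0.03,
        shape="diamond", rim_um=1.5, vacuole=False, granule_density=0.0,
    ),
    StageClass.YOUNG_MICROSPORE: dict(
        diameter=18.0, diameter_sd=1.2, opacity=0.22, opacity_sd=0.03,
        shape="disc", rim_um=1.0, vacuole=False, granule_density=0.0,
    ),
    StageClass.MEDIUM_MICROSPORE: dict(
        diameter=25.0, diameter_sd=1.3, opacity=0.38, opacity_sd=0.03,
        shape="disc", rim_um=2.5, vacuole=False, granule_density=0.0,
    ),
    StageClass.VACUOLATED_MICROSPORE: dict(
        diameter=32.0, diameter_sd=1.5, opacity=0.45, opacity_sd=0.03,
        shape="disc", rim_um=1.5, vacuole=True, granule_density=0.0,
    ),
    StageClass.YOUNG_POLLEN: dict(
        diameter=38.0, diameter_sd=1.8, opacity=0.58, opacity_sd=0.03,
        shape="disc", rim_um=1.5, vacuole=False, granule_density=0.008,
    ),
    StageClass.MATURE_POLLEN: dict(
        diameter=38.0, diameter_sd=1.8, opacity=0.85, opacity_sd=0.03,
        shape="disc", rim_um=1.5, vacuole=False, granule_density=0.02,
    ),
}

#: Opacity of the vacuole core and its radius as a fraction of cell radius.
VACUOLE_OPACITY = 0.08
VACUOLE_RADIUS_FRACTION = 0.60
#: Minimum circularity the generator guarantees for disc-shaped sprites under
#: a boundary-tracing (marching-squares polygon) perimeter, whose estimate
#: depends on rasterization phase.  Crofton-based measurements run ~0.99.
MIN_DISC_CIRCULARITY = 0.84
#: Rhomboidness rescaling anchors: a disc has extent pi/4, a diamond 1/2.
_EXTENT_DISC = math.pi / 4.0
_EXTENT_DIAMOND = 0.5


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth description of one rendered cell (pixel-measured)."""

    stage: StageClass
    center: tuple[float, float]  # (x, y) px
    equivalent_diameter: float  # µm, from mask area
    mean_opacity: float  # mean over the mask, 1 = fully dark
    circularity: float  # 4*pi*A/P^2 on the mask
    rhomboidness: float  # 0 disc .. 1 diamond
    has_vacuole: bool
    granule_density: float  # per µm²


@dataclass
class CellSprite:
    """A rendered cell: opacity raster, mask and tight bounding box."""

    spec: CellSpec
    opacity: np.ndarray  # float, 0 outside the cell
    mask: np.ndarray  # bool
    bbox: tuple[int, int, int, int]  # (x, y, w, h) within the sprite raster


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return (int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))


def synthesize_cell(
    stage: StageClass,
    geometry: AcquisitionGeometry = DEFAULT_GEOMETRY,
    rng_state=0,
    params: dict | None = None,
) -> CellSprite:
    """Render one cell sprite of the given stage.

    Returns a :class:`CellSprite` whose ``spec`` carries pixel-measured
    features (so the raster matches the spec by construction, up to the
    measurement itself) and whose ``bbox`` is the tight axis-aligned box of
    the sprite mask.  Deterministic for a fixed (stage, seed).
    """
    if stage is StageClass.DOUBTFUL:
        raise ValueError("DOUBTFUL is annotation-only and cannot be synthesized")
    rng = _rng(rng_state)
    p = dict(STAGE_PARAMS[stage])
    if params:
        p.update(params)
    pitch = geometry.pixel_pitch

    d_um = max(4.0, rng.normal(p["diameter"], p["diameter_sd"]))
    base_op = float(np.clip(rng.normal(p["opacity"], p["opacity_sd"]), 0.05, 0.98))
    r_px = d_um / pitch / 2.0
    pad = 4
    n = int(math.ceil(2 * r_px)) + 2 * pad
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dx, dy = xx - cx, yy - cy

    if p["shape"] == "diamond":
        # square with the same area as the equivalent disc, rotated near the
        # vertex-up (diamond) orientation
        theta = rng.uniform(math.radians(30), math.radians(60))
        half_side = r_px * math.sqrt(math.pi) / 2.0
        u = np.abs(dx * math.cos(theta) + dy * math.sin(theta))
        v = np.abs(-dx * math.sin(theta) + dy * math.cos(theta))
        mask = (u <= half_side) & (v <= half_side)
        dist_in = half_side - np.maximum(u, v)  # distance to the nearest side
    else:
        rr = np.sqrt(dx**2 + dy**2)
        mask = rr <= r_px
        dist_in = r_px - rr

    opacity = np.zeros((n, n), float)
    opacity[mask] = base_op
    rim_px = max(p["rim_um"] / pitch, 1.0)
    rim = mask & (dist_in <= rim_px)
    opacity[rim] = min(1.0, base_op + 0.30)

    if p["vacuole"]:
        # vacuole: bright central region where the cytoplasm is pushed aside
        vac = (np.sqrt(dx**2 + dy**2) <= VACUOLE_RADIUS_FRACTION * r_px) & mask
        opacity[vac] = VACUOLE_OPACITY

    if p["granule_density"] > 0:
        area_um2 = mask.sum() * pitch**2
        n_gran = rng.poisson(p["granule_density"] * area_um2)
        interior = np.argwhere(mask & (dist_in > rim_px + 1))
        if len(interior) and n_gran:
            picks = interior[rng.integers(0, len(interior), size=n_gran)]
            for gy, gx in picks:
                rad = rng.uniform(1.0, 2.0)
                gslice = np.s_[
                    max(gy - 2, 0) : gy + 3, max(gx - 2, 0) : gx + 3
                ]
                gyy, gxx = np.mgrid[gslice]
                blob = (gyy - gy) ** 2 + (gxx - gx) ** 2 <= rad**2
                patch = opacity[gslice]
                patch[blob & mask[gslice]] = min(1.0, base_op + 0.12)
                opacity[gslice] = patch

    feats = measure_sprite(opacity, mask, pitch)
    spec = CellSpec(
        stage=stage,
        center=(cx, cy),
        equivalent_diameter=feats["equivalent_diameter"],
        mean_opacity=feats["mean_opacity"],
        circularity=feats["circularity"],
        rhomboidness=feats["rhomboidness"],
        has_vacuole=bool(p["vacuole"]),
        granule_density=float(p["granule_density"]),
    )
    return CellSprite(spec=spec, opacity=opacity, mask=mask, bbox=_tight_bbox(mask))


def measure_sprite(opacity: np.ndarray, mask: np.ndarray, pixel_pitch: float) -> dict:
    """Pixel-counting feature oracle on a sprite's opacity raster.

    Measures equivalent diameter (area), circularity (Crofton perimeter),
    mean opacity, rhomboidness (bounding-box extent rescaled between the
    disc and diamond anchors) and a vacuole score (bright core vs cytoplasm
    ring contrast).
    """
    area = int(mask.sum())
    if area < 4:
        raise ValueError("degenerate mask")
    eq_d_px = 2.0 * math.sqrt(area / math.pi)
    perim = perimeter_crofton(mask, directions=4)
    circularity = min(4 * math.pi * area / perim**2, 1.0) if perim > 0 else 0.0
    x, y, w, h = _tight_bbox(mask)
    extent = area / (w * h)
    rhomboidness = float(np.clip((_EXTENT_DISC - extent) / (_EXTENT_DISC - _EXTENT_DIAMOND), 0.0, 1.0))
    mean_opacity = float(opacity[mask].mean())

    # core/ring bands in units of the max inscribed distance; the ring sits
    # clear of the exine rim (outer ~20%) and of the vacuole edge (inner 40%)
    dist = ndi.distance_transform_edt(mask)
    dmax = dist.max()
    core = dist > 0.65 * dmax
    ring = (dist > 0.22 * dmax) & (dist <= 0.38 * dmax)
    if core.any() and ring.any():
        contrast = float(opacity[ring].mean() - opacity[core].mean())
        vacuole_score = float(np.clip(contrast / 0.30, 0.0, 1.0))
    else:
        vacuole_score = 0.0
    return dict(
        equivalent_diameter=eq_d_px * pixel_pitch,
        mean_opacity=mean_opacity,
        circularity=float(circularity),
        rhomboidness=rhomboidness,
        vacuole_score=vacuole_score,
        area_um2=area * pixel_pitch**2,
    )


def oracle_stage(features: dict) -> StageClass:
    """Re-derive the generating stage from pixel-measured features.

    Interval rules on the stage-conditional defaults; used to close the
    generator/oracle loop (a sprite should be reassigned its own stage).
    """
    d = features["equivalent_diameter"]
    op = features["mean_opacity"]
    if features["rhomboidness"] > 0.5:
        return StageClass.TETRAD
    if features["vacuole_score"] > 0.35 and d > 26.0:
        return StageClass.VACUOLATED_MICROSPORE
    if d < 21.5:
        return StageClass.YOUNG_MICROSPORE
    if d < 28.5:
        return StageClass.MEDIUM_MICROSPORE
    if op > 0.72:
        return StageClass.MATURE_POLLEN
    return StageClass.YOUNG_POLLEN


# ---------------------------------------------------------------------------
# Slide rendering


@dataclass
class SlideSimConfig:
    """Parameters of one simulated scan."""

    cells_per_tile: float = 8.0
    stage_mixture: tuple = (1 / 6,) * 6
    grid: tuple[int, int] = (2, 2)
    overlap_fraction: float = 0.2
    jitter_px: int = 3
    blur_fraction: float = 0.0
    blur_sigma: float = 3.0
    background_level: float = 0.92
    noise_sigma: float = 0.012
    clutter: float = 0.0  # probability that a cell may overlap others
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.stage_mixture) - 1.0) > 1e-9:
            raise ValueError("stage_mixture must sum to 1")
        if len(self.stage_mixture) != 6:
            raise ValueError("stage_mixture must have 6 entries")
        if not (0 <= self.overlap_fraction <= 0.5):
            raise ValueError("overlap_fraction must be in [0, 0.5]")
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError("grid must contain at least one tile")


@dataclass
class SlideSample:
    """A rendered slide: tiles, truth boxes, true offsets and blur flags."""

    tiles: list  # list[Tile]
    tile_annotations: dict  # tile image_id -> list[BoxAnnotation]
    macro_annotations: list  # list[BoxAnnotation] in macro frame
    true_offsets: dict  # grid_pos -> (x, y)
    blur_flags: dict  # grid_pos -> bool
    macro_pixels: np.ndarray  # uint8, pre-blur mosaic
    config: SlideSimConfig
    geometry: AcquisitionGeometry
    cells: list = field(default_factory=list)  # list[CellSpec] (macro coords)


def tile_id(grid_pos) -> str:
    return f"tile_{grid_pos[0]}_{grid_pos[1]}"


def render_slide(
    config: SlideSimConfig, geometry: AcquisitionGeometry = DEFAULT_GEOMETRY
) -> SlideSample:
    """Render a full simulated scan.

    Tiles share ``overlap_fraction`` of their width/height with grid
    neighbors plus a per-tile uniform jitter of at most ``jitter_px`` (the
    anchor tile (0,0) is not jittered).  Every placed cell appears exactly
    once in the macro-frame annotation list; cells spanning tile borders are
    annotated in every covering tile, clipped to tile bounds.  A fixed
    fraction of tiles (``round(blur_fraction * n_tiles)``) is rendered out
    of focus with a Gaussian blur and flagged in the ground truth.
    """
    tile_px = geometry.tile_px
    overlap_px = round(config.overlap_fraction * tile_px)
    if config.jitter_px > 0 and overlap_px < config.jitter_px + 8:
        raise ValueError("overlap too small for the requested jitter (registration unsolvable)")
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid
    stride = tile_px - overlap_px

    offsets = {}
    for r in range(rows):
        for c in range(cols):
            jx = jy = 0
            if (r, c) != (0, 0) and config.jitter_px > 0:
                jx = int(rng.integers(-config.jitter_px, config.jitter_px + 1))
                jy = int(rng.integers(-config.jitter_px, config.jitter_px + 1))
            offsets[(r, c)] = (c * stride + jx, r * stride + jy)
    # shift everything by a jitter margin so row-0/col-0 jitter stays inside
    # the canvas; the macro frame is the canvas frame (anchor tile at
    # (margin, margin), which is also its nominal offset)
    margin = config.jitter_px
    offsets = {p: (x + margin, y + margin) for p, (x, y) in offsets.items()}
    width = max(x for x, _ in offsets.values()) + tile_px + margin
    height = max(y for _, y in offsets.values()) + tile_px + margin

    n_tiles = rows * cols
    n_cells = int(rng.poisson(config.cells_per_tile * n_tiles))
    canvas = np.zeros((height, width), float)
    macro_annotations: list[BoxAnnotation] = []
    cells: list[CellSpec] = []
    placed = []  # (cx, cy, radius)
    for _ in range(n_cells):
        stage = DETECTABLE_STAGES[rng.choice(6, p=np.asarray(config.stage_mixture))]
        sprite = synthesize_cell(stage, geometry, rng)
        sh, sw = sprite.opacity.shape
        radius = max(sh, sw) / 2.0
        for _try in range(200):
            x0 = int(rng.integers(0, max(width - sw, 1)))
            y0 = int(rng.integers(0, max(height - sh, 1)))
            cx, cy = x0 + sw / 2.0, y0 + sh / 2.0
            if config.clutter > 0 and rng.random() < config.clutter:
                break
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 > (radius + pr + 2) ** 2
                for px, py, pr in placed
            ):
                break
        else:
            continue  # no room; skip this cell
        placed.append((cx, cy, radius))
        region = canvas[y0 : y0 + sh, x0 : x0 + sw]
        np.maximum(region, sprite.opacity, out=region)
        bx, by, bw, bh = sprite.bbox
        macro_annotations.append(
            BoxAnnotation(
                image_id="macro",
                bbox=(x0 + bx, y0 + by, bw, bh),
                stage=stage,
                source="inferred",
            )
        )
        cells.append(replace(sprite.spec, center=(cx, cy)))

    intensity = config.background_level * (1.0 - canvas)
    if config.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sigma, intensity.shape)
    macro = np.clip(np.round(intensity * 255.0), 0, 255).astype(np.uint8)

    n_blur = int(round(config.blur_fraction * n_tiles))
    grid_order = [(r, c) for r in range(rows) for c in range(cols)]
    blur_picks = (
        {grid_order[i] for i in rng.choice(n_tiles, size=n_blur, replace=False)}
        if n_blur
        else set()
    )

    tiles, tile_annotations, blur_flags = [], {}, {}
    for pos in grid_order:
        x, y = offsets[pos]
        pix = macro[y : y + tile_px, x : x + tile_px].copy()
        blurred = pos in blur_picks
        if blurred:
            pix = np.clip(
                np.round(ndi.gaussian_filter(pix.astype(float), config.blur_sigma)),
                0,
                255,
            ).astype(np.uint8)
        tid = tile_id(pos)
        anns = []
        for ann in macro_annotations:
            shifted = replace(
                ann, image_id=tid, bbox=(ann.bbox[0] - x, ann.bbox[1] - y, ann.bbox[2], ann.bbox[3])
            )
            clipped = shifted.clipped(tile_px, tile_px)
            if clipped is not None:
                anns.append(clipped)
        tiles.append(
            Tile(
                pixels=pix,
                grid_pos=pos,
                nominal_offset=(pos[1] * stride + margin, pos[0] * stride + margin),
            )
        )
        tile_annotations[tid] = anns
        blur_flags[pos] = blurred

    return SlideSample(
        tiles=tiles,
        tile_annotations=tile_annotations,
        macro_annotations=macro_annotations,
        true_offsets=offsets,
        blur_flags=blur_flags,
        macro_pixels=macro,
        config=config,
        geometry=geometry,
        cells=cells,
    )


# ---------------------------------------------------------------------------
# Anther-range profile model


@dataclass
class MaturationProfileModel:
    """Maps anther size ranges to stage mixtures along the maturation axis.

    Each of the eight ranges sits at a mean maturation position
    (``stage_positions``, in stage-index units 0=T .. 5=MP, increasing with
    anther size); the stage mixture of a range is a discretized Gaussian
    around that position, truncated at ``truncation`` stage units (so e.g.
    mature pollen is absent from the smallest anthers).  Counts are a
    multinomial draw of ``cells_per_range`` cells.  The default positions
    put the vacuolated-microspore mode at 5.5–6 mm, the young-microspore
    mode at 3.5–4 mm and the mature-pollen mode at >6.5 mm.
    """

    stage_positions: tuple = (0.3, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)
    sigma: float = 0.6
    truncation: float = 2.0
    cells_per_range: float = 30000.0
    n_anthers: int = 100

    def stage_weights(self, range_label: str) -> np.ndarray:
        label = parse_range_label(range_label)
        m = self.stage_positions[RANGE_LABELS.index(label)]
        s = np.arange(6, dtype=float)
        w = np.exp(-((s - m) ** 2) / (2 * self.sigma**2))
        w[np.abs(s - m) > self.truncation] = 0.0
        return w / w.sum()

    def expected_counts(self, range_label: str) -> np.ndarray:
        return self.cells_per_range * self.stage_weights(range_label)


def sample_range_profile(
    range_label: str, profile_model: MaturationProfileModel | None = None, seed=0
) -> AntherRangeCount:
    """Sample the stage counts observed in one anther size range."""
    model = profile_model or MaturationProfileModel()
    label = parse_range_label(range_label)
    rng = _rng(seed)
    weights = model.stage_weights(label)
    counts = rng.multinomial(int(model.cells_per_range), weights)
    return AntherRangeCount(
        range_label=label,
        counts={s: int(c) for s, c in zip(DETECTABLE_STAGES, counts)},
        n_anthers=model.n_anthers,
    )


def sample_profile(profile_model: MaturationProfileModel | None = None, seed=0):
    """Sample a full eight-range profile (one seed stream, deterministic)."""
    model = profile_model or MaturationProfileModel()
    rng = np.random.default_rng(seed)
    return [sample_range_profile(lbl, model, rng) for lbl in RANGE_LABELS]
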