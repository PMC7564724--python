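"""Acquisition-side processing of scanner tiles.

The motorized microscope acquires overlapping 512 x 512 px tiles on a grid;
mechanical play in the stage (thread pitch) jitters each tile around its
nominal position.  This module registers the tiles into a macro image by
normalized cross-correlation on the overlap strips, re-extracts clean tiles,
and provides the quality-control passes applied before labeling/detection:
a Fourier focus score, focus filtering, brightness equalization, and
empty-tile removal.

Coordinates are 0-based, x right, y down; boxes are (x, y, w, h) half-open.
No operation mutates its input rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu


@dataclass
class Tile:
    """One scanner tile: raster, grid position, nominal macro-frame offset."""

    pixels: np.ndarray
    grid_pos: tuple[int, int]  # (row, col)
    nominal_offset: tuple[int, int]  # (x, y) px in macro frame
    focus_score: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class MacroImage:
    """Mosaic assembled from registered tiles.

    ``registry`` offsets are in the anchor frame (the (0,0) tile sits at its
    nominal offset); ``origin`` is the anchor-frame coordinate of the
    mosaic's top-left pixel, so pixel position = registry offset - origin.
    """

    pixels: np.ndarray
    registry: dict  # grid_pos -> registered (x, y) offset, anchor frame
    origin: tuple[int, int] = (0, 0)
    overlap_map: dict = field(default_factory=dict)  # (pos_a, pos_b) -> NCC
    warnings: list = field(default_factory=list)


def _as_float(img) -> np.ndarray:
    a = np.asarray(img)
    return a.astype(float) / 255.0 if a.dtype == np.uint8 else a.astype(float)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shaped patches."""
    if a.std() < 1e-9 or b.std() < 1e-9:  # flat patch: correlation undefined
        return float("nan")
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def _overlap_ncc(img_a, off_a, img_b, off_b) -> float:
    """NCC over the intersection of two placed tiles; NaN if none/flat."""
    ax, ay = off_a
    bx, by = off_b
    ha, wa = img_a.shape[:2]
    hb, wb = img_b.shape[:2]
    x0, x1 = max(ax, bx), min(ax + wa, bx + wb)
    y0, y1 = max(ay, by), min(ay + ha, by + hb)
    if x1 - x0 < 4 or y1 - y0 < 4:
        return float("nan")
    pa = img_a[y0 - ay : y1 - ay, x0 - ax : x1 - ax]
    pb = img_b[y0 - by : y1 - by, x0 - bx : x1 - bx]
    return _ncc(pa, pb)


def stitch(tiles, overlap_fraction, jitter_window_px=5, corr_floor=0.2):
    """Register tiles into a macro image.

    Placement is greedy in row-major grid order, anchored at the (0, 0) tile.
    Each tile's offset maximizes the mean normalized cross-correlation with
    its already-placed grid neighbors over a +/- ``jitter_window_px`` search
    window around the nominal offset; ties are broken by smaller displacement
    magnitude, then lexicographically on (dy, dx).  A tile whose best
    correlation falls below ``corr_floor`` (or that has no textured overlap)
    is flagged unregistered and placed at its nominal offset.

    Overlap pixels are blended by linear feathering (per-tile weight falls
    off linearly toward the tile edge).
    """
    tiles = list(tiles)
    if not tiles:
        raise ValueError("cannot stitch zero tiles")
    tile_h, tile_w = tiles[0].pixels.shape[:2]
    overlap_px = round(overlap_fraction * tile_w)
    if len(tiles) > 1 and overlap_px <= jitter_window_px:
        raise ValueError("overlap strip must be wider than the jitter window")

    order = sorted(tiles, key=lambda t: t.grid_pos)
    by_pos = {t.grid_pos: t for t in order}
    floats = {t.grid_pos: _as_float(t.pixels) for t in order}
    registry: dict = {}
    overlap_map: dict = {}
    warnings: list = []

    window = range(-jitter_window_px, jitter_window_px + 1)
    candidates = sorted(
        ((dx, dy) for dy in window for dx in window),
        key=lambda d: (d[0] * d[0] + d[1] * d[1], d[1], d[0]),
    )
    for t in order:
        r, c = t.grid_pos
        neighbors = [p for p in ((r, c - 1), (r - 1, c)) if p in registry]
        if not neighbors:
            registry[t.grid_pos] = tuple(t.nominal_offset)
            continue
        nx, ny = t.nominal_offset
        best, best_score = None, -np.inf
        for dx, dy in candidates:
            off = (nx + dx, ny + dy)
            scores = [
                _overlap_ncc(floats[t.grid_pos], off, floats[p], registry[p])
                for p in neighbors
            ]
            scores = [s for s in scores if np.isfinite(s)]
            if not scores:
                continue
            score = float(np.mean(scores))
            if score > best_score:  # strict: earlier (smaller) offsets win ties
                best, best_score = off, score
        if best is None or best_score < corr_floor:
            registry[t.grid_pos] = tuple(t.nominal_offset)
            warnings.append(
                f"tile {t.grid_pos} unregistered "
                f"(best correlation {best_score:.3f}); placed at nominal offset"
            )
        else:
            registry[t.grid_pos] = best
            for p in neighbors:
                overlap_map[(p, t.grid_pos)] = best_score

    # Compose the mosaic with linear feather blending.
    min_x = min(x for x, _ in registry.values())
    min_y = min(y for _, y in registry.values())
    max_x = max(x + floats[p].shape[1] for p, (x, _) in registry.items())
    max_y = max(y + floats[p].shape[0] for p, (_, y) in registry.items())
    acc = np.zeros((max_y - min_y, max_x - min_x), float)
    wacc = np.zeros_like(acc)
    ramp_y = _feather_profile(tile_h, overlap_px)
    ramp_x = _feather_profile(tile_w, overlap_px)
    weight = ramp_y[:, None] * ramp_x[None, :]
    for p, (x, y) in registry.items():
        img = floats[p]
        sl = np.s_[y - min_y : y - min_y + img.shape[0], x - min_x : x - min_x + img.shape[1]]
        acc[sl] += img * weight
        wacc[sl] += weight
    mosaic = acc / np.maximum(wacc, 1e-12)
    was_uint8 = order[0].pixels.dtype == np.uint8
    pixels = (
        np.clip(np.round(mosaic * 255.0), 0, 255).astype(np.uint8)
        if was_uint8
        else mosaic
    )
    return MacroImage(
        pixels=pixels,
        registry=registry,
        origin=(min_x, min_y),
        overlap_map=overlap_map,
        warnings=warnings,
    )


def _feather_profile(n: int, margin: int) -> np.ndarray:
    """Weight profile: 1 in the interior, linear ramp over the overlap margin."""
    w = np.ones(n)
    m = max(int(margin), 1)
    ramp = np.linspace(1.0 / (m + 1), m / (m + 1), m)
    w[:m] = ramp
    w[-m:] = np.minimum(w[-m:], ramp[::-1])
    return w


def extract_tiles(macro: MacroImage | np.ndarray, tile_px: int, remainder="drop"):
    """Cut a non-overlapping grid of ``tile_px`` tiles from a macro image.

    remainder: "drop" discards partial last row/column; "pad" pads them with
    the image median.
    """
    pixels = macro.pixels if isinstance(macro, MacroImage) else np.asarray(macro)
    h, w = pixels.shape[:2]
    if (h < tile_px or w < tile_px) and remainder == "drop":
        raise ValueError("macro smaller than one tile and remainder policy is 'drop'")
    if remainder == "drop":
        rows, cols = h // tile_px, w // tile_px
    elif remainder == "pad":
        rows, cols = -(-h // tile_px), -(-w // tile_px)
        padded = np.full(
            (rows * tile_px, cols * tile_px) + pixels.shape[2:],
            np.median(pixels).astype(pixels.dtype)
            if pixels.dtype == np.uint8
            else np.median(pixels),
            dtype=pixels.dtype,
        )
        padded[:h, :w] = pixels
        pixels = padded
    else:
        raise ValueError(f"unknown remainder policy {remainder!r}")
    out = []
    for r in range(rows):
        for c in range(cols):
            y, x = r * tile_px, c * tile_px
            out.append(
                Tile(
                    pixels=pixels[y : y + tile_px, x : x + tile_px].copy(),
                    grid_pos=(r, c),
                    nominal_offset=(x, y),
                )
            )
    return out


def focus_score(image) -> float:
    """High-frequency spectral energy fraction (Fourier focus measure).

    Fraction of the non-DC power spectrum lying above a radial frequency
    cutoff of 0.25 x Nyquist.  Invariant to constant intensity shifts and to
    translations; strictly decreased by Gaussian blurring.  A constant image
    scores 0.
    """
    img = _as_float(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.size == 0:
        raise ValueError("empty image")
    power = np.abs(np.fft.fft2(img)) ** 2
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    radius = np.sqrt(fx**2 + fy**2)  # cycles/px; Nyquist = 0.5
    nondc = radius > 0
    total = power[nondc].sum()
    if total <= 0:
        return 0.0
    cutoff = 0.25 * 0.5
    return float(power[nondc & (radius > cutoff)].sum() / total)


def filter_unfocused(images, threshold_policy="otsu"):
    """Partition images into (kept, removed) by focus score.

    threshold_policy: "otsu" splits the batch's score histogram; a float is
    used as a fixed threshold.  Images scoring below the threshold are
    removed.  Returns (kept, removed, report) where report maps index ->
    (score, kept?).
    """
    images = list(images)
    scores = [
        focus_score(im.pixels if isinstance(im, Tile) else im) for im in images
    ]
    if not images:
        return [], [], {"threshold": None, "scores": []}
    if threshold_policy == "otsu":
        # scores span orders of magnitude: split the log-score histogram
        arr = np.log10(np.maximum(np.asarray(scores), 1e-12))
        threshold = float(10 ** threshold_otsu(arr)) if np.ptp(arr) > 0 else -np.inf
    else:
        threshold = float(threshold_policy)
    kept, removed = [], []
    for im, s in zip(images, scores):
        if isinstance(im, Tile):
            im.focus_score = s
        (kept if s >= threshold else removed).append(im)
    return kept, removed, {"threshold": threshold, "scores": scores}


def equalize(image, target_mean=128.0, target_range=200.0):
    """Affine brightness/contrast normalization (per channel).

    Maps the channel mean to ``target_mean`` and the full intensity span to
    ``target_range``; idempotent up to integer rounding.  A constant channel
    is shifted to the target mean.
    """
    img = np.asarray(image)
    was_uint8 = img.dtype == np.uint8
    work = img.astype(float)
    chans = work[..., None] if work.ndim == 2 else work
    out = np.empty_like(chans)
    for k in range(chans.shape[-1]):
        ch = chans[..., k]
        span = float(ch.max() - ch.min())
        gain = target_range / span if span > 0 else 1.0
        out[..., k] = (ch - ch.mean()) * gain + target_mean
    out = out[..., 0] if work.ndim == 2 else out
    if was_uint8:
        return np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out


def _background_mode(img: np.ndarray) -> float:
    """Background intensity as the histogram mode."""
    if img.dtype == np.uint8:
        return float(np.bincount(img.ravel(), minlength=256).argmax())
    hist, edges = np.histogram(img.ravel(), bins=256)
    i = int(hist.argmax())
    return float((edges[i] + edges[i + 1]) / 2)


def foreground_fraction(image, deviation=10.0) -> float:
    """Fraction of pixels deviating from the background mode by > deviation.

    ``deviation`` is in gray levels for uint8 images (scaled to /255 for
    float images).
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    dev = deviation if img.dtype == np.uint8 else deviation / 255.0
    mode = _background_mode(img)
    mask = np.abs(img.astype(float) - mode) > dev
    # ignore isolated noise pixels: require a little spatial support
    mask = ndi.binary_opening(mask, structure=np.ones((2, 2), bool))
    return float(mask.mean())


def drop_empty(images, foreground_min_fraction=0.001, deviation=10.0):
    """Partition images into (kept, removed) by foreground content.

    An image is removed when the fraction of pixels deviating from the
    background mode is strictly below ``foreground_min_fraction`` (a
    threshold of 0 therefore removes nothing).
    """
    kept, removed = [], []
    for im in images:
        px = im.pixels if isinstance(im, Tile) else im
        frac = foreground_fraction(px, deviation)
        (kept if frac >= foreground_min_fraction else removed).append(im)
    return kept, removed
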