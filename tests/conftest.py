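import dataclasses

import numpy as np
import pytest

from pollenscan.geometry import AcquisitionGeometry
from pollenscan.simcell import SlideSimConfig, render_slide


@pytest.fixture(scope="session")
def geometry():
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def small_slide():
    """3x3 jittered slide shared by stitching/QC tests."""
    cfg = SlideSimConfig(grid=(3, 3), jitter_px=3, seed=4, cells_per_tile=8)
    return cfg, render_slide(cfg)


@pytest.fixture(scope="session")
def zero_jitter_slide():
    cfg = SlideSimConfig(grid=(2, 2), jitter_px=0, seed=9, cells_per_tile=8)
    return cfg, render_slide(cfg)


def brute_force_registry(tiles, jitter_window_px):
    """Independent exhaustive-search stitching oracle.

    Plain-loop greedy placement in grid order: every candidate offset in the
    full +/- window is scored by the Pearson correlation of the raw overlap
    pixels with each already-placed left/up neighbor (no shortcuts shared
    with the implementation).
    """
    registry = {}
    for tile in sorted(tiles, key=lambda t: t.grid_pos):
        r, c = tile.grid_pos
        neighbors = [p for p in ((r, c - 1), (r - 1, c)) if p in registry]
        if not neighbors:
            registry[tile.grid_pos] = tuple(tile.nominal_offset)
            continue
        nx, ny = tile.nominal_offset
        best, best_score = None, -np.inf
        cands = []
        for dy in range(-jitter_window_px, jitter_window_px + 1):
            for dx in range(-jitter_window_px, jitter_window_px + 1):
                cands.append((dx * dx + dy * dy, dy, dx))
        for _, dy, dx in sorted(cands):
            ox, oy = nx + dx, ny + dy
            vals = []
            for p in neighbors:
                px, py = registry[p]
                other = next(t for t in tiles if t.grid_pos == p).pixels
                a, b = _overlap_pixels(tile.pixels, (ox, oy), other, (px, py))
                if a is None or a.std() == 0 or b.std() == 0:
                    continue
                vals.append(np.corrcoef(a.ravel(), b.ravel())[0, 1])
            if vals and np.mean(vals) > best_score:
                best, best_score = (ox, oy), float(np.mean(vals))
        registry[tile.grid_pos] = best if best is not None else tuple(tile.nominal_offset)
    return registry


def _overlap_pixels(img_a, off_a, img_b, off_b):
    ax, ay = off_a
    bx, by = off_b
    ha, wa = img_a.shape[:2]
    hb, wb = img_b.shape[:2]
    x0, x1 = max(ax, bx), min(ax + wa, bx + wb)
    y0, y1 = max(ay, by), min(ay + ha, by + hb)
    if x1 - x0 < 4 or y1 - y0 < 4:
        return None, None
    a = img_a[y0 - ay : y1 - ay, x0 - ax : x1 - ax].astype(float)
    b = img_b[y0 - by : y1 - by, x0 - bx : x1 - bx].astype(float)
    return a, b


def brute_force_ap(labels, n_truth):
    """Trapezoid-on-interpolated-PR-curve AP oracle (independent of the
    implementation): evaluates the interpolated precision at every recall
    step and integrates stepwise."""
    labels = list(labels)
    n = len(labels)
    precisions, recalls = [], []
    tp = fp = 0
    for lab in labels:
        tp += bool(lab)
        fp += not lab
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_truth)

    def interp(r):
        vals = [p for p, rr in zip(precisions, recalls) if rr >= r]
        return max(vals) if vals else 0.0

    ap = 0.0
    prev = 0.0
    for r in sorted(set(recalls)):
        if r > prev:
            ap += (r - prev) * interp(r)
            prev = r
    return ap


def shift_to_common_frame(per_tile_objects):
    """Offset boxes tile-by-tile so detections from different tiles never
    overlap when pooled into one evaluation."""
    out = []
    for i, objs in enumerate(per_tile_objects):
        for obj in objs:
            x, y, w, h = obj.bbox
            if dataclasses.is_dataclass(obj):
                out.append(dataclasses.replace(obj, bbox=(x + 4000.0 * i, y, w, h)))
            else:
                raise TypeError(type(obj))
    return out
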