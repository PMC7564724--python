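"""Stitching, focus scoring and tile QC."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import brute_force_registry
from pollenscan.scanproc import (
    MacroImage,
    Tile,
    drop_empty,
    equalize,
    extract_tiles,
    filter_unfocused,
    focus_score,
    foreground_fraction,
    stitch,
)
from pollenscan.simcell import SlideSimConfig, render_slide, synthesize_cell
from pollenscan.stages import StageClass


def test_stitch_single_tile_identity():
    rng = np.random.default_rng(0)
    px = rng.integers(0, 255, (64, 64)).astype(np.uint8)
    macro = stitch([Tile(pixels=px, grid_pos=(0, 0), nominal_offset=(0, 0))], 0.2)
    np.testing.assert_array_equal(macro.pixels, px)
    assert macro.registry[(0, 0)] == (0, 0)


def test_stitch_recovers_true_offsets(small_slide):
    cfg, slide = small_slide
    macro = stitch(slide.tiles, cfg.overlap_fraction, jitter_window_px=5)
    for pos, true in slide.true_offsets.items():
        assert tuple(macro.registry[pos]) == tuple(true)
    assert not macro.warnings


def test_stitch_matches_exhaustive_oracle(small_slide):
    cfg, slide = small_slide
    macro = stitch(slide.tiles, cfg.overlap_fraction, jitter_window_px=5)
    oracle = brute_force_registry(slide.tiles, jitter_window_px=5)
    assert {p: tuple(v) for p, v in macro.registry.items()} == oracle


def test_zero_jitter_registered_at_nominal(zero_jitter_slide):
    cfg, slide = zero_jitter_slide
    macro = stitch(slide.tiles, cfg.overlap_fraction, jitter_window_px=2)
    for t in slide.tiles:
        assert tuple(macro.registry[t.grid_pos]) == tuple(t.nominal_offset)


def test_textureless_tile_flagged_unregistered():
    bg = np.full((64, 64), 200, np.uint8)
    tiles = [
        Tile(pixels=bg.copy(), grid_pos=(0, 0), nominal_offset=(0, 0)),
        Tile(pixels=bg.copy(), grid_pos=(0, 1), nominal_offset=(48, 0)),
    ]
    macro = stitch(tiles, overlap_fraction=0.25, jitter_window_px=3)
    assert macro.registry[(0, 1)] == (48, 0)
    assert any("unregistered" in w for w in macro.warnings)


def test_inputs_not_mutated(zero_jitter_slide):
    _, slide = zero_jitter_slide
    before = [t.pixels.copy() for t in slide.tiles]
    stitch(slide.tiles, 0.2, jitter_window_px=2)
    for t, b in zip(slide.tiles, before):
        np.testing.assert_array_equal(t.pixels, b)


def test_extract_tiles_counts():
    rng = np.random.default_rng(1)
    macro = MacroImage(pixels=rng.integers(0, 255, (1024, 1024)).astype(np.uint8), registry={})
    assert len(extract_tiles(macro, 512)) == 4
    macro2 = MacroImage(pixels=rng.integers(0, 255, (1025, 512)).astype(np.uint8), registry={})
    assert len(extract_tiles(macro2, 512, remainder="drop")) == 2
    assert len(extract_tiles(macro2, 512, remainder="pad")) == 3
    with pytest.raises(ValueError):
        extract_tiles(MacroImage(pixels=np.zeros((100, 100), np.uint8), registry={}), 512)


def test_stitch_extract_round_trip(zero_jitter_slide):
    """On a zero-jitter slide the mosaic reproduces the original pixels
    everywhere outside the blended overlap strips."""
    cfg, slide = zero_jitter_slide
    macro = stitch(slide.tiles, cfg.overlap_fraction, jitter_window_px=2)
    tile_px = slide.geometry.tile_px
    overlap = round(cfg.overlap_fraction * tile_px)
    tiles_out = extract_tiles(macro, tile_px)
    # interior of the anchor tile (clear of any neighbor strip)
    orig = slide.tiles[0].pixels
    got = next(t for t in tiles_out if t.grid_pos == (0, 0)).pixels
    np.testing.assert_array_equal(
        got[: tile_px - overlap, : tile_px - overlap],
        orig[: tile_px - overlap, : tile_px - overlap],
    )


# ---------------------------------------------------------------------------
# Focus scoring


def test_constant_image_scores_zero():
    assert focus_score(np.full((64, 64), 77, np.uint8)) == 0.0


def test_blur_strictly_decreases_score():
    rng = np.random.default_rng(2)
    img = rng.integers(0, 255, (128, 128)).astype(np.uint8).astype(float)
    scores = [focus_score(img)]
    for _ in range(3):
        img = ndi.gaussian_filter(img, 1.5)
        scores.append(focus_score(img))
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_focus_score_shift_and_translation_invariance():
    rng = np.random.default_rng(3)
    img = rng.uniform(0.3, 0.7, (64, 64))
    assert focus_score(img + 0.2) == pytest.approx(focus_score(img), rel=1e-9)
    assert focus_score(np.roll(img, 7, axis=1)) == pytest.approx(
        focus_score(img), rel=1e-9
    )


def _sharp_and_blurred_tiles(n=20, seed=0):
    rng = np.random.default_rng(seed)
    cfg = SlideSimConfig(grid=(1, 1), jitter_px=0, cells_per_tile=8, seed=seed)
    sharp, blurred = [], []
    for i in range(n):
        slide = render_slide(SlideSimConfig(grid=(1, 1), jitter_px=0, cells_per_tile=8, seed=seed + i))
        px = slide.tiles[0].pixels
        sharp.append(px)
        blurred.append(
            np.clip(np.round(ndi.gaussian_filter(px.astype(float), 3.0)), 0, 255).astype(np.uint8)
        )
    return sharp, blurred


def test_focus_filter_separates_sharp_from_blurred():
    sharp, blurred = _sharp_and_blurred_tiles()
    kept, removed, report = filter_unfocused(sharp + blurred, "otsu")
    assert len(kept) == 20 and len(removed) == 20
    assert all(any(k is s for s in sharp) for k in kept)
    assert all(any(r is b for b in blurred) for r in removed)


def test_focus_filter_fixed_threshold_and_empty():
    sharp, _ = _sharp_and_blurred_tiles(n=5, seed=50)
    kept, removed, _ = filter_unfocused(sharp, threshold_policy=1e-6)
    assert len(removed) == 0 and len(kept) == 5
    kept, removed, rep = filter_unfocused([], "otsu")
    assert kept == [] and removed == []


# ---------------------------------------------------------------------------
# Equalization and empty-tile removal


def test_equalize_identity_offset_idempotence():
    rng = np.random.default_rng(4)
    img = rng.integers(60, 180, (64, 64)).astype(np.uint8)
    eq = equalize(img)
    assert abs(float(eq.mean()) - 128.0) < 1.0
    # an additive offset is normalized away
    eq_off = equalize(np.clip(img.astype(int) + 30, 0, 255).astype(np.uint8))
    assert np.abs(eq_off.astype(int) - eq.astype(int)).max() <= 1
    # idempotent up to rounding
    assert np.abs(equalize(eq).astype(int) - eq.astype(int)).max() <= 1


def test_equalize_constant_image_shifts_mean():
    out = equalize(np.full((16, 16), 40, np.uint8))
    assert float(out.mean()) == pytest.approx(128.0)


def test_drop_empty():
    slide = render_slide(SlideSimConfig(grid=(1, 1), jitter_px=0, cells_per_tile=0, seed=1))
    background = slide.tiles[0].pixels
    sp = synthesize_cell(StageClass.MEDIUM_MICROSPORE, rng_state=0)
    with_cell = background.copy().astype(float) / 255.0
    h, w = sp.opacity.shape
    region = with_cell[100 : 100 + h, 200 : 200 + w]
    region *= 1 - sp.opacity
    with_cell = np.clip(np.round(with_cell * 255), 0, 255).astype(np.uint8)

    kept, removed = drop_empty([background, with_cell], foreground_min_fraction=0.001)
    assert removed == [background]
    assert kept == [with_cell]
    kept, removed = drop_empty([background, with_cell], foreground_min_fraction=0.0)
    assert removed == []
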