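"""Simulator ground truth: sprites, slides and anther-range profiles."""

import numpy as np
import pytest
from skimage.measure import find_contours

from pollenscan.antherselect import RANGE_LABELS
from pollenscan.geometry import AcquisitionGeometry
from pollenscan.simcell import (
    MIN_DISC_CIRCULARITY,
    MaturationProfileModel,
    SlideSimConfig,
    measure_sprite,
    oracle_stage,
    render_slide,
    sample_range_profile,
    synthesize_cell,
    tile_id,
)
from pollenscan.stages import DETECTABLE_STAGES, StageClass


def test_chamber_height_and_pixel_pitch():
    geom = AcquisitionGeometry(coverslip_side=11.0, drop_volume=20.0)
    assert round(geom.chamber_height, 3) == 0.165
    assert round(geom.pixel_pitch, 3) == 0.996


def test_doubtful_stage_rejected():
    with pytest.raises(ValueError, match="DOUBTFUL"):
        synthesize_cell(StageClass.DOUBTFUL)


def test_sprite_determinism():
    a = synthesize_cell(StageClass.TETRAD, rng_state=42)
    b = synthesize_cell(StageClass.TETRAD, rng_state=42)
    assert np.array_equal(a.opacity, b.opacity)
    assert a.spec == b.spec
    assert a.bbox == b.bbox


def test_mature_pollen_darkest_every_rep(geometry):
    """Mature pollen is the most opaque cell type: its mean interior
    intensity is the darkest in every one of 100 repetitions."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        opacities = {
            s: synthesize_cell(s, geometry, rng).spec.mean_opacity
            for s in DETECTABLE_STAGES
        }
        mp = opacities.pop(StageClass.MATURE_POLLEN)
        assert mp > max(opacities.values())


def test_diameter_ordering(geometry):
    rng = np.random.default_rng(5)
    means = {
        s: np.mean(
            [synthesize_cell(s, geometry, rng).spec.equivalent_diameter for _ in range(30)]
        )
        for s in DETECTABLE_STAGES
    }
    assert (
        means[StageClass.YOUNG_MICROSPORE]
        < means[StageClass.MEDIUM_MICROSPORE]
        < means[StageClass.VACUOLATED_MICROSPORE]
        < means[StageClass.YOUNG_POLLEN]
    )


def _contour_perimeter(mask):
    """Boundary-tracing perimeter oracle: polygon length of the marching-
    squares contour of the mask."""
    total = 0.0
    for contour in find_contours(mask.astype(float), 0.5):
        total += np.sqrt((np.diff(contour, axis=0) ** 2).sum(axis=1)).sum()
    return total


def test_vacuolated_circularity_against_boundary_oracle(geometry):
    rng = np.random.default_rng(17)
    for _ in range(10):
        sp = synthesize_cell(StageClass.VACUOLATED_MICROSPORE, geometry, rng)
        perim = _contour_perimeter(sp.mask)
        circ = 4 * np.pi * sp.mask.sum() / perim**2
        assert circ >= MIN_DISC_CIRCULARITY


def test_true_box_is_tight(geometry):
    sp = synthesize_cell(StageClass.MEDIUM_MICROSPORE, geometry, rng_state=1)
    x, y, w, h = sp.bbox
    ys, xs = np.nonzero(sp.mask)
    assert (x, y) == (xs.min(), ys.min())
    assert (w, h) == (xs.max() - xs.min() + 1, ys.max() - ys.min() + 1)


def test_generator_oracle_closure(geometry):
    """The pixel-counting feature oracle reassigns the generating stage for
    at least 99% of sprites at default parameters."""
    rng = np.random.default_rng(21)
    ok = total = 0
    for stage in DETECTABLE_STAGES:
        for _ in range(100):
            sp = synthesize_cell(stage, geometry, rng)
            feats = measure_sprite(sp.opacity, sp.mask, geometry.pixel_pitch)
            ok += oracle_stage(feats) is stage
            total += 1
    assert ok / total >= 0.99


# ---------------------------------------------------------------------------
# Slides


def test_empty_slide():
    cfg = SlideSimConfig(cells_per_tile=0, grid=(2, 2), jitter_px=0, seed=1)
    slide = render_slide(cfg)
    assert slide.macro_annotations == []
    assert all(not anns for anns in slide.tile_annotations.values())
    for t in slide.tiles:
        assert np.ptp(t.pixels) < 40  # background + sensor noise only


def test_overlap_strips_agree_without_jitter(geometry):
    cfg = SlideSimConfig(grid=(2, 2), overlap_fraction=0.2, jitter_px=0, seed=2)
    slide = render_slide(cfg, geometry)
    overlap = round(0.2 * geometry.tile_px)
    assert overlap == 102
    tiles = {t.grid_pos: t.pixels for t in slide.tiles}
    np.testing.assert_array_equal(
        tiles[(0, 0)][:, -overlap:], tiles[(0, 1)][:, :overlap]
    )
    np.testing.assert_array_equal(
        tiles[(0, 0)][-overlap:, :], tiles[(1, 0)][:overlap, :]
    )


def test_blur_fraction_exact():
    cfg = SlideSimConfig(grid=(2, 5), blur_fraction=0.5, jitter_px=0, seed=3)
    slide = render_slide(cfg)
    assert sum(slide.blur_flags.values()) == 5


def test_annotation_completeness():
    cfg = SlideSimConfig(grid=(2, 2), jitter_px=0, seed=7, cells_per_tile=10)
    slide = render_slide(cfg)
    assert len(slide.macro_annotations) == len(slide.cells)
    tile_px = slide.geometry.tile_px
    # every macro box reappears, clipped, in each tile whose window it meets
    for ann in slide.macro_annotations:
        x, y, w, h = ann.bbox
        covering = 0
        for pos, (ox, oy) in slide.true_offsets.items():
            if x < ox + tile_px and x + w > ox and y < oy + tile_px and y + h > oy:
                covering += 1
                tid = tile_id(pos)
                match = [
                    b
                    for b in slide.tile_annotations[tid]
                    if b.stage == ann.stage
                    and abs(b.bbox[0] - max(x - ox, 0)) < 1e-9
                    and abs(b.bbox[1] - max(y - oy, 0)) < 1e-9
                ]
                assert match, f"cell missing from covering tile {tid}"
        assert covering >= 1
    for tid, anns in slide.tile_annotations.items():
        for b in anns:
            assert 0 <= b.bbox[0] and b.bbox[0] + b.bbox[2] <= tile_px
            assert 0 <= b.bbox[1] and b.bbox[1] + b.bbox[3] <= tile_px


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SlideSimConfig(grid=(0, 2))
    with pytest.raises(ValueError):
        SlideSimConfig(stage_mixture=(0.5, 0.5, 0, 0, 0, 0.1))
    with pytest.raises(ValueError):
        # registration unsolvable: jitter exceeds the overlap margin
        render_slide(SlideSimConfig(overlap_fraction=0.02, jitter_px=5))


# ---------------------------------------------------------------------------
# Anther-range profiles


def test_vacuolated_mode_at_5p5_6mm():
    model = MaturationProfileModel()
    counts = {
        lbl: sample_range_profile(lbl, model, seed=11)[StageClass.VACUOLATED_MICROSPORE]
        for lbl in RANGE_LABELS
    }
    assert max(counts, key=counts.get) == "5.5–6 mm"


def test_no_mature_pollen_below_3p5mm():
    rc = sample_range_profile("<3.5 mm", seed=5)
    assert rc[StageClass.MATURE_POLLEN] == 0


def test_profile_determinism_and_unknown_label():
    a = sample_range_profile("5.5-6", seed=8)
    b = sample_range_profile("5.5–6 mm", seed=8)
    assert a.counts == b.counts
    with pytest.raises(ValueError, match="5.5–6 mm"):
        sample_range_profile("7-8 mm")


def test_stage_counts_unimodal_across_ranges():
    model = MaturationProfileModel()
    expected = np.array([model.expected_counts(lbl) for lbl in RANGE_LABELS])
    for k in range(6):
        col = expected[:, k]
        peak = int(col.argmax())
        assert np.all(np.diff(col[: peak + 1]) >= 0)
        assert np.all(np.diff(col[peak:]) <= 0)
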