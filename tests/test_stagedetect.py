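"""Segmentation, morphology features, rule classification, detector contract."""

import numpy as np
import pytest

from pollenscan.detmetrics import iou
from pollenscan.geometry import DEFAULT_GEOMETRY
from pollenscan.simcell import synthesize_cell
from pollenscan.stagedetect import (
    Detection,
    MorphologyDetector,
    RuleSet,
    classify_cell,
    default_ruleset,
    detect,
    extract_features,
    segment_cells,
)
from pollenscan.stages import DETECTABLE_STAGES, StageClass

PITCH = DEFAULT_GEOMETRY.pixel_pitch


def _blank(px=256, level=235):
    rng = np.random.default_rng(0)
    img = np.clip(level + rng.normal(0, 3, (px, px)), 0, 255)
    return img.astype(np.uint8)


def _tile_with_sprites(sprites, positions, px=512, seed=0):
    rng = np.random.default_rng(seed)
    canvas = np.zeros((px, px))
    boxes = []
    for sp, (x0, y0) in zip(sprites, positions):
        h, w = sp.opacity.shape
        region = canvas[y0 : y0 + h, x0 : x0 + w]
        np.maximum(region, sp.opacity, out=region)
        bx, by, bw, bh = sp.bbox
        boxes.append((x0 + bx, y0 + by, bw, bh))
    inten = 0.92 * (1 - canvas) + rng.normal(0, 0.012, canvas.shape)
    return np.clip(np.round(inten * 255), 0, 255).astype(np.uint8), boxes


def test_segment_blank_tile():
    assert segment_cells(_blank()) == []


def test_segment_five_cells_match_truth():
    rng = np.random.default_rng(3)
    sprites = [synthesize_cell(s, rng_state=rng) for s in DETECTABLE_STAGES[:5]]
    img, truth_boxes = _tile_with_sprites(
        sprites, [(30, 30), (150, 60), (300, 100), (80, 300), (350, 350)]
    )
    segs = segment_cells(img, pixel_pitch=PITCH)
    assert len(segs) == 5
    for tb in truth_boxes:
        assert max(iou(bbox, tb) for _, bbox in segs) >= 0.8


def test_size_gate_excludes_debris():
    img = _blank(128).astype(float)
    img[60:62, 60:62] = 60.0  # ~2 µm speck
    segs = segment_cells(img.astype(np.uint8), min_diameter_um=10, pixel_pitch=PITCH)
    assert segs == []


def test_disc_circularity_near_one():
    yy, xx = np.mgrid[0:64, 0:64]
    mask = (xx - 31.5) ** 2 + (yy - 31.5) ** 2 <= 20**2
    img = np.where(mask, 100, 235).astype(np.uint8)
    f = extract_features(mask, img, PITCH)
    assert f.circularity == pytest.approx(1.0, abs=0.03)


def test_diamond_more_rhomboid_than_disc():
    yy, xx = np.mgrid[0:64, 0:64]
    disc = (xx - 31.5) ** 2 + (yy - 31.5) ** 2 <= 18**2
    diamond = (np.abs(xx - 31.5) + np.abs(yy - 31.5)) <= 24
    img_disc = np.where(disc, 100, 235).astype(np.uint8)
    img_dia = np.where(diamond, 100, 235).astype(np.uint8)
    f_disc = extract_features(disc, img_disc, PITCH)
    f_dia = extract_features(diamond, img_dia, PITCH)
    assert f_dia.rhomboidness > f_disc.rhomboidness
    assert f_dia.rhomboidness > 0.8 and f_disc.rhomboidness < 0.2


def test_mature_pollen_most_opaque_feature():
    opac = {}
    for s in DETECTABLE_STAGES:
        sp = synthesize_cell(s, rng_state=11)
        img, _ = _tile_with_sprites([sp], [(40, 40)], px=160, seed=1)
        f = extract_features(
            np.pad(sp.mask, ((40, 160 - 40 - sp.mask.shape[0]), (40, 160 - 40 - sp.mask.shape[1]))),
            img,
            PITCH,
        )
        opac[s] = f.mean_opacity
    assert max(opac, key=opac.get) is StageClass.MATURE_POLLEN


def test_degenerate_mask_rejected():
    mask = np.zeros((8, 8), bool)
    mask[3, 3] = True
    with pytest.raises(ValueError, match="degenerate"):
        extract_features(mask, np.full((8, 8), 200, np.uint8), PITCH)


# ---------------------------------------------------------------------------
# Classification


def _prototype_features(stage):
    """Features at the plateau center of the shipped ruleset."""
    rs = default_ruleset()
    feats = {}
    for feat, (a, b, c, d) in rs.rules[stage].items():
        feats[feat] = (b + c) / 2
    # fill unused features with anything finite
    for extra in ("circularity", "rim_thickness", "interior_variance"):
        feats.setdefault(extra, 0.0)
    return feats


def test_mature_pollen_prototype_confident():
    scores = classify_cell(_prototype_features(StageClass.MATURE_POLLEN), default_ruleset())
    assert DETECTABLE_STAGES[int(np.argmax(scores))] is StageClass.MATURE_POLLEN
    assert scores.max() > 0.5
    assert scores.sum() == pytest.approx(1.0)


def test_equidistant_features_score_equally():
    rules = {
        StageClass.YOUNG_POLLEN: {"mean_opacity": (0.4, 0.5, 0.6, 0.8)},
        StageClass.MATURE_POLLEN: {"mean_opacity": (0.6, 0.8, 0.9, 1.0)},
    }
    for other in DETECTABLE_STAGES:
        rules.setdefault(other, {"mean_opacity": (-2.0, -1.5, -1.2, -1.0)})
    rs = RuleSet(rules=rules)
    # x = 0.7 sits exactly between the two prototypes (both memberships 0.5)
    scores = classify_cell({"mean_opacity": 0.7}, rs)
    yp = scores[DETECTABLE_STAGES.index(StageClass.YOUNG_POLLEN)]
    mp = scores[DETECTABLE_STAGES.index(StageClass.MATURE_POLLEN)]
    assert abs(yp - mp) < 1e-9


def test_out_of_range_features_yield_flat_distribution():
    scores = classify_cell(
        {"equivalent_diameter": 500.0, "mean_opacity": 0.0, "rhomboidness": 0.0, "vacuole_score": 0.0},
        default_ruleset(),
    )
    assert np.allclose(scores, 1 / 6)


def test_classifier_never_emits_doubtful():
    assert len(classify_cell(_prototype_features(StageClass.TETRAD), default_ruleset())) == 6
    assert StageClass.DOUBTFUL not in DETECTABLE_STAGES


# ---------------------------------------------------------------------------
# Detector contract


def test_detect_blank_image():
    assert detect(_blank(), MorphologyDetector()) == []


def test_baseline_detects_and_classifies_five_cells():
    rng = np.random.default_rng(8)
    stages = [
        StageClass.TETRAD,
        StageClass.YOUNG_MICROSPORE,
        StageClass.VACUOLATED_MICROSPORE,
        StageClass.YOUNG_POLLEN,
        StageClass.MATURE_POLLEN,
    ]
    sprites = [synthesize_cell(s, rng_state=rng) for s in stages]
    img, truth_boxes = _tile_with_sprites(
        sprites, [(30, 30), (160, 60), (300, 100), (80, 320), (350, 350)]
    )
    dets = detect(img, MorphologyDetector())
    assert len(dets) == 5
    for stage, tb in zip(stages, truth_boxes):
        best = max(dets, key=lambda d: iou(d.bbox, tb))
        assert iou(best.bbox, tb) >= 0.5
        assert best.top_class is stage
    confs = [d.confidence for d in dets]
    assert confs == sorted(confs, reverse=True)


def test_mock_detector_passthrough_and_contract():
    fixed = Detection(bbox=(5, 5, 10, 10), scores=np.full(6, 1 / 6))
    dets = detect(_blank(), lambda img: [fixed])
    assert dets == [fixed]

    class Bad:
        bbox = (0, 0, 5, 5)
        scores = np.array([0.9, 0.9, 0, 0, 0, 0])  # sums to 1.8

    with pytest.raises(ValueError, match="distribution"):
        detect(_blank(), lambda img: [Bad()])


def test_detection_scores_validated():
    with pytest.raises(ValueError):
        Detection(bbox=(0, 0, 1, 1), scores=np.array([0.5, 0.5]))
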