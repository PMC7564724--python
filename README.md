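# pollenscan

Desk-scale toolkit for identifying pollen developmental stages in brightfield
slide scans and for steering eggplant (*Solanum melongena*) anther culture
toward doubled haploids (DHs).

Androgenesis — regenerating plants from male gametophytic cells — works only
when the microspores inside the cultured anther are at the right stage,
chiefly the **vacuolated microspore**. Since anther length tracks microspore
maturation, the practical question is: *which anther size range carries the
most vacuolated microspores?* This package implements the full analysis
chain used to answer it:

- **`simcell`** — a synthetic slide simulator. Renders microspore/pollen
  sprites for the six optical stages (tetrad → young → medium → vacuolated
  microspore → young pollen → mature pollen) with the published qualitative
  contrasts (tetrads rhomboid; young microspores small and faint; vacuolated
  microspores circular with a bright vacuole; mature pollen darkest),
  composes them into overlapping, jittered scanner tiles with ground-truth
  boxes, blur flags and true offsets, and samples per-anther-range stage
  profiles along a maturation axis. Everything downstream is testable
  against this ground truth with no real data.
- **`scanproc`** — acquisition-side processing: normalized cross-correlation
  stitching of overlapping tiles into a macro image, tile re-extraction, a
  Fourier focus score (high-frequency spectral energy fraction) with
  focus filtering, affine brightness equalization, empty-tile removal.
- **`labelset`** — COCO-style bounding-box annotations (categories 1–6 =
  stages, 7 = "doubtful"), stratified 80/10/10 train/test/val splits with
  largest-remainder sizes, inverse-frequency class weights, and
  box-consistent augmentation (rotation, blur, scaling).
- **`stagedetect`** — the detector contract plus a deterministic morphology
  baseline: segmentation against the background mode, shape/opacity feature
  extraction, and per-stage trapezoidal membership rules producing a proper
  score *distribution* over the six stages (never a hard label). A trained
  neural detector drops into the same contract; training one is out of
  scope here.
- **`detmetrics`** — IoU, greedy class-wise matching, average precision
  (all-point interpolated PR curve) and mAP, with Table-style CSV output.
- **`antherselect`** — aggregates stage counts per anther size range
  (8 ranges from <3.5 mm to >6.5 mm) and recommends the culture range that
  maximizes the target stage, plus young-microspore / mature-pollen control
  ranges.
- **`dhverify`** — DH verification: filter SNPs to positions where the
  anther donor is heterozygous, per-sample/per-group heterozygosity
  (a true DH is near 0%, a backcross near 50%, the donor 100% by
  construction), flow-cytometry ploidy calls against a diploid reference
  peak at 50, and androgenesis outcome reports.
- **`pipeline` / `cli`** — a `pollenscan` command with subcommands
  `simulate, stitch, qc, split, detect, evaluate, recommend, dhcheck,
  report, run`; `run` executes the whole chain into a run directory with a
  content-hash manifest.

## Worked example

```python
import dataclasses
from pollenscan.simcell import SlideSimConfig, render_slide, sample_profile, tile_id
from pollenscan.scanproc import stitch
from pollenscan.stagedetect import MorphologyDetector, detect, Detection
from pollenscan.detmetrics import evaluate
from pollenscan.antherselect import recommend_range

cfg = SlideSimConfig(grid=(2, 2), cells_per_tile=8, jitter_px=3, seed=42)
slide = render_slide(cfg)
macro = stitch(slide.tiles, cfg.overlap_fraction, jitter_window_px=5)
assert macro.registry == slide.true_offsets   # registration is exact here

detector = MorphologyDetector()
preds, truth = [], []
for i, tile in enumerate(slide.tiles):       # pool tiles into one evaluation
    for d in detect(tile.pixels, detector):
        preds.append(Detection(bbox=(d.bbox[0] + 4000*i, *d.bbox[1:]), scores=d.scores))
    for a in slide.tile_annotations[tile_id(tile.grid_pos)]:
        truth.append(dataclasses.replace(a, bbox=(a.bbox[0] + 4000*i, *a.bbox[1:])))
print(evaluate(preds, truth, iou_threshold=0.5).to_frame().to_string(index=False))

rec = recommend_range(sample_profile(seed=42))
print(f"recommended range: {rec.selected_range} ({rec.selected_count} VM cells)")
```

prints

```
class  n_truth  AP_pct   TP  FP  FN
    T       11   80.00  9.0 6.0 2.0
   YM        6   83.33  5.0 0.0 1.0
   MM       12  100.00 12.0 0.0 0.0
   VM       13   76.92 10.0 0.0 3.0
   YP        7   85.71  6.0 0.0 1.0
   MP        5   80.00  4.0 0.0 1.0
  mAP       54   84.33  NaN NaN NaN
recommended range: 5.5–6 mm (20007 VM cells)
```

The per-class rows give the average precision (percent), true/false
positives and misses of the morphology baseline against the simulator's
ground-truth boxes at IoU ≥ 0.5; the final row is the unweighted mAP. The
recommendation picks the anther range whose profile holds the most
vacuolated microspores — under the default maturation model that is
5.5–6 mm, with 3.5–4 mm and >6.5 mm as the young/mature culture controls.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full chain from scratch at the given seed — synthetic slide,
stitching, focus/empty QC, baseline detection, mAP evaluation, range
profiling and recommendation, DH family summary, and the outcome/report
arithmetic — and writes the results JSON to `--out`.
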