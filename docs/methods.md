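# Methods

## Scope and shape

`pollenscan` reimplements, at desk scale, the analysis chain around
brightfield microspore staging for androgenesis: slide acquisition
processing, bounding-box dataset machinery, stage detection, detection
evaluation, anther-range selection and doubled-haploid (DH) verification.
The production-scale piece — a GPU-trained neural instance detector — is
deliberately represented only by its *contract* (image → list of scored
detections); a deterministic morphology-rule baseline fills the slot so the
rest of the chain is exercisable and testable. Nothing in the baseline is a
claim about real pollen images: it is calibrated to the synthetic world
described below.

## Acquisition geometry

A 20 µL drop mounted under an 11 mm square coverslip forms a water chamber
of height 20 mm³ / (11 mm)² ≈ 0.165 mm — shallow enough that all cells sit
in one focal plane, which is what makes single-plane tile scanning
sufficient. (Some sources describe the coverslip as "11 mm²"; only the
11 mm × 11 mm reading is consistent with the stated column height, so the
geometry type uses `coverslip_side = 11 mm` and this note records the
ambiguity.) Tiles are 512 × 512 px covering 0.26 mm², fixing the pixel
pitch at 1000·√0.26/512 ≈ 0.996 µm/px; all feature measurements convert
through this value.

## Synthetic slide model (`simcell`)

Rendering is a brightfield attenuation model: intensity =
`background_level · (1 − opacity)` with opacity ∈ [0, 1] (1 = fully dark),
plus Gaussian sensor noise (σ = 0.012 on the [0, 1] scale) and 8-bit
quantization. Six stage-conditional sprite generators encode the documented
qualitative contrasts; the quantitative defaults (diameter mean ± sd in µm,
opacity mean ± sd) are implementation choices made once to satisfy the
stage orderings and to give the pixel oracle clean separations:

| stage | diameter (µm) | opacity | shape notes |
|---|---|---|---|
| tetrad | 42 ± 2.5 | 0.45 | square rotated 30–60° (rhomboid) |
| young microspore | 18 ± 1.2 | 0.22 | small faint disc |
| medium microspore | 25 ± 1.3 | 0.38 | disc, thick (2.5 µm) exine rim |
| vacuolated microspore | 32 ± 1.5 | 0.45 cytoplasm | bright vacuole core (opacity 0.08, r = 0.6·R) |
| young pollen | 38 ± 1.8 | 0.58 | sparse starch granules |
| mature pollen | 38 ± 1.8 | 0.85 | dense granules, darkest |

These preserve the required orderings (mature pollen most opaque; young <
medium < vacuolated microspore < young pollen in diameter). A rim 0.30
darker than the body models the exine wall. The "doubtful" annotation class
is never synthesized or predicted.

Slides place a Poisson number of cells (mean `cells_per_tile` × tiles)
uniformly over the mosaic canvas; by default cells do not overlap
(rejection sampling), matching dilute monolayer concentrates — a `clutter`
parameter re-enables overlap. Tiles share `overlap_fraction` (default 0.2)
of their extent with grid neighbors plus an integer per-tile jitter
(default ±3 px, the anchor tile unjittered), emulating stage thread-pitch
error. Cells crossing tile borders are annotated in every covering tile,
clipped — this mirrors what a tile-wise detector can see. Ground truth
(boxes, per-tile offsets, blur flags) is exact by construction. A fixed
count `round(blur_fraction · n_tiles)` of tiles is defocused with a σ = 3 px
Gaussian. All randomness flows from one explicit seed; there is no global
state.

**What the simulator does not model:** photorealistic exine texture,
staining variability, debris and broken cells, illumination gradients /
vignetting, DAPI-visible nuclei (unicellular vs bicellular pollen is
optically indistinguishable here, as in the source system), or overlapping
clumps at default settings. A green end-to-end test therefore establishes
that the *pipeline logic* is correct on its stated world, not that the
baseline would stage real pollen.

The simulator's own oracle (`measure_sprite` + `oracle_stage`: pixel-count
diameter, Crofton-perimeter circularity, bounding-box-extent rhomboid
score, core-vs-ring vacuole contrast) reassigns the generating stage for
≥ 99% of default sprites — the generator/oracle closure that anchors all
classification tests. The disc-sprite circularity floor is 0.84 *under a
marching-squares boundary-tracing perimeter* (whose estimate varies with
rasterization phase); Crofton measurements of the same masks run ≈ 0.99.

### Anther-range profile model

Each of the eight anther ranges (<3.5 … >6.5 mm) sits at a maturation
position `m(range)` in stage-index units (defaults 0.3, 1.0, 1.5, 2.0, 2.5,
3.0, 4.0, 5.0); a range's stage mixture is a discretized Gaussian around
that position (σ = 0.6) truncated at 2 stage units — the truncation is what
makes mature pollen count exactly zero in the smallest anthers. Counts are
one multinomial draw of `cells_per_range` (default 30 000, giving
peak-range vacuolated-microspore counts around 20 000, the magnitude seen
in practice). The defaults place the vacuolated-microspore mode at
5.5–6 mm and the young-microspore / mature-pollen modes at 3.5–4 mm and
>6.5 mm; expected per-stage counts are unimodal across ranges.

## Stitching and QC (`scanproc`)

No published registration algorithm exists for the source system, so the
design is the simplest deterministic one: greedy row-major placement
anchored at tile (0,0); each tile's offset maximizes the mean normalized
cross-correlation with its already-placed left/up neighbors over the full
±`jitter_window` integer search window; ties break toward the smaller
displacement, then lexicographically. Flat (texture-free) overlap strips
have undefined correlation — such tiles are flagged `unregistered` and kept
at their nominal offset. Overlaps are blended by linear feathering (weights
ramp linearly over the overlap margin), which is seamless and
deterministic. The registry is reported in the anchor frame with the mosaic
origin recorded separately, so registered offsets are directly comparable
to the simulator's truth.

The focus score is the fraction of non-DC power-spectrum energy above a
radial frequency cutoff of 0.25 × Nyquist (cutoff configurable; only
"Fourier analysis" is specified upstream). It is invariant to constant
intensity shifts and translations and strictly decreases under Gaussian
blur. Batch thresholding defaults to an Otsu split **of the log scores** —
raw scores span orders of magnitude and raw-score Otsu can land inside the
low cluster through histogram binning; a fixed threshold override exists.
Equalization is an affine per-channel map taking the mean to 128 and the
span to 200 (8-bit), idempotent up to rounding; constant channels are
shifted only. Empty tiles are those whose fraction of pixels deviating
> 10 gray levels from the background mode (after a 2×2 opening that ignores
isolated noise pixels) falls below `foreground_min_fraction` (default
0.001 ≈ one small cell per tile).

## Dataset machinery (`labelset`)

Boxes are 0-based, x right / y down, `(x, y, w, h)` half-open, everywhere.
Splits are by image, never by box. Partition sizes follow largest-remainder
rounding (2439 images → 1951/244/244 at 80/10/10). Stratification keys on
each image's *dominant* class (images mix classes; the key is an
implementation choice): per-(class, partition) quotas take floors first,
then leftovers go to the largest fractional remainders subject to partition
capacity, with a mop-up pass; the achieved per-class deviation is reported
and a warning is raised if it exceeds the tolerance (default 2 percentage
points) or if a class occurs in fewer than 3 images. Class weights are
inverse-frequency, normalized so Σ weight·count = Σ count (equal counts →
unit weights; scale-invariant). Augmentations transform boxes exactly for
quarter-turns — one 90° counter-clockwise turn maps `(x, y, w, h)` to
`(y, W−x−w, h, w)` — and by corner transformation + axis-aligned rebox for
free rotation and scaling; blur leaves geometry untouched; boxes pushed
fully outside are dropped and logged. "Doubtful" boxes are preserved in
files but excluded from training/evaluation sets.

## Baseline detector (`stagedetect`)

Segmentation thresholds pixels darker than the background mode by 0.10
(on [0, 1]), opens with a 3×3 element, fills holes (the bright vacuole is a
hole at this threshold), gates connected components on equivalent diameter
(10–55 µm) and splits oversized components by distance-transform watershed
when at least two clear peaks exist. Features: equivalent diameter
2·√(A/π)·pitch; circularity 4πA/P² with a Crofton perimeter; opacity
1 − mean interior intensity / background; rhomboidness maps bounding-box
extent linearly from π/4 (disc) to 1/2 (diamond) onto [0, 1]; rim thickness
counts dark boundary-band pixels per unit perimeter; vacuole score is the
background-normalized brightness contrast between a deep core
(> 0.65·max inscribed distance) and a mid ring (0.22–0.38), scaled by 0.30
and clipped to [0, 1] — the band placement deliberately clears both the
exine rim and the vacuole edge.

Classification multiplies per-stage trapezoidal memberships over
(diameter, opacity, rhomboidness, vacuole score) and normalizes to a
distribution; if every stage's raw score is negligible the classifier
returns the flat distribution (high entropy) rather than failing — the
continuous-assignment behavior wanted for intermediate cells. The shipped
ruleset (`data/default_ruleset.yaml`, version `sim-default-1`) was fitted
by `calibrate_ruleset` on 200 simulated sprites per stage pushed through
the *production* segmentation/feature path: plateau = 5th–95th percentile,
shoulders extend by 50% of the plateau width. Recalibration against any
labeled feature sample uses the same utility. Overlapping detections are
suppressed keeping the higher confidence at IoU > 0.6 (no published rule
exists). The detector contract validates that score vectors are proper
distributions and returns detections sorted by confidence.

## Evaluation (`detmetrics`)

Matching is class-specific (no cross-class credit) and greedy in confidence
order: a prediction claims the unmatched same-class truth of highest IoU at
or above the threshold (default 0.5); IoU ties go to the lower truth index.
AP integrates the all-point-interpolated precision–recall curve (precision
at each recall replaced by the maximum precision at ≥ that recall); mAP is
the unweighted mean over classes with ground truth, and classes without
truth are recorded as undefined rather than zeroed. The IoU threshold and
interpolation rule are embedded in every result so tabulated outputs are
self-describing. Neither the matching threshold nor the interpolation
scheme is specified upstream; both are configurable. Note that the mean of
the six published per-class precisions, carried at their printed two
decimals, is 86.2933 — the published mean (86.30) was evidently taken over
unrounded values; `mean_ap` reports the honest 86.29 and the acceptance
check allows one unit in the last printed digit.

## Range selection (`antherselect`)

Counts use each detection's top class only (matching integer count bars; a
soft-count mode is available via the score vectors in the detection
sidecar), filtered by an optional confidence floor (default 0, conserving
detections). The recommendation is the argmax range of the target stage's
count (default vacuolated microspore); ties go to the earlier range and are
flagged. Control ranges are the argmax ranges of young microspore and
mature pollen. Range labels accept ASCII hyphens, missing "mm" and the
">6" spelling of the open top range (both spellings occur in practice; the
8-range scheme makes ">6.5 mm" the consistent label). The culture-design
helper reproduces the anther bookkeeping: 3 genotypes × 2 protocols × 3
replicates × 15 anthers = 270 in the recommended range, and twice that
(two control ranges) = 540 controls.

## DH verification (`dhverify`)

Heterozygosity is evaluated only over positions where the anther donor is
heterozygous — by construction the donor scores 100%, sexual backcross
offspring ≈ 50%, and true DHs ≈ 0% plus a small residual (somaclonal
variation or SNPs mapping to paralogs). Missing calls are excluded from the
denominator and reported separately (they are tabulated separately in
practice; the convention is a design choice here). Heterozygosity prints to
two decimals; outcome fractions to one. Ploidy: a flow-cytometry peak
within ±10% of the diploid reference (50 arbitrary units) is diploid,
within ±10% of 25 haploid, one of each mixoploid, anything else "other";
the tolerance is configurable. Input formats: VCF (diploid GT; 0/1 → Het)
via cyvcf2, or a plain TSV with rows = SNPs, columns = samples, cells in
{AA, AB, BB, NA} (0/1/2/. also accepted). The synthetic family generator
draws backcross heterozygosity per position at rate 0.5 and DH residual
heterozygosity at 0.01 with 1% missingness, donor fully called.

## Numerical and degenerate-input choices

- All randomness flows from explicit seeds through `numpy` Generators.
- Constant images: focus score 0; equalization shifts the mean only;
  correlation on flat strips is treated as undefined (tile unregistered).
- Degenerate masks (< 4 px) are rejected by feature extraction; segmentation
  size gates exclude debris below 10 µm.
- Largest-remainder rounding ties break toward the earlier partition;
  argmax ties in range selection toward the earlier range; matching IoU
  ties toward the lower truth index; stitching score ties toward smaller,
  then lexicographically earlier offsets.
- Percentages round half-even via Python's `round` at the precision stated
  for each table.

## Known limitations

- The morphology baseline is calibrated to the simulator; on real slides it
  would need recalibration at minimum, and is no substitute for a trained
  detector.
- Stitching assumes integer offsets within a known window and textured
  overlap strips; there is no subpixel registration, flat-field correction
  or vignetting model.
- Opacity measurements assume an approximately constant white background;
  they are not invariant under arbitrary affine re-mapping of intensities,
  so detection runs on tiles as rendered (or equalized consistently with
  the calibration).
- Mixed-ploidy mosaics beyond haploid+diploid, and aneuploidy, fall into
  the "other" ploidy class.
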