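# Methods

## The confluence rule and its assumptions

The pipeline's ground-truth definition of geographic atrophy is anatomical:
where the ellipsoid zone and the RPE are lost, a multi-layer segmentation
places the EZ, RPE and BM boundary lines on top of each other, so both the
EZ–RPE and the RPE–BM thickness are zero. `detect_confluence` flags a
column when both thicknesses are at most `tol_px` and all three boundaries
are defined. Assumptions worth making explicit:

- Boundary rows are real-valued (sub-pixel) image rows, row 0 on the
  vitreous side, and satisfy `ez ≤ rpe ≤ bm` wherever defined. Rounding to
  integer rows happens only at mask rasterization.
- `tol_px` defaults to 0.5: with sub-pixel boundaries, "concurrent" is read
  as thickness below half a pixel. Inputs with integer rows work with the
  same default (exact zeros pass any non-negative tolerance), and the knob
  accommodates segmentation platforms that leave small residual offsets.
- A column with any undefined boundary is never GA: the rule requires all
  three lines to be present and concurrent. The alternative (treating a
  missing EZ as atrophy) would conflate segmentation failure with disease.

Flagged columns are dilated to a `thickness_px = 10` band centered on the BM
row. "Centered" needs a convention for even thickness: the band covers rows
`[round(bm) − 5, round(bm) + 5)` — five rows above the BM row, the BM row,
four below — clipped at the image edges. Any fixed convention would do;
this one is documented and tested, and the en face stage is insensitive to
it (only column occupancy matters there). `round` is numpy's
round-half-to-even; boundaries land on .5 only in contrived inputs.

## En face maps

Compilation is exactly two reductions: a per-column maximum over depth
(so the result does not depend on where in the column the band sits), then
a horizontal block maximum onto the target width. Block maximum — not
interpolation — because the masks are binary and the compilation rule is a
per-x maximum; interpolation would produce fractional values and could drop
a single-column lesion entirely. For non-integer width ratios, target
column x covers the half-open source interval [x·W/T, (x+1)·W/T) and takes
the maximum over every source column overlapping it, which preserves
presence per row. There is no vertical rescaling: row b of the map is
B-scan b.

Projection back onto B-scans expands the map to the B-scan width by
nearest-source-column lookup and re-applies the BM-band convention, so
`compile(project(M)) == M` at matched width; this round trip is a tested
invariant. Model confidence maps are binarized at 0.5 by default before
presence or lesion logic; the threshold is exposed everywhere it is used
(the original operating point is not pinned down by the ROC analysis alone,
so it is configurable).

## Lesion morphometry

Connected components on the binary en face map use 8-connectivity by
default ("a single continuous lesion" read inclusively; 4-connectivity is a
config option). The greatest linear dimension of a component is the major
axis of the ellipse with the same second central moments as the pixel
centers after scaling each axis to µm — the standard image-moments major
axis, identical to `skimage.regionprops(..., spacing=...).axis_major_length`.
Scaling before the moment computation matters: measuring on raw pixels
would conflate the ~12 µm column spacing with the ~47–62 µm B-scan spacing
and misstate any oblique lesion. A maximum-Feret-diameter option is
provided for sensitivity analysis; for convex blob-like lesions the two
differ by a few percent. A single-pixel component returns the larger pixel
spacing.

Rasterization accuracy: on the 97-B-scan grid the moments axis of a 400-µm
disc deviates from 400 µm by up to ~5% depending on grid phase, dominated
by the 62-µm row spacing. The CAM classifier is nevertheless exact away
from the threshold: over 500 random single-lesion phantoms per device with
axes in [100, 600] µm, excluding a one-coarse-pixel band around 250 µm,
classification matches the analytic axis in 100% of cases (an acceptance
check recomputed by `scripts/acceptance.py`).

The 250-µm comparator is ≥ (a lesion of exactly 250 µm meets the threshold
and is cRORA); `strict=True` switches to >. Area summaries divide positive
pixels by total field pixels; removing iRORA lesions can only decrease the
area, a tested monotonicity.

## Evaluation statistics

Confusion-derived metrics follow the standard definitions; any metric with
a zero denominator is reported as NaN with an explicit reason, and F is
defined as 0 when there are no true positives but errors exist (tp = 0,
fp + fn > 0). Detection-level evaluation applies the same machinery to
per-scan or per-volume presence booleans.

The ICC is the two-way random-effects, **absolute-agreement,
single-measure** form — the standard choice for method-vs-ground-truth
agreement, where a constant bias should count against the method — computed
from the two-way ANOVA mean squares with the F-distribution
(Satterthwaite) confidence interval; a consistency variant ("ICC3") is a
config knob. ROC curves pool pixels across all scans (not per-scan
averaging; the pooled form weights scans by their pixel count and matches
how the pixel-level confusion metrics are computed), sweep every observed
confidence, include the (0,0) and (1,1) endpoints, and integrate AUC by the
trapezoid rule.

## The phantom generator

Phantoms emulate what the pipeline actually consumes, at the two device
geometries (97×512 and 128×512 over a 6 mm × 6 mm field; the field size of
the 97-B-scan protocol is assumed equal to the 6 mm × 6 mm of the other
device and is configurable). Atrophy is a union of elliptical en face
regions; membership of a pixel is decided at its physical center, and the
same test generates both the layer confluence and the analytic truth map,
so footprint recovery through the rule is exact by construction. Outside
lesions the three boundaries ride a shared smooth undulation (a sum of
three seeded low-frequency sinusoids, default amplitude 2 px) with fixed
EZ–RPE and RPE–BM thicknesses; inside, all three collapse onto the BM row.
Intensity B-scans are banded reflectivity profiles; below BM the choroid of
a confluent column is `hyper_gain` (default 2.0) times brighter than intact
columns before additive Gaussian noise (default sd 0.05), which is the
hypertransmission the en face model learns from. Lesion axes default to
[100, 600] µm — spanning both sides of the 250-µm CAM threshold — with
centers rejected until bounding circles are separated by three coarse
pixels, so components stay distinct.

What the phantoms deliberately do **not** contain: speckle statistics,
drusen, vessel shadows, motion/registration artifacts, curved foveal
anatomy, or partial (iRORA-like) thinning gradients — lesions are
binary-atrophic with sharp edges. Tests passing on phantoms therefore
demonstrate the correctness of the pipeline's logic and the learnability of
the confluence rule from intensity contrast; they say nothing about
robustness to real-scanner artifacts, and the demonstrator model would need
retraining for clinical images.

## The segmentation demonstrator

Two model flavors share one architecture: the en face flavor (input =
mean-over-depth intensity projection, target = en face GA map) and the
B-scan flavor (input = intensity B-scan, target = BM-band mask). The
network is a symmetric encoder–decoder with skip connections implemented
directly in numpy (NHWC float32; convolution as one GEMM per kernel tap,
hand-written backpropagation, seeded He initialization): `depth` 2×2
max-pooling stages, two 5×5 convolutions per stage with `base_filters`
doubling per stage, nearest-neighbor upsampling followed by a convolution
on the decoder path, and a 1×1 sigmoid head. At the full-scale
configuration (256-px inputs, depth 4, base 32) it has 23.97 M parameters;
that configuration is preserved as `PAPER_CONFIG` for fidelity but is not
trained in the test suite.

Training samples `samples_per_epoch = 200` items per epoch with replacement
(batch 40), minimizes binary cross-entropy with RMSprop, stops after
`early_stop_patience` epochs without validation improvement, and restores
the best-validation weights. Sampling with replacement is what makes
hard-example duplication effective: a duplicated item is drawn twice as
often in expectation. Mining profiles a seeded sample of up to 100 training
items for pixel F-scores, takes the 30th percentile (linear interpolation)
as the threshold, and appends one copy of every training item strictly
below it; all-tied scores duplicate nothing. Retraining continues from the
round-one weights with identical parameters.

Desk scaling (`DESK_CONFIG`, the default): 64-px inputs, depth 3, base 4
(93 k parameters), learning rate 1e-2, patience 6, at most 25 epochs, and
the output head's bias initialized to −4 (the prior logit of a few-percent
lesion prevalence) so early training does not spend its steps pushing the
background toward zero. The desk learning rate is two orders above the
full-scale 1e-4 because a desk run takes ~100 optimizer steps rather than
thousands; both values are plain config fields. Phantom images for the
desk experiment are 128×128 (a 128-B-scan × 128-A-scan × 64-depth cube over
6 mm × 6 mm) and are resized to the model input on entry, the confidence
map resized back on exit. With 60 training / 10 validation / 20 held-out
volumes, hypertransmission gain 2 and noise 0.05, the train→mine→retrain
cycle reaches pooled held-out pixel F of ~0.83–0.87 (seed-dependent); the
residual error is concentrated at lesion boundaries and in lesions only a
couple of en face pixels across, which is a resolution limit rather than a
training limit. Training determinism is best-effort: a fixed seed
reproduces runs bit-for-bit on a given BLAS, and to recorded loss traces
otherwise.

## Patient-grouped splitting

`patient_split` shuffles patients (never timepoints) with a seeded
generator and allocates contiguously by largest-remainder rounding, so all
timepoints of a patient land in exactly one of train/validation/test and
each realized split is within one patient of its 80/10/10 target. This is
the guard against leakage of longitudinal scans across splits.

## Known limitations

- The phantom's sharp, fully-confluent lesions make the learning task
  easier than clinical GA with fuzzy margins and partial atrophy.
- The GLD of lesions spanning fewer than ~3 B-scans carries rasterization
  error of order the B-scan spacing; the CAM classifier is only guaranteed
  outside a one-pixel band around the threshold.
- The en face stage supports downsampling (mask width → map width); maps
  wider than the source masks are not produced.
- The numpy trainer targets CPU-scale demonstrations; it is not a
  general-purpose deep-learning framework and has no GPU path.
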