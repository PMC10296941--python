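# Methods

`hsipath` implements a complete micro-hyperspectral pathology pipeline:
calibration of transmitted-light datacubes, PCA pseudo-color synthesis,
spectral/patch sample extraction, a 3D spectral-spatial CNN
("BufferNet"), a staged transfer-learning image branch, and a
slide-level joint diagnosis procedure.  Patient hyperspectral data of
this kind cannot be redistributed, so the package ships a synthetic
phantom generator that emulates the statistical structure the pipeline
assumes; all quantitative tests run against phantoms with known ground
truth.

## Data model

A datacube is a `(band, row, col)` array with a per-band wavelength
axis.  The nominal acquisition is 256 bands over 1000 x 1000 pixels,
stored band-interleaved-by-pixel (BIP: all bands of a pixel contiguous,
pixels row-major).  The first 30 and last 26 bands are trimmed, leaving
200 bands covering 410–900 nm.  The retained grid is assumed linear
between the endpoints; the instrument's ~3 nm resolution is consistent
with this but the true grid is unknown, and the axis is metadata only —
no computation depends on its exact spacing.  Label rasters use integer
codes 0 unlabeled / 1 normal / 2 cancer / 3 other tissue / 4 background.

## Calibration

Two-step standardization of raw counts into unitless transmittance:

1. **Flat-field** (per scanning column, per band): sort the column's
   values, drop the `trim_count` largest and smallest (default 150 for
   1000-row columns; for cubes under 601 rows the count scales down to
   `(rows-1)//4` so desk-scale cubes remain calibratable), average the
   remaining p values, and divide every pixel in the column by that
   average.  The trimming is applied independently per (column, band)
   pair — the only reading that keeps p well defined per averaged
   quantity.  Division guards use an epsilon floor (1e-8 of the cube
   maximum); a structurally all-zero column raises instead.
2. **Transmission standardization**: divide every spectrum by the mean
   spectrum SC of a background (no-tissue) region.  Afterward the
   background averages to exactly 1 per band and the result is invariant
   to any global intensity scale (slice thickness, lamp brightness).
   SC is computed *after* flat-fielding, following the pipeline order of
   the two steps.

`auto_background` offers mask-free operation: pixels brighter than the
0.95 quantile of band-mean intensity with spectral coefficient of
variation below 0.05.  It is a convenience for clean slides; phantoms
with strong residual column structure at the flat-fielded stage should
pass an explicit mask (the CLI accepts the label raster).

On a phantom whose columns are compositionally identical (the `stripes`
layout), the composed calibration is *exactly* invertible at zero noise:
the trimmed column mean factors into (clean mean) x (column gain) x
(global scale), so both nuisance factors cancel.  The identifiability
test exploits this; the `quadrant` layout is not column-homogeneous and
carries a small composition-dependent residual, which is representative
of real slides.

## PCA and pseudo-color composites

PCA is an eigendecomposition of the band covariance (n-1 denominator)
of pixel spectra, components sorted by descending eigenvalue, each
sign-fixed so its largest-magnitude loading is positive.  The
implementation forms the covariance explicitly and uses a symmetric
eigensolver; tests cross-check it against scikit-learn's PCA and a 2x2
closed form.  Composites place min-max-stretched score images of three
chosen components into the RGB channels; the index order is significant
(PCA514 and PCA145 are different images).  A constant score image maps
to 0.5 rather than raising.  Default fitting scope is the data at hand
(per cube or training split); fitting across train+test is possible but
not the default, to avoid leakage.

## Sampling and augmentation

Spectral samples are `bands x 9 x 9` windows centered on labeled cell
pixels; centers whose window crosses the border are skipped, never
padded (padding would fabricate tissue).  Patch samples tile the slide
into a non-overlapping row-major grid (a 1000 x 1000 slide gives 16
patches of 250 x 250).  A patch is discarded when more than half its
pixels are blank (band-mean transmittance > 0.92 — empty glass
transmits ~1) or when neither class reaches 80% of its labeled pixels;
both numbers are configurable and were chosen as round defaults, not
fitted.  Augmentation is restricted to the 8 dihedral variants plus
translation realized as jittered crop offsets at extraction time; no
scaling operator exists because microscopic morphology is
scale-bearing.

## BufferNet

A 3D CNN for `200 x 9 x 9` spectral samples.  A stem convolution with
spectral kernel 5, spatial kernel 1, stride (2,1,1) and no padding
halves the spectral axis (98 x 9 x 9, 64 channels).  Three *buffer
blocks* follow; each is one down-sampling conv (kernel 3, stride 2,
padding 1) plus three buffer convs (stride 1, padding 1), with 64 / 128
/ 256 output channels — 13 conv layers in all, each followed by 3D
batch normalization.  Average pooling (kernel 2, stride 2, floor mode)
and a dense layer emit two class logits.  This reproduces the reference
feature-map chain 98x9x9 → 49x5x5 → 25x3x3 → 13x2x2 → 6x1x1 exactly;
padding 1 in the blocks is the unique choice consistent with that
chain, and the spectral-5/spatial-1 stem is the unique single-padding
reading that yields 98 x 9 x 9.  The declarative spec lists only
conv/norm/pool/dense/softmax layers; the runtime builder inserts ReLU
after each normalization and hidden dense layer.  `base_channels`
scales width (64 at full scale, 16 in desk-scale runs) without changing
the shape chain.  The average pool clips its kernel on axes shorter
than it, so narrow-band scaled variants degrade to extent 1 instead of
erroring.

The networks are built on a small numpy layer library with manual
backpropagation (`hsipath.nn`).  Convolutions are evaluated per kernel
offset with BLAS contractions, keeping memory at one padded input copy;
every layer's gradients are verified against central differences, and
the forward 3D convolution against a naive triple-loop oracle.
Computation is float32; training is bit-reproducible given a seed.

## Training and transfer

SGD with momentum and softmax cross-entropy (the standard loss for a
two-class softmax head).  Full-scale defaults: batch 128, lr 1e-4,
momentum 0.9, 30 epochs, per-epoch shuffling.  "Iterations" are read as
epochs.  For the desk-scale protocol (base_channels 16, 2000 phantom
samples, 5 epochs) the learning rate is 0.01 — the narrow scaled
network needs a larger step than the full-width model, and no rate is
prescribed for scaled runs.

The transfer branch uses the standard VGG-16 arrangement (5 blocks of
2/2/3/3/3 3x3 convs, channels 64–512, five 2x2 max pools, three dense
layers), width- and input-size-scalable.  The staged protocol is:
(1) train backbone + head on the large conventional-pathology set
("Trans"); (2) replace the head and train it on the target set at a low
rate with all conv blocks fixed — at desk scale, updating the full
network with a fresh random head destroys the pretrained features
(classic catastrophic forgetting / dying-ReLU collapse), and head-only
warm-up is the standard remedy; (3) fine-tune with blocks 1–4 frozen so
only block 5 and the head learn (defaults lr 8e-4, batch 50, 17
epochs).  Frozen parameters are bit-identical before and after
training, which tests assert exactly.  No pretrained weights are
downloaded; pretraining runs on synthetic texture data.

## Joint diagnosis

Five steps per calibrated slide: (1) tile into patches; (2) score each
patch with the spectral-spatial model and gate: probability > 0.9 →
cancer, < 0.1 → normal, the closed band between → undetermined;
(3) for undetermined patches, cluster pixel spectra (seeded KMeans,
k=6: the five emulated tissue populations plus slack) and remove any
cluster whose centroid lies within 0.10 rad spectral angle of a
non-target reference (red blood cells, lymphocytes, cytoplasm,
interstitium); (4) classify surviving candidate pixels with the
spectral model (same 9 x 9 border rule) giving a cancer fraction;
(5) fuse patch probability and pixel fraction as an equal-weight convex
combination and call cancer when the joint probability reaches the
final threshold.  The fusion form and the k/angle-threshold values are
not prescribed anywhere and are exposed in `JointConfig`.  The default
final threshold is 0.3 — deliberately conservative so that borderline
joint probabilities (e.g. 0.377) are still flagged, prioritizing
sensitivity over specificity as clinical screening requires; 0.5 gives
the symmetric rule.  If filtering removes every pixel, the patch falls
back to its gate probability alone and is flagged.

Overlays color patches green (normal), blue (cancer) and yellow
(suspected: joint probability within ±0.15 of the threshold); the
continuous per-pixel map runs blue (normal) to red (cancerous), with
gated patches filled by their patch probability and undetermined
patches showing per-pixel model probabilities.

## Phantom generator

Bright-field convention: background transmits ~1, tissue less.  Each
population's transmission spectrum is 1 minus Gaussian absorption dips
(Beer-Lambert flavor): a broad stain band shared by stained tissue
(center 600 nm, depth 0.45, width 150 nm — band-mean transmittance
~0.6–0.8, as heavily stained H&E sections show) plus narrow fingerprint
features per class.  The red-cell analogue carries a Soret-like 420 nm
band plus the 545/577 doublet.  Feature placements were chosen so every
target↔non-target spectral angle exceeds 1.5x the 0.10 rad SAM
threshold, giving the filter honest work with honest margins.  Nuclei
are disks (radius 3 px, density 0.012/px², toward the dense end of
cellular tissue) in a cytoplasm/interstitium stroma with sprinkled red
cells and lymphocytes; the `quadrant` layout makes the slide's top-left
quarter cancerous.  Per-pixel signal = population spectrum x smooth
column gain (amplitude 0.2) x global scale (1.3) + Gaussian noise
(sd 0.01, ~1% of full transmittance).  Everything derives from one
seed, bit-reproducibly.

What the phantom does **not** emulate: chromatic aberration and focus
variation, stain batch variability, spatially correlated noise, nuclear
pleomorphism and texture inside nuclei, and partial-volume mixing at
structure boundaries.  Passing tests therefore demonstrate the
pipeline's correctness and identifiability under its stated
assumptions, not clinical performance on patient slides — the printed
patient-data accuracies are out of scope by construction.

## Problem sizes and numerical choices

Desk-scale defaults: 200 x 200 px, 50 bands (a `paper_scale()`
constructor gives 1000 x 1000 x 200).  The end-to-end checks train the
base-16 BufferNet on 2000 spectral samples for 5 epochs (~2 min on one
CPU core) and diagnose a 16-patch phantom slide with
nearest-reference-spectrum oracle models.  Ties in min-max stretching
map constant channels to 0.5; KMeans uses a fixed seed and n_init=4;
spectral angles clip the cosine into [-1, 1]; eigenvalues are clipped
at zero.  Known limitations: no GPU path, no whole-slide pyramid
formats, no wavelength calibration, and the image branch is practical
only at reduced width/size on a single CPU.
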