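# Methods note

This note records the quantitative model implemented by `nucleoprofiler`,
the fixed parameter choices, and the numerical conventions that outputs
depend on. Vocabulary: a *nucleus crop* is a single-nucleus multi-channel
image (markers H3K27ac and CTCF plus a DNA counterstain); *puncta* are
bright discrete foci inside the nucleus in a marker channel.

## 1. Nucleus geometry

**Moment-equivalent ellipse.** The nucleus mask's largest connected
component is summarized by the ellipse with the same second central image
moments: center = centroid, semi-axes `a = 2*sqrt(lambda_max)`,
`b = 2*sqrt(lambda_min)` of the covariance eigenvalues (each moment gets the
`+1/12` pixel-variance correction before eigendecomposition), orientation =
major eigenvector angle in the (row, col) frame, normalized to `[0, pi)`.
Degenerate masks (all pixels collinear before the pixel correction) raise.

**Five concentric zones.** With normalized elliptical radius
`rho(p) = sqrt((u/a)^2 + (v/b)^2)` (offsets rotated into the ellipse frame),
pixel `p` belongs to zone `j = ceil(5*rho)`; `rho = 0` maps to zone 1,
`rho = 1` to zone 5 (the periphery), `rho > 1` to no zone. Zones are scaled
copies of the fitted ellipse (equal axis fractions), so their areas follow
the odd-number ratio 1:3:5:7:9 up to rasterization. Zone areas partition the
interior pixel count exactly.

**Roundness.** `4*pi*A / P^2` with `A` the pixel count and `P` the length of
the marching-squares contour simplified by a 1-px Douglas-Peucker tolerance.
The simplification removes the staircase bias of rasterized smooth shapes: a
disc scores ~1.0, a square ~pi/4, thin bars near 0.

## 2. Puncta segmentation (`thre_h_watershed`)

1. 4-class multi-Otsu on the intensities **inside the nucleus mask** (the
   zero-padding class never participates). The brightest class is the
   foreground; a config switch takes the top two classes. The histogram uses
   256 bins, escalating to 512/1024/2048 only if the threshold search is
   infeasible at the coarser resolution (narrow background peaks under a
   large dynamic range).
2. Euclidean distance transform of the foreground.
3. Markers = local maxima of the distance map with minimum separation 3 px,
   collapsed to **one marker per equal-value plateau** at the plateau's
   lexicographically smallest `(row, col)` pixel. Plateau handling prevents
   flat ridges (e.g. the distance transform of a rectangle) from seeding
   several basins; the minimum separation prevents oversplitting of round
   spots.
4. Watershed of the negated distance map restricted to the foreground.
5. Objects with area **strictly greater than** 300 px are discarded (area
   exactly 300 is kept).

Per-punctum measurements: centroid, area `A_i`, mean intensity `I_i` from
the original channel, axis lengths `L_major/L_minor` of the
moment-equivalent ellipse, irregularity `C_i = L_major/L_minor` (undefined
and excluded, with a warning, when `L_minor = 0`), effective radius
`r_i = (L_major + L_minor)/4`.

Per-nucleus aggregates: count `N`, mean area, mean intensity, mean
irregularity, and radial densities `d_j = n_j * 250 / A_j` (puncta per
250-px^2 unit of zone area), where a punctum's zone is that of its
pixel-rounded centroid. `sum(n_j) + (centroids outside the ellipse) = N`.

Operating range: on fields with SNR >= 5 (peak/noise-sigma), centroid
separation >= 8 px and radii 2-5 px, detection of planted puncta is >= 95%
with centroid RMSE <= 1.5 px. At the SNR-5 boundary the brightest Otsu class
also captures upper-tail noise pixels, which appear as small spurious
objects; the criterion above concerns recovery of true puncta.

## 3. Colocalization

For source set `S` and target set `T` (the two marker channels):

* **Minimum distances**: for each source centroid, the Euclidean distance to
  the nearest target centroid; summarized by the mean and a histogram with
  left-closed 10-px bins.
* **Overlap ratio**: fraction of source puncta with at least one target
  punctum satisfying `d <= r_i + r_j` (boundary inclusive) using effective
  radii. Empty source: metric missing; empty target: 0 with a warning.

Both metrics equal their O(N^2) brute-force definitions exactly (verified
bit-for-bit in the acceptance battery).

## 4. Nucleus QC

Candidate segments from the classical field segmenter (Gaussian smoothing
sigma 2, Otsu, hole filling, distance transform, watershed with 50-px marker
separation) are rejected when any of the following holds:

* bounding-box aspect-ratio z-score > 1.5, computed over the batch with the
  sample standard deviation (`ddof=1`); with fewer than two records or zero
  variance all z-scores are 0;
* any bounding-box side outside [200, 600] px;
* pixel area below 30,000 px^2 (direction configurable; see below);
* roundness < 0.7.

**Area-rule direction.** A rejection rule of the form "area > 30,000" is
inconsistent with the side-length floor: a round nucleus at the minimum
200-px side already has area ~31,400 px^2, so the two rules together would
reject every acceptable nucleus. The default therefore rejects *small*
outliers (area < 30,000), consistent with the other thresholds; the
opposite direction is available via `QCThresholds(area_reject_above=True)`.

Accepted crops are centered on a zero canvas (600 x 600 by default) with the
centering offset and original field bounding box recorded, and pixels of
other instances inside the bounding box zeroed.

## 5. Classifier

A compact residual CNN ("9conv_1f"): a 7x7 stem convolution with stride 2,
four residual blocks of two 3x3 convolutions each (strides 2,2,2,2; widths
16,24,32,32), and one fully connected layer producing a single binary
logit — exactly 9 convolutions, 9 batch-norm layers and 1 FC layer.
Shortcuts are parameter-free (ResNet option A: stride slicing plus channel
zero-padding), so the census is not inflated by projection convolutions.
Variants: "9conv_gap_1f" (global average pooling before the FC) and
"17conv_gap_1f" (eight blocks). The input side is configurable because the
network is fully convolutional up to the FC layer.

Single-marker images are presented as pseudo-RGB (the plane duplicated
across three channels). Inputs are scaled by `1e-3` (part of the model
contract). Training: Adam, binary cross-entropy on the logit, cosine
learning-rate decay 1e-4 -> 1e-6 over all steps, batch 128, 300 epochs at
full scale; the desk-scale recipe (used by the validation experiments) is
128-px inputs, batch 32, 20 epochs. The layers are implemented directly on
NumPy (im2col convolutions, batch norm, Adam) and are deterministic given
the seed in single-threaded execution; gradients were verified against
numerical differentiation.

## 6. Score-CAM and heatmap metrics

For the K activation maps of the last residual block: upsample bilinearly to
input size, min-max normalize to [0, 1] (constant maps carry no spatial
information and are skipped with a warning), multiply elementwise with the
input, forward-pass each masked input, record the target-class score
(`sigmoid(logit)` for class 1, `sigmoid(-logit)` for class 0); weights =
softmax over the K scores; heatmap `S = ReLU(sum_k w_k * map_k)`.

* **Nuclear intensity** = `(1/|M|) * sum_{p in M} S(p)` with
  `M = {p in mask : S(p) > 0}`; missing when `M` is empty.
* **Nuclear periphery enrichment** = mean of `S` over **all** pixels of
  zone 5 divided by the nuclear intensity. The numerator includes zero
  pixels while the denominator excludes them; this asymmetry follows the two
  defining formulas verbatim.

Group-average heatmaps: each heatmap is resampled (bilinear; mask nearest-
neighbor) onto a canonical axis-aligned ellipse frame (semi-axes 150/100 px)
via rotation by the fitted orientation and anisotropic axis scaling, then
averaged pixel-wise. Alignment is for visualization; per-cell metrics use
original coordinates.

A frozen 24-feature battery (version 1.0) summarizes heatmaps across five
categories — Size, Shape, Intensity, Edge, Texture — using region
properties, Canny/Sobel edge statistics, a 32-level gray-level
co-occurrence matrix (distance 1, four directions averaged, background
level excluded) and Shannon entropy.

## 7. Low-resolution simulation

Convolution with a normalized k x k Gaussian kernel, reflect boundary.
Default k = 11; at 50 nm/px the kernel spans 550 nm, more than four times
the ~120 nm effective resolution of the source imaging, merging sub-micron
foci. The kernel sigma follows the frozen convention
`sigma = 0.3*((k-1)/2 - 1) + 0.8` (sigma = 2.0 at k = 11) so results never
depend on a library default. On dense fixtures blurring strictly reduces
the puncta count and suppresses detection of radius <= 2 px puncta by more
than half.

## 8. Group statistics

Per-feature two-sample Student's t-tests (equal-variance by default; Welch
via `equal_var=False`), with degenerate cases defined explicitly: identical
zero-variance groups give `t = 0, p = 1`; zero variance with unequal means
reports the 0-limit (`t = +-inf, p = 0`) with a warning; groups with fewer
than two values are skipped with a warning. Category-level summaries report
the fraction of features with raw `p < 1e-2` (no multiple-testing
correction; the mean fraction on null data is within binomial error of 1%).
Box-plot IQR trimming (1.5 IQR fences, single pass, quartiles by linear
interpolation) exists for visualization only — the comparison functions
take no trimming parameter, so statistics are always computed on untrimmed
data.

## 9. Synthetic nucleus generator

An elliptical nucleus (semi-axes drawn uniformly from configured ranges,
orientation uniform in `[0, pi)`) on a square canvas; puncta are isotropic
2D Gaussians with `sigma = radius/2` (mimicking PSF-convolved foci), placed
by drawing a zone from the configured five-zone weights and a position
area-uniformly within that zone (rejection sampling enforces an optional
minimum separation). A fraction `rho` of channel-2 puncta is copied from
channel-1 positions with Gaussian jitter; with zero jitter the coincident
fraction equals `rho` exactly. Puncta counts are dispersed by a Fano
factor: 0 = fixed count, 1 = Poisson, > 1 = negative binomial. The DNA
channel is a filled ellipse with limb darkening. Noise is additive Gaussian
(optionally Poisson). All randomness flows from a single seed through
spawned `SeedSequence` streams, so every output is reproducible.

The generator is a phantom for validating the measurement pipeline, not a
biophysical model: it does not simulate chromatin structure, optical
aberrations, depth effects, or camera noise models beyond the two offered.

### Preset study conditions

* `recovery_config()` — 600-px crop, 50 homogeneous puncta per marker at
  SNR 5 (peak 1000, noise sigma 200), radii 2-5 px, separation >= 8 px.
* `desk_base_config(128)` / `desk_separable_config(128)` — desk-scale class
  pair for classifier experiments; class 1 doubles puncta count and peak
  intensity.
* `desk_quadrant_configs(128, q)` — class pair differing only by 20 extra
  puncta in ellipse quadrant `q` (orientation pinned to 0), used to score
  Score-CAM localization against the known signal location.
* `dense_lowres_config(300)` — dense many-foci fixture with radii 1.5-3 px
  for resolution-degradation experiments.

Desk-scale problem sizes (128-px crops, 200 nuclei per class, 20 epochs,
batch 32) are this package's own choice so the full validation battery runs
in minutes on one CPU; they are not the scale at which the underlying
method would be applied to real data (600-px crops, hundreds of epochs).
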