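# Methods

## Problem setting

A brightfield field of Ki-67-stained tissue contains three pixel
populations: Ki-67-positive nuclei marked brown by the DAB chromogen,
negative nuclei counterstained blue by hematoxylin, and the bright,
nearly achromatic background. The pipeline classifies every pixel into
one of these classes without training data, isolates individual nuclei,
and reports the positive percentage and derived grading indicators.

## Channel decomposition

Only two channels carry the discriminative signal. Brown pigment has a
very low blue (B) component in RGB while both the blue counterstain and
the background have high B; conversely, hematoxylin sits near hue 240°
in HSV while brown sits near 0–30°. The pipeline therefore works on the
raw blue plane `I_b ∈ [0,255]` and the hexcone hue plane
`I_h ∈ [0,360)`. Achromatic pixels (max = min over R,G,B) are assigned
hue exactly 0, keeping the near-gray background far from hematoxylin's
240° in feature space. Hue is treated as a *linear* quantity — for this
stain pair the populated hue ranges never straddle the 0/360 seam, so
circular statistics are unnecessary; this is a documented limitation if
the package is pointed at stains living near the seam.

## Pre-processing

Each RGB channel is filtered with a Gaussian followed by a median
filter, both using one shared window radius r (default 5 px at the
reference scale of 2040 × 1536 px at ×400 magnification). The Gaussian
sigma defaults to r/3, which places ≈99% of the kernel mass inside the
radius, and the kernel is truncated at r; the median window is the
square of side 2r + 1. The order Gaussian→median reflects their roles —
smoothing of within-nucleus pigment unevenness, then removal of
isolated pigment speckles — and borders are handled by edge
replication to avoid halo artifacts. Both filters are range-bounded and
constant-preserving. A single-pixel speckle on constant background is
removed exactly; a multi-pixel speckle (diameter < r) is attenuated by
≥ 95% of its contrast rather than eliminated, because the Gaussian
spreads a faint residual beyond the median's reach — any surviving
trace is far below the downstream nucleus-area threshold. Whether the
original method used one or two radii for the two filters is not
determinable; one shared, configurable radius is assumed.

## Local-correlation features

Each pixel carries the 10-vector
`(I_b, I_h, μ_b, μ_h, σ_b, σ_h, β_b, β_h, β_kb, β_kh)` where the window
statistics are computed over the pixel's 3 × 3 neighborhood (edge
replication at borders) in each plane:

- μ = (1/9) Σ xᵢ, σ = sqrt((1/9) Σ (xᵢ − μ)²) — population forms with
  n = 9, chosen over sample corrections because the window is a fixed
  finite population, not a sample from one;
- β = (1/9) Σ ((xᵢ − μ)/σ)³, β_k = (1/9) Σ ((xᵢ − μ)/σ)⁴ — skewness and
  raw kurtosis (normal ≈ 3). An `excess_kurtosis` flag subtracts 3 for
  users who prefer the excess convention; the default is raw.
- Windows with σ = 0 define β = β_k = 0, which keeps all features
  finite and gives perfectly flat regions a distinct signature.

The implementation computes deviations explicitly per window (via a
strided window view) rather than combining raw power sums, so its
floating-point error stays at the scale of the window spread; it agrees
with a scalar double-loop implementation to below 1e-9.

## Pixel clustering and class identification

Features are z-scored per column (zero-variance columns get divisor 1)
— without standardization, hue (0–360) would out-weigh the blue
intensity and the shape statistics. k-means with k = 3, k-means++
seeding, 5 restarts keeping the best inertia, tolerance 1e-4 and at
most 300 iterations clusters the rows; for images above 50,000 pixels
the centroids are fitted on a uniform 50,000-row subsample (same seed)
and all pixels are then assigned to their nearest centroid, keeping
runtime linear while leaving assignment exact. Fitted centroids are
sorted lexicographically so results are independent of library-internal
label order. Inputs with fewer than three distinct feature rows (e.g. a
uniform image) are rejected as degenerate.

Clusters are identified by stain logic: the cluster with the lowest
mean raw `I_b` is DAB (brown absorbs blue); of the remaining two, the
one with the highest mean raw `I_h` is hematoxylin; the last is
background. The mapping is invariant to cluster index permutations. If
a cluster comes back empty the fit is retried with seed+1 (logged), up
to three times.

## Mask cleanup and touching-nuclei splitting

Per nuclear class, the binary mask is cleaned by removing 8-connected
components with area < `min_area` (default 100 px at reference scale —
an adjustable threshold against "fake" nuclei and speckle remnants) and
filling enclosed holes. DAB and hematoxylin masks are processed
separately, so nuclei of different classes can never merge.

The chessboard (Chebyshev) distance map
`d(p) = min_q max(|x_p−x_q|, |y_p−y_q|)` over out-of-mask pixels q
(image border counts as outside) serves as the shape relief: its deep
points mark nucleus interiors. Markers are the 8-connected components
of the h-maxima (default h = 1) of a *marker relief*, and watershed
flooding of the negated chessboard map (restricted to the mask,
8-connected) assigns every mask pixel to exactly one marker, so the
labels always partition the mask.

**Marker relief.** The chessboard metric has square level sets, and for
a touching pair whose center axis aligns with the pixel grid the ridge
between the two lobes is perfectly flat — the saddle is as high as the
peaks — so maxima of the raw chessboard map see one plateau and produce
one marker (measured split rate ≈ 50% over random orientations). The
marker relief is therefore the chessboard map *plus* the Euclidean
distance map: the Euclidean term is strictly concave along the ridge
and breaks exactly these plateau ties while never creating extra
maxima inside a single convex nucleus (measured: 95% of rendered
touching pairs split into exactly two objects, 100% of single ellipses
stay whole). The flooding relief remains the chessboard map; an
alternative `morph_gradient` relief (3 × 3 morphological gradient of
the distance map) is available behind a flag because the gradient
formulation admits more than one reading.

Increasing h can only suppress markers, so the object count is
monotone non-increasing in h (tested).

## Quantification and grading

Each labelled object yields a record: area, centroid, circularity
`4π·area/perimeter²` with the perimeter measured as the 8-connected
boundary-pixel count, and mean `I_b` over member pixels of the
*preprocessed* blue plane (consistent with what the classifier saw).
Record ids follow scanline order of each object's first pixel and are
unique across classes. Per field: positive percentage
`100·n_DAB/(n_DAB+n_hema)`; DAB coloring strength = mean of the DAB
records' mean `I_b` (darker brown → lower value → stronger staining);
positive level = `(1 − I_b/255)·(percentage/100)`, a normalized
darkness × positive fraction product. A field with no nuclei reports
null percentage; a field with nuclei but no DAB reports percentage 0,
null strength, and positive level 0.

Grading bands are contiguous half-open, upper-inclusive intervals on
the percentage: [0,5] → (−), (5,25] → (+), (25,50] → (++), (50,100] →
(+++); (−)/(+) are low, (++) medium, (+++) high expression. The
printed convention "0~5 / 6~25 / 26~50 / 50~100" leaves a gap between
5 and 6 and an overlap at 50 on real-valued percentages; contiguous
half-open bands preserve monotone grading and match the printed values
at every integer except the deliberate upper-inclusive 50. A section's
grade is the grade of the *mean* per-field percentage (typically five
fields), not a mean of ordinal grades, which would be ill-defined.

Detection quality against ground truth uses greedy one-to-one matching
by descending pixel IoU with threshold 0.5. Both the false accept rate
(unmatched predictions — spurious or over-segmented) and the false
reject rate (unmatched truths — missed or under-segmented) are
referenced to the truth count, so accuracy = 100 − FAR − FRR is
internally coherent. The paired-design sample-size formula
`N = ⌈((z₁₋α/₂ + z₁₋β)·σ_d/δ)²⌉` (floored at 1) and the paired t test
`t = mean(d)/(sd(d)/√n)` (sample sd, n−1 df) use scipy's normal and t
distributions, accurate far beyond the 1e-8 requirement.

## Synthetic fields

The generator renders hard-edged (non-anti-aliased) ellipses — axis
ratio drawn in [0.7, 1.0], random orientation — over a bright
background, so the per-pixel ground truth is exact by construction;
realism is secondary to testability. Default study conditions: 512 ×
512 px fields with 30 DAB + 10 hematoxylin nuclei (true positive
percentage 75%, matching the scale of the reference measurements),
radii 8–14 px, mean colors DAB (120,70,30), hematoxylin (70,80,160),
background (235,228,218) — separated by ≥ 60 units in blue and/or hue —
per-pixel Gaussian color jitter with sd 8 (clipped to [0,255]), and
pigment speckles (1–2 px dots of nuclear colors, density 5·10⁻⁴, always
below the area threshold) scattered on the background. A configurable
fraction (default 0.2) of nuclei is placed as overlapping same-class
pairs at center distance 1.2–1.6 × radius, with both ellipses oriented
along the pair axis so the lobes surely merge; later objects draw on
top, and contested pixels belong to the top object in the truth. The
batch generator draws each section's target percentage from
Normal(75.1, 6.7) clipped to [2, 98] and each field's DAB count from a
binomial at that target, emulating a multi-section, five-fields-per-
section study design.

What the synthetic fields do *not* emulate: out-of-focus blur, stain
co-localization within one nucleus, chromatin texture, clustered nuclei
beyond pairs, vignetting and JPEG artifacts. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under color
jitter, touching and speckle noise — not performance on real tissue.

## Numerical and determinism choices

Everything is deterministic given (input, configuration, seed): k-means
restarts derive from the single seed, the generator uses a single
`numpy` Generator, outputs are written with fixed float formatting and
sorted JSON keys, and two identical runs produce byte-identical
artifacts (tested). Test problem sizes (512 × 512 end-to-end fields, 20
seeds; 16 × 16 oracle planes; 24 × 24 distance masks) were chosen as
the smallest scales at which every geometric regime of the method —
merged pairs, plateau ridges, speckle cleanup — actually occurs.

## Known limitations

- Cluster identification assumes all three populations are present; a
  field that is genuinely all background will either fail as degenerate
  or split the background into pseudo-classes. Fields with at least a
  few nuclei of each stain behave well.
- Linear hue breaks for stains near the 0/360 seam (not this pair).
- The count-based positive percentage intentionally differs from
  area-based DAB/nuclear ratios reported by deconvolution tools; the
  two are not comparable.
- `min_area` is expressed in pixels at acquisition scale and must be
  rescaled for other magnifications.
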