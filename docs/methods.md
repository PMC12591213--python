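# Methods

## Scope and model

`ecmorph` quantifies collagen ultrastructure in picrosirius-red-style
birefringence images and summarizes it as an anchored ECM Turnover Score.
Under polarized light, picrosirius-red-stained collagen appears red where
fibers are mature and densely packed (COL1-like) and green where they are
immature (COL3-like). The pipeline treats an RGB image as a Beer–Lambert
transmittance raster: stain amounts are linear in optical density
(OD = −log10(I/I0)), so per-pixel unmixing into stain contributions is a
linear solve against a basis of stain absorbance vectors. The default
basis assigns pure red to the mature stain, pure green to the immature
stain, and grey `[1, 1, 1]` to a residual channel; rows are
unit-normalized before inversion. Negative unmixed amounts (noise or
basis mismatch) are clipped to zero, with the clipped mass recorded.

Whether the original-style analysis unmixed intensities or optical
densities is ambiguous in common practice; we work in OD space, the
standard convention for linear colour deconvolution.

## Per-channel morphometry

Each stain channel passes through:

1. **Adaptive Wiener filter** (default 3×3 window): per pixel, with local
   mean m and variance v and a global noise variance nv estimated as the
   mean of all local variances, the output is
   `m + max(0, v − nv)/v · (x − m)`. Flat regions collapse toward their
   mean; high-variance structure (fiber edges) passes nearly unchanged.
   Borders use edge-inclusive reflection. This is implemented directly
   rather than via `scipy.signal.wiener`, whose zero-padded borders and
   unclamped gain differ from the behaviour described above.
2. **Binarization** at 0.5 of the channel maximum (Otsu available as a
   config option). An all-zero channel yields an empty mask.
3. **Morphological fiber selection**: the union of openings with linear
   structuring elements (default length 5 px) at 0°, 45°, 90° and 135°,
   followed by a diamond closing (default radius 1). Elongated objects
   survive at least one orientation; isolated specks smaller than every
   element vanish.
4. **Skeletonization and graph tracing**: the medial skeleton is traced
   into nodes (8-connected degree ≠ 2 pixels) and segments (maximal
   degree-2 paths, plus isolated cycles). Junction pixels within 2 px
   merge into one node, because thinning splits an X-crossing into
   adjacent T-pixels nondeterministically; stub segments internal to a
   merged junction are discarded. Geodesic length is the arclength of the
   path subsampled every 5 pixels — summing raw 1/√2 pixel steps
   overestimates oblique straight lines by up to ~8 % (staircase bias),
   while the subsampled polyline is unbiased to <1 % and still never
   shorter than the end-to-end chord. Half-width samples the Euclidean
   distance transform of the mask along the path; orientation is the
   axial angle of the chord (principal axis for cycles).

### The 13 channel parameters

Per channel: Brightness (mean OD over the mask), NumberOfFibers
(connected skeleton components), FiberLength, FiberWidth (2 × mean
distance-transform value over skeleton pixels, in µm), Persistence
(length-weighted mean of chord/geodesic straightness per segment),
AngleRandomness (1 − |length-weighted mean resultant| of doubled axial
orientations; 0 = perfectly aligned, 1 = isotropic), Branchpoints
(merged junction nodes), EulerNumber (components − holes, 8-connected
objects/4-connected holes), and area-weighted means of per-component
Extent, Perimeter, Solidity, Eccentricity and EquivalentDiameter.
Concatenating mature then immature channels gives the canonical 26-entry
feature vector. An empty mask yields all zeros.

**FiberLength** is the mean total skeleton length per connected skeleton
object, a per-object measurement in the spirit of region-properties
analysis. We deliberately do not use the mean inter-junction segment
length: in dense fibrotic mats, junctions chop long fibers into short
pieces, which inverts the expected ordering between fibrotic and
homeostatic matrix; the per-object definition recovers it robustly. The
simplified human-sample workflow (`simple_fiber_metrics`) reports the
mean segment length on the merged two-channel mask together with
porosity % = 100 × (non-fiber pixels / total); fiber-area fraction and
porosity/100 sum to 1 exactly by construction.

"Persistence" here means segment straightness and "angle randomness"
the circular variance of axial orientations under the doubled-angle
convention; both are stand-in definitions for informally named
quantities, chosen as the field's most common readings.

## Synthetic fiber fields

The generator emulates three ECM states with one preset each
(rate = expected fibers per 256×256 µm field; lengths/widths log-normal,
given as median and log-σ; orientations von Mises on doubled angles
about the stretch axis):

| preset | rate | length (µm) | width (µm) | κ | p_red | fragments | waviness |
|---|---|---|---|---|---|---|---|
| control | 60 | 40, σ=0.4 | 3.0, σ=0.2 | 0.5 | 0.70 | 1 | 0.08 |
| deposition | 90 | 80, σ=0.4 | 5.0, σ=0.2 | 4.0 | 0.85 | 1 | 0.04 |
| degradation | 50 | 15, σ=0.4 | 2.5, σ=0.2 | 0.3 | 0.50 | 3 | 0.12 |

Only the orderings are biologically anchored — fibrotic deposition means
longer, thicker, more aligned, red-dominant fibers; degradation means
sparser, shorter, fragmented, disorganized fibers with more immature
signal. The absolute values are this package's choice of a realistic
regime with comfortable contrast. Gaussian OD noise (σ = 0.02) is shared
by all presets. The default field is 512×512 px at 0.5 µm/px.

Fibers are rendered as constant-width anti-aliased strokes along one
sinusoidal bend (amplitude = waviness × length, polyline rescaled so the
arclength equals the nominal contour length); fragmented fibers lose 25 %
of each piece at the breaks. Strokes accumulate by maximum into the OD
plane of their stain class (a mask-like, not additive, overlap model),
then mix through the stain basis into RGB transmittance. Coverage at
half-peak OD defines the ground-truth porosity and mature-area fraction.

What the generator does **not** emulate: polarization physics and hue
gradation within a fiber, cellular context, uneven illumination, and
section artefacts. Passing tests therefore demonstrate correctness of
the measurement chain and the scoring machinery on controlled geometry,
not performance on real histology.

## Turnover scoring model

Calibration uses only the two anchor groups: non-stretched control
(label 0) and fibrosis (label 1), the gold standard of deposited
collagen. Features are z-scored with calibration-set statistics only (no
leakage into scored test groups); zero-variance columns are dropped with
a warning. Feature selection runs a coordinate-descent LASSO path over
100 penalties log-spaced four decades down from λmax = max|Xᵀy|/n, with
seeded 10-fold cross-validation and the one-standard-error rule (the
conventional choice of the usual CV-LASSO tooling). The selected
features then enter an ordinary least-squares fit of the anchor labels;
collinear columns are dropped before the solve. Scores are unbounded:
≈0 homeostatic, ≈1 fibrotic deposition, negative = net degradation
(degradation-preset images score below control by construction of the
morphology, not by any constraint in the fit). λ = 0 is solved by exact
least squares, since coordinate descent is undefined there.

The UMAP embedding (15 neighbours, min-dist 0.1, seeded) is a QC
visualization only; nothing downstream consumes it.

## Expansion index

The expander is modelled as a hemisphere (V = (2/3)πr³, A = 2πr²), so
skin area scales as V^(2/3). The theoretical index is
T(d) = (V(d)/V(4))^(2/3) under the default inflation protocol (0.6 mL at
day 0, 0.3 mL every 4 days, capped at a 3.0 mL total; the cap reconciles
the stated increment with the stated total, since the final injection
day is a protocol detail we leave open). The empirical index uses hair
follicle density α (per mm²): follicles neither form nor vanish, so
E(d) = α(4)/α(d) tracks realized area growth. Both are exactly 1 at the
reference day and invariant to uniform rescaling of volumes or
densities. Decoupling — regenerative exhaustion — is the smallest
observed day from which E < (1 − δ)·T persists through the end of the
series (δ = 0.10 by default; the deviation is described qualitatively in
the source context, so the tolerance is ours). Detection is monotone in
δ: a larger tolerance never yields an earlier day.

## Problem sizes and numerical choices

The validation experiments use 30 images per calibration group at the
default 512×512 field, 11 gradient steps × 5 images, and 50 single-fiber
replicates on 256×256 fields — sizes at which every reported property is
stable across seeds while the whole suite stays cheap to re-run. All
randomness flows from `numpy.random.SeedSequence` children of one seed;
images are bit-identical under a fixed seed. Transmittance is floored at
1/65536 of the white point before the log (16-bit quantum), the white
point defaults to the per-channel 99th percentile, and a stain basis
with condition number above 1e8 after normalization is rejected as
degenerate.

## Known limitations

- Width estimates via the distance transform are biased low by ~half a
  pixel per side on very thin (≤2 px) fibers.
- The junction-merge radius (2 px) can fuse genuinely distinct
  branchpoints in very dense meshes, undercounting them.
- Scores are calibrated per experiment; transferring a model across
  imaging setups requires re-anchoring with control and fibrosis groups
  measured under the same conditions.
- The overlap-by-maximum rendering means crossing fibers do not add OD,
  so synthetic crossings are darker than a physical double layer would
  be.
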