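# Methods

## The measurement model

A field is a set of co-registered 2-D intensity rasters (gfp, mcherry,
optional lamp1 and dapi) at a fixed lateral scale (default 9.7 px/µm,
coordinates 0-based, row-major, origin top-left). The tandem-reporter logic
is: healthy mitochondria emit in both gfp and mcherry; mitochondria inside
acidic lysosomes emit in mcherry only. Mitophagic flux is read out as the
count of mCherry-only particles divided by the number of cells in the
field; cells are counted as DAPI nuclei (Otsu threshold, two binary-opening
passes, minimum nucleus area 20 µm²) unless the caller supplies an explicit
count.

## Pre-processing operators

Applied per channel, in order, on float copies (integer quantization only
at write time):

1. **Rolling-ball background subtraction**, radius 10 px. The background is
   the grayscale opening of the intensity surface by a ball
   (`skimage.restoration.rolling_ball`); subtraction is clamped at 0. The
   operator is exactly invariant to constant offsets.
2. **Normalized unsharp mask**: `(img − w·G_σ(img)) / (1 − w)` with σ = 1 px
   and w = 0.6; w < 1 is enforced (the normalization diverges at 1).
   Overshoot above the input maximum is kept — it is the operator's point —
   while negatives clamp to 0.
3. **CLAHE**, block 127 px, 256 bins, max slope 3.0. The image is split
   into ⌈dim/block⌉ near-equal tiles per axis; each tile's histogram (on the
   shared global bin grid) is clipped at `slope · n_tile / bins` with the
   excess redistributed uniformly, and per-pixel output is bilinearly
   interpolated between the four surrounding tile mappings. This
   slope-parametrized form is implemented in-package because the common
   library CLAHE exposes a normalized clip limit rather than a maximum
   slope; in the single-tile unclipped limit it reduces to global histogram
   equalization (tested against that closed form).
4. **Median filter** over a pixel-center disc of radius 2 px, borders by
   edge replication.

All four are deterministic and shape-preserving; constant rasters come out
(near-)constant, and a constant field ends near zero after the chain
(background removal dominates).

## Pixel classification

A random forest (default 200 trees, √d features per split, fixed seed)
over a fixed 10-feature bank per input channel: raw intensity, Gaussian
blurs at σ ∈ {1, 2, 4, 8}, the three adjacent difference-of-Gaussians,
gradient magnitude and Laplacian (both at σ = 1). The red-puncta model uses
gfp *and* mcherry so that "mCherry-positive, GFP-negative" is learnable;
the mitochondria model uses gfp alone. Probability maps are thresholded at
an inclusive lower bound (default 0.31, unbounded above); mask polarity is
normalized so that objects are the minority (foreground) phase.

Training sets may come from brush annotations (x, y, class CSV) on real
data or from a synthetic scene's ground-truth masks. Scene-derived sets
oversample three decision-critical strata in addition to uniform per-class
samples: the 3-px background rim around objects and the 2-px inner edge of
red-only and healthy objects. PSF blurring gives these pixels intermediate
intensities that uniform sampling rarely covers; without them the forest
fragments object borders into spurious 1–4 px "mitophagy" components.

## Morphometry

Objects are 8-connected components (8-connectivity keeps thin diagonal
tubules whole); components below the minimum area (0.3 µm² for the
mitochondria channel, none for red puncta) are removed, survivors
renumbered in raster order. Each object gets 32 descriptors in a fixed
column order. Conventions chosen where the descriptor names do not pin down
formulas:

- **Area** = pixel count / s²; **perimeter** by the 4-direction Crofton
  estimator. The chain-length estimator (edge 1, diagonal √2) biases the
  circularity of a rasterized disc down to ≈ 0.95 and a regular hexagon's
  shape factor up by 3 %; Crofton keeps both within ~1–3 % of the analytic
  values and is used throughout. `circularity = min(4πA/P², 1)`;
  `thinness_ratio` is the uncapped value.
- **Ellipse measures** from second central moments (major, minor,
  orientation θ); degenerate (single-pixel/collinear) objects fall back to
  the area-equivalent disc. `aspect_ratio = major/minor`,
  `round = 4A/(π·major²)`, `roundness_corr_ar = minor/major`,
  `compactness = √(4A/π)/major`, `elongation = 1 − minor/major`.
- **Feret measures** by rotating calipers over the convex hull of pixel
  centers plus 1 px caliper compensation for the unit-square pixel
  footprint (a single pixel then measures exactly 1 px in every direction;
  a 10 × 40 px rectangle's Feret is its corner-to-corner diagonal to
  within 0.25 px). `feret_ar` and `ar_feret` are synonyms (both
  Feret/MinFeret), so the effective descriptor rank is 31 while the column
  count stays 32 — the column metadata flags this.
- **Solidity** = A over the pixel-center hull polygon area, clamped at 1:
  exact for convex digital shapes, whereas corner-point or rasterized hulls
  over-count the boundary band of smooth blobs by 3–5 %. **Convexity** =
  corner-hull perimeter / P, clamped at 1.
- **Angles** (`feret_angle`, θ) in degrees from the image x-axis in
  [0, 180); `*_0_90` variants folded into [0, 90];
  `circ_to_ellipse_tilt = |feret_angle − θ|` folded likewise.
- **Equivalent diameters**: area-equivalent `√(4A/π)`; perimeter-equivalent
  `P/π`; spherical-equivalent `(major·minor²)^{1/3}` (sphere of equal
  volume to the spheroid of revolution about the major axis);
  `interfacial_density = P/A`.
- **Hexagonal family**: side `a = √(2A/(3√3))` (regular hexagon of equal
  area), perimeter 6a, shape factor `P/6a`, its reciprocal, and
  `hexagonality = min(6a/P, 1)`.

## Morphology classification

Four classes — network, unbranched, swollen, punctate — in that canonical
order (ties in the probability argmax resolve toward the earlier class).
Training mirrors the reference protocol: stratified 80/20 split (per-class
ceiling rounding, deterministic under seed), 25 bootstrap-resampling
iterations scoring mtry over {2, 6, 16, 32} by out-of-bootstrap accuracy,
then a final 500-tree forest with mtry = 2. Tuning fits use 100-tree
forests — the resampling search needs rank information, not converged
vote shares — and the final fit always honors the configured values, so
the configured final-model shape is reproduced regardless of the search
outcome. The packaged `hand_label_schema.json` records the per-class label
counts (236/851/458/797, total 2342) of the hand-labeled corpus this
design targets, as the reference schema for labeled input tables.

## Quantification endpoints

- Red puncta are counted with no size filter (every above-threshold
  particle counts) and normalized per cell. LAMP1 particles take the same
  threshold-and-count path (Otsu on the processed lamp1 channel).
- Pearson's coefficient is computed over the whole field by default (an
  ROI may be given); zero-variance inputs raise a distinct
  `UndefinedStatisticError` rather than returning a number.
- Mander's M1/M2 use per-channel Otsu thresholds by default; explicit
  thresholds give the raw variants. Zero above-threshold signal is again a
  distinct error, not 0.
- Per-class mitophagy fraction = red-only\_c / (red-only\_c + healthy\_c).
  The printed counting rules differ between the two paths (no size filter
  for red puncta, 0.3 µm² for mitochondria); normalizing one by the other
  would inflate the punctate fraction because only the denominator loses
  small objects. The fraction therefore counts both paths without a size
  filter, while the 0.3 µm² filter is retained for the per-class object and
  area summaries. Classes with zero denominator report "undefined", never
  0.

## Synthetic scenes

The generator emulates the statistical structure of stressed primary
neuron fields, not their appearance. Defaults: 512 px fields at 9.7 px/µm,
4 nuclei (8 µm discs) defining cells, 60 objects drawn from the class
mixture network 0.1 / unbranched 0.3 / swollen 0.1 / punctate 0.5 (the
punctate-heavy composition reported for neurons under stress). Archetypes:
networks are 3–6 branch Bézier skeletons (2–5 µm branches) dilated to
0.4 µm width; unbranched are 2–8 µm curved tubules of the same width;
swollen are 1.6–2.5 µm ellipses; punctate are 0.3–0.9 µm discs (sequestered
mitochondria are small, < 1 µm). Mitophagy-flagged objects render in
mcherry only, at their class archetype's size — so "red-only objects are
mostly punctate" is a measured outcome, not a construction artifact — and
each is co-rendered with a 1.2 µm LAMP1 disc. Flags are drawn per class
(defaults 0.02/0.05/0.2/0.5), or an exact flagged count can be requested;
timecourses translate an overall programmed rate into per-class
probabilities through fixed punctate-preferring weights
(0.1/0.2/0.5/1.0) normalized so the mixture-expected fraction equals the
rate. The camera model is Gaussian PSF (σ = 1 px), linear background
gradient, Poisson shot noise at a configurable photon scale and Gaussian
read noise. Objects are placed with a ≥ 6 px mutual gap so ground-truth
objects stay resolvable after blurring — the property that makes exact
count recovery a meaningful end-to-end check.

What the generator does *not* emulate: cytoskeleton-constrained object
placement and within-cell crowding, out-of-focus light and 3-D sectioning,
chromatic shift, photobleaching, or autofluorescence. Passing tests
therefore demonstrate that the measurement chain is correct and unbiased
under the stated imaging model, not that segmentation accuracy transfers
to arbitrary real acquisitions; on real data the pixel models should be
retrained from brush annotations.

## Problem sizes and numerical choices

Tests and the acceptance script run on 384–448 px scenes with 40–60
objects and 3 cells, a 2000-row descriptor corpus for classifier
evaluation, and 3–5 seed replicates per condition — sizes chosen so the
full suite exercises every stage end to end at desk scale. Degenerate
inputs are defined, not accidental: empty masks give empty tables with
full headers; single-pixel objects get finite descriptors via the
area-equivalent-disc fallback; probability ties break toward the earlier
class; all randomness flows from explicit integer seeds and every
generator is bit-reproducible under its seed.

## Known limitations

- Equivalence with the original interactive toolchain's segmentations
  cannot be claimed (its feature bank, annotations and trained models are
  not recoverable); the package demonstrates functional equivalence on
  synthetic ground truth instead.
- The Crofton perimeter is accurate for smooth convex shapes but, like all
  digital estimators, is biased on very thin (1–2 px) structures; ratios
  built on it (convexity, hexagonality) are clamped at their theoretical
  bounds.
- Mander's coefficients depend on the thresholding convention; both
  Otsu-thresholded (default) and explicit-threshold variants are exposed.
- The 89 % punctate share among red-only objects reported for real neurons
  is a biological quantity; the synthetic analog depends on the programmed
  mitophagy preference and is reported, not asserted.
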