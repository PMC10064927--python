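# Methods

## Masks, classes and coordinates

Segmentation masks are single-channel rasters whose gray levels encode
three tissue classes.  The class set is fixed (islet, exocrine,
background); the gray levels are a convention of this package —
255 = islet, 128 = exocrine, 0 = background by default, configurable per
call — because mask-producing tools vary.  Any gray level outside the
declared encoding is an error rather than a guess: a silently misread
level would corrupt every downstream area and volume.

All coordinates are 0-based `(row, col)` with the origin at the top-left
and y increasing downward.  Physical pixel sizes are read from a CSV
(`image,pixel_size_um_per_px`) and sanity-bounded to 0.1–20 µm/px; typical
islet-counting micrographs sit between roughly 1.4 and 3.8 µm/px, which is
also what the synthetic generator draws from.

Islet objects are maximal connected components of islet-class pixels.
The default connectivity is 8, the usual choice for blob-like biological
objects; 4 is available because diagonally touching islets are exactly the
ambiguous case a reviewer may want separated.

## Morphometry

The equivalent-circle diameter of an islet of area `A_px` pixels is
`d = 2·√(A_px·s²/π)` µm at pixel size `s`.  Volumes use the continuous
spherical model `V = (d/150)³` IE, i.e. the volume of a d-µm sphere in
units of the 150 µm reference sphere.  A continuous model keeps relative
errors and CVs of contour-derived volumes well defined; the classical
stepwise per-category IEQ factor table (0.167 IE for 50–100 µm, … ,
15.833 IE for ≥350 µm) is available as `model="stepwise"` for
manual-count emulation.

Size categories are half-open 50 µm bins closed at the lower edge and
labeled by it, so a 50.0 µm islet falls in category 50 and a 400 µm islet
is representable.  The size threshold of the selection engine excludes
small islets from *marking* only — they remain in morphometry summaries.

## Boundary extraction and rendering

The boundary of a component is its *inner* boundary under the 4-neighbor
criterion: a pixel belongs to the boundary iff it is in the component and
at least one 4-neighbor (or the image edge) is not.  This reproduces a
closed 1-px edge made of object pixels, which is what a contour overlay
on the original image needs.  Overlay thickness t recolors the boundary
dilated by a disc of radius `(t−1)//2`; no pixel outside that set is
touched.  Arrow glyphs are purely presentational (default 40 px shaft at
45°, tip 6 px short of the islet centroid) and bit-deterministic.

## The selection engine

A validation review set is drawn by one seeded generator in a fixed
order: first a uniform sample of `n_images` images without replacement
(kept in input order so per-set numbering is stable), then, per image,
islets with equivalent diameter ≥ threshold (default 50 µm) grouped by
size category and drawn round-robin over the occupied categories in
ascending order, uniformly without replacement within a category, until
the per-image quota (default 7) is reached or eligibility is exhausted.
Round-robin is the simplest rule that guarantees every occupied category
is represented whenever the quota allows; ascending order makes the draw
reproducible.  Manifests therefore satisfy, by construction: bit-identical
output under a fixed seed, no marked islet below threshold, and full
category coverage when `quota ≥ #occupied categories`.

Inquiry sets bypass the engine: a hand-picked, order-preserving list of
islet labels on a single image, with duplicates and unknown labels
rejected.

## Tracing accuracy and volume agreement

Template and expert lines are polylines in real coordinates, rasterized
to 8-connected 1-px chains (Bresenham per segment, closed lines joining
last to first).  Both chains are trimmed to the ground-truth islet
component by per-pixel membership — a separation line is meaningful only
within the islet mass — and compared by the mean nearest-neighbour
Euclidean distance.  The symmetric form (average of both directed means)
is the default: the notion of "corresponding points" between two freehand
lines is otherwise ill-defined, and the symmetric form is zero exactly on
identity and has no direction bias.  The directed expert→template form is
available; for a straight template it estimates the mean absolute
perpendicular displacement E|N(0,σ)| of the tracing noise, which is what
the calibration property tests use.  A tracing is *good* if the mean
distance is strictly below 2 px; a tracing whose trim is empty (it never
entered the islet) is flagged and scored poor with an infinite distance.

Closed contours are compared by volume instead: the polygon is filled by
scan conversion (even-odd rule, no self-intersection validation — flagged
as a known limitation), the pixel count converted to an IE volume, and
agreement expressed as `RE = |V_e − V_t|/V_t` and the normalized volume
`V_e/V_t`.  The pixel-fill area was checked against the analytic shoelace
area and converges to it as contours grow (≤2 % volume error for a 75 px
radius disc, ≤1 % at ≥150 px).  Degenerate zero-area contours yield 0 IE
with a warning.

Repeatability of replicate tracings is the coefficient of variation of
the replicate volumes, using the sample (n−1) standard deviation
(replicates are a sample; `ddof=0` is available).  A replicate set
containing a zero volume is *excluded* rather than scored: a zero means
the object was not recognised at all, and a CV over such a set would
measure recognition failure, not drawing repeatability.

## Opinions and consensus

An islet opinion is True / False / skipped; only False opinions may carry
graphical edits, and an opinion is counted as *graphical* iff its edit
list is nonempty.  "Not an islet" is an edit kind with no geometry but
still counts as a graphical opinion — it is a drawing-level judgement.
Separation lines must be open, full redraws and missing contours closed.
Consensus reports render each disputed islet's crop with the ground-truth
boundary in blue and all expert edits in white (both configurable), with
expert identities replaced by stable anonymous labels e1..eN in order of
first appearance.

## SUS scoring

Odd items contribute `item−1`, even items `5−item`; the sum × 2.5 gives
0–100.  Marks use the Sauro–Lewis curved grading scale with bins closed
at their lower bound (A+ ≥ 84.1, …, F < 51.7); a 0.1-step sweep test
verifies the bins partition [0, 100] monotonically.  The cohort mean is
reported truncated (not rounded) to one decimal — reporting aggregates at
the precision of the individual scores without overstating them — and the
exact mean is returned alongside.

## The synthetic generator

Scenes emulate dithizone-stained micrographs at the level the metrics
need: islets are discs or "blobs" (discs perturbed by order-2..4 radial
harmonics, rescaled so the enclosed area — hence the equivalent
diameter — is preserved), placed without overlap on a light background
with small exocrine distractor blobs; embedded islets get a 5 px exocrine
annulus so their boundary is visually ambiguous.  Default layouts span
50–400 µm diameters with a right-skewed size distribution (squared-uniform
draw), 6–14 islets per 512² scene, and pixel sizes uniform in
1.41–3.77 µm/px.  Masks are exact by construction; the RGB rendering is
cosmetic (flat class colors plus mild Gaussian brightness jitter).

Simulated experts displace each template vertex along the local normal by
N(0, σ²) pixels, optionally followed by a 3-point moving average that
mimics the low-pass character of finger or stylus drawing.  Template
polylines are resampled to ~2 px vertex spacing so per-vertex jitter acts
as approximately independent pixel-scale noise; with smoothing off, the
directed mean distance to a straight template recovers E|N(0,σ)| = σ√(2/π)
within 25 % for σ ≥ 1 (the symmetric metric reads systematically lower at
large σ because the template→expert direction can shortcut across jagged
excursions — measured ratios drop to ≈0.6 at σ = 4).  Smoothing shrinks
the effective σ by about √3, which is why calibration tests disable it.

One master seed fans out to per-stage generators through fixed offsets
(`np.random.default_rng([seed, stage, …])`), so every stage is
independently reproducible.

What the generator does **not** emulate: staining variability, focus
gradients, debris, image-to-image illumination differences, and the
*correlated* tremor of real hand drawing (real jitter is not white).
Green tests therefore demonstrate correctness of the measurement chain
and the engine's invariants, not robustness of any segmentation to real
image artifacts — no segmentation is performed here at all; masks are
inputs.

## Problem sizes and numerical choices

Test and acceptance runs use 19-image bundles of 384² px scenes, 9
simulated experts, 15 separation-line templates, 8-image review sets and
triplicate contour tracings — matching the shape of a small multi-center
review round while keeping the full suite in seconds.  Distances use
exact Euclidean nearest neighbours (KD-tree, verified to 1e-9 against an
all-pairs scan); rasterization tolerances quoted above (2 % for discs at
r ≈ 75 px, 10 % for irregular blobs) were set from the geometry of scan
conversion, and verdict and bin edges (2 px, 50 µm, grade bounds) are
compared exactly.

## Known limitations

- Self-intersecting expert contours are filled even-odd without warning.
- Template "length" is reported as trimmed pixel count, not arc length.
- The stepwise IEQ factor table is a fixed convention; centers using
  variant factors must supply their own.
- Zip bundles are extracted to a temporary directory rather than read
  in-place.
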