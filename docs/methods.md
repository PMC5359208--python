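# Methods

## The model

`mcseg` treats microcalcification extraction as two morphological problems.

**Detection** finds *where* lesions are. Microcalcifications are small
(2–20 px at a 50 µm pixel pitch), brighter than their immediate
surroundings, and embedded in a smooth but textured parenchymal background.
Three mechanisms encode this prior:

* the residue detector `T = I − min(γ_S[φ_S(I)], I)` responds only to
  structures that a 3 × 3 opening-of-closing removes, i.e. bright details
  at the scale of the structuring element.  Running it at pyramid levels 2
  and 3 (stride-2 closing–opening pyramid) makes the effective scale 2–4
  times larger without growing the structuring element, so lesions of
  different sizes are caught;
* the extended-maximum stage keeps only plateaus standing at least
  `h = 5` gray levels above their surroundings — a contrast prior.  Its
  support ("bright regions") contains lesions *and* larger bright tissue;
  the chord rule then deletes any region through which a directional chord
  longer than `nPxls = 50` px fits, which no real microcalcification can
  contain;
* cleaning enforces the size prior: component areas must lie in
  `[minPxls, maxPxls] = [10, 70]` px, components may not touch the ROI
  border, and holes are closed.

The map is the OR of per-level reconstructions: the bright-region component
is recovered *in full* whenever a pyramid signal touches it, so the map
component shape comes from the image's own bright plateau, not from the
pyramid's blocky upsampled mask.

**Segmentation** finds *what shape* each lesion has.  The ROI is
closing–opening filtered and inverted, so lesions become dark basins.
Internal markers are the regional minima (8-neighborhood) inside the map;
external markers are the watershed lines of the prepared image itself, a
ridge network that surrounds every basin.  The internal marker is pulled
clear of the dilated external marker so the two never touch.  Imposing the
combined marker as the only minima of the morphological gradient and
flooding it with the immersion watershed yields exactly one basin per
marker component — the standard cure for oversegmentation.  Basins seeded
by an internal marker are the objects; the 0-labeled divide pixels trace
their contours.  Both the basin interiors (`object_mask`) and the divide
pixels (`watershed_lines`) are exposed, so downstream users choose either
convention for "the contour".

An empty detection map yields an empty segmentation result
(`n_objects = 0`) rather than an exception, so batch runs degrade
gracefully.  Note the external marker only exists where the background has
structure: on a perfectly flat synthetic background there are no watershed
lines, and the single marked basin floods the whole frame.

## Parameters

| name      | default | unit  | role |
|-----------|---------|-------|------|
| `diff`    | 21      | gray  | stage-1 clip level; variance below it is discarded |
| `th`      | 4       | gray  | threshold on the pyramid residue (≥ th fires) |
| `h`       | 5       | gray  | required height of a bright plateau above surroundings |
| `n_pxls`  | 50      | px    | longest admissible directional chord through a bright region |
| `min_pxls`| 10      | px    | smallest admissible map component |
| `max_pxls`| 70      | px    | largest admissible map component |
| `tau`     | 0.5     | ratio | truth-area overlap required for a TP match (evaluation) |

The detection defaults are the values established for this method on its
20-ROI training set; the watershed stage has no free parameters.  `tau` has
no counterpart in a radiologist's manual TP/FP/FN calls; 0.5 of the truth
object's area is the common choice in detection evaluation and is exposed
on the command line.

## Evaluation conventions

The four indices are computed from pixel-set cardinalities exactly as
defined (`EF` may exceed 1; all others lie in [0, 1], with
`OV ≤ OF` and `OV ≤ SI` by set algebra).  Object matching is greedy,
one-to-one, by decreasing pixel overlap, with a candidate pair admitted
when the segmented object covers at least `tau` of the truth object's
area.  Unmatched segmented objects are false positives regardless of their
position relative to the ground-truth area; unmatched truth objects are
false negatives.  Reported per-ROI sensitivities are *truncated* (not
rounded) to two decimals — e.g. 2 hits of 3 lesions prints as 0.66 — while
full-precision ratios are stored.

## The phantom generator

The generator emulates the descriptive statistics of real
microcalcification ROIs, not their physics:

* **background** — flat, linear gradient, or a smoothed Gaussian random
  field (40 gray levels of amplitude over the frame).  The field's
  amplitude and correlation length are chosen so the background rise across
  one lesion (a few px) stays well below the `h = 5` dome height; steeper
  fields make a lesion's bright plateau merge with the background's own
  maxima, after which the chord rule deletes it;
* **lesions** — isotropic *flattened* super-Gaussian profiles
  `c · exp(−(r²/2σ²)^p)` with order `p = 2` and peak contrast `c` drawn
  from `contrast_range`.  Calcium deposits are sharply bounded and
  near-uniform in brightness; a pure Gaussian peak (`p = 1`) concentrates
  the top `h` gray levels into only ~4 px per gray level, so a single
  positive noise pixel at the apex shrinks the detector's extended-maximum
  cap below the 10 px area floor and the lesion is deleted by the
  method's own cleaning rule.  The flat-topped profile matches the real
  signal and gives the cap a two-gray-level safety margin.  The truth mask
  is the half-peak support, so `diameter` is the FWHM in px (2–20 px ↔
  0.1–1.0 mm at the fixed 50 µm pitch);
* **spatial pattern** — benign: ≤ 5 lesions spread over the frame;
  malignant: > 5 lesions inside a cluster disk (default radius 80 px ≈ the
  1 cm² concentration area).  Centers are rejection-sampled with a
  separation of 1.2× the summed diameters + 6 px; impossible requests
  raise `PlacementError`;
* **distractors** — optional elongated bright bands (70–110 px long) whose
  chords exceed `n_pxls`, exercising the chord-removal rule;
* **noise** — additive i.i.d. Gaussian, then clipping to [0, 255].

Identical spec + seed gives bit-identical output.  `easy_spec()` fixes the
favourable study conditions used by the recovery tests: 5 lesions of
8.2–9.2 px FWHM (half-peak areas ~53–66 px), contrast 20–24, noise σ = 1,
textured background, no distractors.  These values are derived from the
detector's own geometry: the extended-maximum cap of a lesion must itself
clear the 10 px area floor (analytically ≥ ~17 px for this range, with a
~0.7 discretization factor), while the half-peak truth areas must stay
under the 70 px ceiling.  Noise σ = 1 keeps pixel noise below the margins
the method's `th = 4` and `h = 5` assume — the regime of digitized film
mammograms; at σ ≥ 2 the h-maxima support of a dome fragments and
detection degrades, which the generator can reproduce but the recovery
tests deliberately avoid.

What passing phantom tests show: that the implementation realizes the
method's guarantees (map cleaning invariants, one object per marker
component, full recovery under favourable contrast/noise).  What they do
not show: performance on real parenchyma, where lesion profiles, tissue
texture, film artifacts and expert-tracing variability are all outside the
generator's vocabulary.

## Numerical choices

* Erosion/dilation use edge replication, so flat images are fixed points
  and no phantom responses appear at ROI borders.
* All subtractive arithmetic is carried in wide signed integers and clipped
  to image range only where a uint8 product is required; the gradient is
  never display-scaled.
* Connectivity: 8 for regional minima, component labeling and watershed
  flooding; 4-connected background for hole filling (the standard dual
  pairing).
* The immersion watershed is a direct Vincent–Soille implementation
  (level-synchronous FIFO flooding with explicit 0-labeled divide pixels).
  Plateau ties are broken by raster-scan order within each gray level, so
  results are bit-for-bit reproducible.  On a constant image the result is
  a single basin with no lines.
* Minima imposition follows the standard formulation — reconstruction by
  erosion of `min(img + 1, f_m)` from `f_m` (0 on the marker, a maximal
  sentinel elsewhere) — and guarantees the output's minima coincide with
  the marker components.
* `h`-convexity is the reconstruction residue `img − R^δ(img − h, img)`.
  A constant image is one global maximum plateau, so its residue is `h`
  everywhere, and the global maximum of any image always carries residue
  `h`; callers must not interpret the residue as "prominence" for the
  image's brightest structure.
* Greedy object matching sorts candidates by (overlap desc, labels asc), so
  the result is independent of label permutation.
* Chord removal uses linear structuring elements of length `n_pxls + 1`
  (odd for the default 50), the only reading under which a 50 px object
  survives and the erosion construction is exact.

## Problem sizes

Unit and property tests run on images ≤ 16 × 16 against nested-loop
brute-force oracles (100 random images for the primitive-equivalence
suite).  End-to-end recovery and cleaning guarantees run on 256 × 256
phantoms (10–20 seeds), where one full detect + segment pass takes well
under a second; 512 × 512 runs take ~2.5 s and are exercised once.

## Known limitations

* The detector's minimum component area (10 px) bounds the smallest
  recoverable lesion: sub-0.15 mm calcifications are, by design,
  indistinguishable from noise.
* Lesions sitting on bright elongated structures are deleted together with
  the structure by the chord rule.
* The external marker requires background texture; fully flat synthetic
  backgrounds degenerate (see above).
* TP/FP/FN calls automate a radiologist's judgment with a fixed-overlap
  rule; the two agree only to the extent that `tau` reflects the expert's
  implicit criterion.
* The phantom makes no attempt at breast-density categories, film MTF, or
  anatomically structured texture.
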