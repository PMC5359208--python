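# mcseg — morphological microcalcification detection and watershed segmentation

Microcalcifications — calcium deposits of 0.1–1.0 mm that appear as tiny,
low-contrast bright spots on mammograms — are the primary early indicator of
breast cancer, and the shape and spatial distribution of a cluster help
distinguish benign from malignant disease. `mcseg` implements a two-part
morphological pipeline that extracts individual microcalcification shapes
from 8-bit mammogram regions of interest (ROIs, nominally 512 × 512 px):

1. **Multiscale morphological detection** producing a binary
   microcalcification *map*:
   - clip gray levels below `diff` = 21 (removes dark-region variance),
   - detect bright spots at levels 2 and 3 of a morphological pyramid
     (closing–opening filter + stride-2 sampling per level) with the residue
     detector `T = I − min(γ_S[φ_S(I)], I)` (3 × 3 square `S`), thresholded
     at `Th` = 4 and restored to full size by block replication,
   - keep only bright plateaus standing at least `h` = 5 gray levels above
     their surroundings (support of the h-maxima residue), discarding any
     region through which a horizontal/vertical/diagonal chord longer than
     `nPxls` = 50 px can be drawn,
   - reconstruct the bright regions hit by the pyramid signals, then clean:
     drop border-touching components, keep areas in
     [`minPxls`, `maxPxls`] = [10, 70] px, close holes.
2. **Marker-controlled watershed** recovering per-lesion contours:
   internal markers = regional minima of the closing–opening filtered,
   inverted ROI restricted to the map; external markers = watershed lines of
   that prepared image; minima imposition forces the morphological gradient
   `grad_B(I) = δ_B(I) − ε_B(I)` to have minima only at the markers; the
   final immersion watershed (Vincent–Soille, with explicit divide lines)
   then yields exactly one basin per marker component — no oversegmentation.

Segmentations are scored against expert masks `E` with four pixel-overlap
indices — similarity index `SI = 2|M∩E|/(|M|+|E|)`, overlap fraction
`OF = |M∩E|/|E|`, overlap value `OV = |M∩E|/|M∪E|`, extra fraction
`EF = |M∩Ē|/|E|` — and per-lesion TP/FP/FN counts with
`sensitivity = TP/(TP+FN)`.

A synthetic phantom generator (`mcseg.phantom`) renders ROIs with
pixel-exact ground truth (lesion masks, labels, a ground-truth area) that
reproduce the descriptive statistics of real microcalcifications, so the
whole pipeline is testable without any mammography download.

## Worked example

Generate four favourable phantoms, run detection + segmentation on each and
score against the generated truth:

```bash
mcseg run-all --seed 0 --n-phantoms 4 --size 256 --out demo/
```

```
   roi_id       si       of       ov       ef  tp  fp  fn  fpi  sensitivity
phantom_0 0.897887 0.847176 0.814696 0.039867   5   0   0    0          1.0
phantom_1 0.872531 0.815436 0.773885 0.053691   5   0   0    0          1.0
phantom_2 0.860759 0.804054 0.755556 0.064189   5   0   0    0          1.0
phantom_3 0.890485 0.829431 0.802589 0.033445   5   0   0    0          1.0
```

Each row is one ROI: all five lesions per phantom are found (`tp = 5`,
`sensitivity = 1.0`) with no spurious objects (`fpi = 0`); the segmented
shapes overlap the true lesion masks with Dice ≈ 0.86–0.90 and Jaccard
≈ 0.76–0.81, and the spurious-area fraction `ef` stays below 7 %.
`demo/` additionally holds `per_roi.csv`, `summary.csv` (mean/SD/min/max per
index) and `sensitivity_by_fpi.csv`.

The same pipeline is available per image:

```bash
mcseg phantom --seed 0 --size 256 --out roi/        # synthetic ROI + truth
mcseg detect  roi/image.png --out det/              # microcalcification map
mcseg segment roi/image.png --map det/map.png --out seg/
mcseg eval    seg/objects.png roi/calc_mask.png --gta roi/gta.png --out eval/
```

or from Python:

```python
from mcseg import detection, segmentation, evaluation, phantom

truth = phantom.generate(phantom.easy_spec(seed=0, size=256))
mc_map = detection.detect(truth.image)                  # binary map
result = segmentation.segment(truth.image, mc_map)      # per-lesion shapes
idx = evaluation.overlap_indices(result.object_mask, truth.calc_mask)
```

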