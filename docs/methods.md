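# Methods

This note describes the counting model implemented by `adipocount`, the
parameters it exposes, the synthetic data used to validate it, and the
numerical conventions that make results reproducible to the byte.

## Problem

Mature adipocytes in a membrane-stained histology section appear as bright
convex regions separated by thin dark membrane walls. Counting them and
measuring their size distribution is routine in metabolic studies but slow
and subjective by hand. The task is complicated by three defects of real
slides: uneven illumination (bright center, dark corners), stain debris
("minced membrane" fragments inside cells), and missing dye — gaps in the
membrane that visually merge neighboring cells into one region.

## Pipeline

### 1. Preprocessing (`preprocessing.py`)

RGB input is converted to 8-bit gray with BT.601 luma weights
(0.299, 0.587, 0.114), rounding half up. Two enhanced images are derived:

- **Illumination-corrected image.** A difference-of-Gaussians filter,
  `I * (g2 − g1)`, with truncated normalized Gaussians g1 (σ = 0.5, 3×3
  window) and g2 (σ = 30, window 60 → realized 61×61 so the kernel has a
  center pixel). Both convolutions use reflect padding and are computed as
  two 1-D passes (the truncated kernel is exactly separable). The wide
  Gaussian estimates the illumination field; the difference leaves membrane
  as a positive response. Negative values are clipped and the result scaled
  so its maximum maps to 255. A response that is nowhere positive (up to
  1e−9, absorbing float round-off on constant images) yields all zeros.
- **Equalized image.** Global histogram equalization (empirical-CDF transfer)
  followed by a full-range stretch, so occupied levels span [0, 255] and
  pixel rank order is preserved. Feeds the edge detector.

### 2. Membrane segmentation (`membrane_segmentation.py`)

Two detectors are run and their binary outputs OR-ed:

- **Otsu thresholding** of the illumination-corrected image: exhaustive
  search over all 256 levels maximizing between-class variance; ties take the
  lowest threshold; foreground is `> t`. A constant image is flagged
  degenerate and returns an empty mask with a warning.
- **Canny edges** of the equalized image (σ = 1). Hysteresis thresholds
  default to automatic: high = 90th percentile of the smoothed gradient
  magnitude, low = 0.4 · high.

The union is deliberately over-complete; cleanup follows.

### 3. Cleanup and re-segmentation (`resegmentation.py`)

Membrane components are 8-connected; cell interiors 4-connected. The
complementary pairing prevents interiors leaking through diagonal membrane
junctions.

Cleanup: drop 8-connected membrane components with area < 64 px (debris),
then opening, closing, dilation with a disk of radius 1 each. Interiors are
the filled complement: inverting the mask and filling holes absorbs any
membrane fragment floating inside a cell.

Missing-dye gaps merge k cells into one component. Recovery:

1. Exact Euclidean distance transform of the interior mask.
2. Marker extraction: regional maxima of the h-maxima reconstruction
   `reconstruction(dist − h, dist, method="dilation")` with h = 1. Taking
   maxima on the reconstructed surface (not on `dist`) matters: two peaks
   whose saddle is less than h below them join into one plateau and yield a
   single connected marker, so pixelation noise cannot split a convex cell.
   The distance map of a convex region is concave, hence has one regional
   maximum — clean cells get exactly one seed. A shallow component whose
   peak height is ≤ h is flattened into the background plateau and would
   yield no marker at all; such components are seeded at their deepest pixel
   so nothing is dropped.
3. Marker-controlled watershed of the negated distance map
   (4-connectivity, with watershed lines kept as label 0).
4. Every internal line between a pair of adjacent basins becomes a
   candidate. A candidate with line length L and flanking basin areas
   A1 ≥ A2 is **accepted** as inferred membrane iff

       L < max_length   and   A1 / A2 < max_area_ratio

   (both strict; defaults 50 px and 3). Short lines match the geometry of a
   small stain gap; the area-ratio test rejects lines that would slice a
   lobe off a single large cell.
5. Rejected pairs are merged back with a union-find; accepted lines stay as
   background pixels. Line pixels whose whole (same-parent) neighborhood
   merged into one region are re-attached to it. Labels are renumbered
   1..n in raster order.

All basin-adjacency scans are restricted to the line pixel's own parent
component: interiors of two different parents can touch diagonally, and
without the guard the union-find would merge separate cells.

**Count arithmetic.** With one accepted split per parent, the final count is
exactly (initial 4-connected components) + (accepted lines); this is tested
on simple fixtures. In a parent holding many basins, an accepted pair can
still end up merged when its basins are also joined through a chain of
rejected lines (merging is transitive), so in general the count lies between
the component count and components + accepted.

### 4. Counting and statistics (`cell_counting.py`)

Labeled 4-connected regions below `min_cell_area` (default 30 px) are
removed; optionally cells touching the border are excluded. Per cell the
package reports centroid, area, equivalent-circle diameter `2·sqrt(area/π)`,
and an inclusive bounding box; physical units are attached when
`microns_per_pixel` is set. Manual corrections are supported as edit scripts
(JSON): `add_line` draws a membrane segment of given width, `delete_rect`
erases membrane in a rectangle; edits are validated against the image frame.

### 5. Evaluation (`evaluation.py`)

Count-based scores use GT (ground-truth count), EN (enumerated count) and TP
(true positives):

    P = TP / GT,   R = TP / EN,   F1 = 2PR / (P + R) = 2·TP / (GT + EN).

Note the denominators: this follows the convention of the published
benchmark table the package reproduces, which swaps the usual roles of GT
and EN in precision and recall. F1 is invariant to the swap. Label-map
evaluation matches predicted to true regions greedily by descending pixel
overlap, one-to-one, accepting pairs with IoU ≥ `iou_threshold` (0.5).

## Synthetic data (`synthetic_data.py`)

Ground-truthed fixtures are generated, not stored:

1. Seed points by dart throwing with a minimum spacing (default 24 px,
   35 cells on 256×256).
2. Cells are the Voronoi regions of the seeds (nearest-seed assignment);
   the truth label map is this exact partition.
3. The membrane skeleton (thick inter-region boundaries) is dilated to the
   drawn width (3 px).
4. Degradations, each independently controllable: gap erasure (random runs
   of exponential length along the skeleton, `gap_fraction` of its pixels),
   debris disks inside cells, a radial vignette darkening the corners, and
   per-pixel Gaussian noise. Gray levels ~70 (membrane) on ~215
   (background) are mapped through a brown-stain ramp to RGB.

Fidelity limits: cells are convex polygons (real adipocytes are rounded and
can be slightly concave), membrane width is uniform, debris is circular, and
the vignette is radially symmetric. These are sufficient to exercise every
pipeline stage but do not model tearing, folds, or out-of-focus blur.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the CLI exposes seeds, so outputs are byte-identical across runs.
- Rounding is half-up (`floor(x + 0.5)`) wherever floats become uint8.
- Thresholds are strict (`<`) where documented; ties in Otsu take the lowest
  threshold; labels are always renumbered in raster order.
- Areas are pixel counts; distances are exact Euclidean.

## Limitations

- The area-ratio rule cannot recover a gap between a very large and a very
  small neighbor (ratio ≥ 3), by design.
- Transitive merges can override an accepted split in heavily gapped
  regions (see count arithmetic above).
- The benchmark F1 values embedded in the tests are reproduced from
  published counts; the underlying micrographs are not available, so
  pixel-level replication of that experiment is out of scope.
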