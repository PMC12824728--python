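# Methods

## Input model and conventions

The pipeline operates on per-pixel label masks with the convention
0 = background, 1 = root hair, 2 = root. Coordinates are row-major with the
origin top-left; "tip points down" means the tip has the maximum row index.
All physical quantities are reported in millimetres via a single
calibration constant `conv` (pixels per millimetre, default 102 — a typical
value for a stereomicroscope at low magnification). The spatial unit of
analysis is a window of `resolution` rows of the straightened root (default
20 px ≈ 0.2 mm at the default calibration).

The package assumes one root per image, growing roughly top-to-bottom
(rotations of several tens of degrees, or a full half turn, are corrected
automatically), with the tip inside the field of view and the shoot-ward
end cut by the image border.

## Geometric normalisation

1. **Mask cleanup.** The largest 8-connected root component is kept (ties
   broken by the topmost-then-leftmost pixel), its interior holes filled
   (hairs, being thin and porous, are never hole-filled), and hair
   components kept only if they touch the root dilated by
   `adjacency_radius` (default 5 px). Cleanup never adds foreground outside
   the filled root. A mask with no root pixels or a root below
   `min_root_area` (default 100 px) is rejected with a taxonomised error.

2. **Skeleton and midline.** The root is thinned to one pixel width
   (`skimage.morphology.skeletonize`). Side spurs shorter than a prune
   length are removed by walking from each endpoint to the nearest
   junction; the default prune length adapts to the root's inradius
   (1.5 × max distance-transform value + 5 px) because the medial axis of a
   blunt-ended band forks into legs of about half the root width. Skeleton
   columns are then grouped into row windows of `resolution` px; the median
   column per window, placed at the window-centre row, forms knots through
   which a monotone cubic (PCHIP) is interpolated and evaluated at every
   integer row. The first and last knots are discarded when at least four
   exist: the end windows overlap the medial-axis end forks and bias the
   end tangents, which would otherwise shear the straightening mesh near
   the root ends.

3. **Orientation.** The mask is rotated (nearest-neighbour, padded canvas)
   so the midline's end-to-end vector points down. Which end is the tip is
   decided by hair mass near the two midline endpoints: hairs emerge behind
   the elongation zone, so the tip end carries less hair; ties go to the
   end with the larger row index. After any rotation the skeleton and
   midline are re-estimated.

4. **Straightening.** A piecewise affine warp maps the midline onto a
   vertical line at its mean column. Control points are midline samples
   every `control_spacing` rows (default 50) with lateral companions offset
   perpendicular to the local tangent; destination rows are spaced by
   cumulative arc length, so the root keeps its length and "distance from
   tip" afterwards means distance along the root. The lateral offset covers
   the widest observed lateral reach of the foreground (otherwise the hair
   fringes would fall outside the control mesh and be erased), capped
   against mesh folding using the midline curvature. The mesh is extended
   past the midline ends, with the end tangents, to the full foreground
   extent — the skeleton stops about half a root-width short of the root
   ends. Labels are always resampled nearest-neighbour; interpolation would
   invent fractional labels.

5. **Tip and per-side split.** The straightened root's skeleton is
   convolved with a 3×3 all-ones kernel; endpoints have value 2 (isolated
   pixels, value 1). The lowest endpoint, refined by descending through
   root pixels to the actual bottom row, is the tip. (If thinning leaves a
   pixel clump instead of a clean endpoint, the lowest skeleton pixel of a
   path-like skeleton is used; a closed-curve skeleton is an error.) Per
   row, the root occupies a column interval `[c_min, c_max]`; hair pixels
   left of it form the left fringe, right of it the right fringe, interior
   strays go to the nearer boundary (ties left). Hair below the tip row is
   measured against the tip row's interval. Rows above the topmost root row
   are discarded.

## Trait extraction

Rows are tiled into consecutive windows ("bins") of `resolution` rows
starting at the tip and proceeding upward. Only complete windows enter the
binned statistics: the top of the captured root is an oblique field-of-view
cut that leaves a partial, contaminated window (captured root length still
reports the full extent). Per bin and side:

- **RHL** = max over rows of the lateral hair extent from the root
  boundary column to the farthest hair pixel, / `conv`. This is the width
  of the hair mask; it deliberately does not trace the curvature of
  individual hairs, and per-row runs need not be contiguous (gaps between
  filaments do not shorten the measurement).
- **RHA** = hair pixel count in the bin / `conv`². Binned areas partition
  the retained hair mask exactly, so total RHA × `conv`² equals the
  retained hair pixel count to machine precision.

Summary traits: mean/max/min RHL pool both sides over all retained bins;
heterogeneity records per-bin |left − right| for RHL and RHA, its maximum,
and the bin-centre position of the maximum (ties toward the tip). Root
thickness is the mean over windows of the mean per-row root width;
captured root length is the straightened root's full row extent. With
`length_cutoff` set, bins whose centre lies beyond the cutoff are dropped
before *every* statistic.

**Elongation zone.** The per-bin mean of the two sides' RHL is smoothed
with LOWESS (span `lowess_frac`, default 0.1 of the data, with a minimum of
3 points; 0 robustifying iterations). Backward differences of the fitted
curve give the rise into each bin; the longest run of bins rising faster
than a floor of 0.5 px per bin (sub-pixel fitted changes are below the
measurement quantum of a pixel-counted profile) is the candidate zone, ties
going to the run nearest the tip. Run boundaries are then refined by a
hinge rule: boundary bins rising at under 30% of the zone's median rate
belong to the smoother's boundary tail, not the zone, and are trimmed.
The gradient trait is (max − min fitted RHL within the zone) / zone length.
A profile with no qualifying run yields an empty zone (distance 0, missing
gradient).

Three smoothing choices matter and are configurable:

- *No robustifying iterations* (`lowess_it=0`): the profile is an envelope
  (per-bin max) statistic; reweighting systematically pulls the fit off the
  envelope near the transition to the mature zone and displaces the
  detected end.
- *Span ≈ 6 bins* (`lowess_frac=0.1` at typical root lengths): wide enough
  to bridge single-bin jitter, narrow enough that the boundary tail stays
  within about one bin. Noisier segmentations may warrant a larger span at
  the cost of end localisation.
- *Gradient floor 0.5 px/bin*: resampling during rotation and warping
  perturbs the profile at the sub-pixel level; treating sub-pixel fitted
  changes as flat prevents spurious long runs on plateaus.

**Density proxy.** Mean grayscale intensity (channel average of the raw
image) over hair pixels divided by the mean over background pixels. Under
backlit imaging, denser hairs block more light, so lower ratios indicate
denser hairs. The proxy needs the raw image; in masks-only runs the three
intensity traits are written as empty cells (zero is a legal intensity).
Batch QC flags images whose background mean deviates more than a z-score
threshold (default 3) from the batch — an inconsistency in lighting that
also invalidates cross-image comparison of the proxy.

## Random-forest segmentation front end

For desk-scale use without a trained neural segmenter, a per-pixel random
forest is trained on one representative annotated image and applied to the
rest of a batch acquired under the same conditions. Features per channel:
raw intensity, Gaussian-smoothed intensity and Gaussian gradient magnitude
at scales {1, 2, 4} px — 21 features for RGB input; feature order and count
are stored with the model and enforced at prediction. The forest uses 100
trees, a fixed seed, and at most 20 000 training pixels per class (seeded
subsample). Dice and IoU (per class, with empty-vs-empty scoring 1)
quantify agreement with reference masks. The forest keys on intensity and
local texture only; it transfers across images from one rig but not across
lighting setups — unlike a trained CNN it has no shape prior.

## Synthetic roots as oracle

The generator renders a single root: a vertical or sinusoidal midline
(amplitude, wavelength) of constant odd width, flanked by solid per-row
hair runs whose extent follows a configurable profile of distance from the
tip — constant, linear ramp to plateau, or either with a localised
"bump" patch on one side. Because hairs are solid runs, every trait has a
closed form: rendered hair count equals the sum of per-row extents exactly,
and per-bin RHL/heterogeneity/elongation-zone values follow from the
profile functions. For curved midlines the ground truth accounts for the
two geometric effects of straightening — positions become arc-length
distances, and horizontally rendered runs foreshorten by cos θ of the local
slope. The oracle bins with the same complete-window rule and applies the
same 0.5 px rise floor and hinge trim as the pipeline, so oracle and
pipeline disagree only through genuine measurement error.

Images take configurable class intensities (defaults: dark root 40,
mid-grey hairs 120, bright background 230, emulating backlit plates) plus
clipped additive Gaussian noise; the mask stays clean, separating
segmentation tests from geometry tests. A "filament" style renders hairs as
regularly spaced 1-px runs in the image only (the mask keeps the solid
fringe), giving the density proxy a controlled density contrast.

What the fixtures do not emulate: curved or tangled individual hairs,
agar artefacts and reflections, uneven illumination, root taper, and
multi-root scenes. Passing the recovery suite therefore demonstrates the
geometry and measurement chain, not segmentation robustness on real
imagery.

The randomized recovery suite (20 seeded fixtures) draws straight and
gently curved roots (midline slope ≲ 0.15, the gravitropic regime of
agar-grown seedlings selected for plate phenotyping), constant and ramp
profiles, and one-window unilateral hair patches of 40–80 px — a localised
asymmetry whose position is well defined, unlike a distributed left/right
difference. Measured on this suite, mean RHL recovers within ~1 px,
thickness within ~0.1 px, elongation-zone end within one bin, zone gradient
within ~6%, and the asymmetry position within one bin; these are the
quantities `scripts/acceptance.py` recomputes.

## Numerical choices and degenerate inputs

- Ties: largest root component → topmost-then-leftmost anchor; tip
  endpoint → larger column; heterogeneity and zone runs → nearest the tip.
- Degenerate inputs raise taxonomised errors rather than returning junk:
  no root pixels (`no-root`), root smaller than the minimum area or
  shorter than two windows (`degenerate-root`), closed-curve skeleton
  (`geometry`), label values outside {0, 1, 2} (`label-convention`). The
  batch runner records these per image and continues.
- A root thinner than 2 px everywhere skips thinning with a warning.
- Reruns are bit-identical for fixed inputs and seeds; the only randomness
  (forest training, training-pixel subsampling, image noise) is seeded.

## Known limitations

- RHL measures the fringe width, not individual hair lengths; curled hairs
  are under-measured. Individual-hair tracing is out of scope.
- Strong curvature (midline slope ≳ 0.2) smears the elongation-zone corner
  by 1–2 bins through warp resampling and foreshortening; zone-end
  localisation degrades accordingly.
- The heterogeneity traits are absolute differences and inherit any
  segmentation error unattenuated; treat them with caution on noisy masks.
- The zone detector does not discriminate biological anomalies (e.g. bald
  patches near the tip) from the true elongation zone; inspect the
  `--plot-summary` figures when a reported zone looks implausible.
- The density proxy compares only within a batch imaged under constant
  lighting; the QC table is the guard.
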