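# rootfringe

Spatially resolved root-hair morphometrics from segmented microscope images
of agar-grown seedling roots.

Root hairs — single-cell projections of the root epidermis — drive nutrient
and water uptake, but quantifying them by hand from microscope images is
slow and biased. Given a per-pixel segmentation mask of a root image
(labels: 0 = background, 1 = root hair, 2 = root), `rootfringe`
geometrically normalises the root and extracts a per-position profile of
hair length and area plus a per-image table of summary traits, in
millimetres. Segmentation masks can come from any external tool, or from
the package's built-in random-forest pixel classifier trained on a single
annotated image.

## Method

For each mask the pipeline:

1. removes segmentation noise (largest 8-connected root component kept,
   holes filled, detached hair debris dropped);
2. skeletonises the root and estimates its midline from per-window medians
   of the skeleton columns;
3. rotates the mask so the root tip points down, re-estimates the midline,
   and straightens the whole mask by a piecewise affine warp that maps the
   midline onto a vertical line with rows spaced by arc length;
4. locates the tip by kernel convolution along the straightened skeleton
   and splits the hair mask into the left and right fringe;
5. tiles the root into windows of `--resolution` pixels (default 20) from
   the tip upward and records, per window and side,

   - RHL, root-hair length: max lateral extent of the fringe from the root
     boundary (the width of the hair mask — individual hair curvature is
     not traced),
   - RHA, root-hair area: hair pixel area in the window;

6. summarises per image: mean/max/min RHL, total RHA, left/right
   heterogeneity (max RHL δ and max RHA δ with their positions along the
   root), the root-hair elongation zone (longest region of continuous rise
   of the LOWESS-smoothed profile: start, end, length, and gradient
   = δRHL / zone length), mean root thickness, captured root length, and —
   when the raw image is available — the hair/background mean pixel
   intensity ratio, a density proxy under backlit imaging.

Pixel measurements convert to millimetres through `--conv` (pixels per mm;
default 102). `--length-cutoff N` restricts every statistic to the first
N mm from the tip, standardising traits across images with unequal captured
root length.

## Worked example

The package ships a synthetic-root generator whose fixtures have
closed-form trait values (see `docs/methods.md`). Generate two fixtures and
process their masks:

```
rootfringe make-fixtures --out fx --preset straight-ramp --preset asymmetric
mkdir masks
cp fx/straight-ramp/mask.png masks/seedling_01.png
cp fx/asymmetric/mask.png   masks/seedling_02.png
rootfringe run -i masks -b demo -o out --conv 102
```

which prints

```
processed 2/2 images
summary: out/demo/summary.csv
raw:     out/demo/raw.csv
```

and the summary table contains (columns abridged):

```
       name  mean_rhl  max_rhl  total_rha  ez_start  ez_end  ez_gradient  max_rhl_delta  max_rhl_delta_pos  root_thickness  captured_root_length
seedling_01     0.805    0.980     20.944     0.098     5.0        0.191          0.000              0.098           0.206                13.147
seedling_02     0.529    0.784     13.758     0.098     5.0        0.118          0.461              3.824           0.206                13.147
```

`seedling_01` was generated with hair extents ramping from 0 at the tip to
100 px (0.98 mm) at 500 px (4.9 mm) and flat beyond: the pipeline reports
max RHL 0.980 mm, an elongation zone ending at 5.0 mm with gradient 0.191
(analytic value 0.2), and zero left/right heterogeneity. `seedling_02` has
a shorter right-side fringe; its largest left/right difference, 0.461 mm,
sits 3.8 mm from the tip. Both roots are 21 px (0.206 mm) thick and 13.1 mm
long. The raw table holds one row per (image, window, side) with the
RHL/RHA profile.

`--plot-summary`, `--plot-segmentation` and `--plot-transformation` save
per-image figures of the profiles, the cleaned mask, and the straightening
warp. A batch QC table (`qc.csv`) flags images whose background intensity
deviates from the batch — a lighting-consistency check.

To segment raw images without an external tool, train the pixel classifier
on one annotated image and pass it to the batch run:

```
rootfringe train-rfc --image annotated.png --mask annotated_mask.png --out model.joblib
rootfringe run -i images -b run1 -o out --rfc-model model.joblib
```

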