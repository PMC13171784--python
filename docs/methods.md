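# Methods

## The problem and the model system

Whole-slide images (WSIs) of liver tissue are gigapixel mosaics in which
vascular structures span two orders of magnitude in size: bile ducts of
10–30 µm sit next to portal veins of 100 µm and more, inside lobules of
400–1,000 µm. In pig liver the lobules are bounded by collagen-rich septa
that Picro-Sirius Red (PSR) stains red, and a glutamine synthetase (GS)
immunostain marks perivenous hepatocytes brown, so both the lobular
skeleton and the vessel walls are optically distinct. The package segments
five structure classes (portal vein, central vein, hepatic artery, bile
duct, lobule) with two separate networks — vessels and lobules are learned
independently because central veins lie *inside* lobules and a single
multi-class model would have to resolve that containment — and then
quantifies the segmented structures morphometrically.

## Patch extraction and splits

Slides are processed as non-overlapping square patches anchored at the
top-left corner: 1024 px for the vessel task, 2048 px for lobules (lobules
are larger structural units and need more context per patch). Patch sizes
must be divisible by 2⁵ so that five levels of down/upsampling reproduce
the input size exactly. Edge remainders smaller than one patch are dropped
during training extraction; tiled inference covers edges separately by
shifting boundary tiles inward. Coordinates are 0-based (row, col) with
half-open extents, and stitching extracted patches by origin reproduces
the cropped source bit-exactly.

The test split takes ⌈n·f⌉ patches (7,272 vessel patches at 10% give 728;
7,500 lobule patches give 750); the remainder is divided into k folds
differing in size by at most one, larger folds first (6,750 lobule
training patches give five folds of 1,350, hence 5,400 training / 1,350
validation patches per fold). Splits are reproducible under a fixed seed;
patch-level random splitting allows adjacent-patch correlation between
train and internal test, which is a property of the study design rather
than of this implementation.

Masks are stored as single-channel integer TIFFs with a JSON palette
sidecar; RGB-painted masks are accepted on read with exact color matching
(tolerance 0), and any unmatched color is reported with its pixel count.

## Networks

Both networks share one encoder–decoder topology: four encoder blocks of
DoubleConv (3×3 convolution → instance normalization → leaky ReLU, twice,
padding 1) followed by 2×2 max-pooling, channels 32→64→128→256; a
512-channel bottleneck (64×64×512 for a 1024² input); a mirrored decoder
with 2×2 stride-2 transposed-convolution upsampling and skip-connection
concatenation; and a 1×1 class head (5 classes for vessels, 2 for
lobules). The two variants are parameter-identical except for the head.
Instance normalization and leaky rectification follow the nnU-Net
convention; the decoder uses transposed convolutions with channel
concatenation, the standard U-Net reading.

The layers are implemented directly on NumPy (im2col convolutions,
analytic backward passes, Adam with L2 weight decay), verified against
finite differences through the whole graph. This keeps the package
dependency-free beyond scientific Python and is sized for the desk-scale
models the test-suite trains; it is not a GPU training stack, and
full-scale WSI training is outside the package's scope.

## Training

The vessel loss is `L = 0.2·CE + 0.6·(1 − softDice) + 0.2·Focal`; the
lobule loss is `0.5·CE + 0.5·(1 − softDice)`. Soft Dice uses the per-class
probability-overlap form with smoothing ε = 10⁻⁵, averaged over foreground
classes; focal uses the standard form with γ = 2 and no α term, since
per-class weighting is already carried by the adaptive class weights. Each
component is class-weighted; cross-entropy and focal terms normalize by
the summed pixel weights (so uniform weights reduce exactly to the plain
losses).

**Adaptive weight boosting** is the imbalance mechanism: every 15 epochs,
each foreground class is assessed by its validation Dice and its loss
weight is multiplied by 1.3 (Dice in [0, 0.3)), 1.2 ([0.3, 0.5)) or 1.1
([0.5, 0.7)); at 0.7 and above the weight is unchanged. Intervals are
half-open, background is never boosted, weights start at 1.0, never
decrease, are not renormalized across classes, and are capped at 10× the
initial value to prevent divergence (the cap and η_min = 0 are choices the
hyperparameter description leaves open). Boosting is exposed for both
networks; the lobule model defaults to boosting off, matching its
less-imbalanced class distribution.

The learning rate follows cosine annealing,
η_t = η_min + ½(η_max − η_min)(1 + cos(tπ/T)), from η_max = 5·10⁻⁴ over
T = 250 epochs; the optimizer is Adam with weight decay 2·10⁻⁴, batch
size 8. Early stopping ends training after 20 consecutive epochs without
validation-loss improvement, and the best-validation checkpoint is kept.
Augmentation applies random horizontal/vertical flips, rotations from
{30°, 60°, 90°, 120°, 150°, 180°, 270°} (right-angle rotations are exact
grid rotations; oblique angles resample the image bilinearly and the mask
nearest-neighbour, so no interpolated labels appear) and intensity jitter
on the image only.

Cross-validation trains each fold independently and aggregates per-class
validation Dice as mean ± sample SD over folds.

## Metrics

Dice, IoU and TPR are computed per class as one-vs-rest binary overlaps;
both-empty mask pairs score 1 by convention, and TPR of an absent class is
an NaN sentinel excluded from aggregation. The identity IoU = DSC/(2−DSC)
holds exactly and is fuzz-tested. ASSD extracts boundary pixels (a
foreground pixel with any 4-neighbour background), measures Euclidean
nearest-boundary distances between pixel centers in both directions,
averages the two directional means, and scales by µm/pixel; an empty
surface yields an NaN sentinel with a warning. The confusion matrix is
row-normalized to percentages of true-class pixels. The relative error
100·ASSD/diameter expresses boundary error as a fraction of a typical
structure dimension. ASSD aggregation across a test set is per structure.

## Tiled inference

Inference tiles a large image at stride `patch_size·(1 − overlap)`
(default overlap 0.5), shifts edge tiles inward for full coverage, and
averages per-class scores over all covering tiles — order-invariant
uniform blending. Labels are per-pixel argmax with ties toward the lowest
label. Images smaller than one patch are predicted on a centered
zero-padded tile and cropped back. When vessel and lobule views are
merged, vessel labels take precedence, since central veins sit inside
lobules.

## Morphometry

Lobule counting first closes the septum phase (dilation then erosion with
a disk; default radius 15 µm ≈ the septum half-width, a choice the
procedure description leaves open) so lobules connected through septum
gaps narrower than twice the radius separate; the closing necessarily
contracts net lobule area. Because the closing disk also rounds sharp
lobule corners, shape measurement grows each closed component back over
the original lobule pixels (marker-based watershed): counts reflect the
separation, calipers reflect the segmentation.

Components are 8-connected. Pixels are treated as unit squares (corner
convention), so a single pixel has Feret major √2 px and minor 1 px; this
avoids the systematic −1 px bias of measuring between pixel centers. The
major Feret diameter is the maximum pairwise distance between boundary
points and the minor is the narrowest parallel-slab width over all
orientations; both are computed on the convex hull of the pixel corners —
the hull preserves both extrema — with the minor taken by rotating
calipers over exact edge normals (an exhaustive 0.5° sweep serves as test
oracle only). Aspect ratio is minor/major. Perimeter is the polygonal
outer-contour length (marching squares at level 0.5). Area is
pixel count · (µm/px)², 0.227 µm/px at the reference scan resolution.

Per-class area filters suppress false positives: lobules
12,500–1,250,000 µm² (the upper bound excludes falsely connected
lobules), portal veins ≥1,000 µm², arteries, bile ducts and central veins
≥125 µm², with no upper bound for vessels; bounds are inclusive.
Densities are counts per mm² of analyzed tissue (non-glass pixels by
intensity threshold, or an explicit area override), reported to two
decimals. Group comparisons between artifact-free and artifact-affected
slides use sample (n−1) SDs and Student's pooled-variance two-sample
t-test, two-sided — this reproduces the published lobule-density
statistics (mean 1.19 ± 0.34, p ≈ 0.93) from the per-slide values. Box
summaries use Tukey whiskers: the last data point within 1.5·IQR beyond
the quartiles.

## Synthetic histology

The generator emulates GS-PSR porcine liver at a configurable µm/px.
Lobules are Voronoi cells of a jittered hexagonal point process; mirror
points across the image edges close border cells exactly at the frame,
and each cell is offset inward by half the septum width (default 30 µm
septa) — the removed band is the red septum. The lattice spacing is drawn
so that cell calipers stay inside the anatomical 400–1,000 µm range after
jitter and erosion. Portal triads (portal vein 80–160 µm thin-walled,
artery 10–90 µm thick-walled, bile duct 10–30 µm) are planted at Voronoi
vertices — the lobule corners — and central veins (30–60 µm, with a brown
GS halo) at lobule centers; placements are rejection-sampled so structures
never touch, and requesting more structures than there are feasible sites
is an explicit infeasible-packing error. Colors follow the stain logic
(pale pink parenchyma, PSR-red septa, darker red walls, white lumina,
brown halo) with Gaussian jitter.

Ground truth is exact: the vessel and lobule masks are rasterized from
the same geometry as the image, and every structure's record carries its
planted class, center and diameter — lobule calipers analytically from
the cell polygons, vessel calipers as the planted disk diameters. This is
what makes the end-to-end parameter-recovery test meaningful: counting
and measuring the generated masks must return the planted truth (counts
exactly, diameters within 2 px rasterization error).

Artifacts are injected into the image only, never the masks: tears are
glass-colored rip polylines crossing the tissue, folds are darkened
duplicated bands, uneven staining is a smooth multiplicative gain field.

What the generator does *not* emulate: real stain variability and optics
(no Beer–Lambert model), tissue texture (sinusoids, nuclei), annotation
noise, and the merging/fragmentation ambiguity of real septa. Passing
tests on synthetic data therefore validate the pipeline's mechanics —
geometry, losses, metrics, counting — not segmentation accuracy on real
slides, which requires real annotated WSIs and full-scale training.

## Desk-scale test conditions

The test-suite and the acceptance script run on one CPU, so they use
synthetic fields of 1024² px at 2 µm/px (a 2×2 mm field holding 10–20
lobules) and tiny networks (base 8 channels, depth 2–3, 64² windows).
The overfit check trains the vessel configuration — with its default
weight boosting — until it memorizes 8 windows (foreground Dice > 0.9).
The directional check trains the same data twice at a matched seed, with
and without boosting, under a fixed uniform-weight evaluation, and
compares minority-class Dice; it is a scaled-down analogue of the
boosted-vs-standard comparison, stochastic by nature. Anatomical
parameters (diameter ranges, septum width, filters, loss weights,
schedules) are never scaled — only field size, resolution and network
size.

## Known limitations

- No GPU path; full-scale 1024²-patch training at batch 8 is out of reach
  of the NumPy engine in reasonable time.
- Pyramidal/NDPI slide reading is not included; inputs are flat RGB
  TIFF/PNG mosaics at level-0 resolution.
- No stain normalization and no test-time augmentation.
- The patch-level split reproduces the study design's adjacency caveat.
- Focal-loss internals (γ, α) and the boosting cap are reasonable
  defaults where the training description is silent.
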