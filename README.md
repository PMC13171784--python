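# hepaseg

Segmentation and morphometry of hepatic vessels and lobules in whole-slide
images of GS-PSR stained porcine liver.

Porcine liver is a favourable model system for computational histology: its
lobules — the polygonal functional units of the liver, 400–1,000 µm across —
are bounded by collagen-rich septa that stain red with Picro-Sirius Red
(PSR), while a glutamine synthetase (GS) immunostain marks the hepatocytes
around each central vein brown. `hepaseg` implements an end-to-end pipeline
for such slides:

1. **Patch extraction** — non-overlapping 1024 px (vessels) or 2048 px
   (lobules) tiles from level-0 slide mosaics, with integer-label annotation
   masks (0 background, 1 portal vein, 2 central vein, 3 artery, 4 bile
   duct; lobules binary) and reproducible test/5-fold splits.
2. **Segmentation networks** — two U-Net style encoder–decoders (four
   double-convolution encoder blocks, channels 32→64→128→256, a 512-channel
   bottleneck, mirrored decoder with skip connections), one with a 5-class
   head for vessels and one with a 2-class head for lobules, implemented on
   a self-contained NumPy layer engine with analytic backpropagation.
3. **Training** — a composite loss
   `L = w_CE·CE + w_Dice·(1 − softDice) + w_Focal·Focal`
   (0.2/0.6/0.2 for vessels, 0.5/0.5/0 for lobules), cosine-annealed
   learning rate `η_t = η_min + ½(η_max−η_min)(1 + cos(tπ/T))` from
   5·10⁻⁴, Adam with weight decay 2·10⁻⁴, early stopping after 20 stagnant
   validation epochs, and **adaptive weight boosting**: every 15 epochs each
   foreground class whose validation Dice falls in [0, 0.3), [0.3, 0.5) or
   [0.5, 0.7) has its loss weight multiplied by 1.3, 1.2 or 1.1. This is the
   mechanism that rescues minority classes (bile ducts occupy well under 1%
   of the pixels).
4. **Tiled inference** — overlapping tiles (default 50%), per-pixel score
   averaging, argmax stitching, and colored overlays on the histology.
5. **Metrics** — per-class Dice, IoU, TPR, average symmetric surface
   distance (ASSD, µm), row-normalized confusion matrices, and the relative
   error `100·ASSD/diameter` that puts boundary errors in biological scale.
6. **Morphometry** — septa closing to separate touching lobules, connected
   components, per-class area filters (lobules 12,500–1,250,000 µm², portal
   veins ≥1,000 µm², other vessels ≥125 µm²), Feret major/minor calipers via
   rotating calipers on the convex hull, aspect ratio, perimeter, per-mm²
   densities, and pooled two-sample t-tests between slide groups.
7. **Synthetic histology** — a generator of GS-PSR-like fields with exact
   ground truth (Voronoi lobules on a jittered hex lattice, portal triads at
   lobule corners, central veins with GS halos, optional tears, folds and
   uneven staining), so every stage is testable without real slides.

## Worked example

```python
import hepaseg as hs

# a 1024² synthetic field at 2 µm/px with exact ground truth
params = hs.TissueParams(height_px=1024, width_px=1024,
                         pixel_size_um=2.0, seed=5)
image, vessel_mask, lobule_mask, truth = hs.generate_tissue(params)

# morphometry on the vessel mask: counts and calipers after size filtering
records = hs.apply_size_filters(
    hs.measure_structures(vessel_mask, "central_vein"))
print(len(records), round(records[0].feret_major_um, 1),
      round(records[0].aspect_ratio, 2))
```

prints

```
13 54.0 0.96
```

— thirteen central veins survive the ≥125 µm² filter, the first has a major
Feret diameter of 54.0 µm (the planted diameters are drawn from 30–60 µm)
and is nearly circular (aspect ratio 0.96). The same field's lobules, after
septa closing and filtering, are recovered at exactly the planted count with
calipers within two pixels of the planted polygons.

The `hepaseg` command exposes the pipeline stages
(`make-synthetic`, `extract-patches`, `split`, `train`, `crossval`,
`evaluate`, `predict-wsi`, `morphometry`, `report`); every run writes a
JSON manifest with its configuration and seed.

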