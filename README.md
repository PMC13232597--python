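# tubulopy

Automated segmentation, classification and quantification of seminiferous
tubules and their cells in multi-channel immunofluorescence images of
testicular tissue.

Histology-based quantification of the prepubertal testis — how many
spermatogonia (MAGE-A⁺ germ cells) and Sertoli cells (SOX9⁺) a section
contains, where they sit inside the tubule, and how mitotically active
they are — is traditionally done by manual annotation, which is slow and
observer-dependent. `tubulopy` implements the automated alternative as a
tested Python library: a pixel classifier segments tubules from
interstitial tissue and background, nuclei are segmented inside tubule
ROIs, cells are phenotyped by marker fluorescence, and spatial and
DNA-content statistics are derived per tubule region. A synthetic-scene
generator with complete ground truth makes every stage testable without
clinical images.

## The method

1. **Pixel classification** — each pixel is described by four filter
   families per channel at scales σ ∈ {1, 2, 4, 8} px: Gaussian-smoothed
   intensity G_σ, gradient magnitude |∇G_σ|, structure-tensor coherence
   (λ₁−λ₂)/(λ₁+λ₂), and the Hessian determinant. A small MLP (one
   logistic hidden layer, softmax output) trained on ~3 sparse disc
   annotations per class per image maps features to
   {tubule, tissue, background}. Training images include antibody
   controls. Class regions become ROIs via 8-connected components with
   minimum object size 400 μm² and minimum hole size 200 μm².
2. **Cell segmentation** — watershed on the Hoechst counterstain:
   log-Otsu threshold per ROI, Euclidean distance transform, seeds at
   distance maxima ≥ 7 μm apart, watershed, nucleus area filter
   [10, 400] μm², then 5 μm expansion into non-overlapping cell
   boundaries. A plugin slot accepts external star-convex detectors
   (e.g. a StarDist label map) behind the same interface.
3. **Classification** — one label per cell from ordered rules on
   compartment intensity (nuclear mean SOX9, nuclear mean MAGE-A,
   cytosolic MVH, …); ties resolve by fold over threshold; cells firing
   no rule are `unclassified`.
4. **Spatial analysis** — each tubule is split at 35 μm inside its
   boundary into a membrane-associated band and a luminal core; cells of
   the same class with centroids ≤ 15 μm apart form a neighbour graph
   whose degree distribution summarises clustering.
5. **DNA content** — nuclear Hoechst mean proxies DNA content (G1 peak
   ≈ 9,000 RFU; up to ~30,000 RFU approaching division). Cells above
   14,000 RFU — the top of the post-mitotic SOX9⁺ G1 range — are
   mitotically active; the mitotic index is their percentage per
   class × region.
6. **Reporting** — per-image class counts, tubular areas and densities
   (cells/mm²), plus an area-vs-count OLS regression whose standardised
   residuals flag outlier images (flagged, never dropped).

## Worked example

`examples/` contains one short script per capability. From
`examples/05_mitotic_index.py` (watershed detections on a seeded
synthetic scene, classified and zoned, 14,000 RFU threshold):

```
SOX9 Hoechst peak bin centre: 9250 RFU (G1 reference population)
 class   region  total  g1  mitotic  pct_of_class  pct_g1  mitotic_index_pct
  SOX9    total    114 100       14         100.0    87.7               12.3
MAGE-A    total     95  38       57         100.0    40.0               60.0
...
generator truth SOX9: 12.3% mitotic
generator truth MAGE-A: 60.0% mitotic
```

The measured mitotic indices recover the generator's per-class truth
from pixels alone. The same script applies the identical arithmetic to a
pooled published-style count table (13 sections), e.g. MAGE-A total
11,780 cells of which 5,954 above threshold → index 50.5%, membrane
8,976 + luminal 2,804 = 11,780 exactly.

From `examples/06_full_pipeline.py` over four seeded scenes:

```
875 detections across 4 images, threshold 14000 RFU
count ~ area: r2=0.987, p=0.0063 over n=4 images
QC flags: 0 of 4 images
```

A thin CLI mirrors the stages
(`tubulopy simulate|train|segment|cells|classify|spatial|cycle|report|run`),
e.g. `tubulopy run --config pipeline.yaml`.

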