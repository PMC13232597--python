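# Methods

This note documents the models, parameters and numerical choices behind
`tubulopy`, what the synthetic-scene generator does and does not
emulate, and the known limitations.

## Coordinate and calibration conventions

Rasters are indexed `[row, col]`, y-down. Continuous coordinates are
micrometres with the origin at the top-left corner of pixel (0, 0); the
centre of pixel (r, c) is at ((c + 0.5)·px, (r + 0.5)·px) where `px` is
the pixel edge in μm. Calibration is a required input: TIFF resolution
metadata is honoured (an ImageJ `unit: um` tag, or inch/cm resolution
units), a writer-default resolution of (1, 1) is treated as absent, and
an uncalibrated file without an explicit override is an error — every
μm- or μm²-denominated parameter downstream depends on it. Channel
identity is by name everywhere; a classifier trained on one channel set
refuses any other, which forces retraining per marker panel rather than
silent misapplication.

## Pixel classification

**Features.** Per channel and per scale σ ∈ {1, 2, 4, 8} px (defaults):
Gaussian-smoothed intensity, Gaussian gradient magnitude,
structure-tensor coherence ((λ₁−λ₂)/(λ₁+λ₂), set to 0 where
λ₁+λ₂ = 0) and the determinant of the Gaussian Hessian. All filters use
reflective boundary handling so a flat field yields exactly zero
derivative responses. The scale set spans nucleus-size to
tubule-boundary structure at a typical 20× calibration (0.5 μm/px); the
"colour" aspect of the intensity feature is realised as per-channel
intensity, the natural reading for single-fluorophore channels.

**Model.** One hidden layer of max(32, 2·n_features) logistic units,
softmax output, cross-entropy loss, adam, at most 300 epochs, fixed
random seed (scikit-learn `MLPClassifier`). Features are z-scored with
statistics estimated from the training pixels and stored in the model.
Training pixels come from sparse disc annotations (default three
8 μm-radius discs per class per image) over a handful of fully stained
and antibody-control images; controls teach the model that tubule
texture without a given marker is still tubule. Models serialise to a
single portable JSON file (weights as nested lists), which keeps them
text-diffable and platform-independent at this scale. Prediction is a
plain feed-forward pass implemented in numpy, so training and prediction
are exactly reproducible — repeated runs are bit-identical, which is the
package-level restatement of run-to-run identity.

**ROI extraction.** Per class (background excluded), 8-connected
components are filtered at minimum object size 400 μm² and minimum hole
size 200 μm², both inclusive (keep-if-≥): the thresholds are applied to
exact pixel-count areas, holes below threshold are filled, objects below
threshold dropped. Surviving components are traced as subpixel
marching-squares contours (level 0.5; largest contour = exterior, others
= holes), so re-rasterising a traced polygon by pixel-centre containment
reproduces the source mask and extraction is idempotent. Recorded areas
and perimeters come from the traced polygon. `refined_class_map` exposes
the post-filter class raster — the segmentation the stage actually
hands downstream; isolated misclassified islands around single
interstitial nuclei fall under the 400 μm² filter, which is why
segmentation quality is scored on this map. An optional morphological
opening exists for separating bridged tubules but defaults off. When
polygons are rasterised with overlaps, tubule takes priority over
tissue over background, since tubules are the measurement target.

## Nucleus segmentation and cell expansion

The watershed sequence on the counterstain channel: Gaussian blur
(σ = 1.5 μm), per-ROI threshold, Euclidean distance transform of the
foreground, seed selection, watershed on the inverted distance, nucleus
area filter [10, 400] μm² (inclusive). Three internals are documented
choices:

- **Threshold.** Otsu on log₁₀ intensity of the blurred channel within
  the ROI. Nuclear intensities are heavy-tailed (2n–4n DNA content), and
  a linear-scale Otsu tends to split dim from bright nuclei rather than
  tissue from nuclei; the log transform restores the intended split. A
  bimodality guard — foreground mean must exceed the background mean by
  4 background SDs — returns an empty mask on noise-only ROIs, where
  Otsu would otherwise split the noise in half. A fixed threshold mode
  is available for reproducibility studies.
- **Mask.** The threshold is applied to the *raw* channel
  (`mask_on_raw`, default on). Thresholding the blurred channel grows a
  halo around every nucleus that fuses close neighbours and dilutes the
  nuclear mean intensity — fatal for DNA-content gating near the
  threshold. The blurred channel is used only to estimate the threshold
  robustly.
- **Seeds.** Distance-transform maxima are collected per connected
  component and thinned greedily (highest first) to a Euclidean minimum
  separation of 7 μm, with every foreground component guaranteed one
  seed. Square-window (Chebyshev) suppression, the library default, can
  silence an entire nucleus whose maximum is marginally lower than a
  diagonal neighbour's, which costs several percent of detections in
  packed epithelium.

Cells are nuclei expanded 5 μm (the conventional cytoplasm estimate for
cytosolic markers), clipped to the ROI, with contested pixels going to
the nearest nucleus via the distance transform's nearest-feature
assignment — cells never overlap and always contain their nucleus.
Nuclear and cytosolic (cell minus nucleus) mean/sum/sd/max are measured
per channel on the raw image. The star-convex plugin slot accepts a
callable or a precomputed label map; it is an adapter only, and nothing
in the core requires it.

## Cell classification

Ordered rules (class name, marker channel, compartment, statistic,
threshold in RFU); a rule fires when its statistic meets its threshold
(inclusive). Exactly one label per cell: a single firing rule wins;
multiple firing rules resolve by maximum fold over their own thresholds
(rule order available as an alternative); no firing rule means
`unclassified`. Thresholds are configuration, not learned — the
workflow fixes one setting per experiment. Counts therefore always
partition the detections, and raising a threshold can only shrink its
class.

## Spatial organisation

The luminal zone is the inward buffer of the tubule polygon by 35 μm
(about two cell diameters); the membrane-associated zone is the
remainder, so the zones tile the tubule exactly and tubules narrower
than 70 μm have no lumen. Cells are assigned by nucleus centroid;
centroids exactly on the boundary go to membrane (deterministic tie).
The neighbour graph joins same-class cells within the same image whose
centroid distance is ≤ 15 μm (inclusive); unclassified cells are
excluded. Degrees are computed before any region filtering — a membrane
cell can be a luminal cell's neighbour — and region subsets only select
whose degrees enter a histogram. Degree-histogram modes break ties
toward the smaller degree.

## DNA-content gating

The nuclear counterstain *mean* is the gating statistic (configurable);
the 2n→4n doubling argument holds strictly for integrated intensity,
but mean nuclear intensity is the conventional per-cell measurement and
tracks DNA content well for nuclei of similar size. The fixed threshold
is 14,000 RFU — the top of the G1 range of the largely post-mitotic
SOX9⁺ reference population — and cells strictly above it are mitotic
(a cell at exactly 14,000 is G1). A percentile mode (97.5th percentile
of the reference class, ≥ 50 reference cells required) is the
principled analogue of reading the G1 upper edge off a histogram; note
that for the generator's G1 distribution (Normal(9,000, 1,500) truncated
to [6,000, 14,000]) this percentile sits near 11,800 RFU, i.e. the two
modes are deliberately not numerically interchangeable. Mitotic
summaries report counts and one-decimal percentages per class × region
with the invariants G1 + mitotic = total and membrane + luminal = total
enforced by construction; empty groups carry NaN indices rather than
failing silently.

## Reporting and QC

Densities are counts per mm² of tubular area. Across a section series,
total cell count is expected to scale with segmented tubular area;
ordinary least squares of count on area (slope, r², two-sided p via the
t-statistic) is the audit surface, and images with standardised
residuals |z| > 3 are flagged but never dropped — exclusion is an
analyst's decision and must stay auditable. The flagging is invariant
to area units because standardised residuals are scale-free.

## The synthetic-scene generator

The generator emulates what the pipeline measures, not optics. A scene
(default 1,024 px at 0.5 μm/px) holds an elliptical tissue region over
dark background with five non-overlapping circular tubules of 45–70 μm
radius (whole-configuration restarts make packing robust), each with a
5 μm peritubular ring. Diffuse autofluorescence baselines (tubule 1,200,
ring 2,000, interstitium 500 RFU) make the three region classes
optically distinct, as real tissue is against glass. Nuclei are 4 μm
discs rendered at a constant per-cell intensity with centre-to-centre
separation ≥ 2.1 nucleus radii (disjoint by construction; the factor is
exposed to deliberately stress watershed splitting). Hoechst intensity
is drawn per cell: G1 from Normal(9,000, 1,500) truncated to
[6,000, 14,000] RFU, mitotic from Uniform(14,000, 30,000) RFU, with
per-class mitotic fractions (defaults: SOX9 0.11, MAGE-A 0.50).
Nuclear markers render into the nucleus disc, cytosolic markers into a
3 μm annulus around it; positives draw from Normal(5,000, 800), negatives
from Normal(300, 120). Membrane-band cells are dispersed; luminal
germ cells arrive partly as five-cell cliques (pairwise within 15 μm),
planting the clustered-lumen signature. Interstitial cells are unmarked.
Cell packing is 0.007 nuclei/μm² in tubules and 0.0015 interstitially;
additive Gaussian noise (sd 200 RFU, clipped at zero) is drawn from
per-channel child streams so antibody-control renders can keep the
identical counterstain while replacing omitted marker channels with
noise alone. Everything is deterministic from the scene seed.

Not emulated: point-spread blur and chromatic effects, spectral
crosstalk, intensity gradients and vignetting, tissue damage, folds and
staining artefacts, out-of-focus regions, nucleus shape variation and
true 3D overlap. Passing tests therefore demonstrate the pipeline's
logic and numerics — segmentation separability at realistic geometry
and contrast, statistic recovery, invariants — not robustness to
acquisition pathology; on real images the pixel classifier carries that
burden and may need artefact classes.

## Test and acceptance problem sizes

Detection-stage tests use the default 1,024 px scene (~200 tubule cells
per scene); classifier-stage tests use a 640 px, two-tubule variant so
that six trainings plus predictions stay quick. Mitotic-fraction
recovery pools ten seeded scenes (~2,000 measured cells) and checks the
pooled index against the 99% binomial interval of the generator
fraction. The acceptance script mirrors these sizes and also re-derives
the summary percentages of a published-style pooled count table
(13 sections' worth of counts) through the same arithmetic the pipeline
uses on its own detections.

## Known limitations

- Adjacent tubules closer than the feature scales can bridge into one
  ROI; the optional opening step mitigates but is off by default.
- The watershed assumes roughly convex, similar-sized nuclei; heavily
  overlapping or elongated nuclei (e.g. peritubular myoid) are better
  served through the star-convex plugin slot.
- Marker thresholds are per-experiment constants; no cross-batch
  intensity normalisation is provided.
- Mean-intensity DNA gating conflates ploidy with nucleus-size effects
  in tissues with strongly varying nuclear volume.
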