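# Methods

`benthoscope` implements a machine-learning-assisted annotation workflow for
large collections of seabed photographs. The goal is not fully automatic
detection — reliable class labels for benthic megafauna require domain
experts — but to remove the slowest part of manual annotation: *finding*
objects of interest (OOI) in tens of thousands of images. The pipeline
proposes candidate regions; humans only filter and refine them.

## The model

### Background clustering

A survey dataset `{I_i}` usually spans several background appearances
(sediment changes, illumination, altitude). Images are grouped into `K`
clusters of globally similar background so that one background model can be
trained per cluster. Each image is mapped to a feature vector: a 32×32
grayscale thumbnail projected onto the dataset's first `d = 8` principal
components, plus the Shannon entropy (bits, 256-bin histogram) of its
intensities. k-means (k-means++ init, 10 restarts, fixed seed) partitions
the images. The default `K = 5` reflects the operating point that performed
well across heterogeneous surveys; it is a config parameter, not a tuned
constant of this package.

Feature scaling was a genuinely open design point. Z-scoring every feature
individually makes all PCA components equally loud, which on small datasets
lets noise components drown the separating direction; we therefore scale
the PCA block by one shared factor (preserving the variance ordering) and
z-score only the entropy term. With this recipe, sediment types with
disjoint base-colour ranges are recovered exactly by k-means at `K` equal
to the number of types (asserted in the tests).

### The data-driven background model (DBM)

Per cluster, a three-layer autoencoder is trained on `10⁴` random patches
of `r_e × r_e` RGB pixels (default `r_e = 39`, so the input dimension is
`r = 3·r_e² = 4563`):

```
l  = σ(W x + b)          latent, s = round(s_c · r) units (s_c = 0.1 → s = 456)
x′ = σ(W′ l + b′)        reconstruction
σ(x) = log(1 + e^x)      softplus
F(x, x′) = Σ_j (x_j − x′_j)²   reconstruction error
```

Training minimises the minibatch-mean of `F` for 100 epochs at minibatch
128 with Adam (lr `10⁻³`, β₁ = 0.9, β₂ = 0.999) and Xavier-uniform
initialisation of both weight matrices. Patches are flattened pixel-major
(`p1_r, p1_g, p1_b, p2_r, …`). Pixels are normalised to `[0, 1]` by the
dtype maximum; softplus outputs are nonnegative, so this target range keeps
reconstruction feasible. `F` is the *sum* of squared component differences
(sum vs. mean only rescales the maps; the percentile threshold below is
scale-invariant).

The network is three dense layers, so it is implemented directly on NumPy:
float32 GEMMs with hand-derived gradients (`softplus′ = logistic`). The
softplus is computed as `max(x,0) + log1p(e^{−|x|})`, which neither
overflows for large positive inputs nor underflows to zero prematurely for
large negative ones. Training is bit-reproducible for a fixed seed and
takes seconds at the reduced test sizes.

### Novelty maps

The trained DBM is applied like a convolution: every patch position (stride
2 by default — halving the resolution with no practical effect on detection)
is scored with `F`, stored at the patch-centre coordinate. The stride grid
is upscaled to the image resolution by bilinear interpolation, exact at
grid centres, with the `(r_e−1)/2` border margin edge-replicated so the map
covers the whole image. Application runs in horizontal slices (config
`slice_rows`) purely to bound memory; sliced and unsliced results are
identical. The map is then convolved with an all-ones `r_e × r_e` kernel
(zero-padded, separable implementation), a dilation that smooths region
boundaries and spreads high novelty over the object's neighbourhood.

### Thresholding and proposals

Per cluster `U_k`, the segmentation threshold is

```
t_k = (1/|U_k|) Σ_i P99(N_i)
```

the mean of the 99th percentiles (linear interpolation convention) of the
cluster's dilated novelty maps. Dilation precedes the percentile: the
threshold is computed on the maps that are actually segmented. Pixels
strictly above `t_k` form 8-connected "interesting" regions. Each region
becomes one training proposal: the minimum square bounding box centred on
the tight box's centre, expanded to at least 30 px, shifted inward at
image borders so crops stay square. Each proposal carries the cumulated
novelty `η` of its region's pixels; proposals are ranked by descending `η`
(ties broken by image id and region id for determinism) so a reviewer
starting at the top sees the most object-like patches first and can stop
once enough training samples per class (default limit 600) are collected.

### Review, training samples and candidates

The human decisions are *inputs* to this package: filtering is a map from
rank to label-or-reject over a prefix of the ranking; refinement replaces
the default suggestion (the box's inscribed circle) with an adjusted
circle. Around each refined circle a 500×500 crop is cut (shifted inward at
borders; all intersecting circles are carried over) so that OOI missed by
the novelty stage fall outside the training crops rather than being learned
as background. All pixels inside a circle count as object when rendering
masks. The small training set is "boosted" into many augmented variants:
the 8 dihedral symmetries first, then random dihedral × ±10 % scale jitter,
all label-preserving and deterministic per seed.

The instance-segmentation network itself is out of scope; it sits behind
the `SegmentationBackend` interface (padded RGB image in → per-pixel class
mask out, background 0). Inference inputs are zero-padded right/bottom to
multiples of 64, keeping original pixel coordinates valid. Any nonzero mask
pixel is "interesting"; each 8-connected region of interesting pixels
yields the exact minimum enclosing circle of its pixel centres (iterative
Welzl with a fixed shuffle; single-pixel regions get a displayable 0.5 px
radius) as an annotation candidate. A trivial thresholding backend and an
oracle backend make the plumbing testable without a network.

### Evaluation and time economics

Detection is scored at region level: recall counts distinct OOI whose
centre lies in some region (`TP_θ / (TP_θ + FN_θ)`), precision counts
regions containing at least one OOI centre (`TP_ρ / (TP_ρ + FP_ρ)`).
Centre-containment is the strictest simple reading of "contained" and is
the package default. With no regions at all, precision is reported as 0
with an explicit `precision_defined=False` flag. The F2 score
`5·R·P / (4·P + R)` weights recall over precision, matching the review
economics: false alarms are cheap to dismiss in a grid review, missed
organisms are not.

The time model is linear:

```
τ_assisted(n) = 18.34 s/image · n + 12327 s
τ_manual(n)   = 89.27 s/image · n
```

The defaults are recomputed (not hard-coded) from the bundled benchmark
review sessions of three AUV/ROV surveys: the intercept is the mean over
surveys of (filter+refine seconds per image × the 500-image training
subset), the slope the mean candidate-review rate. Break-even is exact:
`n* = setup / (trad_rate − review_rate) ≈ 173.8` images; at 550 images the
assisted workflow is 2.19× faster. All rates are `TimeModelParams` data and
can be recomputed from any logged sessions.

A parameter-search harness runs the proposal stage end-to-end over a grid
of `K ∈ {1,5,10,50,100} × r_e ∈ {29,39} × s_c ∈ {0.1,0.2}` with a shared
seed and emits one recall/precision/F2 row per triplet; the stage-1 runner
is injectable, so the harness is also testable without retraining.

## The synthetic study conditions

The fixture generator emulates what matters for reconstruction-error
novelty detection, nothing more: a textured sediment background (base
colour + band-limited noise — blurred white noise, chosen over Perlin for
dependency-free determinism), an optional smooth illumination gradient, and
rare planted objects (disks/ellipses/blobs) of controlled size and
contrast. Defaults: 512×512 px, 2 expected objects per image (object
pixels ≲ 0.25 % of the image, far below the 2 % rarity bound the novelty
assumption needs; exceeding the bound warns), object diameter 20 px,
contrast 0.8, two sediment types with disjoint base colours. It does not
model mosaicing artifacts, lens distortion, colour casts, camouflage or
taxonomic ambiguity — so passing tests show the pipeline's machinery is
correct and well-behaved under its stated assumptions, not that field
imagery will reach the same scores.

Pipeline tests run at a reduced problem size chosen to exercise every code
path at realistic ratios: 20 images of 512×512 with the default operating
point (K=5, r_e=39, s_c=0.1, stride 2) but 20 epochs on 2000 patches per
cluster. At this size the proposal stage recovers ≥ 90 % of planted
objects and planted-object pixels score well over twice the background's
mean novelty.

## Numerical choices and edge cases

- Segmentation uses strict `>` (a map exactly at threshold stays
  background); mask size is monotone non-increasing in the threshold.
- Percentiles use NumPy's linear-interpolation convention, asserted against
  a sort-based oracle.
- 8-connectivity for regions (both novelty and mask post-processing):
  more forgiving of thin diagonal structures.
- Patch edges must be odd (centre pixel well-defined); coordinates are
  0-based, x right, y down.
- Empty clusters, undersized images, non-finite training losses, even
  dilation kernels, decisions referencing unknown proposals and
  out-of-bounds circles all raise validation errors naming the offender.
- Proposal CSV floats are written in shortest round-trip representation so
  identical runs produce byte-identical files.

## Known limitations

- One autoencoder per cluster assumes backgrounds within a cluster are
  homogeneous; slowly varying illumination is partly absorbed by dilation
  and per-cluster thresholds but strong gradients can inflate novelty at
  image corners.
- The 99th-percentile threshold always marks ~1 % of pixels per map as
  interesting, even for images containing no objects — precision on empty
  images is intrinsically low, which the downstream human filter (and the
  F2 choice) accepts by design.
- The synthetic generator's objects are high-contrast and unoccluded;
  camouflaged fauna will sit closer to the background manifold and score
  lower novelty than any fixture here suggests.
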