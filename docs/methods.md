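# Methods

`podquant` quantifies *Arabidopsis* fruits (siliques) in flatbed scans of
mature inflorescences with a two-phase procedure: a small convolutional
network classifies 32 × 32 image patches into four structural classes —
silique **base** (0), silique **body** (1), **stem** (2) and silique
**tip** (3) — and a deterministic post-processing stage turns overlapping
patch predictions into a sub-patch label image, assembles tip–body–base
regions into silique objects, splits overlapping pods with an angle
threshold, and reports per-image counts and lengths.  This note records
the model, its assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## Patch classification

**Supervision.** Annotation is a set of clicked points, one class per
point.  Training examples are 50 × 50 windows centred on the points,
reduced to random 32 × 32 crops with random mirroring and k·90°
rotation (`augment_per_point` crops per point, default 4); validation and
test points contribute the single centred crop.  Points closer than 25 px
to an image border are skipped, never padded — padding would fabricate
plant tissue.  Coordinates are 0-based (x = column), windows half-open.
The 65/20/15 split is at image level, by largest-remainder rounding with
ties to later partitions (so 144 images give a 93/29/22 split);
the assignment is order-invariant and seeded.

**Normalization.** Channel means and standard deviations are fitted on
training patches only; the mean patch is computed on channel-standardized
training patches.  Every patch fed to a model receives channel z-score
followed by mean-patch subtraction, identically at training and test
time.  Applying either elementary step alone is supported
(`apply_normalization` modes), but the composed form is the default
because the two steps are only consistent when applied in that fixed
order on both sides.

**Architectures.** The baseline is the classic two-stage LeNet
(conv 20@5×5 → maxpool → conv 50@5×5 → maxpool → fc 500 → fc 4,
ReLU after the first fully connected layer only, following the canonical
reference implementation).  The main model is a DenseNet-Basic-style
classifier: initial 16-filter 3 × 3 convolution; three dense blocks with
growth rate k = 12 at feature-map sizes 32, 16 and 8, where layer *i* of a
block receives the concatenation of the block input and all preceding
layers' outputs (composite function BN → ReLU → 3×3 conv → dropout);
transition layers of BN → 1 × 1 conv (channel-preserving) → dropout →
2 × 2 average pooling; then BN → ReLU → global average pooling → softmax
over the 4 classes.  Depth per block defaults to 12 (the standard k = 12
configuration); tests and the scaled-down acceptance surface use
`layers_per_block=4`.  The dropout rate (0.2) applies inside blocks and
transitions — the standard setting when training without heavy
augmentation.

**Training protocol.** SGD with momentum 0.9, weight decay 10⁻⁵, base
learning rate 0.001, and a step-down schedule dividing the rate by 10 at
each third of the epoch budget (lr = 0.001·0.1^⌊3e/E⌋, capped at two
steps).  Protocol defaults: batch 64 / 15 epochs for LeNet, batch 8 / 30
epochs for the dense network.  Loss is softmax cross-entropy; the weights
with the best validation accuracy are retained.  Training is
deterministic for a fixed seed.  Initialization is seeded He-normal;
weights pretrained elsewhere can be loaded from file instead.

**Engine.** No GPU framework is used; layers are implemented directly on
float32 channels-last arrays.  Stride-1 convolutions use a shifted-GEMM
scheme: with channels last, shifting the flattened padded tensor by one
receptive-field offset yields a contiguous (positions × channels) matrix,
so a k × k convolution is k² BLAS products accumulated in place, with
wrap-around contamination confined to padding positions that are sliced
away.  Gradients of every layer are verified against central finite
differences in the test suite.

## Whole-image prediction

Test images are tiled into 32 × 32 patches at stride 16 (50 % overlap both
directions), so interior pixels fall in four tiles.  Images are padded
bottom/right with the scene background estimate (median of the four 8 × 8
corner blocks) to a stride multiple; for dimensions divisible by 32 the
tile count is (H/16 − 1)(W/16 − 1), approaching 4× a non-overlapping
tiling as images grow.  Tiles of bare background are excluded before any
normalization by a raw-intensity rule: a tile is background iff the
fraction of pixels whose minimum channel ≥ 230 exceeds 0.99.  Both
constants are configuration-exposed; the white level is defined in raw
units, which is why the test precedes normalization.

## Label reconstruction

Each tile splits into four 16 × 16 sub-patches; a sub-patch collects the
argmax class of every covering foreground tile (up to 4).  Majority vote
decides; a vote tie is broken by the highest mean probability of the tied
classes across the covering tiles; a residual exact tie falls to the
lowest class code, making reconstruction fully deterministic.  A
sub-patch is background iff all covering tiles were background-flagged.
The tie rule averages over the *covering tiles of that sub-patch*, not
over the whole image — a whole-image average would let distant pods
outvote local evidence.  Reconstruction is continuously checked against a
brute-force oracle that enumerates covering tiles from footprint geometry.

## Silique assembly and counting

Per class, 8-connected components of the label image form regions;
components below `min_region_area` (2 sub-patches) are discarded as
speckle.  Candidate objects grow from tip–body border contacts through
shared borders among body↔body, body↔tip and body↔base region pairs; stem
regions are never traversed (they separate pods), and a candidate must
contain at least one tip, one body and one base.  Region-to-region
adjacency is 8-connected: an elongated pod at a steep inclination
regularly hands over from base to body or body to tip across a *diagonal*
cell contact on the 16 px lattice, and requiring an edge contact severs
such pods.

Within a candidate, one tip and one base give one silique.  Otherwise
each tip pairs with its nearest base (Euclidean centroid distance, base
reuse allowed — overlapping pods often share an apparent base).  For
pairings sharing a tip or base, the unsigned angle between their
base→tip vectors, θ = atan2(|u×v|, u·v), decides: θ > 0.05 rad keeps them
distinct siliques, θ ≤ 0.05 rad merges them into one (the longer vector
retained; pairings processed greedily in decreasing vector length).
Length is the base-to-tip centroid distance × 16 px/sub-patch; a skeleton
path length was considered and rejected as the default because the
centroid distance is stable on the coarse lattice and matches the
generator's ground-truth definition.

## Synthetic scenes

The generator emulates a white-background flatbed scan of one mature
inflorescence: a near-vertical stem polyline; pods attached by short
pedicels (32–48 px), alternating sides, fanning upward-outward with
inclinations 0.60–1.15 rad from vertical sorted so that higher pods are
more horizontal (same-side neighbours diverge instead of crossing); and
optional overlapping pairs sharing a base point with a controlled
inter-pod angle.  A pod is a capsule whose distal segment (15 % of
length) is a narrow pale stylar beak (~7.5 px spur after an abrupt
shoulder) and whose proximal segment (14 %) carries blunt pale valve
shoulders, slightly wider than the body and rounded at the pedicel
junction.  The two pod ends share one colour, so the hard tip-vs-base
distinction is separable only by end *shape* — a thin pale line versus a
wide pale blob with a stalk — in any window orientation; body and stem
carry their own green hues, as the chlorophyll-rich valves of real
maturing fruit differ from their pale ends.  This end morphology matters:
with rotation/mirror augmentation a classifier cannot tell a narrowing
band from a widening one unless a landmark (apex or stalk) or an
orientation-free cue (absolute width) is visible in the window, and
windows at test time fall on arbitrary offsets.  Pedicels carry the stem
class: they are stalk tissue, and labelling them as base would chain the
base regions of neighbouring pods into one along the stem.  Annotation
points sit where an annotator would click: just inside the apex beak, on
the shoulder at the pedicel junction, and at interior body/stem pixels
away from segment boundaries.  The mask is rasterized without
anti-aliasing; the image is rendered at 2× and downsampled, then Gaussian
intensity noise (σ = 3) is added around the background level 245.

**Resolvability analysis (why these defaults).** The label image lives on
a fixed 16 px sub-patch lattice, and in the classifier pathway every
32 px tile votes its class onto all four of its sub-patches, dilating
labelled regions by up to ~1.5 cells per side.  The study conditions must
therefore be resolvable *after* that dilation:

* pod width 10–14 px (and a 7.5 px beak) keeps every pod part above the
  per-cell plant-fraction threshold (0.15 of a 16 × 16 block) without
  fragmenting, while the beak stays visibly thinner than the ~19 px
  shoulders;
* pod length 320–460 px makes the 0.05 rad angle rule decidable from
  region centroids (at 0.1 rad, tips of an overlapping pair separate by
  ~30–40 px, about two cells);
* non-overlapping pods keep ≥ 80 px capsule clearance (~5 cells), so
  distinct pods do not fuse after dilation; `scene_spec_for_count` scales
  the canvas height with pod count to preserve that clearance instead of
  dropping pods;
* class labels are confined to plant regions found by pixel thresholding
  (`mask_background`) before counting: plant-vs-background is segmented
  first, the four classes apply only inside it.  Without that step,
  border tiles that catch a sliver of a pod spread class labels into the
  white halo around every organ and neighbouring pods fuse.

These are larger pods on a smaller canvas than a literal 300 dpi scan
(where pods are ~120–240 px on 3,600 × 5,100 images), i.e. the scene is
effectively cropped rather than miniaturized: the sub-patch is the fixed
unit, so pod-to-sub-patch ratios stay in the regime where the angle rule
and region assembly behave as designed.

**Ground truth.** Each scene returns the image, the per-pixel mask,
point annotations (one tip and one base point per pod near the pod ends,
plus randomly sampled body and stem interior points), the true count (a
member of an overlapping pair counts once each), and per-pod lengths
defined as the base-segment-centre to tip-segment-centroid distance — the
quantity the measurement stage estimates.  `downsample_mask` reduces the
mask to the sub-patch lattice (modal plant class where the plant fraction
reaches 0.15), which is the oracle pathway for exercising assembly and
counting without a classifier.

**What the generator does not model.** Photo-realistic texture, scanner
artefacts, curved or twisted pods, branching architecture, dehisced or
damaged fruit, and continuous variation in maturity.  Passing tests on
these scenes demonstrate that the pipeline's geometry, voting and
assembly logic are correct and that the patch classifier can learn
shape-based part distinctions; they do not certify accuracy on real
scans, where published results required training on real annotated
images.

## Evaluation conventions

Confusion matrices are oriented rows = Predicted, columns = Actual.
Under this orientation the reported per-class "precision" is
diagonal/column-sum and "recall" is diagonal/row-sum — the reverse of the
textbook mapping, but the operational definition that reproduces the
published per-class tables cell for cell; totals are unweighted macro
averages (patch-weighted averages do not reproduce the printed totals).
Count agreement reports Pearson r, its square, RMSE and the signed error
vector (actual − predicted) for histogramming.  Classes with empty
rows/columns yield undefined metrics, excluded from macro averages with a
warning.

## Scaled-down acceptance surface

Published real-data figures (validation accuracies of 80.55 %/86.80 %,
count correlations 0.932/0.954, RMSE 20.35/12.45 on 22 images, R² = 0.90
on 2,408 images) require the original scan collections and are not
reproducible from synthetic scenes; the acceptance surface instead runs
the full pipeline at desk scale: an 18-scene training pool (≥ 500
training patches per class after 4× augmentation), the shallow
`layers_per_block=4` dense network trained 10 epochs at batch 32 (batch
size is a throughput choice on one CPU; 8 remains the protocol default),
the LeNet baseline at its own protocol, and 30 held-out scenes with
5–20 pods and one overlapping pair each for the count-agreement measurement.
The directional claim that the dense network is at least as good as the
baseline is asserted as a mean margin ≥ 0 over three seeds on a reduced
benchmark at equal training budget.

## Known limitations

* Counting relies on tips and bases surviving at sub-patch resolution;
  pods much thinner than ~8 px or shorter than ~150 px at 16 px
  sub-patches lose their end regions and are undercounted.
* Overlapping pairs below ~0.12 rad may fuse into a single tip region
  before the angle rule can apply; the rule then (correctly, per its
  definition) counts one silique.  This mirrors the published
  observation that overlapping fruit drives undercounting.
* The nearest-base pairing assumes candidates contain few pods; scenes
  whose pods systematically fuse into large multi-pod regions (heavy
  clutter) degrade counts.
* Lengths are centroid-to-centroid distances on a 16 px lattice and carry
  ±1–2 sub-patch quantization error; strongly curved pods would be
  underestimated (synthetic pods are straight).
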