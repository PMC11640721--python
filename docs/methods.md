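# Methods

## Problem setting

Orbital CT analysis needs three quantities per orbit: eyeball volume
(enophthalmos/proptosis and orbital-surgery planning), optic nerve
sheath diameter (ONSD, a proxy for intracranial pressure), and the
apex-to-eyeball distance (AED, surgical safety margin along the nerve).
All three are derived here from a 3-class voxel labeling of a per-orbit
axial stack, so the pipeline decomposes into segmentation (producing the
labels) and mask geometry (producing the numbers). The package keeps the
two strictly separable: every measurement operates on a label grid plus
voxel spacing, regardless of whether the labels are manual, predicted,
or synthetic.

## Synthetic orbit phantoms

Real orbital CT with per-voxel annotation is scarce and not
redistributable, so validation rests on seeded phantoms with analytic
ground truth.

Each phantom is a 64×64×12 voxel stack at 0.5×0.5×3 mm (the 3 mm slice
thickness matches routine orbital CT; the in-plane crop is a free
parameter of the generator, not a claim about any scanner). It contains:

* an **eyeball**: a sphere, default radius 12 mm; cohort radii are drawn
  uniformly from 11.3–13.3 mm, i.e. volumes of roughly 6–10 cm³, the
  adult range;
* an **optic nerve**: a tube running through the posterior slices to the
  orbital apex with an *elliptical* cross-section (per-slice long/short
  axes, default taper to ~55–75 % at the apex, axis ratio 1.2–1.6, a few
  mm of in-plane drift). The elliptical section is deliberate: with a
  circular tube the longest/shortest-diameter distinction in the ONSD
  formula is degenerate and untested.

Voxel membership is decided at voxel centers (x = column·sx, y = row·sy,
z = slice·sz); this is unambiguous and reproducible. Where eyeball and
nerve would overlap the eyeball takes precedence; the generator keeps the
tube's slice range disjoint from the globe (the nerve starts on the first
slice clear of the sphere), so the analytic ONSD/AED truth is exact under
the precedence rule.

Intensities are class means plus i.i.d. Gaussian noise — background 0,
eyeball 100, nerve 85, noise SD 15. Eyeball and nerve means sit ~1 SD
apart on purpose: per-pixel intensity alone should not separate the two
foreground classes, so the segmentation task retains a shape/position
component. This is the simplest model that makes segmentation
non-trivial yet CPU-learnable. It deliberately omits beam hardening, HU
calibration, bone/fat compartments, partial-volume blur and pathology;
conclusions from passing tests are about the pipeline's correctness and
trainability, not about clinical-grade accuracy on real CT.

Cohorts draw per-subject parameters uniformly from the stated ranges,
generate two mirrored orbits per subject (shared subject id, drift
mirrored in x), and attach sex and age-group labels purely as stratum
annotations for the reporting tools.

## Measurement conventions

* All internal geometry is mm; volumes are reported in cm³ (÷1000),
  diameters and distances in cm (÷10).
* **Area/volume**: area = pixel count × sx·sy; volume = Σ area · sz.
  This equals voxel count × voxel volume exactly; versus the analytic
  sphere it carries a discretization error well inside 5 % at the
  default resolution, shrinking with finer in-plane spacing.
* **Caliper diameters**: computed on the largest 4-connected component
  of the slice, on its half-level (marching-squares) contour — the
  sub-pixel boundary midway between foreground and background pixel
  centers, the same convention scikit-image uses for region properties.
  Longest = max pairwise distance between convex-hull vertices; shortest
  = minimum width over hull-edge support directions (the minimum width of
  a convex polygon is attained flush with an edge). Pixel-center
  boundaries were rejected: they under-measure by up to ~1.4 px in
  oblique directions, violating the one-pixel-spacing recovery tolerance;
  the half-level contour keeps signed errors centered on zero and within
  one pixel spacing for all tested shapes. Degenerate regions (single
  pixel) are floored at one in-plane spacing so the longest ≥ shortest
  > 0 invariant always holds. "Shortest" is the minimum Feret width, not
  the width perpendicular to the longest axis — well-defined for
  arbitrary blobs.
* **ONSD**: measured on the first nerve-bearing slice in stored order
  and the immediately consecutive slice (reported missing if the nerve
  is absent there). Stored order is ascending acquisition index; a
  `reverse_slices` flag flips the convention, since the anatomical scan
  direction is site-specific.
* **AED**: nerve centroids (mean of pixel centers of the largest
  component) on the first and last nerve-bearing slices; n is the slice
  *index gap* (end − start), so a nerve visible in one slice gives
  n = 0 and AED = 0 for a centered tube. The axial term n·sz is a lower
  bound on AED, with equality iff the centroids coincide.
* **Prediction cleanup**: per class, only the largest 3D 26-connected
  component is retained (`clean_prediction`). Off for ground-truth
  masks, recommended for predictions, and kept outside the model module
  so the ablation compares raw network output.

## Segmentation model

A 2D attention U-Net (default depth 3, base width 8, ~28 k parameters)
over per-orbit axial slices. Each skip connection passes through an
additive attention gate: with skip features s and gating signal g (the
upsampled coarser decoder feature), α = σ(ψ(ReLU(W_g g + W_x s))) and
the gate passes s·α, with α ∈ [0,1] by construction (instrumented and
tested). The final 1×1 convolution emits 3-class scores per pixel.

**Slice positional encoding.** The slice index k is embedded as
pe_dim = 8 sinusoidal components, pairs (sin k·ωⱼ, cos k·ωⱼ) with
ωⱼ = 100^(−2j/pe_dim) — the geometric frequency ladder standard for
sequence positions, with base 100 chosen so that stacks up to 64 slices
produce pairwise-distinct encodings with good spread. Components are
broadcast to constant spatial planes and **concatenated** with the image
channel (concatenation rather than addition, because image intensities
and encodings live on different scales). `pe_mode="off"` reduces the
model to a plain single-channel attention U-Net; only the input channel
count changes, never the measurement code path.

**Training.** Adam (lr 2·10⁻³ default), loss = cross-entropy +
soft-Dice equally weighted (the Dice term protects the tiny nerve class
against the ~98 % background imbalance), image channel scaled by 1/100
into unit range, batch 16, folds partitioned **by subject** so both
orbits and all slices of a subject stay on one side of every split (no
left/right leakage). All randomness (phantom noise, parameter draws,
fold shuffling, weight init, batch order) flows from explicit integer
seeds through `numpy.random.default_rng`, which makes phantom
generation, fold assignment and loss curves bit-reproducible on a given
machine.

The network, autodiff and optimizer are implemented in numpy (im2col
convolutions through BLAS; fused softmax cross-entropy; argmax-routed
max-pool gradients). Gradient correctness is verified against central
finite differences in the test suite. Checkpoints are plain `.npz`
arrays plus a JSON config.

## Evaluation protocol

Per-class Dice, IoU, sensitivity and specificity from confusion counts,
aggregated **per volume and then averaged** across held-out volumes
(pooling voxels across volumes would weight large orbits more; the
per-volume unit matches mean ± SD reporting). Empty-vs-empty masks score
Dice = IoU = 1 and sensitivity = NaN (undefined, reported missing).

Agreement between paired measurement sources: RMSE, MAPE (denominator =
ground truth; flagged undefined when a truth value is 0), Bland–Altman
mean difference with 1.96·SD limits, Pearson correlation, two-sample KS
and Mann–Whitney U tests (two-sided, scipy defaults: exact small-sample
p-values without ties, asymptotic/tie-corrected otherwise; the U
statistic is reported in the smaller orientation so identical samples
give n₁n₂/2 and full separation gives 0). α = 0.05 is quoted in reports
with no multiple-testing correction. The outlier rule excludes a subject
only when the relative error exceeds 0.35 in **both** eyes; the
retained subset is labeled "sorted" in reports.

## Problem sizes and observed behavior

Chosen as desk-scale defaults: the held-out training demonstration uses
a 20-subject cohort (40 orbits, 480 slices), one subject-grouped fold of
five, 8 epochs — reaching held-out eyeball Dice ≈ 0.99 and nerve Dice
≈ 0.92 in about a minute and a half on one CPU core. The
positional-encoding ablation runs a 10-subject cohort for 10 epochs over
three seeds per mode.

On these phantoms the ablation does **not** reproducibly favor the
encoding: in-plane appearance (intensity statistics plus cross-section
shape) already determines the class almost everywhere, leaving little
ambiguity for slice position to resolve, and occasionally a PE-on run
fails to pick up the nerve class within the short budget, dragging its
mean down. The comparison is therefore reported as measured rather than
asserted. This is a statement about the phantom family — genuinely 2.5D
ambiguities (structures whose identity depends on stack position at
identical in-plane appearance) are exactly what the phantoms lack and
real orbital anatomy has.

## Known limitations

* Phantom realism: no CT physics, no pathology, no annotation noise;
  segmentation scores on phantoms say nothing quantitative about
  clinical Dice.
* Caliper diameters depend on the chosen digital-boundary convention;
  alternatives (pixel centers, pixel corners) shift results by up to
  about one pixel spacing. The half-level convention is documented and
  fixed.
* Whether the slice-index gap n should count inclusively is ambiguous
  for single-slice nerves; the index-gap convention (n = 0 ⇒ axial term
  0) is used and tested.
* The numpy training stack is single-threaded-friendly but slow beyond
  toy scales; it is meant for reproducible CPU experiments, not
  production training.
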