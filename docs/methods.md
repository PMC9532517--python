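# Methods

This note records the models, parameter choices and numerical conventions
behind `synquant`, and what the synthetic-data validation does and does not
establish about real data.

## Coordinate and calibration conventions

Images are row/column pixel grids, origin at the top-left pixel centre,
0-based; a pixel index maps to physical micrometres as `index × pixel_size`
(isotropic lateral calibration). All downstream geometry — traces, Sholl
radii, puncta centroids, spine measurements — is expressed in μm. Z-stacks
are reduced to 2D by maximum-intensity projection before any thresholding;
thresholds are computed on the analysis image as given (no deconvolution).

## Threshold-mask colocalization counting

Each channel is binarized at `mean + k·SD` computed over **all** pixels of
that channel (a per-image adaptive threshold): k = 2 for the two puncta
channels and k = 1 for the cell-fill channel. Conventions the method text
leaves open, fixed here and logged with every result:

* strict inequality (`intensity > T`), so a constant image yields an empty
  mask for any k ≥ 0;
* population SD (ddof = 0) by default; sample SD is available via
  `sd_kind="sample"`;
* masks — and therefore counts and densities — are invariant under any
  affine intensity map `x → a·x + b` (a > 0), since the threshold
  transforms identically.

Colocalization is the literal pixelwise conjunction of binary masks: the
triple mode requires a shared pixel across puncta-A, puncta-B and
cell-fill masks (any shared pixel; no minimum overlap fraction), the dual
mode across the two puncta masks only (two-marker assays, e.g. a
candidate synaptic protein apposed to PSD95). Connected components use 8-connectivity. The size rule
"smaller than 10 μm" is interpreted as **area-equivalent diameter
strictly below 10 μm** (the diameter of the disk with the component's
area); components at or above the limit are discarded, as are components
below `min_area_px` (default 1 px — the method states only an upper size
bound, so no lower bound is imposed by default). Density is the retained
count divided by the traced dendrite length; the trace enters only as the
length denominator.

## Dendrite tracing and Sholl analysis

The tracer is a transparent stand-in for interactive tracing software
(whose algorithms and parameters are not published): the largest connected
component of the cell-fill mask is skeletonized (Zhang–Suen via
scikit-image), converted to an 8-connected pixel graph with edge weights
of 1 or √2 pixels, reduced to a minimum spanning tree (this removes the
spurious one-pixel triangles an 8-connected skeleton graph contains), and
decomposed into unbranched polylines between junctions and tips. The soma
centre is the centre of the maximal disk inscribed in the mask (argmax of
the Euclidean distance transform). On simulated trees the traced length
agrees with the generating skeleton length to within a few percent; the
residual bias comes from pixelation and from the skeleton entering the
soma disk.

Sholl intersections are counted exactly on the vectorized trace: for each
trace segment and each radius the quadratic `|p0 + t·d − c|² = r²` is
solved and transversal roots with `t ∈ [0, 1)` are counted, so a crossing
at a shared polyline vertex is counted once and tangencies (double roots)
are ignored. Radii form an arithmetic progression with 10 μm step starting
at 10 μm and extend one step beyond the maximal branch extent (the last
ring therefore records 0). Exact crossing counting was chosen over
ring-mask pixel counting to avoid resolution artifacts; a dense-sampling
oracle (0.01 μm sampling, sign-change counting) verifies it in the tests.
Group profiles are compared by pooling each group's per-ring intersection
counts into one sample and applying the two-sample K–S test; per-ring
means ± SEM are reported for plotting, with profiles padded with zeros on
the union radii grid.

## Spine morphometry

Published spine classifiers live inside closed tools with undisclosed
thresholds, so `synquant` implements a transparent geometric equivalent;
results on real data are therefore *comparative* (condition vs condition),
not tool-matching. The shaft is the trace dilated to the local shaft
radius (median distance-transform value along the trace); protrusions are
mask components outside the shaft that touch it. Per protrusion, pixels
are binned by distance from the base (the centroid of the shaft-contact
pixels, bin width 2 px); a bin's width is twice the largest full-mask
distance-transform value it contains — using the full mask avoids the
artificial cut at the shaft reading as a boundary. Length is base-to-tip
(plus ~1.5 px hidden by the cut), head width is the widest distal-half
bin, neck width the narrowest bin between base region and head.
Protrusions longer than 5 μm are discarded as non-spines.

Classification (every constant configurable, defaults follow the common
Rodriguez-style heuristic, applied in order):

1. length > 3 μm → **filopodium**
2. head/neck > 1.1 and head > 0.35 μm → **mushroom**
3. length/head > 2.5 → **thin**
4. otherwise → **stubby**

Filopodia are reported separately and excluded from total spine density.
Manual reclassification is supported as an override table
(index → class or `remove`), not an interactive tool. Spines are measured
in 2D projection; 3D reconstruction is out of scope.

## Behavior scoring

A sample explores object *i* when the nose is strictly closer than 2 cm
to the object's **boundary** (centre distance minus object radius;
boundary distance matches ethological convention and is configurable). A
sample within range of several objects is assigned to the nearest.
Exploration time is sample count over sample rate; the readout is the
percentage of total exploration time per object, flagged undefined when
no exploration occurred. Displaced-object preference across
training/test sessions is compared by one-way ANOVA over the
(session, object) cells followed by Fisher's LSD (pooled-variance
pairwise t, unadjusted, per the classical procedure). No body-orientation
gating is applied — scoring is proximity-only, a documented limitation
relative to video-tracking packages that use head direction.

## Densitometry and the statistical battery

Band intensities are normalized per sample as target / loading-control,
then expressed as fold change over the mean normalized value of the
control group (control mean fold = 1 by construction; normalization is
within-table, with a batch column available).

* **Welch t**: unequal-variance t with Welch–Satterthwaite df, two-tailed.
  Zero-variance degenerate inputs are flagged rather than producing NaN.
* **Dunnett's T3** (authored here; no installed package provides it):
  each group vs control by a Welch-type t; the familywise adjustment
  evaluates the studentized maximum modulus distribution
  `P(max_i |T_i| ≤ m) = ∫ (2Φ(m·s) − 1)^k dG_ν(s)` by adaptive quadrature
  with the per-pair Welch df, reducing to the two-sided t CDF at k = 1 and
  to the Šidák normal quantile at ν = ∞. Adjusted p-values are floored at
  the unadjusted p. Monte-Carlo calibration (10,000 null simulations,
  unequal variances) is part of the test suite.
* **Tukey HSD** via the studentized range distribution (scipy), after a
  standard one-way ANOVA F.
* **K–S**: exact ECDF max-gap statistic with asymptotic p.
* Percent-change summaries use `100·(mean_t − mean_c)/mean_c` with SEM by
  first-order error propagation.

All tests are two-tailed with α = 0.05.

## The simulator: what it emulates, and what it does not

`generate_neuron_image` renders a 1024 × 1024 16-bit field at 0.2 μm/px
(≈205 μm, the acquisition regime of a 60x confocal):

* **Geometry** — a random binary tree from a central soma: primary
  branches at jittered regular angles (default 5), each bifurcating once;
  branch lengths 40–80 μm; tube radius 0.5 μm; soma disk radius 5 μm.
* **Synapses** — exactly `round(true_density × skeleton_length)` centres
  placed on the skeleton by hard-core sampling with 1.0 μm minimum
  spacing (synapses are distinct objects; configurations whose requested
  count exceeds the packing bound are rejected with a clear message),
  excluding the soma neighbourhood. Both puncta channels carry a Gaussian
  spot per synapse, independently offset by up to half the 0.1 μm
  colocalization jitter.
* **Optics and noise** — isotropic Gaussian PSF with σ = 0.15 μm (lateral
  FWHM ≈ 0.35 μm; spots are rendered analytically at sub-pixel centres,
  the cell fill is blurred), amplitude 3000 over background 200, Poisson
  shot noise on the expected signal plus Gaussian read noise (SD 30),
  clipped to 16 bits. With these conditions neighbouring puncta at the
  minimum spacing remain resolvable after thresholding, which is the
  regime the counting method assumes.
* **Confounders** — 0.3 spots/μm-of-skeleton per channel of
  channel-specific distractors placed uniformly over the field, so
  single-channel spots must be rejected by the colocalization step.
* Optional 3-slice stacks (Gaussian axial falloff, independent noise per
  slice) exercise the projection path.

Identical configurations (including the seed) are bit-identical by
construction (`numpy.random.default_rng(seed)` drives every draw).

Deliberately **not** modelled: empty-vesicle biology, axial PSF structure,
chromatic shifts, uneven illumination, dendrite-crossing clutter, bleed-
through, and tissue autofluorescence. Passing the recovery tests shows
the measurement chain is correct and well-calibrated under its stated
assumptions — it does not certify accuracy on real images, where
threshold adequacy and marker specificity must be assessed per dataset.

The spine fixture generator renders a straight shaft with spines drawn
from per-class geometric templates (mushroom 1.6 μm × 0.6/0.2 μm
head/neck; thin 1.8 × 0.24; stubby 0.6 × 0.45; filopodium 3.6 × 0.2, each
with ±5–6% jitter) at 0.05 μm/px, alternating sides — clean masks, so
detection noise is small and cohort comparisons mainly reflect the
planned per-segment density jitter (SD 3%), emulating low within-culture
variability.

Trajectories follow a dwell plan exactly: during a dwell segment the nose
is placed uniformly within the exploration annulus of the target object;
during roaming, rejection sampling keeps it strictly clear of every
object. Band tables draw loading controls and normalized ratios from
unit-mean lognormals with prescribed coefficient of variation (cv = 0
reproduces the group means exactly).

## Problem sizes used in the validation suite

Density recovery uses 10 images per condition at true densities 0.25 and
0.55 puncta/μm (bracketing typical control/knockdown values) plus 10
zero-truth images; spine effect detection uses 15 segments per cohort at
densities 1.00 vs 1.16 /μm on 25 μm segments; the Monte-Carlo
calibrations use 10,000 null replicates (n = 8 per group) and 1,000
power replicates (n = 15, 2 SD shift). These sizes give stable estimates
(the recovery means move by well under a percentage point across seeds)
while keeping the full suite fast on one CPU.

## Known limitations

* The tracer is intended for the length denominator and Sholl profiling,
  not for publication-grade morphological reconstruction; highly
  overlapping arbors or very low cell-fill SNR will fragment the skeleton.
* Dunnett's T3 assumes independence of the comparison statistics given
  the scale estimates (the classical studentized-maximum-modulus
  construction); with a shared control group the comparisons are
  positively correlated, making the procedure slightly conservative —
  visible as a familywise error just above the nominal level in the
  Monte-Carlo check, within its stated ≤ 0.06 bound.
* Spine head/neck widths quantize at the pixel scale (0.05 μm defaults);
  classes whose true geometry sits on a rule boundary can flip under
  resampling.
* Behavior scoring has no orientation gating and treats the nose point as
  given; tracking errors upstream propagate directly.
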