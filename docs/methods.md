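# Methods

## The measurement problem

Viral co-labeling gives two channels per brain section: a red cytosolic
reporter that fills dopaminergic axons, and a green synaptophysin-fused
reporter that concentrates in synaptic boutons. The quantities of interest
are per-mouse axon length and bouton counts in a target region (basolateral
amygdala in the motivating application), normalized by the number of labeled
cells at the injection site to cancel animal-to-animal variation in viral
labeling efficiency, and inter-region labeling intensities expressed as log2
ratios. `axonquant` implements this measurement chain and a matched
synthetic-data generator so that the chain can be validated against exact
ground truth.

## Simulator

**Axon geometry.** Axons are persistent random walks: fixed 2 µm steps with
von Mises-distributed heading increments (concentration `axon_heading_kappa`,
default 12, giving gently tortuous paths; `inf` gives straight lines). Walks
start on an expanded frame so axons enter and leave the field; only in-field
portions are kept, clipped exactly with shapely, and the returned total arc
length is the clipped length. Boutons are a homogeneous Poisson process along
the total arc length, so expected count = linear density × length; every
bouton lies exactly on an axon.

**Image formation.** Each structure is assigned one of the 10 focal planes
(1 µm apart, as in the acquisition protocol being emulated). Axons are
rasterized at their physical width (0.75 µm — about one pixel at the default
0.62 µm/px "10x" calibration); boutons are Gaussian spots of 1 µm FWHM
rendered analytically with subpixel centers; somata are filled discs. Planes
are blurred with an isotropic Gaussian PSF (σ = 0.5 µm default) and then
corrupted by noise: `poisson_gaussian` (default) draws Poisson shot noise on
signal + background and adds Gaussian read noise (σ = 2), `gaussian` adds
purely additive noise. Boutons also render into the red channel at 30% of
their green amplitude — the cytosolic reporter fills boutons too, which is
exactly why single-channel intensity thresholding cannot separate axons from
boutons and a second reporter is needed; reproducing it lets the tests
exercise that difficulty. With background 50 the projected-noise floor has
σ ≈ 7–8, so default bouton peaks sit near SNR 8 and axon ridges near SNR 10.

**Calibration defaults.** 0.62 µm/px for the "10x" mode and 0.25 µm/px for
"25x" work — chosen so a 1 µm bouton spans ~2 and ~4 px respectively, typical
of confocal set-ups at those magnifications; the source protocol names
magnifications but not pixel calibrations, so these are declared defaults,
not inferred values.

**Cohorts.** A cohort draws, per mouse, a single lognormal
labeling-efficiency multiplier (mean 1, CV `mouse_effect_cv`, default 0.2)
that scales both the expected axon count per section *and* the expected
soma count at the injection site — efficiency is a property of the
injection, not of a channel. This is precisely the variation the
cell-count normalization is meant to cancel. Defaults: 5 mice/sex,
20 matched target-region sections/mouse (bregma −3.0 to −1.0 mm), 4
injection-site sections (bregma −3.6 to −3.1 mm) with ~30 somata each
(areas uniform on 49–200 µm², placed with 2 µm clearance so that distinct
somata remain resolvable after projection, as membranes and neuropil keep
them in tissue), male bouton density 0.16/µm vs female 0.08/µm, and region
axon densities NAC:BLA:PFC = 2.0:0.5:0.125 × 10⁻³ axons/µm².

**What the simulator does not emulate:** vascular and autofluorescence
artifacts, depth-dependent PSF widening, axon crossing geometry in 3-D,
bleed-through between sequentially imaged channels, tissue deformation, and
atlas-registration error in ROI placement. Passing tests therefore show the
measurement chain is correct for well-behaved two-channel data, not that it
is robust to every artifact of real histology.

## Detectors

All three detectors share one thresholding principle: filter the projected
image, estimate the *filtered response's* background inside the ROI with an
iterated 3σ-clip initialized at the median/MAD (a plain moment start fails
when signal pixels are numerous but not extreme), and threshold at
`threshold_sd` SDs above that background. Because all filters are
derivative-based, adding a constant to the image changes nothing.

* **Axons.** Ridge response = magnitude of the most negative eigenvalue of
  the scale-normalized Hessian (Gaussian derivatives at σ = axon width;
  reflect boundary handling — constant-zero padding would fabricate border
  ridges). The signed response is used for background estimation so the
  noise distribution stays symmetric. Components under 4 px are removed;
  the mask is thinned to a skeleton, and a final pruning pass removes one
  corner of any residual 2×2 block so the skeleton is strictly one pixel
  wide. Skeleton pixel count × pixel size estimates length with a known
  ~−10% bias (a diagonal pixel run covers √2× its pixel count); the bias is
  direction-averaged and group-independent.
* **Boutons.** Negative scale-normalized LoG at σ = diameter/2√2. Within
  suprathreshold components, boutons are regional maxima with a minimum
  separation of one bouton diameter. Pairs closer than the optical
  resolution (~1.5 µm at the 10x defaults) merge into one detection; at
  0.16/µm linear density this costs ~15–20% of counts, at 0.08/µm roughly
  half that. The bias is density-dependent, so a group at half density reads
  a few percentage points above its true percentage in percent-of-male
  terms — visible in the parameter-recovery experiment and well inside its
  tolerance.
* **Cells.** LoG at the equivalent-disc radius of the mid-range soma area
  (σ = r/√2), 3 SD threshold, holes filled (large somata produce annular
  responses). Because the LoG footprint of any compact object is at least
  the kernel support, component *areas* are measured on the intensity
  image: within each footprint, the soma is the connected region above half
  the plateau height over background (plateau = median of above-threshold
  pixels) — for a PSF-blurred disc the half-maximum contour sits at the
  true edge, making the area estimate unbiased, which the 49–200 µm² gate
  requires. Pieces under 49 µm² are dropped; pieces over 200 µm² are split
  by watershed on the distance transform and each resulting piece
  re-gated (discarding large merges would systematically undercount densely
  labeled animals). A component on the ROI boundary counts if its centroid
  is inside. The response background is estimated over image-background
  pixels only, which keeps the threshold meaningful even when somata cover
  a third of the field.

## Quantification rules

* Z-stacks are reduced by per-pixel maximum projection before any detection.
* ROI polygons are in pixel coordinates; a pixel belongs to the ROI iff its
  center (index + 0.5) lies strictly inside the polygon (even-odd rule) —
  stated so areas are bit-reproducible. `apply_roi` zeroes the outside, as
  in the original workflow's binarized figures, but the pipeline hands
  detectors the unmasked image plus the ROI mask: zeroing first would
  manufacture an artificial edge along the contour that the ridge and blob
  filters then detect.
* Section matching: a section position (ordinal index) enters the totals
  only if every mouse has it; with no common position the cohort is
  rejected rather than silently unbalanced.
* Densities are exact ratios of summed counts to injection-site cell
  counts; percentages divide by the male-group mean (males therefore
  average 100% identically).
* Inter-region intensities: per-mouse regional mean raw intensity (no
  background subtraction; a subtraction toggle is deliberately absent from
  the default path since the reference workflow reports raw means) divided
  by the mouse's injection-site mean, then by the cohort's NAC reference,
  log2-transformed. The NAC reference is the *geometric* mean across mice —
  the arithmetic and geometric forms differ by Jensen's gap, and only the
  geometric form makes the NAC column average exactly zero, the invariant
  the downstream comparison assumes. An `nac_average="arithmetic"` option
  retains the plain-mean convention.

## Statistics

* RM-ANOVA from the explicit sums-of-squares decomposition, F with
  df (k−1, (k−1)(n−1)), uncorrected by default (matching the reporting
  convention of the GUI software this layer mirrors); Greenhouse–Geisser
  epsilon is available as an option. The effect size is the partial form
  η² = F·df₁/(F·df₁+df₂) = SS_cond/(SS_cond+SS_err): this is the form that
  reproduces published effect sizes computed from printed F and dfs, even
  where they are labeled simply "eta squared". An all-equal table returns
  F = 0; zero residual error with a nonzero effect returns F = ∞, p = 0.
* Follow-up FDR control at q = 0.05 via the two-stage
  Benjamini–Krieger–Yekutieli step-up (the follow-up default of the
  common GUI software), with plain Benjamini–Hochberg selectable.
* Two-sample t: auto mode runs a two-sided F test for variance equality at
  α = 0.05 and switches to Welch/Satterthwaite when it rejects;
  Shapiro–Wilk p-values are recorded in the decision trail but do not
  change the test (mirroring a workflow where normality was checked, not
  acted on automatically). Cohen's d uses the pooled SD in all cases; the
  average-variance variant under Welch is not reproducible from typical
  printed summaries, so pooled-SD d is reported with the correction flagged.
* `power_check` simulates two-group cohorts with lognormal per-mouse noise
  and reports the rejection rate of the auto t test — at effect ratio 1 it
  doubles as a type-I calibration.

## Problem sizes and numerical choices

The parameter-recovery experiment uses 256×256 px fields (reduced from
full-frame acquisitions; at 0.62 µm/px this is a 159 µm field holding a
representative axon density), 20 sections × 10 mice per cohort, and 10
cohort seeds averaged; the test suite runs a 3-seed version. Detector
scales, thresholds and gates all live in `DetectionParams`; 10x/25x presets
set 5/7 SD. Degenerate inputs raise rather than guess: empty ROIs,
sub-100-pixel ROIs, zero injection-site cell counts, nonpositive
intensities in ratio computations, and soma packings that cannot satisfy
the clearance constraint.

## Known limitations

* Skeleton-pixel length and merged-puncta counting carry the biases
  quantified above; both are inherent to the pixel-counting method being
  implemented, not implementation defects.
* The area gate is a knife edge: a soma whose true area sits within
  measurement noise of 49 µm² is kept or dropped stochastically.
* 2-D projection merges structures that overlap only in depth; with 10
  planes this is rare for somata but contributes to bouton merging.
* The simulator's per-mouse multiplier is a single global scalar; real
  labeling gradients within a brain are not modeled, so the normalization
  is tested only against global efficiency variation.
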