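# Methods

This note documents the models, numerical choices and limitations behind the
package, in the order data flows through the pipeline.

## Coordinate conventions

Grids are axis-aligned: world (mm) = origin + index · spacing, with 0-based
indices and the origin at the centre of voxel (0,0,0). Anisotropic spacing is
the default working resolution (2.07 × 2.07 × 8.0 mm, left-right ×
anterior-posterior × foot-head). Oblique orientations, DICOM I/O and water-fat
reconstruction from multi-echo data are out of scope; the pipeline starts from
co-registered water and fat volumes.

Deformation fields are stored as dense displacements u(x) in mm on the
reference grid, direction reference → subject: φ(x) = x + u(x) gives the
subject point corresponding to reference point x, so warping subject data into
reference space is a single resampling with no field inversion. Trilinear
sampling returns a configurable background (0 = air) outside the grid;
displacement fields are extended with their nearest edge value instead, so
composition and inversion are exact for globally constant fields. Voxel
coordinates within 1e-9 of an integer are snapped onto it before
interpolation — without this, last-edge voxel centres computed through
world-coordinate arithmetic occasionally land at (n−1)+ε and sample background.

Fat fraction is the *signal* fat fraction fat/(water+fat), clipped to [0,1],
with ff = 0 wherever the combined signal is below 10⁻⁶ of its maximum (avoids
0/0 in air). Whether proton-density fat fraction would differ is irrelevant for
the synthetic data, which is generated on the same definition; with real data
the distinction matters and is deliberately not blurred here.

## Reference phantom

The phantom is a deterministic, grid-normalised geometric body: two legs
(superficial-fat shell over muscle, femur cores), a torso (superficial and deep
subcutaneous shells over a muscle wall; visceral fat, liver and two lungs
inside; spine and pelvis), and two arms with bone cores — six articulated bone
segments in total, every declared tissue label non-empty for any grid of at
least 32 × 24 × 64 voxels. Channel intensities follow tissue type (water high
in muscle/organs, fat high in adipose, both ≈0 in air); bone is rendered as the
brightest water structure so a subject skeleton can also be recovered by
thresholding when no segmentation is supplied. Images are smoothed by a
0.7-voxel Gaussian so that intensity gradients exist for the demons forces;
this also means the body boundary is graded rather than binary (relevant for
threshold-based volume estimates, see below). The phantom makes no claim to
anatomical realism: no atlas meshes, no arm-position variation, no breathing.

## Cohort generator

**Covariates.** Per sex, (height, fat mass, lean mass, WHR) are drawn from a
multivariate normal with marginal means/SDs matching the emulated population
(women: height 166.2 (6.6) cm, fat 26.7 (9.9) kg, lean 42.3 (4.7) kg, WHR
0.87 (0.07); men: 179.2 (6.3), 22.0 (8.8), 60.2 (5.9), 0.93 (0.06)). The
within-sex correlation matrix (height–lean 0.5, fat–WHR 0.4, others 0.2) is an
invention — only marginals are available — and is configurable. Weight is
fat + lean + a fixed per-sex residual mass (2.8 kg women, 3.5 kg men) chosen so
mean weight matches the population (71.8 / 85.7 kg); BMI follows from weight
and height; hip is a linear function of fat mass plus noise and waist = WHR·hip.
Draws violating physiologic floors (masses > 1 kg, 0.5 < WHR < 1.3, height
> 100 cm) are resampled. Because truncating the mass marginals at 1 kg would
bias the delivered mean upward by up to ~0.2 kg (more than the calibration
tolerance at n = 10,000), the pre-truncation mass marginals are calibrated by
inverting the truncated-normal moment map, so the *delivered* marginals match
the table.

**Deformations.** Effects are specified on the log-Jacobian per tissue, per
covariate z-score (defaults: subcutaneous +0.12·z_fat, visceral +0.10·z_fat,
liver +0.06·z_fat, lung −0.08·z_fat, muscle +0.08·z_lean, bone +0.02·z_lean,
upper-body fat +0.05·z_whr). The magnitudes are chosen so that designed
voxel-wise |r| comfortably exceeds the 0.50 reporting threshold at ~150
subjects per sex; no effect-size estimates exist to calibrate against, so they
are explicit configuration, not claims about physiology. The per-label target
map L is smoothed (0.7 voxels) and tapered to zero over a 3-voxel boundary
margin; the displacement is u = ∇ψ with ∇²ψ = exp(L) − 1 solved by a
type-I discrete sine transform (homogeneous Dirichlet boundary), for which
div u = exp(L) − 1 and hence det(I + ∇u) ≈ exp(L) up to second-order terms
(≲2% for |L| ≤ 0.25). This potential-flow construction was chosen over
per-organ radial scaling because it composes correctly across adjacent and
overlapping structures and makes the designed expansion directly testable
against the Jacobian map (interior agreement within 5% is part of the test
suite). Fields are validated to have min J > 0. A side effect worth knowing:
volume change inside an organ is accommodated by compensatory deformation of
its surroundings, so thin compression zones appear at tissue interfaces and
can themselves pass the correlation filter — visible as small negative-sign
clusters at boundaries in cluster tables.

**Rendering.** A subject image is the reference resampled through the inverse
mapping (fixed-point inversion v ← −u(x+v), residual measured as the mean
composition error, tolerance 0.05 mm). The adipose fat fraction is shifted by
0.05·z_fat (clipped to [0,1]) before recomposing the channels, and both
channels receive additive Gaussian noise (default SD 0.02 on an intensity
scale of ~1.0), clipped at zero. Real-data complications deliberately not
modelled: Rician noise statistics, phase/eddy-current errors, water-fat swaps,
partial-volume anisotropy, positioning variation. Subject label volumes are
produced by nearest-neighbour warping of the reference labels and stand in for
the bone pre-segmentation a real pipeline performs.

**DXA readouts.** Measured mass = true mass × exp(N(0, σ)) with
σ = √log(1+CV²), CV 1.5% (fat) and 1.0% (lean) — the stated precision errors
of the emulated instrument. The covariate table carries the measured values;
ground truth retains the true ones.

**Determinism.** Each subject's randomness is keyed by (cohort seed, subject
index) through `numpy.random.SeedSequence`, so cohorts are bit-reproducible
and independent of generation order.

## Registration

Stage 1 estimates one affine per bone segment by least squares over matched
landmark sets: the segment centroid plus the six principal-axis endpoints at
one SD extent. Eigenvector sign is aligned to the reference axes, and within
nearly degenerate eigenvalue groups (rotationally symmetric bones, relative
gap < 0.15) the subject axes are replaced by the projection of the reference
axes onto the degenerate subspace — otherwise symmetric segments pick up
arbitrary spin. When no subject segmentation is given, *both* sides' masks are
derived by the same water-intensity thresholding (≥ 0.85 × max) with
supra-threshold voxels assigned to the nearest reference segment by distance
transform, so landmark sets describe comparable subsets. The affines are
blended into a dense field with inverse-square-distance weights
(w_k = 1/(d_k + 0.5 mm)²) and overwritten exactly inside each segment mask.

Stages 2–3 are a demons-style multi-resolution gradient flow (default 3
levels, 50 iterations/level): force = diff · ∇F / (‖∇F‖² + diff²/K) with
K = (mean spacing)², Gaussian smoothing of the update (2 mm, fluid-like) and
of the accumulated field (1.5 mm, diffusion-like), fixed-image gradients
precomputed per level. The 'ncc' metric option z-scores both images globally
before applying the same force — a normalisation layer, not a local-window
NCC. Convergence stops a level when the relative metric change falls below
1e-4; the best-metric field seen is returned, so the final similarity never
exceeds the initial one. Constraints are hard: displacements inside the frozen
mask (dilated by 1 voxel) are reset to their initialisation every iteration
and bit-exactly at the end. Stage 2 freezes bone on the water channels; stage
3 refines the *whole* field on the fat channels starting from the stage-2
result, freezing bone plus water-dominant lean tissue (water > fat and
water > 0.4 × max) — refining everywhere rather than only adipose regions is
an interpretation, flagged as such. Registration is always reference ← subject
(reference fixed), matching the convention that analysis lives in reference
space.

## Morphometry

J(x) = det(I + ∇u(x)) with central differences in mm (one-sided at grid
boundaries; whole-body summaries use the body mask, which never touches the
boundary). Total volume is Σ J · voxel volume over a mask, in litres. Raw J is
correlated (not log J, not normalised by body volume): the analysis convention
here is local volume itself. Inverse consistency composes the backward with
the forward field and reports the per-voxel displacement norm plus its mean
over the body mask (union of non-air reference labels — the averaging mask is
a package choice). Threshold-based volume checks against rendered images use a
half-maximum criterion on the dense body (excluding lung, whose signal is
below any single threshold separating tissue from the smoothed air boundary).

## Voxel-wise statistics

Pearson r is computed per voxel from mean-centred sums; voxels whose imaging
series has zero variance are marked undefined (NaN), excluded from clusters,
and given p = 1. Spearman ρ is Pearson on mid-ranks (average ranks on ties).
Two-sided p-values use the exact t transform t = r√((n−2)/(1−r²)) with n−2
degrees of freedom; |r| within one ulp of 1 maps to p = 0. An optional
analysis mask marks voxels outside it undefined; the pipeline passes the
reference body mask. This matters specifically for ground-truth-field
analyses: generator Jacobians are noise-free, so air voxels carry
deterministic covariate-driven micro-variation that would correlate perfectly
and produce a spurious whole-air cluster. (With registered fields the same
voxels carry registration noise instead; masking air is the honest convention
in both cases, since air has no tissue to correlate.)

Findings control: connected components (26-neighbourhood, split by sign) of
{|r| > 0.50} are retained only if they have ≥ 10 voxels (the "several adjacent
elements forming a plausible structure" rule made concrete — the count is a
package choice) *and* every member voxel has p < 0.05. The concordance filter
then keeps a cluster only if some opposite-sex cluster of the same sign
overlaps it with Dice ≥ 0.3 and at least half of its voxels have |ρ| > 0.5
with matching sign in its own sex's Spearman map; both operationalisations
(Dice, voxel fraction) are package choices where only qualitative requirements
exist. No formal multiple-testing correction is applied, by design. p-maps are
exported with undefined voxels encoded as p = 1 and r-maps with undefined
voxels encoded as 0.

## Problem sizes and what the tests show

The test suite and analysis scripts run at 32 × 24 × 64 (registration
benchmarks at 48 × 32 × 96), with cohorts of 3–150 subjects per sex and
n = 10,000 for covariate calibration — sizes chosen so the full designed
effect structure is recoverable with wide margins while each analysis stays a
desk-scale computation. Passing tests demonstrate that the pipeline recovers
effects *of the designed form* under the generator's assumptions (smooth
diffeomorphic deformations, Gaussian channel noise, exactly shared anatomy up
to deformation). They do not demonstrate robustness to real-data failure
modes: segmentation errors, breathing artefacts, water-fat swaps, anatomy not
diffeomorphic to the reference (post-surgical, prostheses), or registration
accuracy in thin or poorly contrasted structures. The inverse-consistency
score itself is a necessary-not-sufficient accuracy measure — a registration
biased the same way in both directions can score well.

## Known limitations

- The phantom's mirror symmetry plus noise-free ground-truth Jacobians produce
  exactly duplicated mirror-image clusters; real data would break the tie.
- Boundary-compensation clusters (see above) are a property of the
  volume-conserving field construction, not of the biology being emulated.
- The demons engine is intentionally minimal (no local NCC, no B-spline
  alternative, no GPU); it is adequate for the phantom's contrast and
  deformation scale, not tuned for clinical data.
- Fat-fraction findings at tissue boundaries inherit partial-volume effects;
  containment checks in the tests allow a one-voxel dilation of the adipose
  mask for this reason.
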