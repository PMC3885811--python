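# Methods

This note records the models tractokit implements, the tunable parameters
that matter, what the synthetic data does and does not emulate, and the
design choices made where more than one defensible option existed. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Conventions

World coordinates are RAS millimetres; voxel indices are 0-based and map to
world space by `origin + direction·diag(spacing)·index`. NRRD files in LPS
are converted on read by negating the first two rows of the
space-directions matrix, the first two components of the origin, and the
first two rows of the measurement frame; RAS is always written. Gradient
directions are stored as read (measurement frame applied only when tensor
math needs world-frame directions), with `DWMRI_gradient_NNNN` keys
zero-padded to four digits on write. CSV tables are comma-separated UTF-8
with `.` decimal points, a header row, and strictly increasing arclength in
the first column.

## Tensor model and estimation

The signal model is monoexponential, `S = S0·exp(−b·gᵀDg)`. Estimation
log-linearizes per voxel and solves by ordinary least squares (`lls`) or
with one reweighting pass using weights equal to the predicted squared
signal (`wls`, the default; the iteration count is a parameter). At least
one b=0 volume and six non-collinear directions are required; a design
condition number above 1e6 is refused. Voxels with non-positive mean
baseline are masked out. Signal ratios are floored at 1e-10 before the
logarithm.

Negative-eigenvalue filtering clamps eigenvalues at zero and reconstitutes
the tensor; it is what guarantees FA ∈ [0, 1] downstream. Eigensystems are
sorted descending with a deterministic sign convention (first
non-negligible component of each eigenvector positive, right-handed triple).
GA is the dispersion of log-eigenvalues computed after flooring eigenvalues
at 1e-12 mm²/s — the same ε-floor used before all Log-Euclidean logarithms.
"Fro" is the Frobenius norm of D itself; other conventions rescale it, ours
does not.

Log-Euclidean operations: weighted means are `exp(Σ wᵢ log Dᵢ)` with
weights validated to sum to 1; resampling interpolates log-tensors
trilinearly at the mapped positions and exponentiates. Finite-strain
reorientation (the rotation factor of the local mapping Jacobian's polar
decomposition) is applied by default and reduces to the identity for pure
translations; it can be switched off. Sample positions within half a voxel
of the grid boundary are interpolated with nearest-edge extension —
deciding validity by a half-voxel inside band rather than by the
interpolator's out-of-range behaviour, which zeroes samples at coordinates
like −1e-15.

## Quality control

The slice-wise check computes, per gradient, the normalized cross
correlation (NCC) of every adjacent axial slice pair, standardized across
gradients per slice position with a robust z-score (median/MAD, consistency
factor 1.4826); slice mean intensity is scored the same way but within each
gradient across slices, because per-direction mean intensity differs
legitimately. A gradient is excluded only when a score is both a robust-z
outlier (default thresholds 3.5, baselines 3.0) and materially dropped
(NCC drop > 0.5 absolute; intensity drop > 40% relative — below the natural slice-to-slice variation of textured tissue). The two-part rule
exists because NCC is scale-invariant — a purely attenuated slice is
invisible to it — and because a z-score alone explodes when the MAD is
tiny. These statistics are a documented stand-in for the published QC
tool's unpublished internals; thresholds are package defaults, carried in a
JSON-serializable protocol.

The dominant-direction (vibration artifact) check bins principal
eigenvectors of low-FA voxels (FA < 0.25 by default) on an equal-area
hemisphere histogram (16 azimuth × 8 elevation bins, antipodal
identification) and computes its Shannon entropy in nats. Entropy below
`entropy_low` (default 3.5) is an artifact, between 3.5 and 4.2 suspicious,
above passes; fewer than 100 low-FA voxels gives "insufficient data". The
check is meaningful on tensors estimated from noisy data; on an analytic
phantom the low-FA eigenvectors are degenerate and collapse to one bin.

Deformable motion/eddy correction is out of scope: QC here is detection
plus exclusion, with baseline averaging (all b=0 volumes replaced by their
voxelwise mean, placed first).

## Registration and atlas building

Two deliberately desk-scale engines replace the external registration
tools of the original tool chain:

* **Affine**: 12 parameters maximizing NCC, three resolution levels
  (downsampling 4/2/1 with matched Gaussian smoothing), Powell descent.
  Initialization is phase correlation for same-grid images (peak search
  limited to lags within 25% of the FOV, because periodic structure
  produces aliased peaks) or first-moment alignment otherwise. A weak shrinkage
  penalty (1e-6 per squared linear parameter) keeps the optimizer out of
  distant basins when the correlation surface is flat, and each level runs
  two Powell passes — the restart resets the direction set, which escapes
  stalls on anisotropic correlation surfaces.
* **Greedy demons**: classic force `(f−m)∇m / (|∇m|² + k(f−m)²)`,
  Gaussian-smoothed update and field (σ = 1 voxel each by default),
  multi-resolution, with step halving whenever the field's Jacobian
  determinant would become non-positive. Intensity differences below 0.002
  exert no force — without this tolerance the atlas loops chase their own
  resampling blur and the identical-subject fixed point degrades.

The atlas build follows the staged plan: FA maps (after negative-eigenvalue
filtering) are quantile-normalized to the template or to subject 1
(64 landmarks, foreground = FA > 0.05 so interpolation halos cannot skew
the landmarks; a constant image maps to the reference median). Affine loop
1A registers everyone to the initial reference, loop 1B to the affine
atlas; both loops re-center the transforms by the inverse mean affine so
the atlas frame is the cohort barycentre. The greedy stage alternates
(register all to the current mean FA) / (subtract the mean displacement —
the unbiasedness constraint) / (average), three outer iterations by
default. Two demons refinement passes register against the evolving final
atlas. Global Displacement Fields compose the refinement field with the
inverse 1B affine (atlas → subject), and every stage atlas is produced by
a **single** Log-Euclidean resampling of the original subject tensors
through the composed stage transform — resampling the previous stage's
output instead would blur each stage more than the last and break the
sharpness progression. All registrations run on FA scalar images; all DTI
averaging is Log-Euclidean. With no template the first subject seeds loop
1A; the re-centering and the second loop mitigate, but do not eliminate,
that choice — the test suite checks a permutation-style proxy (identical
subjects reproduce themselves) rather than claiming exact unbiasedness.

## Tractography

Streamlines integrate the principal eigenvector with second-order
Runge-Kutta at 0.5 mm steps, interpolating **log-tensors** and taking the
eigensystem at the sample point (eigenvectors of log D equal those of D, so
this stays within the Log-Euclidean framework and avoids eigenvector
interpolation artifacts). Direction sign follows continuity (flip when the
dot product with the previous direction is negative). Stopping: FA below
0.15, turning angle above 45° per step, or leaving the mask; fibers outside
[10, 300] mm are discarded; seeds require FA ≥ 0.20. Seeds sit at voxel
centres (deterministically jittered for multiple seeds per voxel); the
whole stage is bitwise deterministic. All thresholds are package defaults —
the upstream tools publish none.

## Bundle editing

A fiber passes through an ROI iff any point falls inside an ROI voxel (or
world-space box); keep/remove compose iteratively. Pairwise distances:
centre-of-gravity (centroid distance), mean closest point (symmetrized by
averaging both directions), Hausdorff (symmetrized by max — the
symmetrization is our choice), and Danielsson variants that evaluate the
same statistics against per-fiber Euclidean distance maps voxelized on the
bundle bounding grid (1 mm default) — the speed/accuracy trade the name
implies, accurate to about one voxel diagonal. Threshold clustering uses
single linkage (the published tool's agglomeration rule is not public);
normalized cuts use affinity `exp(−d²/σ²)` with σ defaulting to the median
pairwise distance, recursive two-way bisection by the Fiedler vector with a
sweep for the minimal cut, deterministic tie-breaking by lowest fiber
index.

## Parameterization and profiles

The automatic origin plane passes through the bundle centroid with normal
equal to the mean mid-arclength tangent (antipodally aligned before
averaging); if some fiber misses it, candidate planes through each fiber
midpoint are swept and the best must intersect more than half the fibers.
Signed arclength runs from the interpolated plane intersection, oriented so
the positive normal side is positive bundle-wide (the orientation uses the
sign of the plane-distance change at the crossing, which is robust when a
vertex lies exactly on the plane). Fibers crossing several times use the
crossing nearest their mid-arclength; non-crossing fibers are excluded and
reported.

Profiles are extracted in original subject space: parameterized fibers are
mapped through the Global Displacement Field (arclengths travel unchanged —
correspondence is by atlas arclength), scalar maps are computed on the
original subject tensors, and each fiber point contributes its trilinearly
sampled value to every bin of a uniform grid (2nd–98th percentile of
arclengths, 1 mm step) with Gaussian weight `exp(−(s−s_bin)²/2σ²)`,
σ = one grid step by default. The Gaussian-in-arclength kernel is our
choice; bins with negligible total weight are flagged missing, never
zero-filled.

## Statistics

The varying-coefficient model is fitted pointwise: per-bin least squares of
the subject responses on the design (intercept + named covariates; missing
subjects are dropped per bin, bins with fewer than p+2 subjects are
invalid), followed by local-linear smoothing of each coefficient function
with an Epanechnikov kernel (bandwidth 2× the grid step by default).
Residual curves and the pointwise variance come from the **raw** per-bin
fit — using post-smoothing residuals would let the smoothing bias of a
strong effect inflate the noise estimate and deflate its own test.
Functional PCA of the residual curves retains components to 95% variance
and is reported with the fit. The global test integrates the pointwise Wald
statistic over the tract and calibrates it by a wild bootstrap:
subject-level Rademacher signs applied to residual curves from the reduced
(covariate-removed) model, `p = (1 + #{resample ≥ observed})/(1 + B)`,
B = 1000 by default. This resampling statistic is a stand-in with matched
error control for the published functional test, whose exact form lives in
its own reference. Local tests are χ²₁ Wald p-values with
Benjamini–Hochberg correction (via statsmodels) at q = 0.05. Rare missing
cells are imputed by the per-bin mean inside the bootstrap only, to keep
the resampling algebra dense.

Mapping back onto fibers interpolates the chosen statistics column linearly
between grid bins (nearest-neighbour optional), assigns every value at or
above the significance threshold the sentinel value (the threshold itself),
and leaves geometry bitwise untouched; color tables are the viewer's job.

## Synthetic data: what it emulates and what it does not

Phantoms are straight, arc or crossing bundles of axially symmetric tensors
(default eigenvalues (1.7, 0.3, 0.3)·10⁻³ mm²/s inside, isotropic
0.7·10⁻³ background) with the principal axis along the analytic tangent;
the arc tube drops voxels nearest its endpoints so no straight stubs extend
the bundle. DWI simulation is single-shell monoexponential with Rician
noise (two Gaussian channels) and an optional smooth proton-density
texture — real tissue has spatial structure in every slice, and the QC
slice-correlation statistic is meaningless on a structureless background.

Cohorts place a common baseline FA profile (0.45 + 0.2·exp(−(s/12)²)) plus
per-covariate effect curves on the bundle, with per-bin Gaussian profile
noise, and warp each subject by a Gaussian-smoothed random displacement
field (σ = 4 voxels) scaled to the requested magnitude and verified
diffeomorphic. The bundle radius tapers and bulges
(r(x) = r·(1 + 0.3·cos(2πx/16 mm))) and six fixed anisotropic landmark
blobs sit away from the bundle: a bare straight cylinder is
translation-invariant along its own axis and registration would be
unconstrained there, which no real brain is. Covariates default to age in
weeks drawn uniformly from 11.8–14.5 for eight subjects — the shape of a
small infant study. The generator reports the fraction of profile values
clipped by the FA ceiling; study conditions are chosen so it is zero
(effects are specified per unit of the raw covariate, so an amplitude of
0.018 FA/week at ages ~13 weeks is near the physical limit).

The end-to-end study (`tractokit.workflow.run_study`) uses 14 subjects,
profile noise 0.005, 1.2 mm warps, a 4-voxel bundle radius, and a
compactly supported Tukey-window age effect (amplitude 0.018 FA/week, flat
over |s−5| ≤ 3 mm, cosine-tapered to zero at |s−5| = 6 mm). Compact
support makes "the planted region" unambiguous, and the flat top keeps
statistical power roughly uniform over it. The study also uses
DWI noise 5 (SNR 200), and a reduced atlas schedule
(`fast_atlas_params`). Sizes were chosen so a single-CPU run of the full
battery completes in well under half an hour.

What passing these tests does **not** show about real data: no crossing or
fanning fibers inside the analyzed bundle, no susceptibility or eddy
distortions, no multi-shell effects, no head geometry, and anatomical
variability far smaller and smoother than a real cohort's. Registration
and statistics results here bound the pipeline's behaviour under the
stated model, not under scanner physics.

## Known limitations

* Registration-induced correspondence jitter leaks a small fraction of a
  localized effect into neighbouring arclength bins; with a dozen subjects
  the FDR-significant region is therefore systematically a few millimetres
  wider than the planted support, and subject-level multiplicative
  sampling variability can produce short spurious lobes elsewhere on the
  tract. The global test's wild bootstrap is calibrated against exactly
  this subject-level correlation; the local tests are not fully immune.
* Single-tensor tractography cannot represent crossing fibers; the
  crossing phantom documents (not fixes) that limitation.
* The affine engine assumes overlapping fields of view and benefits from
  same-grid inputs for its phase-correlation initialization.
* GIPL/Analyze volume formats are not read; NRRD, NIfTI-1, legacy VTK
  polydata and CSV cover the pipeline.
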