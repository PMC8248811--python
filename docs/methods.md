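# Methods

This note documents the models and algorithms implemented in `mcatlas`,
the choices made where the design was genuinely open, and what the
synthetic phantoms do and do not establish about behaviour on real
data.

## Problem setting

Spatio-temporal ("4D") atlases of the rapidly developing neonatal brain
require non-rigid registration that works simultaneously on structural
MRI contrasts and on diffusion-derived fibre orientation distribution
functions (ODFs), followed by a temporal model that turns discrete
age-binned templates into continuous maps of development. `mcatlas`
implements both halves: a symmetric multi-channel demons registration
driven by correlation metrics, and voxelwise Gompertz growth-curve
fitting of the resulting template series, warps and affines.

## Spherical-harmonic representation

ODF channels are 4D grids of real, even-order spherical-harmonic (SH)
coefficients. The package-wide convention (documented in
`mcatlas.sh`) is: real orthonormal basis under the uniform spherical
measure (`Y_00 = 1/sqrt(4*pi)`), even degrees `l = 0, 2, ..., L` only
(antipodal symmetry), coefficients ordered (l, m) lexicographically
with `m = -l ... l`, real orders built from the complex harmonics with
Condon–Shortley phase. The coefficient count is `(L+1)(L+2)/2`.

Basis evaluation goes through a cached exact polynomial expansion of
each harmonic in Cartesian direction components (harmonics restricted
to the sphere are polynomials of degree ≤ L, so a dense least-squares
fit of monomial coefficients is exact; it is validated against direct
evaluation when the cache is built and in the test suite).

**Rotation.** SH rotation is performed per degree band by an
evaluate–rotate–refit construction: sample the band-limited function at
a fixed direction set rotated by the inverse rotation, then refit
coefficients with a cached pseudo-inverse. For band-limited input this
is exact up to conditioning (≈1e-14 in practice) and avoids hand-coded
Wigner recursions. A batched variant with a small hemisphere direction
set serves per-voxel reorientation during warping. Reorientation by
exact rotation is this package's substitute for apodized-PSF
reorientation; anyone needing bit-compatibility with pipelines that
apodize should note the difference (apodization parameters are not
standardised).

**Quadrature.** Near-uniform antipodally symmetric direction sets
(sizes 60/300/724, deterministic golden-spiral construction) are used
throughout. Quadrature weights start uniform at `4*pi/n` and receive
the least-norm correction that integrates all even harmonics up to
degree 16 exactly, which makes Gram matrices orthonormal to machine
precision on the 724-point set.

## Similarity metrics and demons forces

Two local correlation metrics drive registration, both computed over a
cubic `(2r+1)^3` neighbourhood (default radius 3 voxels) with uniform
weights via exact separable box filtering (neighbourhoods truncate at
the volume border, where the voxel count shrinks accordingly):

* **LNCC** — local normalised cross-correlation of a scalar channel,
  with the local mean subtracted over the same neighbourhood.
* **LAC** — local angular correlation of two SH images: the same
  construction applied jointly over all `l ≥ 2` coefficients (each
  coefficient image centred by its own local mean, the inner products
  accumulated over neighbourhood *and* coefficient axes). Excluding
  `l = 0` makes the metric exactly invariant to isotropic offsets.

The symmetric demons force pair for either metric is

```
lambda_A(x) = 2 <A,B>/( <A><B> ) * ( B(x) - <A,B>/<A> * A(x) ) · ∇A(x)
lambda_B(x) = 2 <A,B>/( <A><B> ) * ( A(x) - <A,B>/<B> * B(x) ) · ∇B(x)
```

with `A`, `B` the locally mean-centred channel vectors, `< >` the
neighbourhood sums, `∇` the central-difference spatial gradient of the
mean-centred channel images (replicate borders, per-mm via the voxel
spacing) and `·` contracting the channel/coefficient axis. Voxels where
either centred sum of squares falls below `1e-6` of its in-mask mean
are flagged undefined and produce zero force. The forces are invariant
under joint positive rescaling of both inputs; their overall constant
is irrelevant because the registration loop renormalises the step (see
below).

## Certainty-weighted fusion

Each channel's influence is weighted by a certainty map: the spatial
gradient magnitude of the (current, warped) channel — root sum of
squares over SH coefficients for ODF channels — normalised so its
maximum is exactly 1 (identically zero for constant channels). The
fused update is the per-voxel certainty-weighted mean of the channel
forces, computed separately for the two directions of the symmetric
pair with each side's own certainty maps; it is therefore contained in
the per-component envelope of the channel forces. A switch restricts
ODF certainty to the `l = 0` coefficient if desired; the full-SH norm
is the default. (The gradient magnitude is used rather than its
square; since the map is max-normalised, either is a valid monotone
weight.)

## Symmetric multi-resolution demons

Both images deform toward a common midpoint via two half-warps,
preserving the symmetric force semantics and yielding forward and
inverse warps naturally. Per resolution level (default scales
{0.5, 0.75, 1.0} with SH band limits {0, 2, 2}) and per iteration:

1. warp both channel sets by their half-warps (ODF channels reoriented
   by the rotational polar factor of the local warp Jacobian);
2. compute per-channel force pairs — LAC for ODF channels, LNCC for
   scalar and mask channels (masks are driven as soft 0/1 scalars
   during iterations; at the `lmax = 0` level an ODF channel has no
   `l ≥ 2` content, so its isotropic coefficient is driven with LNCC);
3. fuse with freshly computed certainty maps; smooth the fused update
   (Gaussian, 1 voxel); normalise its peak magnitude to the step size
   (0.5 voxel); compose into the half-warps; smooth the composed
   fields (Gaussian, 0.75 voxel).

The demons forces carry no intrinsic length scale, so each iteration is
normalised to a fixed maximum step; convergence is instead decided on
the metric: iteration stops when the mean correlation saturates
(`> 1 - 1e-6`, which leaves already-aligned pairs exactly untouched) or
plateaus (no improvement above 1e-6 for 15 iterations), with per-level
iteration caps (80/60/40 by default) and a divergence guard. Iteration
caps, step size and stopping thresholds are this implementation's own
declared defaults — they are configurable and echoed into every log.

Final warps are composed from the half-warps (`(id+u_B) ∘ (id+u_A)^-1`
and its mirror) on the full-resolution grid. Warp inversion uses the
standard fixed-point iteration with a composition-residual guarantee
(< 0.1 voxel for well-behaved fields). Jacobian maps are central
difference determinants of the total world mapping `x → x + u(x)`.

Affine pre-alignment is a deterministic multi-resolution Powell
maximisation of global NCC over 12 parameters (translation, rotation
vector, log-scales, shears about the image centre). All transforms use
the pull-back convention: they map reference-space points into the
moving image's space.

## Atlas construction

**Stage 1** registers every subject to a single structural reference
with scalar + mask channels and builds one global template per channel
by robust averaging. **Stage 2** re-registers against that template
with the ODF channel added — after normalising each subject's SH image
so its mean isotropic coefficient matches the cohort median — then
bins subjects into fifteen 0.5-week windows over 37–44 weeks PMA
(nearest centre, ties toward the younger window) and averages per
window.

**Robust averaging** (per voxel, per coefficient): values deviating
from the across-subject mean by more than 1.5 population standard
deviations receive weight 0, the rest weight 1; the template is the
weighted mean. At this threshold at least one subject is always
retained, so the average is always defined; retention weights are kept
per channel.

**Unbiasing**: per window, the average of the inverted subject warps,
and the scale/shear-only average inverse affine — each subject's linear
part is polar-decomposed `A = R S`, the symmetric factors averaged in
matrix-logarithm space, the average inverted, rotation and translation
dropped.

## Temporal model

Every scalar template trajectory, SH coefficient, displacement
component and scale/shear entry is fitted with the Gompertz sigmoid

```
G(t) = (alpha - delta) * exp(-exp(-gamma * (tau - t))) + delta
```

(early asymptote `alpha`, late asymptote `delta`, rate `gamma` per
week, peak-growth time `tau` in weeks PMA; the curve is monotone
between its asymptotes). Fitting is nonlinear least squares run as a
Levenberg–Marquardt iteration vectorised across voxels with the
analytic Jacobian and box-projected bounds (`|gamma| ≤ 5`/week, `tau`
within the window range ± 4 weeks). Start values: asymptotes from the
first/last thirds of the series, `tau` at mid-range, `gamma` from the
range-normalised central slope (`e · slope / (delta - alpha)`). An
ordinary linear fit is always computed alongside; `R² = 1 − SS_res /
SS_tot` with the convention `R² = 0` for zero-variance series. Voxels
where the nonlinear fit fails to match the line fall back to a
near-linear parameter set (`gamma = ±1e-3`) and are flagged. Windows
are weighted equally regardless of member count.

Identifiability: with 15 time points, `tau` is localised sharply but
`gamma` is intrinsically imprecise when the per-point noise reaches a
few percent of the curve amplitude — a property of the estimation
problem, not the optimiser (the fitter is cross-checked per voxel
against `scipy.optimize.least_squares`). Template averaging across
window members is what brings the effective series noise down to the
regime where rates are reliable.

The fitted curves form the 4D atlas: evaluation at an age `t` within
the fitted range produces per-channel maps, optionally unbiased by
resampling through the fitted inverse warp followed by the scale/shear
inverse affine (SH channels reoriented), together with the warp's
Jacobian map. No extrapolation outside the fitted range is permitted.

## Parcellation and statistics

The mean absolute rate map over selected channels (`gamma_av`) is
thresholded (default 0.25 per week) and decomposed into 26-connected
components; components below 27 voxels (a 3³ block) are dropped and
labels ordered by size. This reproduces the automatic part of
transient-compartment delineation; manual refinement is intentionally
out of scope. Region statistics use the same 1.5-SD robust mean as
template construction. Associations between regional metrics and
gestational age at birth are ordinary least squares with age at scan as
covariate, one test per (region, channel), Bonferroni-corrected by
multiplying p by the number of tests (capped at 1).

## Synthetic phantoms

The generator emulates the *structure* of a co-registered multi-channel
neonatal dataset at desk scale: an ellipsoidal brain with a cortical
ribbon, an off-centre ventricle and two orthogonal crossing WM bundles;
T2w-like (falling) and T1w-like (rising) scalar channels; cortex and
ventricle masks; an `lmax = 4` ODF channel with Watson-like single-fibre
lobes and a genuine two-peak crossing region. Every voxel's scalar
trajectory in age is exactly Gompertz: the parameter maps are smoothed
mixtures of per-tissue values (rates 0.3–1.3 per week, peaks
40.0–41.0 weeks PMA, chosen as representative of late-gestation signal
maturation) plus a static texture on the asymptotes. Subjects are the
template at their age deformed by a seeded sum of low-frequency
sinusoidal displacements (default 2-voxel amplitude, 24-mm wavelength,
Jacobian positivity enforced at generation) with additive noise at 5%
of each channel's dynamic range.

What passing phantom tests establish: the metric formulas, force
fields, fusion, warp algebra, averaging rules, temporal fit and the
pipeline's plumbing are correct, and registration recovers known smooth
deformations to sub-half-voxel accuracy with the ODF channel
contributing measurably in fibre-coherent regions. What they do not
establish: performance under real cortical folding geometry, bias
fields, acquisition artefacts, reconstruction-correlated noise, or
anatomically realistic fibre configurations — the phantom is schematic
by design and makes no attempt to simulate DWI acquisition.

## Numerical choices and degenerate inputs

* Interpolation is trilinear with replicate borders everywhere; masks
  are re-thresholded at 0.5 only when materialised as outputs.
* Downsampling applies Gaussian anti-alias smoothing matched to the
  spacing ratio.
* Polar rotation factors use a scaled Newton iteration with an SVD
  fallback (reflection-repaired) where a field locally folds.
* Constant images give all-zero certainty; zero total certainty gives
  a zero fused update; undefined-metric voxels give zero force.
* Robust averaging with a single member passes the image through.
* The ε-guard threshold, smoothing sigmas and stopping thresholds are
  configuration fields with the defaults above.

## Known limitations

* Reorientation is exact rotation rather than apodized-PSF
  reorientation; small differences from MRtrix-based pipelines are
  expected in sharp-fibre regions.
* The demons scheme is compositive with Gaussian regularisation, not a
  full scaling-and-squaring diffeomorphic exponential; invertibility is
  monitored (Jacobian determinant), not guaranteed.
* Rate estimates from few, noisy time points are imprecise (see
  identifiability above); interpret `gamma` maps from small cohorts
  with caution.
* Problem sizes in the shipped tests (48³ single-subject recovery, 24³
  six-subject pipeline) are the package's reference desk-scale
  conditions; real cohorts run the same code paths at higher cost.
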