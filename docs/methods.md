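# Methods

`cellwarp` registers pairs (or stacks) of 2-D grayscale images of cellular
materials — the motivating case is X-ray microtomography slices of softwood
at two moisture states — and maps the local deformation as strain fields.
This note records the model, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Transformation model

The map from fixed-image coordinates to moving-image coordinates is the sum
of a global affine transform and a local free-form deformation (FFD):

    T(x, y) = A·(x, y) + b + T_local(x, y)

`T_local` is parameterized by a lattice of control-point displacement
vectors Π with uniform spacing δ, blended by tensor-product uniform cubic
B-splines over the 4×4 support of each pixel:

    T_local(x, y) = Σ_{l=0..3} Σ_{m=0..3} B_l(u) B_m(v) Π_{i+l, j+m}

with `i = ⌊x/δ⌋ − 1`, `u = x/δ − ⌊x/δ⌋` (likewise j, v).  The lattice
carries one extra ring of points beyond every image edge so the support is
always complete.  Coordinates are 0-based and pixel-centered; x is the
column (tangential) direction and y the row (radial) direction.  δ sets the
resolution of the non-rigid registration: large spacing captures global
trends, small spacing highly local deformation.

Warping is backward: output pixel p samples the moving image at T(p) by
bilinear interpolation, with out-of-domain samples clamped to the nearest
edge pixel (no holes, and the similarity stays defined near borders).

## Cost function

Registration minimizes

    C(T) = −S(T; I_F, I_M) + γ·P(T)

* **Similarity S.**  Negated per-pixel mean squared difference (SSD) by
  default.  The mean (rather than the raw sum) makes γ transferable across
  image resolutions, which the pipeline relies on when it reuses γ between
  a downsampled stage and a full-resolution stage.  Mutual information (in
  bits, from the joint 64-bin histogram) is provided for image pairs whose
  gray-level histograms diverge: when Σ|hist(I_M) − hist(I_F)| on unit-mass
  64-bin histograms exceeds 0.25, MI is the appropriate measure.  Same-
  material moisture pairs fall well below that threshold, so SSD is the
  operative path; the optimizer differentiates SSD only.  The bin count and
  unit-mass normalization are our choice — the 0.25 threshold is only
  meaningful on normalized histograms.
* **Penalty P.**  The bending energy: the area-averaged integral of squared
  second derivatives of the transform, `(T_xx)² + (T_yy)² + 2(T_xy)²`,
  summed over both displacement components.  It is evaluated exactly for
  the spline family from the analytic second-derivative bases on the pixel
  lattice (quadrature = pixel sum / area) and is identically zero for any
  affine transform, so it penalizes only implausible oscillation of the
  lattice.  P is quadratic in the control coefficients; its Hessian is
  precomputed and cached per (image shape, lattice) pair.

## Optimization

The affine part is optimized first (phase-correlation translation
initialization — kept only if it actually lowers the SSD, since phase
correlation can lock onto a period of repetitive structure — followed by
steepest descent on six parameters expressed in "edge motion" units for
conditioning).  The FFD stage then optimizes the control displacements with
the affine frozen.

Steepest descent steps along the negative analytic gradient — the exact
chain rule through the bilinear interpolant for the SSD term, the exact
quadratic-form derivative for the penalty — with one of two line searches:

* *parametric* (default): bracket a decrease by doubling/halving the trial
  step, then take the minimizer of the quadratic through the last three
  samples, clipped to the bracket;
* *wolfe*: a standard strong-Wolfe search (Armijo c₁ = 1e−4, curvature
  c₂ = 0.9).

Iteration stops when ‖∇C‖ ≤ χ or after `max_iters` (default 200).  Because
the cost is a per-pixel mean, its gradient entries are small numbers; the
default χ = 1e−7 is chosen on that scale (a looser χ such as 1e−4 stops a
barely-started search immediately).  The first trial step is scaled so the
largest control-point motion is `step_init` (default 0.5 px); subsequent
searches start from twice the previously accepted step.  Accepted steps
never increase the cost, and the optimizer contains no randomness.

## The three registration branches

* **Registration 1 (constrained, coarse).**  Both images are downsampled
  (factor 2 by default, anti-aliased), the FFD is optimized with the large
  weight γ₁ (default 1e−2), and the recovered displacement field is lifted
  back to full resolution (coordinates and displacements scaled, then
  condensed onto a full-resolution lattice by linear least squares).  R1
  captures the global, smooth part of the deformation.
* **Registration 2 (free, fine).**  Full-resolution FFD with the small
  weight γ₂ (default 1e−4; the bending validation uses 1e−3), initialized
  from R1's field (resampled onto R2's lattice).  More lattice freedom
  detects local misalignment but can introduce artifacts.
* **Registration P (point-based).**  Feature points are extracted in the
  fixed image (Map = boundary pixels of the thresholded foreground with an
  Otsu default threshold; Skeleton = morphological skeleton; Harris corner
  maxima; Canny edge pixels; or a manual list).  Each point is located in
  the moving image by normalized cross-correlation of an 11×11 patch over
  integer lags within ±4 px, refined on a 0.1-px grid of bilinear-resampled
  fractional lags within ±0.5 px — one-tenth-of-a-pixel adjustment, with
  zero-variance or low-correlation (< 0.5) pairs dropped.  The pairs are
  augmented with the nodes of an artificial regular grid (default spacing
  16 px) mapped through a least-squares affine — or, by option, quadratic —
  fit of the feature pairs, so featureless regions stay anchored.  An FFD
  approximating the pair displacements is then fitted (below), and a short
  refinement loop re-matches the features against the current warped moving
  image — which compensates the in-window deformation that biases a purely
  translational NCC — recomposes and refits, stopping as soon as the pixel
  error reaches a minimum (at most 3 passes).

The **scattered-data FFD fit** first removes the affine trend of the pair
displacements by linear least squares and carries it on the control lattice
exactly (uniform cubic B-splines reproduce affine fields from lattice
samples), so constant or affine pair displacements are reproduced exactly
everywhere.  The detrended remainder is fitted by multilevel B-spline
approximation: coarse-to-fine lattice spacing halving down to the target
spacing, each level approximating the residual displacements with the local
weighted-least-squares control-point formula; a level that fails to reduce
the mean pair residual is skipped, making the residual monotone.  The level
sum is finally condensed onto a single lattice by linear least squares.  A
penalized one-shot least-squares fit was evaluated as an alternative and
rejected: it extrapolates poorly outside the data hull and follows matching
noise at fine spacings, where the multilevel approximation smooths both.

## Error metric, branch selection, local fields

The error of a branch is the fraction of pixels whose absolute intensity
difference between the fixed and the warped moving image exceeds a
tolerance (default 2/255 on unit-range images — robust to interpolation
rounding while counting true mismatches).  The branch with the smallest
error wins; exact ties break R2 > RP > R1 (prefer the intensity branch that
uses every pixel, then the freer lattice).  Each branch is also guarded
against its own affine-only starting point: the optimizer guarantees a
non-increasing SSD, but the pixel-count error is a different functional,
and a constrained or downsampled stage can push sub-tolerance pixels across
the threshold; a branch that scores worse than the pure-affine warp reports
the affine warp instead.

The artifact-suppressed local deformation is the pointwise difference
between the selected fine branch's displacements and R1's (R2 − R1 by
default).  The subtraction direction is exposed as a sign flag because the
strain signs depend on it and the convention is genuinely ambiguous in the
method's description (its overview text and its results section state
opposite orders); we fix fine − reference as the default.

## Strain mapping

Small-strain components from the displacement gradient by central
differences (one-sided at borders; the outer 2-px band is unreliable):

    ε_x = ∂U_x/∂x     ε_y = ∂U_y/∂y     ε_xy = ½(∂U_x/∂y + ∂U_y/∂x)

and the von Mises equivalent strain in its plane simplification

    ε_eq = sqrt(ε_x² + 2·ε_xy² + ε_y²)

The symmetric (tensor) shear convention is used — that is what makes the
2ε_xy² term the plane von Mises form; hygroscopic swelling strains are a
few percent, well inside the small-strain regime, so no finite-strain
tensor is needed.  Total normal strains add the affine small-strain
constants (A₁₁−1, A₂₂−1) to the non-rigid maps.

## Synthetic benchmarks: what they emulate, and what they do not

Real validation data (tomographic volumes at two humidities) cannot ship
with a desk-scale package, so ground truth comes from analytic deformation
fields applied to generated phantoms:

* **Grid phantom** — dark blurred lines on a bright background, defined as
  a *continuous* analytic pattern (box profiles convolved with a Gaussian,
  closed form via erf).  Deformed copies are sampled from the continuous
  pattern directly.  This matters: synthesizing the moving image by
  resampling a discrete phantom freezes interpolation error into the data,
  and at the 2/255 tolerance that error alone dwarfs the registration
  signal.  Defaults: 16-px line spacing, 3-px linewidth, blur σ = 2.5 px —
  chosen so the bilinear-interpolation floor of the pixel-difference metric
  (≈ 0.001–0.006 on the benchmarks) sits well below the error levels being
  compared, emulating the partial-volume smoothness of real tomograms.
* **Cellular phantom** — Voronoi cells whose wall phase is thresholded by
  the seed-distance margin, with the threshold set by quantile so the void
  fraction matches a porosity target (0.78 emulates earlywood, 0.45
  latewood); an optional vertical band of smaller cells mimics a ray.
* **Fields** — pure bending (U_x = κ·x̃·ỹ, U_y = −κ·x̃²/2 about the image
  center: zero affine component, nonzero second derivatives, strain linear
  through the thickness with a sign change at the neutral axis), uniform
  swelling, a smooth slip band, and a random seeded FFD.  Amplitudes are
  enforced as bounds and fields are rejected if the map folds (Jacobian
  ≤ 0).
* **Pairs** — the moving image is the phantom evaluated through the
  numerically inverted field (fixed-point iteration to 1e−6 px), so the
  returned truth is directly the field a perfect registration should
  recover, and warping the moving image by the truth reproduces the fixed
  image up to interpolation.  Optional independent Gaussian noise is seeded.

The **bending validation** (`cellwarp validate-bending`,
`scripts/acceptance.py`) bends a 128×128 grid phantom by at most 4 px and
runs all three branches with γ₁ = 0.01, γ₂ = 0.001 and Map extraction.  The
grid is confined to a centered square specimen with a flat background
margin: a bent specimen must stay inside the field of view, otherwise
content leaving the frame creates an irreducible border error that has
nothing to do with registration quality.  The artificial-grid nodes are
mapped with the quadratic option here because the bending field is exactly
quadratic — an affine node map would inject model error by construction;
the general default remains affine.

Passing these benchmarks shows the machinery recovers known smooth
deformations to a few hundredths of a pixel on clean, high-contrast,
noise-free patterns.  It does not demonstrate robustness to tomographic
noise, intensity drift between moisture states, real cell-wall texture, or
out-of-plane motion — the 2-D slice-by-slice model assumes deformation is
predominantly in-plane.

## Numerical choices and degenerate inputs

* Problem sizes: benchmarks run at 64–128 px with control spacings of
  8–16 px, the regime where every property is measurable in seconds on one
  core.
* `fit_grid_to_field` solves ridge-regularized (1e−10) normal equations —
  exact to solver precision for in-span fields.
* Zero-variance NCC patches are dropped with a recorded reason; texture-
  free images make the point branch unavailable rather than failing the
  pipeline; per-slice failures in a stack are logged and reported while the
  remaining slices proceed.
* Bilinear sampling clamps to the image edge; its analytic gradient is
  zero where a coordinate is clamped, consistent with the clamped value.
* Everything is deterministic: phantom and noise generation flow from a
  single recorded seed; the registration itself contains no randomness.

## Known limitations

* 2-D only; volumetric (3-D) B-spline registration is out of scope.
* MI is available as a measure but the optimizer differentiates SSD only.
* The affine pre-registration is deliberately minimal plumbing (SSD descent
  with phase-correlation initialization), not a full affine registration
  model.
* The pixel-difference error saturates near the bilinear-interpolation
  floor; errors below ~1e−3 on textured images are not meaningfully
  comparable.
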