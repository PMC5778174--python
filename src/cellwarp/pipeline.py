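"""Registration pipeline: affine pre-registration, three non-rigid branches,
error-based branch selection, local-field extraction, slice-by-slice stacks.

For every slice pair the pipeline runs:

* affine pre-registration (global transform, plumbing for the FFD stages);
* ``Registration 1`` — a rough, fast FFD on downsampled images with a large
  regularization weight γ₁ (heavily constrained, captures global trends);
* ``Registration 2`` — an FFD on the original images with a small γ₂ (more
  lattice freedom, captures local misalignment but can introduce artifacts);
* ``Registration P`` — the feature-point branch (optional).

The error of each branch is the fraction of pixels whose intensity still
differs beyond a tolerance after warping; the branch with the smallest error
is selected.  Artifact-suppressed local deformation is obtained by
subtracting the constrained branch's displacements from the selected finer
branch's (R2 − R1 by default; the sign is configurable since strain signs
depend on it).  Everything is deterministic for a given configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import Optional, Sequence

import numpy as np
from skimage import registration as skreg
from skimage import transform as sktransform

from .grid_transform import (
    AffineParams,
    DisplacementField,
    Image2D,
    Transform2D,
    build_grid,
    evaluate_local,
    fit_grid_to_field,
    transform_field,
    warp,
)
from .objective import choose_similarity
from .optimize import OptimizerConfig, minimize_steepest_descent, steepest_descent
from . import points as pointsmod
from . import strainmap

logger = logging.getLogger("cellwarp")

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "SliceReport",
    "affine_preregister",
    "registration1",
    "registration2",
    "registrationP",
    "registration_error",
    "select_best",
    "local_field",
    "run_pair",
    "run_stack",
]

#: Branch preference used to break exact error ties: intensity branches that
#: use every pixel win over the point branch, and the freer lattice wins
#: over the constrained one.
TIE_BREAK_ORDER = ("R2", "RP", "R1")


@dataclass
class RegistrationConfig:
    """Settings for the three-branch registration of one slice pair.

    gamma1, gamma2:
        Penalty weights for the constrained (R1) and free (R2) branches;
        γ₁ > γ₂ so R1 stays smooth and R2 gains lattice freedom.  Defaults
        are the cellular-tissue settings (1e−2 / 1e−4); the synthetic
        bending validation uses 1e−2 / 1e−3.
    downsample_factor:
        Integer image-size reduction for R1.
    spacing_r1:
        Control-point spacing on the *downsampled* R1 image (so the
        effective full-resolution spacing is spacing_r1 × factor).
    spacing_r2, spacing_rp:
        Full-resolution control-point spacings of R2 and the point branch.
    point_method:
        Feature technique for RP: map, skeleton, harris, edges or manual.
    grid_spacing_rp / grid_map_order:
        Artificial-grid spacing and the order of the fit used to map its
        nodes to the moving image (1 = affine, 2 = quadratic).
    tol:
        Intensity tolerance of the pixel-difference error (unit range).
    """

    gamma1: float = 1.0e-2
    gamma2: float = 1.0e-4
    downsample_factor: int = 2
    spacing_r1: float = 16.0
    spacing_r2: float = 8.0
    spacing_rp: float = 8.0
    point_method: str = "map"
    point_params: dict = dfield(default_factory=dict)
    grid_spacing_rp: float = 16.0
    grid_map_order: int = 1
    ncc_window: int = 11
    ncc_search: int = 4
    tol: float = 2.0 / 255.0
    optimizer: OptimizerConfig = dfield(default_factory=OptimizerConfig)
    enable_rp: bool = True
    rp_refine_iters: int = 3
    r2_init_from_r1: bool = True
    local_field_sign: int = 1

    def __post_init__(self) -> None:
        if not self.gamma1 > self.gamma2 >= 0:
            raise ValueError("need gamma1 > gamma2 >= 0 "
                             "(R1 constrained, R2 free)")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.local_field_sign not in (1, -1):
            raise ValueError("local_field_sign must be +1 or -1")


@dataclass
class RegistrationResult:
    """One branch's output on one slice pair."""

    branch: str
    transform: Transform2D
    warped: Image2D
    displacement: DisplacementField
    error: float


@dataclass
class SliceReport:
    index: int
    errors: dict
    chosen: str
    unregistered_error: float
    affine: AffineParams
    local: Optional[DisplacementField] = None
    strain: Optional[strainmap.StrainField] = None
    failed: Optional[str] = None


# ---------------------------------------------------------------------------
# Error metric and branch selection
# ---------------------------------------------------------------------------

def registration_error(fixed: Image2D, registered: Image2D,
                       tol: float = 2.0 / 255.0) -> float:
    """Fraction of pixels whose intensity difference exceeds ``tol``."""
    if fixed.shape != registered.shape:
        raise ValueError("image shapes differ")
    if tol < 0:
        raise ValueError("tol must be non-negative")
    return float(np.mean(np.abs(fixed.pixels - registered.pixels) > tol))


def select_best(results: Sequence[RegistrationResult]) -> RegistrationResult:
    """Branch with the smallest error; documented priority breaks ties."""
    results = [r for r in results if r is not None]
    if not results:
        raise ValueError("no registration results to select from")
    rank = {b: i for i, b in enumerate(TIE_BREAK_ORDER)}
    return min(results, key=lambda r: (r.error, rank.get(r.branch, len(rank))))


def local_field(reference: RegistrationResult, fine: RegistrationResult,
                sign: int = 1) -> DisplacementField:
    """Artifact-suppressed local deformation: fine − reference displacements."""
    if reference.displacement.shape != fine.displacement.shape:
        raise ValueError("displacement shapes differ")
    return DisplacementField(
        sign * (fine.displacement.u_x - reference.displacement.u_x),
        sign * (fine.displacement.u_y - reference.displacement.u_y))


# ---------------------------------------------------------------------------
# Affine pre-registration (minimal plumbing for the global transform)
# ---------------------------------------------------------------------------

def affine_preregister(fixed: Image2D, moving: Image2D,
                       cfg: Optional[OptimizerConfig] = None) -> AffineParams:
    """6-parameter affine minimizing SSD (penalty is zero for affine maps).

    Translation is initialized by phase correlation, then all six parameters
    (parameterized about the image center for conditioning) are refined with
    the same steepest-descent machinery as the FFD stage.  Returns identity
    if the search diverges.
    """
    if fixed.shape != moving.shape:
        raise ValueError("image shapes differ")
    if cfg is None:
        cfg = OptimizerConfig(chi=1e-7, max_iters=150, step_init=0.25)
    h, w = fixed.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    shift, _, _ = skreg.phase_cross_correlation(fixed.pixels, moving.pixels,
                                                normalization=None)
    # warped(p) = moving(p + t): fixed(p) ≈ moving(p − shift) ⇒ t = −shift.
    # phase correlation can lock onto a period of repetitive structure, so
    # only keep the initialization if it actually lowers the SSD
    t0 = np.array([-shift[1], -shift[0]])
    ys, xs = np.mgrid[0:h, 0:w]
    xc = (xs - cx).ravel()
    yc = (ys - cy).ravel()
    fpx = fixed.pixels.ravel()
    n = fpx.size
    from .grid_transform import sample_bilinear

    # variables are expressed in "edge motion" units: a unit change in any
    # component moves the farthest pixel by about one pixel, which keeps
    # plain steepest descent well conditioned across the six parameters
    scale = np.array([max(cx, 1.0), max(cy, 1.0),
                      max(cx, 1.0), max(cy, 1.0), 1.0, 1.0])

    def unpack(theta_scaled):
        theta = theta_scaled / scale
        a = np.array([[1 + theta[0], theta[1]], [theta[2], 1 + theta[3]]])
        t = theta[4:6]
        return a, t

    def fun_grad(theta_scaled):
        a, t = unpack(theta_scaled)
        sx = a[0, 0] * xc + a[0, 1] * yc + cx + t[0]
        sy = a[1, 0] * xc + a[1, 1] * yc + cy + t[1]
        vals, gx, gy = sample_bilinear(moving.pixels, sx, sy, with_gradient=True)
        r = vals - fpx
        f = float(np.mean(r * r))
        coef = 2.0 / n * r
        g = np.array([
            np.sum(coef * gx * xc), np.sum(coef * gx * yc),
            np.sum(coef * gy * xc), np.sum(coef * gy * yc),
            np.sum(coef * gx), np.sum(coef * gy),
        ])
        return f, g / scale

    theta0 = np.zeros(6)
    theta0[4:6] = t0
    f_init, _ = fun_grad(theta0 * scale)
    f_id, _ = fun_grad(np.zeros(6))
    if f_id <= f_init:
        theta0[4:6] = 0.0
    try:
        theta, _trace = minimize_steepest_descent(fun_grad, theta0 * scale, cfg)
    except FloatingPointError:
        logger.warning("affine pre-registration diverged; returning identity")
        return AffineParams.identity()
    a, t = unpack(theta)
    # translation in standard (uncentered) form: A x + b
    b = t + np.array([cx, cy]) - a @ np.array([cx, cy])
    return AffineParams(a, b)


# ---------------------------------------------------------------------------
# Branches
# ---------------------------------------------------------------------------

def _result(branch: str, fixed: Image2D, moving: Image2D, t: Transform2D,
            tol: float) -> RegistrationResult:
    warped = warp(moving, t)
    return RegistrationResult(
        branch=branch,
        transform=t,
        warped=warped,
        displacement=transform_field(t, fixed.shape),
        error=registration_error(fixed, warped, tol),
    )


def _guard_against_baseline(res: RegistrationResult, fixed: Image2D,
                            moving: Image2D, affine: AffineParams,
                            cfg: "RegistrationConfig") -> RegistrationResult:
    """Never let a branch report worse than its affine-only starting point.

    The optimizer guarantees a non-increasing SSD cost, but the reported
    error counts pixels beyond a tolerance — a different functional — and a
    constrained or downsampled stage can nudge sub-tolerance pixels across
    it.  The pipeline already selects by this pixel error, so each branch
    falls back to the pure-affine warp whenever that scores better.
    """
    baseline_t = Transform2D(affine, build_grid(fixed.shape, res.transform.local.spacing))
    baseline = _result(res.branch, fixed, moving, baseline_t, cfg.tol)
    return res if res.error <= baseline.error else baseline


def _downsample(img: Image2D, factor: int) -> Image2D:
    if factor == 1:
        return img
    h, w = img.shape
    out_shape = (max(1, h // factor), max(1, w // factor))
    small = sktransform.resize(img.pixels, out_shape, order=1,
                               anti_aliasing=True, mode="edge")
    return Image2D(small, pitch=None)


def registration1(fixed: Image2D, moving: Image2D, cfg: RegistrationConfig,
                  affine: Optional[AffineParams] = None
                  ) -> RegistrationResult:
    """Constrained coarse branch: FFD with γ₁ on downsampled images."""
    if affine is None:
        affine = AffineParams.identity()
    f = cfg.downsample_factor
    fixed_s = _downsample(fixed, f)
    moving_s = _downsample(moving, f)
    # affine scaled to the small frame: T_s(x') = A x' + b/f
    affine_s = AffineParams(affine.matrix, affine.translation / f)
    t0 = Transform2D(affine_s, build_grid(fixed_s.shape, cfg.spacing_r1))
    t_s, trace = steepest_descent(fixed_s, moving_s, t0, cfg.gamma1,
                                  cfg.optimizer)
    # lift the coarse local field to full resolution: u(x) = f · u_s(x/f)
    h, w = fixed.shape
    ys, xs = np.mgrid[0:h, 0:w]
    hs, ws = fixed_s.shape
    coords = np.stack([np.clip(xs.ravel() / f, 0, ws - 1),
                       np.clip(ys.ravel() / f, 0, hs - 1)], axis=1)
    disp = evaluate_local(t_s.local, coords) * f
    full_field = DisplacementField(disp[:, 0].reshape(h, w),
                                   disp[:, 1].reshape(h, w))
    full_grid = fit_grid_to_field(full_field, cfg.spacing_r1 * f)
    t_full = Transform2D(affine, full_grid)
    res = _result("R1", fixed, moving, t_full, cfg.tol)
    res = _guard_against_baseline(res, fixed, moving, affine, cfg)
    res.trace = trace  # type: ignore[attr-defined]
    return res


def registration2(fixed: Image2D, moving: Image2D, cfg: RegistrationConfig,
                  init: Optional[Transform2D] = None,
                  affine: Optional[AffineParams] = None
                  ) -> RegistrationResult:
    """Free fine branch: full-resolution FFD with γ₂."""
    if affine is None:
        affine = init.global_ if init is not None else AffineParams.identity()
    grid0 = build_grid(fixed.shape, cfg.spacing_r2)
    if init is not None:
        # resample the initializing transform's local field onto R2's lattice
        init_field = transform_field(
            Transform2D(AffineParams.identity(), init.local), fixed.shape)
        grid0 = fit_grid_to_field(init_field, cfg.spacing_r2)
    t0 = Transform2D(affine, grid0)
    t_opt, trace = steepest_descent(fixed, moving, t0, cfg.gamma2,
                                    cfg.optimizer)
    res = _result("R2", fixed, moving, t_opt, cfg.tol)
    res = _guard_against_baseline(res, fixed, moving, affine, cfg)
    res.trace = trace  # type: ignore[attr-defined]
    return res


def registrationP(fixed: Image2D, moving: Image2D, cfg: RegistrationConfig,
                  affine: Optional[AffineParams] = None
                  ) -> Optional[RegistrationResult]:
    """Point branch: extract → NCC-adjust → grid-augment → FFD fit → warp.

    Returns None (branch unavailable) when too few usable pairs exist, e.g.
    on texture-free images; the pipeline then continues with the intensity
    branches.
    """
    if affine is None:
        affine = AffineParams.identity()
    features = pointsmod.extract_features(fixed, cfg.point_method,
                                          **cfg.point_params)
    if len(features) < 3:
        logger.info("RP unavailable: only %d feature points", len(features))
        return None
    # initial moving-side guesses through the global affine
    mx, my = affine.apply(features.coordinates[:, 0], features.coordinates[:, 1])
    init = pointsmod.PointPairs(features.coordinates,
                                np.stack([mx, my], axis=1),
                                np.ones(len(features)))
    pairs = pointsmod.adjust_pairs_ncc(fixed, moving, init,
                                       window=cfg.ncc_window,
                                       search=cfg.ncc_search)
    if len(pairs) < 3:
        logger.info("RP unavailable: only %d pairs survived NCC", len(pairs))
        return None
    augmented = pointsmod.augment_with_grid(pairs, fixed.shape,
                                            cfg.grid_spacing_rp,
                                            order=cfg.grid_map_order)
    t = pointsmod.register_points(augmented, fixed.shape, cfg.spacing_rp)
    best = _result("RP", fixed, moving, t, cfg.tol)
    # refinement loop: re-match the features against the current warped
    # moving image (which compensates the in-window deformation that biases
    # a translational NCC), compose the correction, refit, and stop as soon
    # as the error reaches a minimum
    pf = pairs.fixed_points
    for _ in range(cfg.rp_refine_iters):
        re_init = pointsmod.PointPairs(pf, pf.copy(), np.ones(len(pf)))
        res_pairs = pointsmod.adjust_pairs_ncc(
            fixed, best.warped, re_init, window=cfg.ncc_window,
            search=max(1, cfg.ncc_search // 2))
        if len(res_pairs) < 3:
            break
        from .grid_transform import total_transform
        composed = total_transform(best.transform, res_pairs.moving_points)
        pairs_k = pointsmod.PointPairs(res_pairs.fixed_points, composed,
                                       res_pairs.scores)
        augmented = pointsmod.augment_with_grid(pairs_k, fixed.shape,
                                                cfg.grid_spacing_rp,
                                                order=cfg.grid_map_order)
        t_k = pointsmod.register_points(augmented, fixed.shape, cfg.spacing_rp)
        cand = _result("RP", fixed, moving, t_k, cfg.tol)
        if cand.error >= best.error:
            break
        best = cand
        pf = res_pairs.fixed_points
    return _guard_against_baseline(best, fixed, moving, affine, cfg)


# ---------------------------------------------------------------------------
# Whole-pair and whole-stack runs
# ---------------------------------------------------------------------------

def run_pair(fixed: Image2D, moving: Image2D, cfg: Optional[RegistrationConfig] = None,
             index: int = 0, preregistered_affine: Optional[AffineParams] = None
             ) -> SliceReport:
    """Register one slice pair through all branches and assemble the report."""
    if cfg is None:
        cfg = RegistrationConfig()
    if fixed.shape != moving.shape:
        raise ValueError("fixed/moving shapes differ")
    choice = choose_similarity(fixed, moving)
    if choice.measure != "ssd":
        logger.info("slice %d: histogram divergence %.3f suggests MI; "
                    "intensity branches still optimize SSD", index,
                    choice.histogram_divergence)
    affine = (preregistered_affine if preregistered_affine is not None
              else affine_preregister(fixed, moving))
    unreg = registration_error(
        fixed, warp(moving, Transform2D(affine, build_grid(fixed.shape,
                                                           cfg.spacing_r2))),
        cfg.tol)
    r1 = registration1(fixed, moving, cfg, affine=affine)
    r2 = registration2(fixed, moving, cfg,
                       init=r1.transform if cfg.r2_init_from_r1 else None,
                       affine=affine)
    results = [r1, r2]
    rp = None
    if cfg.enable_rp:
        rp = registrationP(fixed, moving, cfg, affine=affine)
        if rp is not None:
            results.append(rp)
    best = select_best(results)
    errors = {r.branch: r.error for r in results}
    fine = best if best.branch != "R1" else r2
    loc = local_field(r1, fine, sign=cfg.local_field_sign)
    strain = strainmap.strain_components(loc)
    strainmap.equivalent_strain(strain)
    logger.info("slice %d: errors %s → %s (unregistered %.4f)",
                index, {k: round(v, 4) for k, v in errors.items()},
                best.branch, unreg)
    report = SliceReport(index=index, errors=errors, chosen=best.branch,
                         unregistered_error=unreg, affine=affine,
                         local=loc, strain=strain)
    report.results = {r.branch: r for r in results}  # type: ignore[attr-defined]
    return report


def run_stack(fixed_stack: Sequence[Image2D], moving_stack: Sequence[Image2D],
              cfg: Optional[RegistrationConfig] = None) -> list[SliceReport]:
    """Loop a 2-D registration over an image stack, slice by slice.

    Per-slice failures are logged and reported (``failed`` field) while the
    remaining slices are still processed.
    """
    if len(fixed_stack) != len(moving_stack):
        raise ValueError(f"slice counts differ: {len(fixed_stack)} vs "
                         f"{len(moving_stack)}")
    if cfg is None:
        cfg = RegistrationConfig()
    reports = []
    for i, (fx, mv) in enumerate(zip(fixed_stack, moving_stack)):
        try:
            reports.append(run_pair(fx, mv, cfg, index=i))
        except Exception as exc:  # noqa: BLE001 — per-slice isolation
            logger.error("slice %d failed: %s", i, exc)
            reports.append(SliceReport(index=i, errors={}, chosen="none",
                                       unregistered_error=np.nan,
                                       affine=AffineParams.identity(),
                                       failed=str(exc)))
    return reports
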