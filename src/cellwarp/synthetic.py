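"""Synthetic phantoms and ground-truth deformation fields.

Registration accuracy can only be scored against a known deformation, so
this module generates (a) phantom images that stand in for tomographic
slices of cellular material — a line-grid pattern and a Voronoi "cellular"
pattern with a controllable porosity (void fraction) — and (b) analytic
displacement fields with closed-form strains:

* ``bending`` — the Euler–Bernoulli-style pure-bending field
  ``U_x = κ·x̃·ỹ``, ``U_y = −κ·x̃²/2`` about the image center (centered
  coordinates x̃, ỹ).  Purely non-rigid: its second derivatives are nonzero,
  its strain ε_x = κ·ỹ varies linearly through the thickness and changes
  sign at the neutral axis.
* ``uniform_swelling`` — isotropic stretch ``U = (s−1)·(x̃, ỹ)`` with
  constant strain s−1.
* ``slip_band`` — a smooth step in U_y across a vertical band (a localized
  shear discontinuity).
* ``custom_ffd`` — a random, seeded B-spline FFD bounded by an amplitude.

``make_pair`` turns a phantom plus a field into a (fixed, moving, truth)
triple such that warping the moving image by the truth field reproduces the
fixed image up to interpolation: the moving image is synthesized through the
numerically inverted field so the returned truth is directly the field a
perfect registration should recover.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .grid_transform import (
    ControlGrid,
    DisplacementField,
    Image2D,
    build_grid,
    evaluate_local_field,
    sample_bilinear,
)

__all__ = [
    "PhantomSpec",
    "FieldSpec",
    "make_phantom",
    "make_field",
    "make_pair",
    "invert_field",
    "grid_line_positions",
]


@dataclass
class PhantomSpec:
    """Specification of a synthetic phantom image.

    ``grid`` draws dark lines on a bright background; ``cellular`` builds a
    Voronoi lattice of dark lumens in bright wall material targeting the
    requested porosity (void fraction) — ≈0.78 emulates earlywood, ≈0.45
    latewood.  ``ray_band`` adds a vertical band of smaller cells mimicking
    a ray: radially running cells that locally stiffen the tissue.
    """

    shape: tuple[int, int] = (128, 128)
    pattern: Literal["grid", "cellular"] = "grid"
    porosity: float = 0.78
    cell_size: tuple[float, float] = (10.0, 16.0)
    ray_band: bool = False
    seed: int = 0
    line_spacing: int = 16
    linewidth: int = 3
    blur_sigma: float = 2.5
    margin: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("grid", "cellular"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not 0 < self.porosity < 1:
            raise ValueError("porosity must be in (0, 1)")


@dataclass
class FieldSpec:
    """Specification of an analytic ground-truth displacement field.

    ``amplitude`` bounds the maximum displacement magnitude in pixels
    (for ``uniform_swelling`` the stretch is given via ``scale`` instead).
    """

    kind: Literal["bending", "uniform_swelling", "slip_band", "custom_ffd"] = "bending"
    amplitude: float = 4.0
    scale: float = 1.03
    band_center: Optional[float] = None
    band_width: float = 6.0
    spline_spacing: float = 16.0
    seed: int = 0


def grid_line_positions(n: int, spacing: int, offset: Optional[int] = None,
                        margin: int = 0) -> np.ndarray:
    """Line center positions along one axis (offset defaults to spacing//2)."""
    if offset is None:
        offset = margin + spacing // 2
    return np.arange(offset, n - margin, spacing)


def _grid_sampler(spec: PhantomSpec):
    """Continuous grid pattern: dark Gaussian-blurred lines on unit background.

    Each line is a box profile of the given width convolved with a Gaussian
    (closed form via erf); lines multiply as transparencies so crossings stay
    dark.  Defining the phantom analytically lets deformed copies be sampled
    exactly, with no resampling error frozen into the synthetic data.
    """
    from scipy.special import erf

    h, w = spec.shape
    half = spec.linewidth / 2.0
    sig = max(spec.blur_sigma, 1e-6) * np.sqrt(2.0)
    m = spec.margin
    xlines = grid_line_positions(w, spec.line_spacing, margin=m).astype(float)
    ylines = grid_line_positions(h, spec.line_spacing, margin=m).astype(float)

    def profile(dist: np.ndarray) -> np.ndarray:
        return 0.5 * (erf((dist + half) / sig) - erf((dist - half) / sig))

    def extent(coord: np.ndarray, n: int) -> np.ndarray:
        # smooth indicator of the specimen square [m, n-1-m] along the line
        if m <= 0:
            return 1.0
        return 0.5 * (erf((coord - m) / sig) - erf((coord - (n - 1 - m)) / sig))

    def sampler(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        trans = np.ones_like(xs)
        for c in xlines:
            trans = trans * (1.0 - profile(xs - c) * extent(ys, h))
        for c in ylines:
            trans = trans * (1.0 - profile(ys - c) * extent(xs, w))
        return trans

    return sampler


def make_phantom(spec: PhantomSpec) -> Image2D:
    """Deterministic phantom image in [0, 1] per the spec.

    Grid phantoms carry their continuous generator as an ``analytic_sampler``
    attribute so that deformed copies can be synthesized without resampling.
    """
    h, w = spec.shape
    if spec.pattern == "grid":
        sampler = _grid_sampler(spec)
        ys, xs = np.mgrid[0:h, 0:w]
        img = Image2D(sampler(xs.astype(float), ys.astype(float)))
        img.analytic_sampler = sampler  # type: ignore[attr-defined]
        return img
    # cellular: Voronoi cells from seeded points; the wall phase is the set
    # of pixels whose margin between nearest and second-nearest seed is
    # small, with the margin threshold chosen by quantile so the void
    # fraction matches the porosity target
    rng = np.random.default_rng(spec.seed)
    mean_cell = float(np.mean(spec.cell_size))
    n_cells = max(4, int(round(h * w / mean_cell**2)))
    pts = rng.uniform([0, 0], [w, h], size=(n_cells, 2))
    if spec.ray_band:
        band_w = 0.15 * w
        extra = rng.uniform([w / 2 - band_w / 2, 0], [w / 2 + band_w / 2, h],
                            size=(max(2, n_cells // 3), 2))
        pts = np.vstack([pts, extra])
    ys, xs = np.mgrid[0:h, 0:w]
    dists, _ = cKDTree(pts).query(np.stack([xs.ravel(), ys.ravel()], axis=1), k=2)
    margin = (dists[:, 1] - dists[:, 0]).reshape(h, w)
    target_wall = 1.0 - spec.porosity
    thresh = float(np.quantile(margin, target_wall))
    if thresh < 0.5 or thresh > mean_cell:
        raise ValueError(
            f"porosity {spec.porosity} unattainable with cell size {spec.cell_size}")
    img = (margin < thresh).astype(float)  # walls bright, lumens dark
    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma)
    return Image2D(np.clip(img, 0.0, 1.0))


def _centered_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return xs - (w - 1) / 2.0, ys - (h - 1) / 2.0


def _check_jacobian(field: DisplacementField) -> None:
    dux_dy, dux_dx = np.gradient(field.u_x)
    duy_dy, duy_dx = np.gradient(field.u_y)
    det = (1 + dux_dx) * (1 + duy_dy) - dux_dy * duy_dx
    if np.any(det <= 0):
        raise ValueError("field amplitude too large: the map folds "
                         f"(min Jacobian {det.min():.3g})")


def make_field(spec: FieldSpec, shape: tuple[int, int]) -> DisplacementField:
    """Analytic displacement field on an image domain (see module docstring)."""
    xt, yt = _centered_coords(shape)
    h, w = shape
    if spec.kind == "bending":
        # scale curvature so the max displacement magnitude hits the amplitude
        xm, ym = (w - 1) / 2.0, (h - 1) / 2.0
        unit = DisplacementField(xt * yt, -xt**2 / 2.0)
        peak = float(unit.magnitude.max())
        kappa = spec.amplitude / peak if peak > 0 else 0.0
        fld = DisplacementField(kappa * xt * yt, -kappa * xt**2 / 2.0)
    elif spec.kind == "uniform_swelling":
        s = spec.scale
        fld = DisplacementField((s - 1.0) * xt, (s - 1.0) * yt)
    elif spec.kind == "slip_band":
        x0 = spec.band_center if spec.band_center is not None else 0.0
        arg = (xt - x0) / max(spec.band_width, 1e-9)
        step = 0.5 * (1.0 + np.tanh(arg))
        fld = DisplacementField(np.zeros_like(xt, dtype=float),
                                spec.amplitude * step)
    elif spec.kind == "custom_ffd":
        rng = np.random.default_rng(spec.seed)
        grid = build_grid(shape, spec.spline_spacing)
        disp = rng.uniform(-1.0, 1.0, size=grid.displacements.shape)
        grid = ControlGrid(grid.spacing, disp)
        raw = evaluate_local_field(grid, shape)
        peak = float(raw.magnitude.max())
        scale = spec.amplitude / peak if peak > 0 else 0.0
        fld = DisplacementField(raw.u_x * scale, raw.u_y * scale)
    else:
        raise ValueError(f"unknown field kind {spec.kind!r}")
    if float(fld.magnitude.max()) > spec.amplitude * (1 + 1e-9) and \
            spec.kind != "uniform_swelling":
        raise AssertionError("amplitude bound violated")
    _check_jacobian(fld)
    return fld


def invert_field(field: DisplacementField, n_iter: int = 80,
                 tol: float = 1e-6) -> DisplacementField:
    """Displacement V with (id + V) ∘ (id + U) ≈ id, by fixed-point iteration.

    Converges for the smooth, fold-free fields this module generates.
    """
    h, w = field.shape
    ys, xs = np.mgrid[0:h, 0:w]
    vx = -field.u_x.copy()
    vy = -field.u_y.copy()
    for _ in range(n_iter):
        sx = np.clip(xs + vx, 0, w - 1)
        sy = np.clip(ys + vy, 0, h - 1)
        new_vx = -sample_bilinear(field.u_x, sx.ravel(), sy.ravel()).reshape(h, w)
        new_vy = -sample_bilinear(field.u_y, sx.ravel(), sy.ravel()).reshape(h, w)
        shift = max(np.abs(new_vx - vx).max(), np.abs(new_vy - vy).max())
        vx, vy = new_vx, new_vy
        if shift < tol:
            break
    return DisplacementField(vx, vy)


def make_pair(image: Image2D, field: DisplacementField, noise_sigma: float = 0.0,
              seed: int = 0) -> tuple[Image2D, Image2D, DisplacementField]:
    """Build a (fixed, moving, truth) validation triple.

    ``truth`` is the registration field: ``warp(moving, truth)`` reproduces
    the fixed image up to interpolation error.  The moving image is the
    phantom evaluated through the numerical inverse of the field — via the
    phantom's continuous generator when it has one (grid phantoms), else by
    cubic-spline resampling — so no avoidable interpolation error is frozen
    into the synthetic data.  Independent seeded Gaussian noise of
    ``noise_sigma`` is added to each image.
    """
    if field.shape != image.shape:
        raise ValueError("field shape must match image shape")
    inv = invert_field(field)
    sampler = getattr(image, "analytic_sampler", None)
    h, w = image.shape
    ys, xs = np.mgrid[0:h, 0:w]
    if sampler is not None:
        moving = Image2D(sampler(xs + inv.u_x, ys + inv.u_y),
                         pitch=image.pitch)
    else:
        vals = ndi.map_coordinates(image.pixels,
                                   [np.clip(ys + inv.u_y, 0, h - 1).ravel(),
                                    np.clip(xs + inv.u_x, 0, w - 1).ravel()],
                                   order=3, mode="nearest")
        moving = Image2D(vals.reshape(h, w), pitch=image.pitch)
    rng = np.random.default_rng(seed)
    fixed_px = image.pixels.copy()
    moving_px = moving.pixels.copy()
    if noise_sigma > 0:
        fixed_px = fixed_px + rng.normal(0.0, noise_sigma, size=image.shape)
        moving_px = moving_px + rng.normal(0.0, noise_sigma, size=image.shape)
    return (Image2D(fixed_px, pitch=image.pitch),
            Image2D(moving_px, pitch=image.pitch),
            field)
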