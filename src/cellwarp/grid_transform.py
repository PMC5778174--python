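"""Cubic B-spline free-form deformation (FFD) in 2-D.

A deformation is parameterized by a uniform lattice of control-point
displacements ``Π`` with spacing ``δ`` (pixels).  The local displacement at a
pixel is the tensor-product cubic B-spline blend of the 4×4 control points
supporting that pixel::

    T_local(x, y) = Σ_{l=0..3} Σ_{m=0..3}  B_l(u) B_m(v) Π_{i+l, j+m}

with ``i = ⌊x/δ⌋ − 1``, ``u = x/δ − ⌊x/δ⌋`` (and likewise j, v for y).  The
total transform adds a global affine map:  T(x) = A·x + b + T_local(x).

Conventions
-----------
* Coordinates are 0-based and pixel-centered; ``x`` is the column index and
  ``y`` the row index.  Images are indexed ``pixels[y, x]``.
* The control lattice carries one extra ring of points beyond every image
  edge so each pixel always has a complete 4×4 support.
* Warping is backward: the output pixel ``p`` samples the moving image at
  ``T(p)`` with bilinear interpolation; samples outside the moving domain
  are clamped to the nearest edge pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse

__all__ = [
    "Image2D",
    "ControlGrid",
    "AffineParams",
    "Transform2D",
    "DisplacementField",
    "basis",
    "build_grid",
    "evaluate_local",
    "total_transform",
    "warp",
    "sample_bilinear",
    "basis_matrix",
    "fit_grid_to_field",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Image2D:
    """A 2-D grayscale intensity field with intensities in [0, 1].

    Parameters
    ----------
    pixels:
        2-D float array, indexed ``[row, col]`` = ``[y, x]``.
    pitch:
        Optional physical size of one pixel (e.g. 0.8 for a 0.8 μm voxel
        pitch); informational only — all registration math is in pixels.
    """

    pixels: np.ndarray
    pitch: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size < 1:
            raise ValueError("Image2D requires a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ControlGrid:
    """Uniform lattice of control-point displacement vectors.

    ``displacements`` has shape ``(ny, nx, 2)`` where the last axis is
    ``(dx, dy)`` in pixels.  Lattice array index ``a`` along x corresponds to
    lattice coordinate ``(a − 1)·spacing``: the first and last points sit one
    spacing outside the image so every pixel has full cubic support.
    """

    spacing: float
    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("control-point spacing must be positive")
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 3 or self.displacements.shape[2] != 2:
            raise ValueError("displacements must have shape (ny, nx, 2)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("control displacements must be finite")

    @property
    def extent(self) -> tuple[int, int]:
        """Lattice dimensions (nx, ny)."""
        ny, nx, _ = self.displacements.shape
        return nx, ny

    def copy(self) -> "ControlGrid":
        return ControlGrid(self.spacing, self.displacements.copy())


@dataclass
class AffineParams:
    """Global affine map  x ↦ A·x + t  (coordinates as (x, y) vectors)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part must be invertible")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()

    def apply(self, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = self.matrix
        tx, ty = self.translation
        return (a[0, 0] * xs + a[0, 1] * ys + tx,
                a[1, 0] * xs + a[1, 1] * ys + ty)

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, np.eye(2)) and
                    np.allclose(self.translation, 0.0))


@dataclass
class Transform2D:
    """Total transform: global affine plus local B-spline FFD displacement."""

    global_: AffineParams
    local: ControlGrid

    @classmethod
    def identity(cls, image_shape: tuple[int, int], spacing: float) -> "Transform2D":
        return cls(AffineParams.identity(), build_grid(image_shape, spacing))

    def copy(self) -> "Transform2D":
        return Transform2D(
            AffineParams(self.global_.matrix.copy(), self.global_.translation.copy()),
            self.local.copy(),
        )


@dataclass
class DisplacementField:
    """Per-pixel displacement components ``u_x``, ``u_y`` (pixels)."""

    u_x: np.ndarray
    u_y: np.ndarray

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=np.float64)
        self.u_y = np.asarray(self.u_y, dtype=np.float64)
        if self.u_x.shape != self.u_y.shape:
            raise ValueError("u_x and u_y must share a shape")
        if not (np.all(np.isfinite(self.u_x)) and np.all(np.isfinite(self.u_y))):
            raise ValueError("displacement values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u_x.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_x, self.u_y)


# ---------------------------------------------------------------------------
# B-spline bases
# ---------------------------------------------------------------------------

def basis(l: int, u, order: int = 0):
    """Cubic B-spline basis ``B_l(u)`` (or its derivative) for l in {0..3}.

    ``u`` is the local fractional coordinate in [0, 1).  ``order`` selects the
    0th, 1st or 2nd derivative with respect to ``u``.
    """
    if l not in (0, 1, 2, 3):
        raise ValueError(f"basis index l must be in 0..3, got {l}")
    u = np.asarray(u, dtype=np.float64)
    if order == 0:
        if l == 0:
            return (1.0 - u) ** 3 / 6.0
        if l == 1:
            return (3.0 * u**3 - 6.0 * u**2 + 4.0) / 6.0
        if l == 2:
            return (-3.0 * u**3 + 3.0 * u**2 + 3.0 * u + 1.0) / 6.0
        return u**3 / 6.0
    if order == 1:
        if l == 0:
            return -((1.0 - u) ** 2) / 2.0
        if l == 1:
            return (3.0 * u**2 - 4.0 * u) / 2.0
        if l == 2:
            return (-3.0 * u**2 + 2.0 * u + 1.0) / 2.0
        return u**2 / 2.0
    if order == 2:
        if l == 0:
            return 1.0 - u
        if l == 1:
            return 3.0 * u - 2.0
        if l == 2:
            return 1.0 - 3.0 * u
        return u + 0.0 * u
    raise ValueError(f"derivative order must be 0, 1 or 2, got {order}")


def _lattice_size(n_pixels: int, spacing: float) -> int:
    # support indices for the last pixel are floor((n-1)/δ) .. +3, plus the
    # leading margin point → floor((n-1)/δ) + 4 lattice points.
    return int(np.floor((n_pixels - 1) / spacing)) + 4


def build_grid(image_shape: tuple[int, int], spacing: float) -> ControlGrid:
    """Zero-displacement control lattice covering an image domain.

    The lattice extends one control point beyond every edge so that the 4×4
    cubic support of any pixel is complete.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if h < 1 or w < 1:
        raise ValueError("image must be non-empty")
    spacing = float(spacing)
    if spacing < 2:
        raise ValueError("spacing must be at least 2 pixels")
    if spacing > max(h, w):
        raise ValueError(
            f"spacing {spacing} exceeds the image extent {max(h, w)}")
    nx = _lattice_size(w, spacing)
    ny = _lattice_size(h, spacing)
    return ControlGrid(spacing, np.zeros((ny, nx, 2)))


# ---------------------------------------------------------------------------
# Sparse basis operators (pixel lattice → control coefficients)
# ---------------------------------------------------------------------------

_MATRIX_CACHE: dict = {}


def _basis_matrix_points(xs: np.ndarray, ys: np.ndarray, grid: ControlGrid,
                         deriv: tuple[int, int] = (0, 0)) -> sparse.csr_matrix:
    """Sparse matrix mapping flattened control values to values at points.

    ``deriv = (dx, dy)`` gives the corresponding mixed partial derivative of
    the spline with respect to the pixel coordinates (so a 1/δ factor per
    derivative order is included).
    """
    nx, ny = grid.extent
    delta = grid.spacing
    n_pts = xs.size
    tx = xs / delta
    ty = ys / delta
    ix = np.floor(tx).astype(np.int64)          # lattice i + 1 = array col base
    iy = np.floor(ty).astype(np.int64)
    u = tx - ix
    v = ty - iy
    if np.any(ix < 0) or np.any(iy < 0) or np.any(ix + 3 > nx - 1) or np.any(iy + 3 > ny - 1):
        raise ValueError("coordinates outside the control-grid domain")
    dx, dy = deriv
    scale = delta ** (-(dx + dy))
    rows = np.empty(n_pts * 16, dtype=np.int64)
    cols = np.empty(n_pts * 16, dtype=np.int64)
    vals = np.empty(n_pts * 16, dtype=np.float64)
    r = np.arange(n_pts, dtype=np.int64)
    bu = [basis(l, u, order=dx) for l in range(4)]
    bv = [basis(m, v, order=dy) for m in range(4)]
    k = 0
    for m in range(4):
        for l in range(4):
            rows[k * n_pts:(k + 1) * n_pts] = r
            cols[k * n_pts:(k + 1) * n_pts] = (iy + m) * nx + (ix + l)
            vals[k * n_pts:(k + 1) * n_pts] = bu[l] * bv[m] * scale
            k += 1
    mat = sparse.coo_matrix((vals, (rows, cols)), shape=(n_pts, nx * ny))
    return mat.tocsr()


def basis_matrix(image_shape: tuple[int, int], spacing: float,
                 extent: tuple[int, int], deriv: tuple[int, int] = (0, 0)
                 ) -> sparse.csr_matrix:
    """Cached dense-lattice basis operator for a whole image domain."""
    key = (image_shape, float(spacing), extent, deriv)
    mat = _MATRIX_CACHE.get(key)
    if mat is None:
        h, w = image_shape
        ys, xs = np.mgrid[0:h, 0:w]
        grid = ControlGrid(spacing, np.zeros((extent[1], extent[0], 2)))
        mat = _basis_matrix_points(xs.ravel().astype(float),
                                   ys.ravel().astype(float), grid, deriv)
        _MATRIX_CACHE[key] = mat
    return mat


def evaluate_local(grid: ControlGrid, coords: np.ndarray) -> np.ndarray:
    """FFD displacement at scattered points.

    Parameters
    ----------
    coords:
        Array of shape (n, 2) of (x, y) pixel coordinates inside the domain
        covered by the grid.

    Returns
    -------
    Array of shape (n, 2) of (dx, dy) displacements.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    mat = _basis_matrix_points(coords[:, 0], coords[:, 1], grid)
    nx, ny = grid.extent
    px = grid.displacements[:, :, 0].ravel()
    py = grid.displacements[:, :, 1].ravel()
    return np.stack([mat @ px, mat @ py], axis=1)


def evaluate_local_field(grid: ControlGrid, image_shape: tuple[int, int]
                         ) -> DisplacementField:
    """FFD displacement evaluated at every pixel of an image domain."""
    mat = basis_matrix(image_shape, grid.spacing, grid.extent)
    ux = (mat @ grid.displacements[:, :, 0].ravel()).reshape(image_shape)
    uy = (mat @ grid.displacements[:, :, 1].ravel()).reshape(image_shape)
    return DisplacementField(ux, uy)


def total_transform(t: Transform2D, coords: np.ndarray) -> np.ndarray:
    """Apply the total transform T(x) = A·x + b + T_local(x) to points."""
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    gx, gy = t.global_.apply(coords[:, 0], coords[:, 1])
    local = evaluate_local(t.local, coords)
    return np.stack([gx + local[:, 0], gy + local[:, 1]], axis=1)


def transform_field(t: Transform2D, image_shape: tuple[int, int]
                    ) -> DisplacementField:
    """Per-pixel displacement of the total transform, U(p) = T(p) − p."""
    h, w = image_shape
    ys, xs = np.mgrid[0:h, 0:w]
    gx, gy = t.global_.apply(xs.astype(float), ys.astype(float))
    local = evaluate_local_field(t.local, image_shape)
    return DisplacementField(gx - xs + local.u_x, gy - ys + local.u_y)


# ---------------------------------------------------------------------------
# Bilinear sampling and warping
# ---------------------------------------------------------------------------

def sample_bilinear(image: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                    with_gradient: bool = False):
    """Bilinear interpolation with edge clamping.

    Returns the sampled values, and optionally the analytic partial
    derivatives of the interpolant with respect to the sample coordinates
    (zero where a coordinate is clamped outside the domain — consistent with
    the clamped sampling itself).
    """
    h, w = image.shape
    xc = np.clip(xs, 0.0, w - 1.0)
    yc = np.clip(ys, 0.0, h - 1.0)
    x0 = np.minimum(np.floor(xc).astype(np.int64), w - 2) if w > 1 else np.zeros_like(xc, dtype=np.int64)
    y0 = np.minimum(np.floor(yc).astype(np.int64), h - 2) if h > 1 else np.zeros_like(yc, dtype=np.int64)
    fx = xc - x0
    fy = yc - y0
    i00 = image[y0, x0]
    i01 = image[y0, x0 + 1] if w > 1 else i00
    i10 = image[y0 + 1, x0] if h > 1 else i00
    i11 = image[y0 + 1, x0 + 1] if (h > 1 and w > 1) else i00
    top = i00 * (1 - fx) + i01 * fx
    bot = i10 * (1 - fx) + i11 * fx
    vals = top * (1 - fy) + bot * fy
    if not with_gradient:
        return vals
    inside_x = (xs > 0.0) & (xs < w - 1.0)
    inside_y = (ys > 0.0) & (ys < h - 1.0)
    gx = ((i01 - i00) * (1 - fy) + (i11 - i10) * fy) * inside_x
    gy = (bot - top) * inside_y
    return vals, gx, gy


def warp(moving: Image2D, t: Transform2D) -> Image2D:
    """Backward-warp the moving image through the total transform.

    Output pixel ``p`` receives ``moving(T(p))`` by bilinear interpolation;
    coordinates outside the moving domain clamp to the nearest edge pixel.
    """
    h, w = moving.shape
    ys, xs = np.mgrid[0:h, 0:w]
    gx, gy = t.global_.apply(xs.astype(float), ys.astype(float))
    local = evaluate_local_field(t.local, moving.shape)
    vals = sample_bilinear(moving.pixels, gx + local.u_x, gy + local.u_y)
    return Image2D(vals.reshape(moving.shape), pitch=moving.pitch)


def warp_by_field(image: Image2D, field: DisplacementField) -> Image2D:
    """Backward-warp by a dense displacement field: out(p) = image(p + U(p))."""
    if field.shape != image.shape:
        raise ValueError("field shape must match image shape")
    h, w = image.shape
    ys, xs = np.mgrid[0:h, 0:w]
    vals = sample_bilinear(image.pixels, xs + field.u_x, ys + field.u_y)
    return Image2D(vals.reshape(image.shape), pitch=image.pitch)


# ---------------------------------------------------------------------------
# Least-squares fit of a dense field onto a control grid
# ---------------------------------------------------------------------------

def fit_grid_to_field(field: DisplacementField, spacing: float,
                      ridge: float = 1e-10) -> ControlGrid:
    """Fit a control grid whose FFD reproduces a dense displacement field.

    Solves a (mildly ridge-regularized) linear least-squares problem per
    component.  Exact (to solver precision) whenever the field lies in the
    spline space of the requested spacing.
    """
    shape = field.shape
    grid = build_grid(shape, spacing)
    mat = basis_matrix(shape, grid.spacing, grid.extent)
    ata = (mat.T @ mat).tocsc()
    reg = ridge * sparse.identity(ata.shape[0], format="csc")
    solve = sparse.linalg.factorized(ata + reg)
    px = solve(mat.T @ field.u_x.ravel())
    py = solve(mat.T @ field.u_y.ravel())
    ny, nx, _ = grid.displacements.shape
    disp = np.stack([px.reshape(ny, nx), py.reshape(ny, nx)], axis=2)
    return ControlGrid(grid.spacing, disp)
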