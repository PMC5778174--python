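"""Feature points and point-based ("Registration P") machinery.

Intensity-based FFD registration can miss localized deformation in highly
porous cellular structures, so a third registration route works on feature
points instead of gray values:

1. extract feature points in the fixed image (Manual, Map, Skeleton, Harris
   or Edges);
2. locate each point in the moving image by normalized cross-correlation,
   searching up to ±4 px and refining the match on a 0.1-px lag grid;
3. add the nodes of an artificial regular grid to both point sets, mapping
   the moving-side nodes through a low-order (affine or quadratic) fit of
   the feature pairs so featureless regions stay anchored;
4. fit an FFD whose displacement field approximates the pair displacements
   by multilevel B-spline approximation (coarse-to-fine spacing halving).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Optional, Sequence

import numpy as np
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import morphology as skmorph
from scipy import ndimage as ndi

from .grid_transform import (
    ControlGrid,
    DisplacementField,
    Image2D,
    Transform2D,
    AffineParams,
    build_grid,
    evaluate_local,
    evaluate_local_field,
    fit_grid_to_field,
    sample_bilinear,
)

__all__ = [
    "PointSet",
    "PointPairs",
    "AugmentedGrid",
    "extract_features",
    "adjust_pairs_ncc",
    "augment_with_grid",
    "register_points",
]

FEATURE_METHODS = ("manual", "map", "skeleton", "harris", "edges")


@dataclass
class PointSet:
    """Feature coordinates (x, y) in pixels, possibly fractional."""

    coordinates: np.ndarray
    source_method: str

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64).reshape(-1, 2)
        if self.source_method not in FEATURE_METHODS:
            raise ValueError(f"unknown feature method {self.source_method!r}")

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class PointPairs:
    """Matched (fixed, moving) point lists with per-pair NCC scores."""

    fixed_points: np.ndarray
    moving_points: np.ndarray
    scores: np.ndarray
    dropped: list = dfield(default_factory=list)

    def __post_init__(self) -> None:
        self.fixed_points = np.asarray(self.fixed_points, dtype=np.float64).reshape(-1, 2)
        self.moving_points = np.asarray(self.moving_points, dtype=np.float64).reshape(-1, 2)
        self.scores = np.asarray(self.scores, dtype=np.float64).ravel()
        if not (len(self.fixed_points) == len(self.moving_points) == len(self.scores)):
            raise ValueError("pair arrays must have equal lengths")

    def __len__(self) -> int:
        return len(self.fixed_points)


@dataclass
class AugmentedGrid:
    """Feature pairs united with artificial-grid nodes on both sides."""

    fixed_points: np.ndarray
    moving_points: np.ndarray
    grid_spacing: float
    n_features: int

    def __post_init__(self) -> None:
        self.fixed_points = np.asarray(self.fixed_points, dtype=np.float64).reshape(-1, 2)
        self.moving_points = np.asarray(self.moving_points, dtype=np.float64).reshape(-1, 2)
        if len(self.fixed_points) != len(self.moving_points):
            raise ValueError("augmented point counts must be equal")

    def __len__(self) -> int:
        return len(self.fixed_points)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _binarize(image: Image2D, threshold: Optional[float],
              foreground: str) -> np.ndarray:
    if threshold is None:
        threshold = float(skfilters.threshold_otsu(image.pixels))
    if foreground == "dark":
        return image.pixels < threshold
    if foreground == "bright":
        return image.pixels > threshold
    raise ValueError("foreground must be 'dark' or 'bright'")


def _coords_from_mask(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.stack([xs.astype(float), ys.astype(float)], axis=1)


def _subsample(coords: np.ndarray, max_points: Optional[int]) -> np.ndarray:
    if max_points is None or len(coords) <= max_points:
        return coords
    # deterministic uniform thinning in (row-major) scan order
    idx = np.linspace(0, len(coords) - 1, max_points).round().astype(int)
    return coords[np.unique(idx)]


def extract_features(image: Image2D, method: str, *,
                     threshold: Optional[float] = None,
                     foreground: str = "dark",
                     harris_min_distance: int = 3,
                     harris_threshold_rel: float = 0.05,
                     canny_sigma: float = 1.5,
                     canny_low: Optional[float] = None,
                     canny_high: Optional[float] = None,
                     points: Optional[Sequence] = None,
                     max_points: Optional[int] = 600) -> PointSet:
    """Extract feature points with one of the five techniques.

    * ``manual`` — caller-provided (x, y) list, validated in-domain;
    * ``map`` — boundary pixels of the thresholded foreground (Otsu default);
    * ``skeleton`` — morphological skeleton of the thresholded foreground;
    * ``harris`` — local maxima of the Harris corner response;
    * ``edges`` — Canny edge pixels.

    An empty result is returned (not raised) when no features survive;
    ``max_points`` deterministically thins overly dense sets.
    """
    if method not in FEATURE_METHODS:
        raise ValueError(f"unknown feature method {method!r}")
    h, w = image.shape
    if method == "manual":
        if points is None:
            raise ValueError("manual method requires a points list")
        coords = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        oob = ((coords[:, 0] < 0) | (coords[:, 0] > w - 1)
               | (coords[:, 1] < 0) | (coords[:, 1] > h - 1))
        if np.any(oob):
            raise ValueError(f"{int(oob.sum())} manual points outside the image")
        return PointSet(coords, "manual")
    if method == "map":
        mask = _binarize(image, threshold, foreground)
        boundary = mask & ~ndi.binary_erosion(mask, border_value=0)
        coords = _coords_from_mask(boundary)
    elif method == "skeleton":
        mask = _binarize(image, threshold, foreground)
        coords = _coords_from_mask(skmorph.skeletonize(mask))
    elif method == "harris":
        resp = skfeature.corner_harris(image.pixels)
        peaks = skfeature.corner_peaks(resp, min_distance=harris_min_distance,
                                       threshold_rel=harris_threshold_rel)
        coords = np.stack([peaks[:, 1].astype(float),
                           peaks[:, 0].astype(float)], axis=1) if len(peaks) else np.empty((0, 2))
    else:  # edges
        mask = skfeature.canny(image.pixels, sigma=canny_sigma,
                               low_threshold=canny_low, high_threshold=canny_high)
        coords = _coords_from_mask(mask)
    return PointSet(_subsample(coords, max_points), method)


# ---------------------------------------------------------------------------
# NCC pair adjustment
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom <= 0:
        return np.nan
    return float((a * b).sum() / denom)


def _clamped_center(c: float, half: int, size: int) -> int:
    return int(np.clip(round(c), half, size - 1 - half))


def adjust_pairs_ncc(fixed: Image2D, moving: Image2D,
                     initial_pairs: PointPairs | tuple,
                     window: int = 11, search: int = 4,
                     accept_threshold: float = 0.5,
                     fine_step: float = 0.1) -> PointPairs:
    """Re-locate each moving point at the NCC maximum near its initial guess.

    The fixed-centered ``window``×``window`` patch is matched against the
    moving neighborhood at all integer lags within ±``search`` px, then the
    winning lag is refined on a ``fine_step`` grid of fractional lags within
    ±0.5 px using bilinear resampling — one-tenth-of-a-pixel adjustment by
    default.  Pairs with a zero-variance patch or a best correlation below
    ``accept_threshold`` are dropped with a recorded reason.  No adjusted
    point moves more than ``search`` + 0.5 px from its initial guess.
    """
    if search < 0:
        raise ValueError("search must be non-negative")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if isinstance(initial_pairs, PointPairs):
        pf_list, pm_list = initial_pairs.fixed_points, initial_pairs.moving_points
    else:
        pf_list, pm_list = (np.asarray(initial_pairs[0], dtype=float).reshape(-1, 2),
                            np.asarray(initial_pairs[1], dtype=float).reshape(-1, 2))
    half = window // 2
    h, w = fixed.shape
    hm, wm = moving.shape
    # precomputed fractional lag grid for the refinement stage
    frac = np.arange(-0.5, 0.5 + 1e-9, fine_step)
    out_f, out_m, out_s, dropped = [], [], [], []
    win_off = np.arange(-half, half + 1)
    for pf, pm0 in zip(pf_list, pm_list):
        cx = _clamped_center(pf[0], half, w)
        cy = _clamped_center(pf[1], half, h)
        patch = fixed.pixels[cy - half:cy + half + 1, cx - half:cx + half + 1]
        if patch.std() <= 1e-12:
            dropped.append((tuple(pf), "zero-variance fixed patch"))
            continue
        mx = _clamped_center(pm0[0], half + search, wm) if wm >= window + 2 * search \
            else _clamped_center(pm0[0], half, wm)
        my = _clamped_center(pm0[1], half + search, hm) if hm >= window + 2 * search \
            else _clamped_center(pm0[1], half, hm)
        # integer-lag search
        best = (-np.inf, 0, 0)
        for dy in range(-search, search + 1):
            for dx in range(-search, search + 1):
                x0, y0 = mx + dx, my + dy
                if x0 - half < 0 or y0 - half < 0 or x0 + half >= wm or y0 + half >= hm:
                    continue
                cand = moving.pixels[y0 - half:y0 + half + 1, x0 - half:x0 + half + 1]
                score = _ncc(patch, cand)
                if np.isfinite(score) and score > best[0]:
                    best = (score, dx, dy)
        if not np.isfinite(best[0]):
            dropped.append((tuple(pf), "zero-variance moving neighborhood"))
            continue
        score_int, dx_i, dy_i = best
        # fractional refinement on a fine_step lag grid
        gy, gx = np.meshgrid(win_off, win_off, indexing="ij")
        base_x = mx + dx_i + gx.astype(float)
        base_y = my + dy_i + gy.astype(float)
        best_f = (score_int, 0.0, 0.0)
        for fy in frac:
            for fx in frac:
                if abs(fx) < 1e-12 and abs(fy) < 1e-12:
                    continue
                cand = sample_bilinear(moving.pixels,
                                       (base_x + fx).ravel(),
                                       (base_y + fy).ravel()).reshape(window, window)
                score = _ncc(patch, cand)
                if np.isfinite(score) and score > best_f[0]:
                    best_f = (score, fx, fy)
        score, fx, fy = best_f
        if score < accept_threshold:
            dropped.append((tuple(pf), f"correlation {score:.3f} below threshold"))
            continue
        new_m = np.array([mx + dx_i + fx, my + dy_i + fy])
        # hard bound relative to the (clamped) initial guess
        shift = new_m - np.array([mx, my], dtype=float)
        lim = search + 0.5
        new_m = np.array([mx, my], dtype=float) + np.clip(shift, -lim, lim)
        # carry the fixed point's subpixel offset so exact-copy pairs stay exact
        new_m += pf - np.array([cx, cy], dtype=float)
        out_f.append(pf)
        out_m.append(new_m)
        out_s.append(score)
    return PointPairs(np.array(out_f).reshape(-1, 2),
                      np.array(out_m).reshape(-1, 2),
                      np.array(out_s), dropped=dropped)


# ---------------------------------------------------------------------------
# Artificial-grid augmentation
# ---------------------------------------------------------------------------

def _poly_design(pts: np.ndarray, order: int) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    cols = [np.ones_like(x), x, y]
    if order == 2:
        cols += [x * y, x * x, y * y]
    return np.stack(cols, axis=1)


def fit_point_map(fixed_pts: np.ndarray, moving_pts: np.ndarray, order: int = 1):
    """Least-squares affine (order 1) or quadratic (order 2) map fixed→moving."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    need = 3 if order == 1 else 6
    if len(fixed_pts) < need:
        raise ValueError(
            f"need at least {need} pairs for an order-{order} fit; "
            "consider an intensity-based registration branch instead")
    a = _poly_design(fixed_pts, order)
    coef, *_ = np.linalg.lstsq(a, moving_pts, rcond=None)

    def apply(pts: np.ndarray) -> np.ndarray:
        return _poly_design(np.asarray(pts, dtype=float).reshape(-1, 2), order) @ coef

    return apply


def augment_with_grid(pairs: PointPairs, image_shape: tuple[int, int],
                      grid_spacing: float, order: int = 1) -> AugmentedGrid:
    """Union feature pairs with artificial-grid nodes on both sides.

    Fixed-side nodes are the regular grid; moving-side nodes are the same
    nodes mapped through a least-squares affine (or, with ``order=2``,
    quadratic) fit of the feature pairs, so the fitted deformation stays
    anchored where no features exist.
    """
    if grid_spacing < 2:
        raise ValueError("grid_spacing must be at least 2 px")
    if len(pairs) < 3:
        raise ValueError(
            "fewer than 3 feature pairs: cannot fit the grid map; "
            "use an intensity-based registration branch")
    h, w = image_shape
    gx = np.arange(0.0, w - 1 + 1e-9, grid_spacing)
    gy = np.arange(0.0, h - 1 + 1e-9, grid_spacing)
    if gx[-1] < w - 1:
        gx = np.append(gx, w - 1.0)
    if gy[-1] < h - 1:
        gy = np.append(gy, h - 1.0)
    yy, xx = np.meshgrid(gy, gx, indexing="ij")
    nodes = np.stack([xx.ravel(), yy.ravel()], axis=1)
    try:
        mapping = fit_point_map(pairs.fixed_points, pairs.moving_points, order)
    except ValueError:
        if order == 2:
            mapping = fit_point_map(pairs.fixed_points, pairs.moving_points, 1)
        else:
            raise
    mapped = mapping(nodes)
    pi_f = np.vstack([pairs.fixed_points, nodes])
    pi_m = np.vstack([pairs.moving_points, mapped])
    return AugmentedGrid(pi_f, pi_m, float(grid_spacing), n_features=len(pairs))


# ---------------------------------------------------------------------------
# Multilevel B-spline approximation (scattered-data FFD fit)
# ---------------------------------------------------------------------------

def _ba_fit(points: np.ndarray, values: np.ndarray,
            image_shape: tuple[int, int], spacing: float) -> ControlGrid:
    """Single-level B-spline approximation of scattered displacements."""
    grid = build_grid(image_shape, spacing)
    nx, ny = grid.extent
    delta = grid.spacing
    tx = points[:, 0] / delta
    ty = points[:, 1] / delta
    ix = np.floor(tx).astype(np.int64)
    iy = np.floor(ty).astype(np.int64)
    u = tx - ix
    v = ty - iy
    from .grid_transform import basis as _basis
    w_all = np.empty((len(points), 16))
    idx_all = np.empty((len(points), 16), dtype=np.int64)
    k = 0
    for m in range(4):
        for l in range(4):
            w_all[:, k] = _basis(l, u) * _basis(m, v)
            idx_all[:, k] = (iy + m) * nx + (ix + l)
            k += 1
    w2_sum = (w_all**2).sum(axis=1)  # Σ_ab w_ab² per point
    num = np.zeros((nx * ny, values.shape[1]))
    den = np.zeros(nx * ny)
    for comp in range(values.shape[1]):
        phi_c = (w_all * (values[:, comp] / w2_sum)[:, None])  # w_c z / Σw²
        np.add.at(num[:, comp], idx_all.ravel(),
                  (w_all**2 * phi_c).ravel())
    np.add.at(den, idx_all.ravel(), (w_all**2).ravel())
    coeff = np.zeros((nx * ny, values.shape[1]))
    touched = den > 0
    coeff[touched] = num[touched] / den[touched, None]
    disp = np.stack([coeff[:, 0].reshape(ny, nx),
                     coeff[:, 1].reshape(ny, nx)], axis=2)
    return ControlGrid(delta, disp)


def register_points(augmented: AugmentedGrid, image_shape: tuple[int, int],
                    spline_spacing: float) -> Transform2D:
    """Fit an FFD whose displacement field approximates the pair displacements.

    The affine trend of the displacements is fitted first by least squares
    and carried on the control lattice exactly (uniform cubic B-splines
    reproduce affine fields from lattice samples); a constant or affine set
    of pair displacements is therefore reproduced exactly everywhere.  The
    detrended remainder is fitted by multilevel B-spline approximation:
    coarse-to-fine spacing halving, each level approximating the residual
    displacements, with a level skipped whenever it fails to reduce the
    mean pair residual — the residual therefore decreases monotonically.
    The level sum is finally condensed onto a single lattice at
    ``spline_spacing`` by linear least squares.
    """
    if len(augmented) < 4:
        raise ValueError("point-based registration needs at least 4 pairs")
    pts = augmented.fixed_points
    h, w = image_shape
    if np.linalg.matrix_rank(np.column_stack([pts, np.ones(len(pts))])) < 3:
        raise ValueError("all points collinear: degenerate configuration")
    disp = augmented.moving_points - pts
    residual_history = [float(np.abs(disp).mean())]
    # affine trend, exact on the lattice by linear precision
    trend = fit_point_map(pts, augmented.moving_points, order=1)
    resid = augmented.moving_points - trend(pts)
    residual_history.append(float(np.abs(resid).mean()))
    # level spacings: spline_spacing * 2^k, coarsest <= half the image extent
    spacings = [float(spline_spacing)]
    while spacings[-1] * 2 <= max(h, w) / 2:
        spacings.append(spacings[-1] * 2)
    spacings = spacings[::-1]
    mean_resid = residual_history[-1]
    level_grids: list[ControlGrid] = []
    for s in spacings:
        grid = _ba_fit(pts, resid, image_shape, s)
        pred = evaluate_local(grid, pts)
        new_resid = resid - pred
        new_mean = float(np.abs(new_resid).mean())
        if new_mean < mean_resid:
            level_grids.append(grid)
            resid = new_resid
            mean_resid = new_mean
        residual_history.append(mean_resid)
    # condense the level sum onto a single lattice at the finest spacing
    if level_grids:
        total = None
        for grid in level_grids:
            f = evaluate_local_field(grid, image_shape)
            if total is None:
                total = f
            else:
                total = DisplacementField(total.u_x + f.u_x, total.u_y + f.u_y)
        final = fit_grid_to_field(total, spline_spacing, ridge=1e-10)
    else:
        final = build_grid(image_shape, spline_spacing)
    # add the affine trend displacement sampled on the control lattice
    ny, nx, _ = final.displacements.shape
    jj, ii = np.mgrid[0:ny, 0:nx]
    lat = np.stack([((ii - 1) * final.spacing).ravel(),
                    ((jj - 1) * final.spacing).ravel()], axis=1)
    trend_disp = trend(lat) - lat
    final.displacements[:, :, 0] += trend_disp[:, 0].reshape(ny, nx)
    final.displacements[:, :, 1] += trend_disp[:, 1].reshape(ny, nx)
    t = Transform2D(AffineParams.identity(), final)
    t.residual_history = residual_history  # type: ignore[attr-defined]
    return t
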