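"""Registration cost: similarity, histogram rule, bending penalty.

The registration minimizes

    C(T) = −S(T; I_F, I_M) + γ · P(T)

where ``S`` is an image-similarity measure evaluated on the fixed image and
the warped moving image, and ``P`` is the bending-energy penalty — the
area-averaged integral of squared second derivatives of the transform —
which vanishes for any affine map and discourages implausible oscillation of
the control lattice.

Similarity is the (negated, per-pixel mean) sum of squared differences by
default.  Mutual information is available for image pairs whose gray-level
histograms diverge: when the L1 difference of the two unit-mass histograms
exceeds 0.25 the images are considered too differently exposed for SSD and
MI is selected instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import sparse

from .grid_transform import (
    ControlGrid,
    Image2D,
    Transform2D,
    basis_matrix,
    warp,
)

__all__ = [
    "CostBreakdown",
    "SimilarityChoice",
    "ssd",
    "mutual_information",
    "choose_similarity",
    "bending_penalty",
    "cost",
    "HISTOGRAM_BINS",
    "HISTOGRAM_DIVERGENCE_THRESHOLD",
]

#: Bin count for the histogram-divergence rule (the threshold below is only
#: meaningful on unit-mass histograms).
HISTOGRAM_BINS = 64

#: L1 histogram divergence above which mutual information replaces SSD.
HISTOGRAM_DIVERGENCE_THRESHOLD = 0.25


@dataclass
class CostBreakdown:
    """The three ingredients of the regularized cost and their total."""

    similarity: float
    penalty: float
    gamma: float
    measure: str = "ssd"

    @property
    def total(self) -> float:
        return -self.similarity + self.gamma * self.penalty


@dataclass
class SimilarityChoice:
    measure: Literal["ssd", "mi"]
    histogram_divergence: float


def _check_same_shape(a: Image2D, b: Image2D) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


def ssd(fixed: Image2D, warped: Image2D) -> float:
    """Per-pixel mean squared intensity difference (0 iff identical).

    The mean (rather than raw sum) makes the regularization weight γ
    comparable across image resolutions, which matters because the pipeline
    reuses γ between resized and full-size stages.
    """
    _check_same_shape(fixed, warped)
    diff = fixed.pixels - warped.pixels
    return float(np.mean(diff * diff))


def mutual_information(fixed: Image2D, warped: Image2D,
                       bins: int = HISTOGRAM_BINS) -> float:
    """Shannon mutual information of the joint intensity histogram, in bits."""
    _check_same_shape(fixed, warped)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint, _, _ = np.histogram2d(fixed.pixels.ravel(), warped.pixels.ravel(),
                                 bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz]))
    return float(max(mi, 0.0))


def histogram_divergence(fixed: Image2D, moving: Image2D,
                         bins: int = HISTOGRAM_BINS) -> float:
    """Σ |hist(I_M) − hist(I_F)| on unit-mass histograms over a common range."""
    _check_same_shape_allow_any(fixed, moving)
    lo = min(fixed.pixels.min(), moving.pixels.min())
    hi = max(fixed.pixels.max(), moving.pixels.max())
    if hi <= lo:
        hi = lo + 1.0  # both images constant and equal: flat common range
    hf, _ = np.histogram(fixed.pixels, bins=bins, range=(lo, hi))
    hm, _ = np.histogram(moving.pixels, bins=bins, range=(lo, hi))
    hf = hf / hf.sum()
    hm = hm / hm.sum()
    return float(np.abs(hm - hf).sum())


def _check_same_shape_allow_any(a: Image2D, b: Image2D) -> None:
    if a.pixels.size == 0 or b.pixels.size == 0:
        raise ValueError("empty image")


def choose_similarity(fixed: Image2D, moving: Image2D,
                      bins: int = HISTOGRAM_BINS) -> SimilarityChoice:
    """Histogram rule: MI when gray-level histograms diverge, else SSD."""
    div = histogram_divergence(fixed, moving, bins=bins)
    measure = "mi" if div > HISTOGRAM_DIVERGENCE_THRESHOLD else "ssd"
    return SimilarityChoice(measure=measure, histogram_divergence=div)


# ---------------------------------------------------------------------------
# Bending-energy penalty
# ---------------------------------------------------------------------------

def _penalty_operators(image_shape, grid: ControlGrid):
    wxx = basis_matrix(image_shape, grid.spacing, grid.extent, deriv=(2, 0))
    wyy = basis_matrix(image_shape, grid.spacing, grid.extent, deriv=(0, 2))
    wxy = basis_matrix(image_shape, grid.spacing, grid.extent, deriv=(1, 1))
    return wxx, wyy, wxy


def bending_penalty(t: Transform2D, image_shape: tuple[int, int]) -> float:
    """Area-averaged squared second derivatives of the transform.

    The affine part has identically zero second derivatives, so the penalty
    depends only on the local FFD; it is exactly zero for any pure affine
    transform.  The integral is taken as the mean over the pixel lattice
    (quadrature = pixel sum / area), exact enough for the piecewise-cubic
    integrand at registration tolerances.
    """
    wxx, wyy, wxy = _penalty_operators(image_shape, t.local)
    total = 0.0
    for comp in range(2):
        p = t.local.displacements[:, :, comp].ravel()
        total += float(np.mean((wxx @ p) ** 2) + np.mean((wyy @ p) ** 2)
                       + 2.0 * np.mean((wxy @ p) ** 2))
    return total


_PENALTY_QUAD_CACHE: dict = {}


def penalty_quadratic(image_shape, grid: ControlGrid) -> sparse.csr_matrix:
    """Cached K with  penalty(p) = pᵀKp  per component and  ∇ = 2Kp."""
    key = (tuple(image_shape), float(grid.spacing), grid.extent)
    k = _PENALTY_QUAD_CACHE.get(key)
    if k is None:
        wxx, wyy, wxy = _penalty_operators(image_shape, grid)
        n = image_shape[0] * image_shape[1]
        k = ((wxx.T @ wxx) + (wyy.T @ wyy) + 2.0 * (wxy.T @ wxy)) / n
        k = k.tocsr()
        _PENALTY_QUAD_CACHE[key] = k
    return k


def cost(fixed: Image2D, moving: Image2D, t: Transform2D, gamma: float,
         measure: Optional[str] = None) -> CostBreakdown:
    """Regularized registration cost  C = −S + γP  for a candidate transform.

    ``measure`` forces "ssd" or "mi"; by default the histogram rule picks.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if measure is None:
        measure = choose_similarity(fixed, moving).measure
    warped = warp(moving, t)
    if measure == "ssd":
        sim = -ssd(fixed, warped)
    elif measure == "mi":
        sim = mutual_information(fixed, warped)
    else:
        raise ValueError(f"unknown similarity measure {measure!r}")
    pen = bending_penalty(t, fixed.shape)
    return CostBreakdown(similarity=sim, penalty=pen, gamma=float(gamma),
                         measure=measure)
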