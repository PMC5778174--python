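"""Strain maps from displacement fields.

Small-strain (infinitesimal) components from the displacement gradient::

    ε_x  = ∂U_x/∂x        ε_y  = ∂U_y/∂y        ε_xy = ½(∂U_x/∂y + ∂U_y/∂x)

and the scalar deformation intensity as the plane-strain simplification of
the von Mises equivalent strain::

    ε_eq = sqrt(ε_x² + 2·ε_xy² + ε_y²)

The symmetric (tensor) shear convention is used, which is what makes the
2·ε_xy² term the plane form of the von Mises relationship.  Swelling strains
in cellular tissues are a few percent, well within the small-strain regime.

Derivatives are central differences with one-sided stencils at the image
border; the outermost 2-px band of a strain map should be treated as
unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grid_transform import AffineParams, DisplacementField

__all__ = [
    "StrainField",
    "TotalStrainField",
    "strain_components",
    "equivalent_strain",
    "total_strain",
    "BORDER_BAND_PX",
]

#: Width of the border band where one-sided differences make strains unreliable.
BORDER_BAND_PX = 2


@dataclass
class StrainField:
    eps_x: np.ndarray
    eps_y: np.ndarray
    eps_xy: np.ndarray
    eps_eq: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("eps_x", "eps_y", "eps_xy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if not (self.eps_x.shape == self.eps_y.shape == self.eps_xy.shape):
            raise ValueError("strain component shapes must match")

    @property
    def shape(self) -> tuple[int, int]:
        return self.eps_x.shape


@dataclass
class TotalStrainField:
    """Affine plus non-rigid normal strains, E_xx and E_yy."""

    e_xx: np.ndarray
    e_yy: np.ndarray


def strain_components(field: DisplacementField) -> StrainField:
    """Small-strain components of a displacement field (central differences)."""
    # np.gradient axis 0 = y (rows), axis 1 = x (columns)
    dux_dy, dux_dx = np.gradient(field.u_x)
    duy_dy, duy_dx = np.gradient(field.u_y)
    return StrainField(
        eps_x=dux_dx,
        eps_y=duy_dy,
        eps_xy=0.5 * (dux_dy + duy_dx),
    )


def equivalent_strain(s: StrainField) -> np.ndarray:
    """Von Mises equivalent strain, ε_eq = sqrt(ε_x² + 2ε_xy² + ε_y²)."""
    eq = np.sqrt(s.eps_x**2 + 2.0 * s.eps_xy**2 + s.eps_y**2)
    s.eps_eq = eq
    return eq


def total_strain(affine: AffineParams, nonrigid: StrainField) -> TotalStrainField:
    """Total normal strains: affine small-strain constants plus non-rigid maps.

    The affine contribution is read off the linear part in the small-strain
    sense, E_xx^a = A₁₁ − 1 and E_yy^a = A₂₂ − 1, broadcast over the field.
    """
    a = affine.matrix
    return TotalStrainField(
        e_xx=(a[0, 0] - 1.0) + nonrigid.eps_x,
        e_yy=(a[1, 1] - 1.0) + nonrigid.eps_y,
    )


def masked_strain(s: StrainField, mask: np.ndarray) -> StrainField:
    """Strain maps restricted to a foreground mask (NaN elsewhere).

    The deformation is computed independently of the cellular structure, but
    maps are often displayed on the material phase only.
    """
    out = StrainField(np.where(mask, s.eps_x, np.nan),
                      np.where(mask, s.eps_y, np.nan),
                      np.where(mask, s.eps_xy, np.nan))
    if s.eps_eq is not None:
        out.eps_eq = np.where(mask, s.eps_eq, np.nan)
    return out
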