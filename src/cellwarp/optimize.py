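"""Steepest-descent minimization of the registration cost.

The optimizer works on the control-point displacements of the local FFD (the
global affine stays fixed during the non-rigid stage — the pipeline optimizes
it beforehand).  Each iteration steps along the negative analytic gradient of
the cost and picks the step length with one of two line-search strategies:

* ``parametric`` — brackets a decrease by doubling/halving the trial step and
  takes the minimizer of the quadratic through the last three samples;
* ``wolfe`` — a standard line search enforcing the Armijo (c1 = 1e−4) and
  curvature (c2 = 0.9) conditions.

Iteration stops when ‖∇C‖ ≤ χ or a maximum iteration count is reached.
Accepted steps never increase the cost.  The SSD similarity gradient is the
exact chain rule through the bilinear interpolant of the warped image; the
penalty gradient is the exact quadratic-form derivative in the control
coefficients.  There is no randomness anywhere in the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Callable, Literal, Optional

import numpy as np
import scipy.optimize as sopt

from .grid_transform import (
    Image2D,
    Transform2D,
    basis_matrix,
    evaluate_local_field,
    sample_bilinear,
)
from .objective import penalty_quadratic

__all__ = [
    "OptimizerConfig",
    "OptimizerTrace",
    "LineSearchResult",
    "line_search",
    "cost_gradient",
    "steepest_descent",
    "minimize_steepest_descent",
]


@dataclass
class OptimizerConfig:
    """Steepest-descent settings.

    chi:
        Gradient-norm stopping threshold.  The cost is a per-pixel mean, so
        its control-point gradients are small numbers; 1e-7 is "small" on
        that scale without stopping a barely-started search.
    max_iters:
        Iteration cap.
    line_search:
        "parametric" (quadratic-interpolation bracket) or "wolfe".
    step_init:
        Initial trial step expressed as the largest control-point motion in
        pixels it may cause; later iterations reuse twice the previously
        accepted step.
    """

    chi: float = 1e-7
    max_iters: int = 200
    line_search: Literal["parametric", "wolfe"] = "parametric"
    step_init: float = 0.5

    def __post_init__(self) -> None:
        if self.chi <= 0:
            raise ValueError("chi must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.line_search not in ("parametric", "wolfe"):
            raise ValueError(f"unknown line search {self.line_search!r}")


@dataclass
class OptimizerTrace:
    costs: list = dfield(default_factory=list)
    grad_norms: list = dfield(default_factory=list)
    steps: list = dfield(default_factory=list)
    converged: bool = False
    warnings: list = dfield(default_factory=list)


@dataclass
class LineSearchResult:
    step: float
    value: float
    warning: bool = False


# ---------------------------------------------------------------------------
# Line searches
# ---------------------------------------------------------------------------

def _quadratic_min(s0, f0, s1, f1, s2, f2) -> Optional[float]:
    """Vertex of the parabola through three samples; None if not convex."""
    denom = (s0 - s1) * (s0 - s2) * (s1 - s2)
    if denom == 0:
        return None
    a = (s2 * (f1 - f0) + s1 * (f0 - f2) + s0 * (f2 - f1)) / denom
    b = (s2**2 * (f0 - f1) + s1**2 * (f2 - f0) + s0**2 * (f1 - f2)) / denom
    if a <= 0:
        return None
    return -b / (2 * a)


def line_search(phi: Callable[[float], float],
                dphi: Callable[[float], float],
                strategy: str = "parametric",
                step_init: float = 1.0,
                max_halvings: int = 40) -> LineSearchResult:
    """Pick a step along a descent ray.

    ``phi(s)`` is the cost along the ray and ``dphi(s)`` its derivative;
    ``dphi(0) < 0`` is required (descent direction).  The parametric strategy
    samples the ray, brackets a decrease, and returns the minimizer of a
    quadratic through the samples clipped to the bracket.  The Wolfe strategy
    enforces the Armijo (c1 = 1e−4) and curvature (c2 = 0.9) conditions.

    If no decreasing step is found within the bisection limit the smallest
    trial step is returned with ``warning=True``.
    """
    d0 = dphi(0.0)
    if not d0 < 0:
        raise ValueError(f"not a descent direction (directional derivative {d0})")
    f0 = phi(0.0)

    if strategy == "wolfe":
        # scipy's strong-Wolfe search on a 1-D restriction
        res = sopt.line_search(lambda v: phi(float(v[0])),
                               lambda v: np.array([dphi(float(v[0]))]),
                               np.zeros(1), np.ones(1),
                               gfk=np.array([d0]), old_fval=f0,
                               c1=1e-4, c2=0.9, maxiter=max_halvings)
        alpha, fval = res[0], res[3]
        if alpha is not None and fval is not None and fval < f0:
            return LineSearchResult(step=float(alpha), value=float(fval))
        # fall through to a plain backtracking rescue
        s = step_init
        for _ in range(max_halvings):
            fs = phi(s)
            if fs < f0 + 1e-4 * s * d0:
                return LineSearchResult(step=s, value=fs)
            s *= 0.5
        return LineSearchResult(step=s, value=phi(s), warning=True)

    if strategy != "parametric":
        raise ValueError(f"unknown line-search strategy {strategy!r}")

    s1 = float(step_init)
    f1 = phi(s1)
    if f1 < f0:
        # expand until the cost turns upward, then fit the quadratic
        samples = [(0.0, f0), (s1, f1)]
        s_prev, f_prev = s1, f1
        for _ in range(max_halvings):
            s_next = s_prev * 2.0
            f_next = phi(s_next)
            samples.append((s_next, f_next))
            if f_next >= f_prev:
                break
            s_prev, f_prev = s_next, f_next
        (sa, fa), (sb, fb), (sc, fc) = samples[-3:]
        s_quad = _quadratic_min(sa, fa, sb, fb, sc, fc)
        best_s, best_f = min(samples, key=lambda t: t[1])
        if s_quad is not None:
            s_quad = float(np.clip(s_quad, min(sa, 1e-12), sc))
            f_quad = phi(s_quad)
            if f_quad < best_f:
                best_s, best_f = s_quad, f_quad
        return LineSearchResult(step=best_s, value=best_f)

    # shrink until a decrease appears
    s = s1
    for _ in range(max_halvings):
        s *= 0.5
        fs = phi(s)
        if fs < f0:
            s2, f2 = 2 * s, phi(2 * s) if 2 * s != s1 else f1
            s_quad = _quadratic_min(0.0, f0, s, fs, s2, f2)
            if s_quad is not None and 0 < s_quad < s2:
                f_quad = phi(float(s_quad))
                if f_quad < fs:
                    return LineSearchResult(step=float(s_quad), value=f_quad)
            return LineSearchResult(step=s, value=fs)
    return LineSearchResult(step=s, value=phi(s), warning=True)


# ---------------------------------------------------------------------------
# Analytic gradient of the registration cost
# ---------------------------------------------------------------------------

def _warp_residual_and_grads(fixed: Image2D, moving: Image2D, t: Transform2D):
    h, w = fixed.shape
    ys, xs = np.mgrid[0:h, 0:w]
    gx, gy = t.global_.apply(xs.astype(float), ys.astype(float))
    local = evaluate_local_field(t.local, fixed.shape)
    sx = (gx + local.u_x).ravel()
    sy = (gy + local.u_y).ravel()
    vals, dvx, dvy = sample_bilinear(moving.pixels, sx, sy, with_gradient=True)
    resid = vals - fixed.pixels.ravel()
    return resid, dvx, dvy


def cost_gradient(fixed: Image2D, moving: Image2D, t: Transform2D,
                  gamma: float) -> np.ndarray:
    """∂C/∂Π for every control-point displacement component.

    Returns an array shaped like ``t.local.displacements`` (ny, nx, 2).  The
    similarity term is SSD (the default measure of the pipeline); the penalty
    term is the bending energy.  Matches central finite differences to
    roundoff-limited accuracy.
    """
    resid, dvx, dvy = _warp_residual_and_grads(fixed, moving, t)
    n = resid.size
    mat = basis_matrix(fixed.shape, t.local.spacing, t.local.extent)
    gx_ctrl = mat.T @ (2.0 / n * resid * dvx)
    gy_ctrl = mat.T @ (2.0 / n * resid * dvy)
    grad = np.stack([gx_ctrl, gy_ctrl], axis=1)
    if gamma > 0:
        k = penalty_quadratic(fixed.shape, t.local)
        for comp in range(2):
            p = t.local.displacements[:, :, comp].ravel()
            grad[:, comp] += gamma * 2.0 * (k @ p)
    ny, nx, _ = t.local.displacements.shape
    return grad.reshape(ny, nx, 2)


def _cost_value(fixed: Image2D, moving: Image2D, t: Transform2D,
                gamma: float) -> float:
    resid, _, _ = _warp_residual_and_grads(fixed, moving, t)
    total = float(np.mean(resid**2))
    if gamma > 0:
        k = penalty_quadratic(fixed.shape, t.local)
        for comp in range(2):
            p = t.local.displacements[:, :, comp].ravel()
            total += gamma * float(p @ (k @ p))
    return total


# ---------------------------------------------------------------------------
# Steepest descent
# ---------------------------------------------------------------------------

def minimize_steepest_descent(fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
                              x0: np.ndarray,
                              cfg: OptimizerConfig) -> tuple[np.ndarray, OptimizerTrace]:
    """Generic steepest descent with line search on a smooth objective.

    ``fun_grad(x)`` returns ``(value, gradient)``.  Used both for the FFD
    control lattice and (by the pipeline) for the affine pre-registration.
    """
    x = np.asarray(x0, dtype=np.float64).copy()
    trace = OptimizerTrace()
    f, g = fun_grad(x)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite cost at the starting point")
    prev_step = None
    for it in range(cfg.max_iters):
        gnorm = float(np.linalg.norm(g))
        trace.costs.append(f)
        trace.grad_norms.append(gnorm)
        if gnorm <= cfg.chi:
            trace.converged = True
            break
        d = -g

        def phi(s, _x=x, _d=d):
            val, _ = fun_grad(_x + s * _d)
            return val

        def dphi(s, _x=x, _d=d):
            _, grad = fun_grad(_x + s * _d)
            return float(grad @ _d)

        if prev_step is None:
            ginf = float(np.max(np.abs(g)))
            s_init = cfg.step_init / ginf if ginf > 0 else 1.0
        else:
            s_init = prev_step * 2.0
        ls = line_search(phi, dphi, strategy=cfg.line_search, step_init=s_init)
        if not np.isfinite(ls.value):
            raise FloatingPointError(
                f"non-finite cost during line search at iteration {it}")
        if ls.value >= f:
            # no admissible decrease: stop at the current (locally optimal) x
            trace.warnings.append(f"iteration {it}: no decreasing step found")
            break
        x = x + ls.step * d
        f_new, g = fun_grad(x)
        f = f_new
        trace.steps.append(ls.step)
        prev_step = ls.step
        if ls.warning:
            trace.warnings.append(f"iteration {it}: line-search fallback step")
    else:
        # ran out of iterations: record the final state
        gnorm = float(np.linalg.norm(g))
        trace.costs.append(f)
        trace.grad_norms.append(gnorm)
        trace.converged = gnorm <= cfg.chi
    return x, trace


def steepest_descent(fixed: Image2D, moving: Image2D, t0: Transform2D,
                     gamma: float,
                     cfg: Optional[OptimizerConfig] = None
                     ) -> tuple[Transform2D, OptimizerTrace]:
    """Optimize the FFD control displacements of ``t0`` (affine part fixed).

    Returns the optimized transform and the iteration trace.  The cost is the
    per-pixel SSD of (fixed, warped moving) plus γ times the bending energy.
    """
    if cfg is None:
        cfg = OptimizerConfig()
    t = t0.copy()
    shape = t.local.displacements.shape

    def fun_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        t.local.displacements = x.reshape(shape)
        f = _cost_value(fixed, moving, t, gamma)
        g = cost_gradient(fixed, moving, t, gamma)
        return f, g.ravel()

    x_opt, trace = minimize_steepest_descent(
        fun_grad, t0.local.displacements.ravel(), cfg)
    t.local.displacements = x_opt.reshape(shape)
    return t, trace
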