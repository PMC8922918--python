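"""Quasi-Newton (BFGS) minimiser with backtracking line search.

The update maintains an approximation B_k of the Hessian:

    B_{k+1} = B_k - (B_k s_k s_k' B_k) / (s_k' B_k s_k) + (y_k y_k') / (s_k' y_k)

with s_k = x_{k+1} - x_k and y_k = g_{k+1} - g_k, starting from B_0 = I; the
search direction solves B_k d_k = -g_k and the step length satisfies the
Armijo sufficient-decrease condition.  Iteration stops at the first iterate
with ||g|| below ``grad_tol`` (default 1e-6).  Updates with s'y <= 0 (possible
on non-convex stretches) are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["bfgs_minimize", "OptimizeResult", "LineSearchError"]


class LineSearchError(RuntimeError):
    """Backtracking exhausted without sufficient decrease."""

    def __init__(self, message, x, fval, grad):
        super().__init__(message)
        self.x = x
        self.fval = fval
        self.grad = grad


@dataclass
class OptimizeResult:
    x: np.ndarray
    fval: float
    grad: np.ndarray
    n_iter: int
    converged: bool
    n_skipped_updates: int = 0
    message: str = ""
    path: list[np.ndarray] = field(default_factory=list)
    hess_approx: np.ndarray | None = None

    @property
    def grad_norm(self) -> float:
        return float(np.linalg.norm(self.grad))


def bfgs_minimize(
    objective,
    x0,
    grad_tol: float = 1e-6,
    max_iter: int = 500,
    armijo_c1: float = 1e-4,
    backtrack_factor: float = 0.5,
    max_backtracks: int = 50,
    record_path: bool = False,
) -> OptimizeResult:
    """Minimise a smooth function given as ``objective(x) -> (value, gradient)``.

    Non-convergence within ``max_iter`` is reported through the ``converged``
    flag rather than an exception; a failed line search raises
    :class:`LineSearchError` carrying the current iterate.
    """
    x = np.asarray(x0, dtype=float).copy()
    f, g = objective(x)
    g = np.asarray(g, dtype=float)
    if not (np.isfinite(f) and np.isfinite(g).all()):
        raise ValueError("objective non-finite at the starting point")
    B = np.eye(x.size)
    n_skipped = 0
    path = [x.copy()] if record_path else []

    for it in range(max_iter):
        if np.linalg.norm(g) < grad_tol:
            return OptimizeResult(
                x, f, g, it, True, n_skipped, "gradient norm below tolerance",
                path, B,
            )
        d = -np.linalg.solve(B, g)
        slope = float(g @ d)
        if slope >= 0:  # B lost positive definiteness; fall back to steepest descent
            d = -g
            slope = float(g @ d)
        alpha = 1.0
        for _ in range(max_backtracks):
            x_new = x + alpha * d
            f_new, g_new = objective(x_new)
            if np.isfinite(f_new) and f_new <= f + armijo_c1 * alpha * slope:
                break
            alpha *= backtrack_factor
        else:
            raise LineSearchError(
                f"line search failed at iteration {it} (f={f:.6g}, "
                f"||g||={np.linalg.norm(g):.3g})",
                x,
                f,
                g,
            )
        g_new = np.asarray(g_new, dtype=float)
        s = x_new - x
        yk = g_new - g
        sBs = float(s @ B @ s)
        sy = float(s @ yk)
        if sy > 1e-12 * max(1.0, np.linalg.norm(s) * np.linalg.norm(yk)) and sBs > 0:
            Bs = B @ s
            B = B - np.outer(Bs, Bs) / sBs + np.outer(yk, yk) / sy
        else:
            n_skipped += 1
        x, f, g = x_new, f_new, g_new
        if record_path:
            path.append(x.copy())

    converged = bool(np.linalg.norm(g) < grad_tol)
    return OptimizeResult(
        x,
        f,
        g,
        max_iter,
        converged,
        n_skipped,
        "converged" if converged else "maximum iterations reached",
        path,
        B,
    )
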