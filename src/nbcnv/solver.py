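"""Penalized negative-binomial likelihood segmentation by ADMM.

The caller reconstructs a piecewise-constant copy-number signal x from
per-bin counts y by minimizing

    sum_t [ (y_t + a) log(x_t + a) - y_t log x_t ]          (NB fidelity)
    + (lambda1 / s) * sum |x_{t+1} - x_t|                   (total variation)
    + (lambda2 / s) * sum |x_t - c|                         (sparsity at baseline)

subject to x > 0, where a is the NB over-dispersion, c the baseline
(copy-neutral) count level and s the signal scale (by default mean(y)).
Dividing the penalty weights by s expresses lambda1/lambda2 per unit of
*relative read depth*, so the same weights transfer between datasets of
different sequencing depth; the fidelity term keeps y on the count scale,
as the NB pmf requires.  A Poisson fidelity sum_t [x_t - y_t log x_t]
(the "poiCNV" baseline) is available through ``SolverConfig.fidelity``.

The objective is split ADMM-style with the stacked operator
G = [I; I; D; I] (D the forward-difference matrix), attaching to the four
blocks the fidelity term, the positivity indicator, the TV penalty and the
centered-L1 penalty.  The x-update is a symmetric positive-definite
tridiagonal solve (G'G = 3I + D'D), the u-update is blockwise proximal,
and the dual update is d <- d - (Gx - u).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .core import SolverConfig, SolverDivergenceError, ValidationError

_X_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# stacked operator G = [I; I; D; I]
# ---------------------------------------------------------------------------


def block_slices(n: int) -> tuple[slice, slice, slice, slice]:
    """Index slices of the four stacked blocks (n, n, n-1, n)."""
    return (slice(0, n), slice(n, 2 * n),
            slice(2 * n, 3 * n - 1), slice(3 * n - 1, 4 * n - 1))


def apply_G(x: np.ndarray) -> np.ndarray:
    return np.concatenate([x, x, np.diff(x), x])


def apply_Gt(v: np.ndarray, n: int) -> np.ndarray:
    b1, b2, b3, b4 = block_slices(n)
    out = v[b1] + v[b2] + v[b4]
    w = v[b3]
    out[:-1] -= w
    out[1:] += w
    return out


def solve_x_subproblem(u_plus_d: np.ndarray, n: int) -> np.ndarray:
    """Solve (G'G) x = G'(u + d), the quadratic x-update.

    G'G = 3I + D'D is tridiagonal with diagonal (4, 5, ..., 5, 4) and
    off-diagonal -1 (just 3 for n = 1); solved in O(n) with a banded
    Cholesky factorization.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if u_plus_d.shape[0] != 4 * n - 1:
        raise ValidationError("stacked vector has wrong length for n")
    rhs = apply_Gt(u_plus_d, n)
    if n == 1:
        return rhs / 3.0
    ab = np.zeros((2, n))
    ab[0, 1:] = -1.0
    ab[1, :] = 5.0
    ab[1, 0] = ab[1, -1] = 4.0
    return solveh_banded(ab, rhs)


# ---------------------------------------------------------------------------
# proximal operators
# ---------------------------------------------------------------------------


def prox_positive(v):
    """Projection onto the nonnegative orthant."""
    return np.maximum(v, 0.0)


def prox_l1(v, threshold):
    """Soft thresholding, the proximal map of threshold * |.|."""
    return np.sign(v) * np.maximum(np.abs(v) - threshold, 0.0)


def prox_l1_centered(v, threshold, center):
    """Soft thresholding toward ``center`` (proximal map of t*|. - c|)."""
    return center + prox_l1(np.asarray(v) - center, threshold)


def _real_cubic_roots(b, c, d):
    """All real roots of the monic cubics z^3 + b z^2 + c z + d, vectorized.

    Returns an (m, 3) array, NaN where a root does not exist.  Uses the
    trigonometric method for three real roots and Cardano's formula for one.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    m = np.broadcast(b, c, d).size
    b, c, d = np.broadcast_to(b, (m,)).copy(), np.broadcast_to(c, (m,)).copy(), \
        np.broadcast_to(d, (m,)).copy()
    p = c - b * b / 3.0
    q = 2.0 * b**3 / 27.0 - b * c / 3.0 + d
    roots = np.full((m, 3), np.nan)
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    shift = -b / 3.0

    three = (disc <= 0) & (p < 0)
    if np.any(three):
        pp, qq = p[three], q[three]
        r = np.sqrt(-pp / 3.0)
        arg = np.clip(3.0 * qq / (2.0 * pp * r), -1.0, 1.0)
        theta = np.arccos(arg) / 3.0
        for k in range(3):
            roots[three, k] = 2.0 * r * np.cos(theta - 2.0 * np.pi * k / 3.0) \
                + shift[three]
    one = ~three
    if np.any(one):
        dd = np.sqrt(np.maximum(disc[one], 0.0))
        t = np.cbrt(-q[one] / 2.0 + dd) + np.cbrt(-q[one] / 2.0 - dd)
        roots[one, 0] = t + shift[one]
    return roots


def _nb_prox_objective(z, v, y, alpha, penalty, scale):
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (y + alpha) * np.log(scale * z + alpha) - y * np.log(z)
    return g + 0.5 * penalty * (z - v) ** 2


def _nb_prox_grad(z, v, y, alpha, penalty, scale):
    return alpha * (scale * z - y) / (z * (scale * z + alpha)) + penalty * (z - v)


def prox_nb_fidelity(v, y, dispersion: float, penalty: float, scale: float = 1.0):
    """Proximal map of the NB fidelity (y+a)log(s z + a) - y log z.

    Stationarity a(s z - y) + penalty (z - v) z (s z + a) = 0 is a cubic in
    z; all positive real roots are enumerated (the fidelity is not convex
    for small y) and the one with the lowest objective returned, so the
    subproblem is solved exactly even in the nonconvex case.  A safeguarded
    Newton polish tightens each root.  For y = 0 the minimizer may approach
    zero; it is floored at 1e-12.
    """
    if not penalty > 0:
        raise ValidationError("penalty must be positive")
    if not dispersion > 0:
        raise ValidationError("dispersion must be positive")
    if not scale > 0:
        raise ValidationError("scale must be positive")
    scalar = np.isscalar(v) and np.isscalar(y)
    v = np.atleast_1d(np.asarray(v, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    v, y = np.broadcast_arrays(v, y)
    a, mu, s = float(dispersion), float(penalty), float(scale)
    # cubic: mu*s z^3 + mu(a - s v) z^2 + (a s - mu v a) z - a y = 0, monic form
    b = (a - s * v) / s
    c = (a * s - mu * v * a) / (mu * s)
    d = -a * y / (mu * s)
    roots = _real_cubic_roots(b, c, d)
    # two Newton polish sweeps tighten the analytic roots numerically
    vv, yy = v[:, None], y[:, None]
    for _ in range(2):
        z = roots
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            grad = _nb_prox_grad(z, vv, yy, a, mu, s)
            # d(grad)/dz = a (y (2 s z + a) - s^2 z^2) / (z^2 (s z + a)^2) + mu
            dgrad = a * (yy * (2.0 * s * z + a) - (s * z) ** 2) \
                / (z ** 2 * (s * z + a) ** 2) + mu
            polished = z - grad / dgrad
        take = np.isfinite(polished) & (polished > 0)
        roots = np.where(take, polished, roots)
    candidates = np.where(np.isfinite(roots) & (roots > 0), roots, np.nan)
    # y == 0: allow the floor as a candidate (fidelity pushes z toward 0)
    floor_col = np.full((v.shape[0], 1), np.nan)
    floor_col[y == 0, 0] = _X_FLOOR
    candidates = np.concatenate([candidates, floor_col], axis=1)
    obj = _nb_prox_objective(candidates, vv, yy, a, mu, s)
    obj = np.where(np.isfinite(obj), obj, np.inf)
    best = np.argmin(obj, axis=1)
    out = candidates[np.arange(candidates.shape[0]), best]
    # fallback: bisection on the gradient for any row without a usable root
    bad = ~np.isfinite(out) | (out <= 0)
    for i in np.nonzero(bad)[0]:
        out[i] = _nb_prox_bisect(float(v[i]), float(y[i]), a, mu, s)
    out = np.maximum(out, _X_FLOOR)
    return float(out[0]) if scalar else out


def _nb_prox_bisect(v, y, a, mu, s):
    lo, hi = _X_FLOOR, max(abs(v), y / s if s else 0.0, 1.0) * 4 + 10.0
    glo = _nb_prox_grad(lo, v, y, a, mu, s)
    if glo > 0:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _nb_prox_grad(mid, v, y, a, mu, s) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def prox_poisson_fidelity(v, y, penalty: float, scale: float = 1.0):
    """Proximal map of the Poisson fidelity s z - y log z (closed form).

    The stationarity penalty z^2 + (s - penalty v) z - y = 0 has a unique
    positive root z = [(penalty v - s) + sqrt((penalty v - s)^2 + 4 penalty y)]
    / (2 penalty).
    """
    if not penalty > 0:
        raise ValidationError("penalty must be positive")
    scalar = np.isscalar(v) and np.isscalar(y)
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    t = penalty * v - scale
    z = (t + np.sqrt(t * t + 4.0 * penalty * y)) / (2.0 * penalty)
    z = np.maximum(z, _X_FLOOR)
    return float(z) if scalar else z


# ---------------------------------------------------------------------------
# objective and main iteration
# ---------------------------------------------------------------------------


def _fidelity(x, y, cfg: SolverConfig):
    a = cfg.dispersion
    if cfg.fidelity == "negative_binomial":
        return np.sum((y + a) * np.log(x + a) - y * np.log(x))
    return np.sum(x - y * np.log(x))


def objective(x, y, cfg: SolverConfig) -> float:
    """Value of the penalized negative log-likelihood at count-scale x.

    Returns +inf (barrier semantics) if any component of x is nonpositive.
    Penalties are weighted lambda/s with s = ``cfg.signal_scale`` (default
    mean(y)); with s = 1 this is the plain count-scale objective.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        return float("inf")
    s = cfg.signal_scale if cfg.signal_scale is not None else float(np.mean(y))
    c = cfg.baseline_c if cfg.baseline_c is not None else float(np.mean(y))
    pen = (cfg.lambda1 / s) * np.sum(np.abs(np.diff(x))) \
        + (cfg.lambda2 / s) * np.sum(np.abs(x - c))
    return float(_fidelity(x, y, cfg) + pen)


@dataclass
class ADMMState:
    """Final iterates and diagnostics of an ADMM run.

    ``x`` is the fitted signal on the count scale; ``u`` and ``d`` are the
    stacked slack and (scaled) dual blocks on the solver's internal
    relative-read-depth scale, ordered (fidelity, positivity, difference,
    sparsity) with lengths (n, n, n-1, n).
    """

    x: np.ndarray
    u: np.ndarray
    d: np.ndarray
    n_iter: int
    primal_residual: float
    dual_residual: float
    converged: bool


def admm_fit(y, cfg: SolverConfig) -> tuple[np.ndarray, ADMMState]:
    """Minimize the penalized NB (or Poisson) objective over x > 0.

    Parameters
    ----------
    y : array of nonnegative (possibly GC-normalized, hence real-valued)
        per-bin counts.
    cfg : SolverConfig.  ``baseline_c`` and ``signal_scale`` default to
        mean(y).

    Returns
    -------
    x : fitted count-scale signal, elementwise positive (floored at 1e-12).
    state : ADMMState with residuals and iteration count.

    The iteration stops when max(||Gz - u||_2, mu ||u_k - u_{k-1}||_2) /
    sqrt(4n - 1) < tol, or after ``max_iter`` iterations.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValidationError("y must be a nonempty 1-D array")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValidationError("y must be finite and nonnegative")
    n = y.size
    s = cfg.signal_scale if cfg.signal_scale is not None else float(np.mean(y))
    if not s > 0:
        raise ValidationError("signal scale is zero (all-zero counts?)")
    c = cfg.baseline_c if cfg.baseline_c is not None else float(np.mean(y))
    c_z = c / s
    mu = cfg.admm_penalty
    thr1 = cfg.lambda1 / mu
    thr2 = cfg.lambda2 / mu
    b1, b2, b3, b4 = block_slices(n)

    z = np.maximum(y, c / 10.0) / s
    u = apply_G(z)
    d = np.zeros_like(u)
    norm_div = np.sqrt(4.0 * n - 1.0)
    primal = dual = float("inf")
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        z = solve_x_subproblem(u + d, n)
        Gz = apply_G(z)
        v = Gz - d
        u_new = np.empty_like(u)
        if cfg.fidelity == "negative_binomial":
            u_new[b1] = prox_nb_fidelity(v[b1], y, cfg.dispersion, mu, scale=s)
        else:
            u_new[b1] = prox_poisson_fidelity(v[b1], y, mu, scale=s)
        u_new[b2] = prox_positive(v[b2])
        u_new[b3] = prox_l1(v[b3], thr1)
        u_new[b4] = prox_l1_centered(v[b4], thr2, c_z)
        primal = float(np.linalg.norm(Gz - u_new))
        dual = float(mu * np.linalg.norm(u_new - u))
        u = u_new
        d = d - (Gz - u)
        if not (np.isfinite(primal) and np.isfinite(dual)):
            raise SolverDivergenceError(it)
        if max(primal, dual) / norm_div < cfg.tol:
            converged = True
            break
    x = np.maximum(s * z, _X_FLOOR)
    state = ADMMState(x=x, u=u, d=d, n_iter=it,
                      primal_residual=primal, dual_residual=dual,
                      converged=converged)
    return x, state
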