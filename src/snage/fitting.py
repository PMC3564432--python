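"""Fitting snaGe models to time-frequency images.

The pipeline follows three stages:

1. *Initialization* — a slope-bounded horizontal path through the TFR image
   maximizing the sum of traversed pixel intensities is found exactly by
   dynamic programming (a maximum-energy seam).  The smoothed path supplies
   the initial time-frequency coordinates of the peak points; offset and
   spreads get conservative data-driven defaults.
2. *Nonlinear least squares* — the sum of squared residuals between the
   image and the model surface is minimized by a trust-region reflective
   algorithm with per-parameter typical-value scaling.  The surface used by
   the optimizer evaluates the curve parameter on a fixed discrete grid, so
   the analytic Jacobian (envelope rule: differentiate at the selected
   family member) is exact for that objective.
3. *Iterative refinement* — the fitted curve of peaks is resampled at one
   additional uniform site per step and refitted, growing the model order
   robustly while preserving the optimizer's point distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares

from .exceptions import (
    FitDivergedError,
    InvalidArgumentError,
    UndefinedMetricError,
)
from .model import (
    SnaGeParams,
    eval_snage_grid,
    pack_params,
    unpack_params,
)
from .tfr import TFRGrid

__all__ = [
    "OptimalPath",
    "FitResult",
    "FitOptions",
    "sse",
    "optimal_path",
    "smooth_path",
    "init_params",
    "fit",
    "refine",
    "goodness",
]


@dataclass(frozen=True)
class OptimalPath:
    """A left-to-right, slope-bounded path of frequency-bin indices."""

    row_index: np.ndarray
    total_energy: float

    def __post_init__(self):
        object.__setattr__(
            self, "row_index", np.asarray(self.row_index, dtype=int)
        )


@dataclass
class FitResult:
    """Outcome of one nonlinear least-squares fit."""

    params: SnaGeParams
    sse: float
    r2: float
    r2_adj: float
    n_obs: int
    n_params: int
    converged: bool
    sse_init: float = np.nan
    nfev: int = 0


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration.

    ``u_density`` samples per unit of the curve parameter define the
    discrete surface the optimizer sees; 20 is ample for the smooth
    objectives produced by preprocessing.  ``sigma_floor_frac`` scales the
    positivity lower bound of the spreads by the squared axis ranges.

    ``bound_positions`` keeps peak-point coordinates inside the observed
    time-frequency window and ``bound_amplitudes`` keeps the peak
    amplitudes nonnegative (appropriate for clipped, nonnegative TFR data).
    Both constraints prevent degenerate fits in which weakly determined
    peak points wander far from the data.
    """

    u_density: int = 20
    xtol: float = 1e-8
    ftol: float = 1e-8
    gtol: float = 1e-8
    max_iter: int = 400
    sigma_floor_frac: float = 1e-6
    bound_positions: bool = True
    bound_amplitudes: bool = True


def sse(m: SnaGeParams, tfr: TFRGrid, u_density: int = 50) -> float:
    """Sum of squared differences between the image and the model surface."""
    r = residuals(m, tfr, u_density=u_density)
    return float(np.dot(r, r))


def residuals(m: SnaGeParams, tfr: TFRGrid, u_density: int = 50) -> np.ndarray:
    """Per-pixel residual vector ``y_model - y_data`` (row-major order)."""
    Pm = eval_snage_grid(m, tfr.t, tfr.f, grid_density=u_density, polish=False)
    return (Pm - tfr.P).ravel()


def optimal_path(P: np.ndarray, k: int = 2) -> OptimalPath:
    """Maximum-energy horizontal seam with per-column slope bound ``k``.

    Dynamic programming guarantees the global optimum over all paths whose
    row index changes by at most ``k`` between adjacent columns.  Ties are
    broken deterministically: the smallest row index wins at the final
    column, and backtracking prefers the smallest absolute row step (then
    the smaller row).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.size == 0:
        raise InvalidArgumentError("P must be a nonempty 2-D matrix")
    if k < 0 or int(k) != k:
        raise InvalidArgumentError("slope bound k must be a nonnegative integer")
    k = int(k)
    nr, nc = P.shape
    cum = P[:, 0].astype(float).copy()
    # offsets ordered by |step| then signed value: 0, -1, +1, -2, +2, ...
    offsets = [0]
    for s in range(1, k + 1):
        offsets.extend([-s, s])
    back = np.zeros((nr, nc), dtype=int)
    for j in range(1, nc):
        best = np.full(nr, -np.inf)
        best_prev = np.zeros(nr, dtype=int)
        for off in offsets:
            prev = np.arange(nr) + off  # candidate predecessor rows
            ok = (prev >= 0) & (prev < nr)
            cand = np.where(ok, cum[np.clip(prev, 0, nr - 1)], -np.inf)
            better = cand > best
            best = np.where(better, cand, best)
            best_prev = np.where(better, np.clip(prev, 0, nr - 1), best_prev)
        cum = best + P[:, j]
        back[:, j] = best_prev
    end = int(np.argmax(cum))  # first max -> smallest row index
    rows = np.empty(nc, dtype=int)
    rows[-1] = end
    for j in range(nc - 1, 0, -1):
        rows[j - 1] = back[rows[j], j]
    return OptimalPath(row_index=rows, total_energy=float(cum[end]))


def smooth_path(
    s: OptimalPath,
    t_axis: np.ndarray,
    f_axis: np.ndarray,
    window: int | None = None,
):
    """Smooth the raw seam into a curve ``t -> f``.

    A centered moving average (shrinking symmetrically at the edges, so
    constant paths are preserved) is applied to the path's frequency values;
    the default window is 10% of the number of columns, odd-rounded.
    Returns ``(t_values, f_values)`` plus a linear interpolant as a callable.
    """
    t_axis = np.asarray(t_axis, dtype=float)
    f_axis = np.asarray(f_axis, dtype=float)
    fvals = f_axis[s.row_index]
    nc = fvals.size
    if window is None:
        window = max(3, int(round(0.10 * nc)) | 1)
    if window < 1:
        raise InvalidArgumentError("smoothing window must be >= 1")
    window = min(int(window), nc)
    if window > 1:
        fvals = uniform_filter1d(fvals, size=window, mode="nearest")
    interp = interp1d(
        t_axis, fvals, kind="linear", bounds_error=False,
        fill_value=(fvals[0], fvals[-1]),
    )
    return t_axis, fvals, interp


def init_params(
    tfr: TFRGrid,
    K: int,
    k: int = 2,
    smooth_window: int | None = None,
) -> SnaGeParams:
    """Data-driven initial parameters from the optimal image path.

    Offset starts at zero; each spread at one fifth of its axis range; the
    peak points' time-frequency coordinates are ``K`` evenly spaced (in
    time) samples of the smoothed optimal path, all with initial amplitude
    ``max(y_TFR)`` relative to the zero offset.
    """
    if K < 1:
        raise InvalidArgumentError("model order K must be >= 1")
    if K > tfr.t.size:
        raise InvalidArgumentError("model order K exceeds the number of time columns")
    path = optimal_path(tfr.P, k=k)
    _, _, f_of_t = smooth_path(path, tfr.t, tfr.f, window=smooth_window)
    t_pts = np.linspace(tfr.t[0], tfr.t[-1], K)
    f_pts = np.asarray(f_of_t(t_pts), dtype=float)
    a0 = float(tfr.P.max())
    points = np.column_stack([t_pts, f_pts, np.full(K, a0)])
    sigma = np.array(
        [(tfr.t[-1] - tfr.t[0]) / 5.0, (tfr.f[-1] - tfr.f[0]) / 5.0]
    )
    return SnaGeParams(C=0.0, sigma_diag=sigma, peak_points=points)


def _jacobian_from_aux(aux, K):
    """Analytic Jacobian of the surface w.r.t. the flat parameter vector.

    At the selected family member u* the surface is
    ``C + A(u*) exp(E)`` with ``A(u*) = sum_i b_i A_i`` and
    ``mu(u*) = sum_i b_i (t_i, f_i)``; differentiating at fixed u*
    (envelope rule) gives exact gradients almost everywhere.
    """
    e = aux["exp_term"]
    A = aux["amp"]
    dt = aux["dt"]
    df = aux["df"]
    b = aux["basis"]  # (npx, K)
    s1, s2 = aux["sigma_diag"]
    npx = e.size
    J = np.empty((npx, 3 + 3 * K))
    J[:, 0] = 1.0  # dC
    Ae = A * e
    J[:, 1] = Ae * 0.5 * dt**2 / s1**2
    J[:, 2] = Ae * 0.5 * df**2 / s2**2
    J[:, 3::3] = (Ae * dt / s1)[:, None] * b  # d/dt_i
    J[:, 4::3] = (Ae * df / s2)[:, None] * b  # d/df_i
    J[:, 5::3] = e[:, None] * b  # d/dA_i
    return J


def fit(
    tfr: TFRGrid,
    init: SnaGeParams,
    options: FitOptions | None = None,
) -> FitResult:
    """Trust-region nonlinear least squares from the given initial model.

    The flat parameter vector is optimized with per-parameter typical-value
    scaling (axis ranges for positions/spreads, peak power for amplitudes
    and offset); spreads are kept positive by box lower bounds.  The
    returned SSE never exceeds the initial SSE.
    """
    opts = options or FitOptions()
    K = init.K
    t, f = tfr.t, tfr.f
    y = tfr.P.ravel()
    x0 = pack_params(init)
    t_range = max(t[-1] - t[0], np.finfo(float).tiny)
    f_range = max(f[-1] - f[0], np.finfo(float).tiny)
    p_scale = max(float(np.abs(tfr.P).max()), np.finfo(float).tiny)

    lb = np.full(x0.size, -np.inf)
    ub = np.full(x0.size, np.inf)
    lb[1] = opts.sigma_floor_frac * t_range**2
    lb[2] = opts.sigma_floor_frac * f_range**2
    if opts.bound_positions:
        lb[3::3] = t[0]
        ub[3::3] = t[-1]
        lb[4::3] = f[0]
        ub[4::3] = f[-1]
    if opts.bound_amplitudes:
        lb[5::3] = 0.0
    x0 = np.clip(x0, lb, ub)

    x_scale = np.empty(x0.size)
    x_scale[0] = p_scale
    x_scale[1] = t_range**2 / 25.0
    x_scale[2] = f_range**2 / 25.0
    x_scale[3::3] = t_range
    x_scale[4::3] = f_range
    x_scale[5::3] = p_scale

    cache: dict = {}

    def _eval(x):
        key = x.tobytes()
        if cache.get("key") != key:
            m = unpack_params(x, K)
            Pm, aux = eval_snage_grid(
                m, t, f, grid_density=opts.u_density, polish=False,
                return_aux=True,
            )
            aux["sigma_diag"] = m.sigma_diag
            r = Pm.ravel() - y
            if not np.all(np.isfinite(r)):
                raise FitDivergedError(
                    "non-finite cost during optimization", last_params=cache.get("x")
                )
            cache.update(key=key, x=x.copy(), r=r, aux=aux)
        return cache

    def fun(x):
        return _eval(x)["r"]

    def jac(x):
        c = _eval(x)
        return _jacobian_from_aux(c["aux"], K)

    sse0 = float(np.dot(fun(x0), fun(x0)))
    res = least_squares(
        fun,
        x0,
        jac=jac,
        bounds=(lb, ub),
        method="trf",
        x_scale=x_scale,
        xtol=opts.xtol,
        ftol=opts.ftol,
        gtol=opts.gtol,
        max_nfev=opts.max_iter,
    )
    sse_fit = float(2.0 * res.cost)
    if sse_fit <= sse0:
        params = unpack_params(res.x, K)
        sse_val = sse_fit
    else:  # defensive: trust-region steps cannot increase the cost
        params = init
        sse_val = sse0
    r2, r2_adj = _r2_pair(sse_val, y, 3 + 3 * K)
    return FitResult(
        params=params,
        sse=sse_val,
        r2=r2,
        r2_adj=r2_adj,
        n_obs=y.size,
        n_params=3 + 3 * K,
        converged=bool(res.status > 0),
        sse_init=sse0,
        nfev=int(res.nfev),
    )


def refine(
    tfr: TFRGrid,
    first: FitResult,
    K_max: int,
    options: FitOptions | None = None,
) -> list[FitResult]:
    """Iterative refinement: resample the fitted curve, add one site, refit.

    Starting from the fitted order-``K0`` model, each step evaluates its
    curve of peaks at ``K+1`` uniform sites in ``[1, K]``, replaces the peak
    points by those samples, and refits.  Returns the nested sequence of
    fits for orders ``K0 .. K_max`` (including the input fit).
    """
    K0 = first.params.K
    if K_max < K0:
        raise InvalidArgumentError("K_max must be >= the initial model order")
    results = [first]
    current = first
    while current.params.K < K_max:
        m = current.params
        curve = m.curve()
        u_new = np.linspace(1.0, float(m.K), m.K + 1)
        new_points = curve(u_new)
        init_next = SnaGeParams(
            C=m.C, sigma_diag=m.sigma_diag, peak_points=new_points
        )
        current = fit(tfr, init_next, options=options)
        results.append(current)
    return results


def _r2_pair(sse_val: float, y: np.ndarray, n_params: int):
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return np.nan, np.nan
    r2 = 1.0 - sse_val / sst
    n = y.size
    dof = n - n_params - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    return r2, r2_adj


def goodness(fit_result: FitResult, tfr: TFRGrid):
    """Coefficient of determination and its adjusted version.

    ``R^2 = 1 - SSE/SST``;
    ``R^2_adj = 1 - (1 - R^2)(n - 1)/(n - p - 1)`` with ``p = 3 + 3K``.
    Raises for constant data, where the metrics are undefined.
    """
    y = tfr.P.ravel()
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("R^2 undefined for constant data (SST = 0)")
    if fit_result.n_obs <= fit_result.n_params + 1:
        raise InvalidArgumentError("need n_obs > n_params + 1")
    r2, r2_adj = _r2_pair(fit_result.sse, y, fit_result.n_params)
    return r2, r2_adj
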