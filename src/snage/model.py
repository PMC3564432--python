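"""The Gaussian peak model and its smooth natural Gaussian extension (snaGe).

A classical bivariate Gaussian surface ``C + A exp(-1/2 d_Sigma(x, mu)^2)``
describes one isolated peak of activity in the time-frequency plane.  The
snaGe model generalizes it to *bent* patterns: ``K`` peak points
``P_i = (t_i, f_i, A_i)`` are interpolated by a smooth spline curve of peaks
``P(u) = (mu1(u), mu2(u), A(u))`` on ``u in [1, K]``, and the surface value at
a point ``x = (t, f)`` is taken from the family member (value of ``u``) whose
amplitude relative to the offset is largest in magnitude.  With ``K = 1`` the
model degenerates exactly to the single Gaussian peak.

Only diagonal spread matrices are supported; the spreads are constant along
the curve.  The flat parameter vector of an order-``K`` model has length
``3 + 3K``: ``(C, s11, s22, t_1, f_1, A_1, ..., t_K, f_K, A_K)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .exceptions import InvalidArgumentError

__all__ = [
    "GaussianParams",
    "SnaGeParams",
    "PeakCurve",
    "build_peak_curve",
    "eval_gaussian",
    "eval_family",
    "u_star",
    "eval_snage",
    "eval_snage_grid",
    "pack_params",
    "unpack_params",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class GaussianParams:
    """Parameters of the classical offset Gaussian surface.

    ``sigma_diag`` holds the diagonal entries of the spread matrix; the
    exponent is ``-1/2 * sum_d (x_d - mu_d)^2 / sigma_dd`` (weighted-Euclidean
    form of the squared Mahalanobis distance).
    """

    C: float
    A: float
    mu: np.ndarray
    sigma_diag: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma_diag", np.asarray(self.sigma_diag, dtype=float))
        if self.mu.shape != self.sigma_diag.shape:
            raise InvalidArgumentError("mu and sigma_diag must have equal length")
        if np.any(self.sigma_diag <= 0):
            raise InvalidArgumentError("all spread parameters must be positive")


@dataclass(frozen=True)
class SnaGeParams:
    """Parameters of an order-``K`` snaGe model.

    ``peak_points`` is a ``(K, n+1)`` array of peak points; for the
    time-frequency case each row is ``(t_i, f_i, A_i)``.
    """

    C: float
    sigma_diag: np.ndarray
    peak_points: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sigma_diag", np.asarray(self.sigma_diag, dtype=float))
        pts = np.atleast_2d(np.asarray(self.peak_points, dtype=float))
        object.__setattr__(self, "peak_points", pts)
        n = self.sigma_diag.shape[0]
        if np.any(self.sigma_diag <= 0):
            raise InvalidArgumentError("all spread parameters must be positive")
        if pts.ndim != 2 or pts.shape[1] != n + 1:
            raise InvalidArgumentError(
                f"peak_points must be (K, {n + 1}) for {n} independent dimensions"
            )
        if pts.shape[0] < 1:
            raise InvalidArgumentError("at least one peak point is required (K >= 1)")
        if not np.all(np.isfinite(pts)):
            raise InvalidArgumentError("peak points must be finite")

    @property
    def K(self) -> int:
        return self.peak_points.shape[0]

    @property
    def n(self) -> int:
        """Number of independent (domain) dimensions."""
        return self.sigma_diag.shape[0]

    def curve(self) -> "PeakCurve":
        return build_peak_curve(self.peak_points)


class PeakCurve:
    """Interpolating spline through the peak points, on sites ``u_i = i``.

    The spline degree is ``min(3, K - 1)``; it passes through every peak
    point exactly, so ``P(i) == P_i``.  Evaluation outside ``[1, K]`` is an
    error.  ``basis(u)`` returns the cardinal interpolation basis: the
    ``(len(u), K)`` matrix ``B`` with ``P(u) = B @ points``.
    """

    def __init__(self, points: np.ndarray):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.size == 0:
            raise InvalidArgumentError("peak point list must not be empty")
        if not np.all(np.isfinite(points)):
            raise InvalidArgumentError("peak points must be finite")
        self.points = points
        self.K = points.shape[0]
        self.sites = np.arange(1.0, self.K + 1.0)
        self.degree = min(3, self.K - 1)
        if self.K == 1:
            self._spline = None
            self._basis_spline = None
        else:
            self._spline = make_interp_spline(self.sites, points, k=self.degree)
            self._basis_spline = make_interp_spline(
                self.sites, np.eye(self.K), k=self.degree
            )

    def __call__(self, u):
        """Evaluate the curve; returns shape ``(n+1,)`` or ``(len(u), n+1)``."""
        u = np.asarray(u, dtype=float)
        scalar = u.ndim == 0
        u = np.atleast_1d(u)
        self._check_domain(u)
        if self._spline is None:
            out = np.broadcast_to(self.points[0], (u.shape[0], self.points.shape[1])).copy()
        else:
            out = self._spline(u)
        return out[0] if scalar else out

    def basis(self, u) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        self._check_domain(u)
        if self._basis_spline is None:
            return np.ones((u.shape[0], 1))
        return self._basis_spline(u)

    def _check_domain(self, u):
        if u.size and (u.min() < 1.0 - 1e-9 or u.max() > self.K + 1e-9):
            raise InvalidArgumentError(
                f"curve parameter u must lie in [1, {self.K}]"
            )


def build_peak_curve(points) -> PeakCurve:
    """Interpolate the ordered peak points by a spline of degree <= 3."""
    return PeakCurve(points)


def eval_gaussian(x, g: GaussianParams):
    """Classical Gaussian surface ``C + A exp(-1/2 sum_d (x_d-mu_d)^2/s_dd)``."""
    x = np.asarray(x, dtype=float)
    d2 = np.sum((x - g.mu) ** 2 / g.sigma_diag, axis=-1)
    return g.C + g.A * np.exp(-0.5 * d2)


def eval_family(x, u, m: SnaGeParams):
    """One member of the Gaussian family: peak slid to the curve point ``P(u)``."""
    curve = m.curve()
    p = curve(float(u))  # raises if u outside [1, K]
    g = GaussianParams(C=m.C, A=p[-1], mu=p[:-1], sigma_diag=m.sigma_diag)
    return eval_gaussian(x, g)


def _family_abs_amplitude(curve: PeakCurve, sigma_diag, x, u):
    """|y~(x, u) - C| for per-element (x, u) pairs; x (..., n), u (...)."""
    p = curve(u)
    amp = p[..., -1]
    d2 = np.sum((x - p[..., :-1]) ** 2 / sigma_diag, axis=-1)
    return np.abs(amp) * np.exp(-0.5 * d2)


def _golden_polish(curve, sigma_diag, x, lo, hi, iters=40):
    """Vectorized golden-section maximization of |y~(x,u)-C| per point.

    ``x`` is (npts, n); ``lo``/``hi`` bracket each point's grid argmax.
    Returns the polished u per point.
    """
    a = lo.copy()
    b = hi.copy()
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = _family_abs_amplitude(curve, sigma_diag, x, c)
    fd = _family_abs_amplitude(curve, sigma_diag, x, d)
    for _ in range(iters):
        left = fc >= fd  # maximum in [a, d]; ties move left (smaller u)
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc = _family_abs_amplitude(curve, sigma_diag, x, c)
        fd = _family_abs_amplitude(curve, sigma_diag, x, d)
    return 0.5 * (a + b)


def _u_grid(K: int, grid_density: int) -> np.ndarray:
    if K == 1:
        return np.array([1.0])
    n_pts = int(grid_density) * (K - 1) + 1
    return np.linspace(1.0, float(K), n_pts)


def _select_u(curve, sigma_diag, x, ug, polish, polish_iters=40):
    """Per-point argmax of |y~(x, u) - C| over the u-grid, optionally polished.

    ``x`` is (npts, n).  When polishing, the two best *local maxima* of the
    grid scores are each refined by golden section and the better one kept:
    near-tie configurations (e.g. a positive- and a negative-amplitude
    branch of almost equal strength) would otherwise resolve to the wrong
    branch.  Ties break toward the smaller u.
    """
    pts = curve(ug)  # (nu, n+1)
    s1, s2 = sigma_diag
    d2 = (
        (x[None, :, 0] - pts[:, 0, None]) ** 2 / s1
        + (x[None, :, 1] - pts[:, 1, None]) ** 2 / s2
    )
    scores = np.abs(pts[:, 2])[:, None] * np.exp(-0.5 * d2)  # (nu, npts)
    nu, npts = scores.shape
    iu = np.argmax(scores, axis=0)  # first max -> smallest u
    if not polish or nu < 2:
        return ug[iu]
    larger_prev = np.ones_like(scores, dtype=bool)
    larger_prev[1:] = scores[1:] >= scores[:-1]
    larger_next = np.ones_like(scores, dtype=bool)
    larger_next[:-1] = scores[:-1] >= scores[1:]
    masked = np.where(larger_prev & larger_next, scores, -np.inf)
    top2 = np.sort(np.argpartition(-masked, 1, axis=0)[:2], axis=0)
    cols = np.arange(npts)
    best_u = None
    best_f = None
    for row in top2:  # ascending u, so equal scores keep the smaller u
        u_p = _golden_polish(
            curve, sigma_diag, x,
            ug[np.maximum(row - 1, 0)], ug[np.minimum(row + 1, nu - 1)],
            iters=polish_iters,
        )
        f_p = _family_abs_amplitude(curve, sigma_diag, x, u_p)
        worse = f_p < scores[row, cols]  # never below the grid candidate
        u_p = np.where(worse, ug[row], u_p)
        f_p = np.where(worse, scores[row, cols], f_p)
        if best_u is None:
            best_u, best_f = u_p, f_p
        else:
            take = f_p > best_f
            best_u = np.where(take, u_p, best_u)
            best_f = np.where(take, f_p, best_f)
    return best_u


def u_star(x, m: SnaGeParams, grid_density: int = 50, polish: bool = True):
    """Curve parameter assigning ``x`` the largest |amplitude| above the offset.

    A discrete grid of ``grid_density`` samples per unit of ``u`` is scanned
    (ties broken toward the smallest ``u``), optionally followed by a
    golden-section polish inside the bracketing grid interval.
    """
    if grid_density < 1:
        raise InvalidArgumentError("grid_density must be >= 1")
    if m.K == 1:
        return 1.0
    x = np.asarray(x, dtype=float)
    ug = _u_grid(m.K, grid_density)
    u = _select_u(m.curve(), m.sigma_diag, x[None, :], ug, polish=polish)
    return float(u[0])


def eval_snage(x, m: SnaGeParams, grid_density: int = 50, polish: bool = True):
    """snaGe surface value at ``x``: the family member selected by ``u_star``."""
    u = u_star(x, m, grid_density=grid_density, polish=polish)
    return eval_family(x, u, m)


def eval_snage_grid(
    m: SnaGeParams,
    t: np.ndarray,
    f: np.ndarray,
    grid_density: int = 50,
    polish: bool = True,
    polish_iters: int = 40,
    return_aux: bool = False,
):
    """Evaluate the snaGe surface on a full time-frequency grid.

    Returns the power matrix ``P`` indexed ``[frequency, time]`` with shape
    ``(len(f), len(t))``.  Equals pointwise evaluation at every grid node.

    With ``return_aux=True``, additionally returns a dict with the selected
    ``u`` per pixel and intermediate quantities (used by the fitting module
    to assemble an analytic Jacobian via the envelope rule).
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    tg, fg = np.meshgrid(t, f)  # (nf, nt)
    x = np.column_stack([tg.ravel(), fg.ravel()])  # (npx, 2)
    curve = m.curve()
    ug = _u_grid(m.K, grid_density)
    s1, s2 = m.sigma_diag
    u_sel = _select_u(
        curve, m.sigma_diag, x, ug, polish=polish and m.K > 1,
        polish_iters=polish_iters,
    )
    p_sel = curve(u_sel)  # (npx, 3)
    dt = x[:, 0] - p_sel[:, 0]
    df = x[:, 1] - p_sel[:, 1]
    e = np.exp(-0.5 * (dt**2 / s1 + df**2 / s2))
    y = m.C + p_sel[:, 2] * e
    P = y.reshape(len(f), len(t))
    if not return_aux:
        return P
    aux = {
        "x": x,
        "u": u_sel,
        "exp_term": e,
        "amp": p_sel[:, 2],
        "dt": dt,
        "df": df,
        "basis": curve.basis(u_sel),  # (npx, K)
    }
    return P, aux


def pack_params(m: SnaGeParams) -> np.ndarray:
    """Flatten to ``(C, s11, ..., snn, P_1, ..., P_K)``, points interleaved."""
    return np.concatenate([[m.C], m.sigma_diag, m.peak_points.ravel()])


def unpack_params(v: np.ndarray, K: int, n: int = 2) -> SnaGeParams:
    """Inverse of :func:`pack_params`; the vector length must be ``1+n+(n+1)K``."""
    v = np.asarray(v, dtype=float)
    expected = 1 + n + (n + 1) * K
    if v.shape != (expected,):
        raise InvalidArgumentError(
            f"parameter vector for K={K}, n={n} must have length {expected}, "
            f"got shape {v.shape}"
        )
    return SnaGeParams(
        C=float(v[0]),
        sigma_diag=v[1 : 1 + n],
        peak_points=v[1 + n :].reshape(K, n + 1),
    )
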