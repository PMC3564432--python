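"""Shape distances between snaGe models via discrete Fréchet distances.

Two fitted models are compared through their curves of peaks: each curve is
sampled at ``M`` uniform sites in ``[1, K]`` and the sampled polylines are
aligned by monotone couplings (each step advances one or both indices,
repeats allowed).  The classical variant minimizes the *maximum* pointwise
weighted Euclidean distance over the coupling; the sum variant minimizes the
*total* distance over coupling steps, acting as an average distance that is
less sensitive to single outlying curve segments.

Curve-based distances interrelate models of different orders and ignore the
less interpretable offset and spread parameters.  For noisy data whose power
scale varies wildly, the amplitude dimension can be zeroed out so that only
the time-frequency geometry of the pattern is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError
from .model import SnaGeParams

__all__ = [
    "SampledCurve",
    "sample_curve",
    "default_weights",
    "frechet_max",
    "frechet_sum",
]


@dataclass(frozen=True)
class SampledCurve:
    """An ordered point sequence in (t, f, A) space with metric weights."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        w = np.asarray(self.weights, dtype=float).ravel()
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)
        if pts.shape[0] < 2:
            raise InvalidArgumentError("a sampled curve needs at least 2 points")
        if w.shape[0] != pts.shape[1]:
            raise InvalidArgumentError("one weight per coordinate dimension required")
        if np.any(w <= 0):
            raise InvalidArgumentError("metric weights must be positive")

    def __len__(self):
        return self.points.shape[0]


def default_weights(m: SnaGeParams) -> np.ndarray:
    """Reciprocal-range weights making the three dimensions comparable.

    Time and frequency are scaled by the reciprocal span of the reference
    model's peak points, amplitude by the reciprocal peak magnitude; a
    degenerate (zero) span falls back to weight 1.
    """
    pts = m.peak_points
    spans = np.array(
        [
            np.ptp(pts[:, 0]),
            np.ptp(pts[:, 1]),
            np.abs(pts[:, 2]).max(),
        ]
    )
    spans[spans <= 0] = 1.0
    return 1.0 / spans


def sample_curve(
    m: SnaGeParams,
    M: int = 100,
    weights: np.ndarray | None = None,
    ignore_amplitude: bool = False,
) -> SampledCurve:
    """Sample the model's curve of peaks at ``M`` uniform sites in [1, K]."""
    if M < 2:
        raise InvalidArgumentError("need M >= 2 curve samples")
    curve = m.curve()
    u = np.linspace(1.0, float(m.K), M)
    pts = curve(u)
    if ignore_amplitude:
        pts = pts.copy()
        pts[:, -1] = 0.0
    if weights is None:
        weights = default_weights(m)
    return SampledCurve(points=pts, weights=weights)


def _pairwise(c1: SampledCurve, c2: SampledCurve) -> np.ndarray:
    if not np.allclose(c1.weights, c2.weights, rtol=0, atol=0):
        raise InvalidArgumentError("both curves must carry identical metric weights")
    diff = (c1.points[:, None, :] - c2.points[None, :, :]) * c1.weights
    return np.sqrt(np.sum(diff**2, axis=-1))


def _frechet_dp(d: np.ndarray, combine) -> float:
    """DP over monotone couplings of the pairwise-distance matrix ``d``.

    ``combine(d_ij, best_predecessor)`` is ``max`` for the classical
    Fréchet functional and ``+`` for the sum variant.
    """
    m, n = d.shape
    acc = np.empty((m, n))
    acc[0, 0] = d[0, 0]
    for i in range(1, m):
        acc[i, 0] = combine(d[i, 0], acc[i - 1, 0])
    for j in range(1, n):
        acc[0, j] = combine(d[0, j], acc[0, j - 1])
    for i in range(1, m):
        prev_row = acc[i - 1]
        row = acc[i]
        for j in range(1, n):
            best = min(prev_row[j], prev_row[j - 1], row[j - 1])
            row[j] = combine(d[i, j], best)
    return float(acc[-1, -1])


def frechet_max(c1: SampledCurve, c2: SampledCurve) -> float:
    """Discrete Fréchet distance (minimax over monotone couplings)."""
    return _frechet_dp(_pairwise(c1, c2), max)


def frechet_sum(c1: SampledCurve, c2: SampledCurve) -> float:
    """Sum-variant Fréchet distance: minimal total distance over couplings."""
    return _frechet_dp(_pairwise(c1, c2), lambda dij, best: dij + best)
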