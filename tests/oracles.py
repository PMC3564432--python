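"""Independent brute-force oracles used by the test suite.

Each oracle solves the same problem as the library by exhaustive
enumeration or dense sampling, sharing no code with the implementation it
checks.
"""

import itertools

import numpy as np


def enumerate_paths_best(P, k):
    """Best slope-bounded left-to-right path by exhaustive enumeration.

    Returns (best_total, set of optimal row tuples).  Exponential; only for
    tiny matrices.
    """
    nr, nc = P.shape
    best_total = -np.inf
    best_paths = set()
    frontier = [((r,), P[r, 0]) for r in range(nr)]
    for j in range(1, nc):
        nxt = []
        for rows, total in frontier:
            for r in range(max(0, rows[-1] - k), min(nr, rows[-1] + k + 1)):
                nxt.append((rows + (r,), total + P[r, j]))
        frontier = nxt
    for rows, total in frontier:
        if total > best_total + 1e-12:
            best_total = total
            best_paths = {rows}
        elif abs(total - best_total) <= 1e-12:
            best_paths.add(rows)
    return best_total, best_paths


def frechet_brute(d, variant):
    """Min over all monotone couplings by recursive enumeration.

    ``d`` is the pairwise distance matrix; ``variant`` is 'max' or 'sum'.
    """
    m, n = d.shape
    best = [np.inf]

    def rec(i, j, acc):
        acc = max(acc, d[i, j]) if variant == "max" else acc + d[i, j]
        if acc >= best[0]:
            return  # cannot improve: both functionals are non-decreasing
        if i == m - 1 and j == n - 1:
            best[0] = acc
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < m and j + dj < n:
                rec(i + di, j + dj, acc)

    rec(0, 0, -np.inf if variant == "max" else 0.0)
    return best[0]


def weighted_dist_matrix(pts1, pts2, weights):
    diff = (pts1[:, None, :] - pts2[None, :, :]) * np.asarray(weights)
    return np.sqrt((diff**2).sum(axis=-1))


def snage_brute_force(m, t, f, n_u=10_000):
    """snaGe surface by dense u-grid evaluation, independent of the package.

    Rebuilds the interpolating curve with scipy directly and scans ``n_u``
    uniformly spaced curve parameters per grid point, applying the
    largest-|amplitude| rule.
    """
    from scipy.interpolate import make_interp_spline

    pts = m.peak_points
    K = pts.shape[0]
    if K == 1:
        mu = np.repeat(pts[:, :2], n_u, axis=0)
        amp = np.repeat(pts[:, 2], n_u)
    else:
        spl = make_interp_spline(np.arange(1, K + 1), pts, k=min(3, K - 1))
        uu = np.linspace(1.0, K, n_u)
        vals = spl(uu)
        mu, amp = vals[:, :2], vals[:, 2]
    tg, fg = np.meshgrid(t, f)
    out = np.empty(tg.shape)
    s1, s2 = m.sigma_diag
    for idx in np.ndindex(tg.shape):
        d2 = (tg[idx] - mu[:, 0]) ** 2 / s1 + (fg[idx] - mu[:, 1]) ** 2 / s2
        fam = amp * np.exp(-0.5 * d2)
        i = np.argmax(np.abs(fam))
        out[idx] = m.C + fam[i]
    return out


def stft_ridge(x, fs, nperseg=128):
    """Dominant frequency per STFT column — an independent ridge locator."""
    from scipy.signal import spectrogram

    freqs, times, S = spectrogram(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    return times, freqs[np.argmax(S, axis=0)]
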