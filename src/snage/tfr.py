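"""Time-frequency representations: SPWVD computation and preprocessing.

The smoothed pseudo Wigner-Ville distribution (SPWVD) is a quadratic
transform with independent time- and frequency-smoothing windows,

    W(t, f) = sum_tau  h(tau) [ sum_s g(s) z(t+s+tau) z*(t+s-tau) ] e^{-j4 pi f tau},

where ``z`` is the analytic signal, ``g`` the time-smoothing window and
``h`` the frequency-smoothing window.  It estimates signal power on a joint
time-frequency grid while suppressing the raw Wigner-Ville cross terms; some
negative values remain and are usually clipped to zero before model fitting.

No SPWVD routine exists in the scientific Python stack, so the transform is
implemented here directly from its definition: per lag ``tau`` the
instantaneous autocorrelation is time-smoothed by convolution with ``g``,
then a single FFT over the lag axis yields each frequency column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve
from scipy.signal import get_window, hilbert

from .exceptions import InvalidArgumentError, InvalidDataError

__all__ = [
    "Signal",
    "TFRGrid",
    "compute_spwvd",
    "preprocess_tfr",
    "restrict_band",
    "default_time_window",
    "default_freq_window",
]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled 1-D signal with sampling rate ``fs`` in Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if self.samples.size < 2:
            raise InvalidArgumentError("signal must contain at least 2 samples")

    def __len__(self):
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class TFRGrid:
    """A real-valued time-frequency image.

    ``P`` is indexed ``[frequency, time]`` (rows are frequency bins, columns
    time instants), matching the left-to-right "horizontal path" convention
    used by the optimal-path initializer.
    """

    t: np.ndarray
    f: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float).ravel()
        f = np.asarray(self.f, dtype=float).ravel()
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "P", P)
        if P.shape != (f.size, t.size):
            raise InvalidArgumentError(
                f"P must have shape (len(f), len(t)) = {(f.size, t.size)}, "
                f"got {P.shape}"
            )
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("time axis must be strictly increasing")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise InvalidArgumentError("frequency axis must be strictly increasing")

    @property
    def shape(self):
        return self.P.shape


def _round_odd(x: float) -> int:
    n = max(int(round(x)), 3)
    return n if n % 2 == 1 else n + 1


def default_time_window(fs: float) -> int:
    """Default time-smoothing window length: fs/4 samples, rounded to odd."""
    return _round_odd(fs / 4.0)


def default_freq_window(n_samples: int) -> int:
    """Default frequency-smoothing window length: N/4 samples, rounded to odd."""
    return _round_odd(n_samples / 4.0)


def compute_spwvd(
    sig: Signal,
    n_freq_bins: int = 256,
    time_window: int | None = None,
    freq_window: int | None = None,
    window: str = "hamming",
) -> TFRGrid:
    """Smoothed pseudo Wigner-Ville distribution of the analytic signal.

    Parameters
    ----------
    sig
        Input signal.
    n_freq_bins
        Number of frequency bins; the frequency axis is
        ``m * fs / (2 * n_freq_bins)`` for ``m = 0 .. n_freq_bins-1``,
        covering the band up to the Nyquist frequency.
    time_window, freq_window
        Odd lengths of the separable smoothing windows (defaults: fs/4 and
        N/4 samples, odd-rounded).  Longer frequency windows sharpen the
        frequency resolution; longer time windows suppress cross terms.
    window
        Window family passed to :func:`scipy.signal.get_window`.

    Returns the real-valued transform; values may be negative (residual
    Wigner-Ville cross terms) until clipped by :func:`preprocess_tfr`.
    """
    x = sig.samples
    if not np.all(np.isfinite(x)):
        raise InvalidDataError("signal contains non-finite samples")
    N = x.size
    if n_freq_bins < 2:
        raise InvalidArgumentError("n_freq_bins must be >= 2")
    if time_window is None:
        time_window = default_time_window(sig.fs)
    if freq_window is None:
        freq_window = default_freq_window(N)
    for name, w in (("time_window", time_window), ("freq_window", freq_window)):
        if w % 2 == 0:
            raise InvalidArgumentError(f"{name} must be odd")
        if w >= N:
            raise InvalidArgumentError(f"{name} must be shorter than the signal")

    z = hilbert(x)
    g = get_window(window, time_window, fftbins=False)
    g = g / g.sum()
    h = get_window(window, freq_window, fftbins=False)
    h = h / h[(freq_window - 1) // 2]  # unit gain at zero lag
    Lh = (freq_window - 1) // 2
    # wrapped negative lags occupy the upper half of the FFT input,
    # so positive lags must stay below n_freq_bins / 2
    taumax = min(Lh, n_freq_bins // 2 - 1)

    # R[tau, n] = h(tau) * sum_s g(s) z(n+tau-s) z*(n-tau-s); FFT over tau.
    acf = np.zeros((n_freq_bins, N), dtype=complex)
    for tau in range(taumax + 1):
        prod = np.zeros(N, dtype=complex)
        if tau == 0:
            prod[:] = z * np.conj(z)
        else:
            prod[tau : N - tau] = z[2 * tau :] * np.conj(z[: N - 2 * tau])
        sm = convolve(prod.real, g, mode="constant") + 1j * convolve(
            prod.imag, g, mode="constant"
        )
        acf[tau] = h[Lh + tau] * sm
        if tau:
            acf[n_freq_bins - tau] = np.conj(acf[tau])
    P = np.real(np.fft.fft(acf, axis=0))
    # pure tone at f0 appears at bin m with m/n_freq_bins = 2 f0 / fs
    f = np.arange(n_freq_bins) * sig.fs / (2.0 * n_freq_bins)
    t = np.arange(N) / sig.fs
    return TFRGrid(t=t, f=f, P=P)


def restrict_band(tfr: TFRGrid, f_min: float, f_max: float) -> TFRGrid:
    """Crop the TFR to the frequency band of interest ``[f_min, f_max]``."""
    if f_max <= f_min:
        raise InvalidArgumentError("f_max must exceed f_min")
    keep = (tfr.f >= f_min) & (tfr.f <= f_max)
    if keep.sum() < 2:
        raise InvalidArgumentError("band keeps fewer than 2 frequency bins")
    return TFRGrid(t=tfr.t, f=tfr.f[keep], P=tfr.P[keep, :])


def _block_mean(P: np.ndarray, rf: int, cf: int) -> np.ndarray:
    nr = (P.shape[0] // rf) * rf
    nc = (P.shape[1] // cf) * cf
    Pc = P[:nr, :nc]
    return Pc.reshape(nr // rf, rf, nc // cf, cf).mean(axis=(1, 3))


def preprocess_tfr(
    tfr: TFRGrid,
    smooth_kernel: np.ndarray | int | None = 3,
    subsample: tuple[int, int] = (1, 1),
    clip_negative: bool = True,
) -> TFRGrid:
    """Smooth, block-subsample and (optionally) clip a TFR for fitting.

    ``smooth_kernel`` may be a 2-D nonnegative kernel (normalized to sum 1
    internally), an integer ``w`` meaning a ``w x w`` mean kernel, or ``None``
    to skip smoothing.  ``subsample`` gives the (frequency, time) block
    factors; each output pixel is the mean of one block.  Negative values
    carry no power interpretation, so ``clip_negative`` sets them to zero —
    the default for fitting.
    """
    rf, cf = subsample
    if rf < 1 or cf < 1:
        raise InvalidArgumentError("subsample factors must be >= 1")
    if rf > tfr.P.shape[0] or cf > tfr.P.shape[1]:
        raise InvalidArgumentError("subsample factor exceeds axis length")
    P = tfr.P
    if smooth_kernel is not None:
        if np.isscalar(smooth_kernel):
            w = int(smooth_kernel)
            kernel = np.full((w, w), 1.0 / (w * w))
        else:
            kernel = np.asarray(smooth_kernel, dtype=float)
            if kernel.ndim != 2 or np.any(kernel < 0) or kernel.sum() <= 0:
                raise InvalidArgumentError("kernel must be 2-D and nonnegative")
            kernel = kernel / kernel.sum()
        if kernel.size > 1:
            P = convolve(P, kernel, mode="nearest")
    P = _block_mean(P, rf, cf)
    f = _block_mean(tfr.f[:, None], rf, 1).ravel()
    t = _block_mean(tfr.t[None, :], 1, cf).ravel()
    if clip_negative:
        P = np.maximum(P, 0.0)
    return TFRGrid(t=t, f=f, P=P)
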