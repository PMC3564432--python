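"""Synthetic EEG-like signals and the noise-robustness experiment.

The test pattern is an alpha-theta-alpha oscillation: three consecutive
unit-amplitude sinusoid segments at 10 Hz, 4 Hz and 10 Hz over 2.5 s sampled
at 250 Hz.  Its TFR shows three distinct ridges of activity that a bent
snaGe curve must connect — deliberately hard for a model that assumes one
connected path of peaks.

The robustness experiment adds band-limited Gaussian noise at controlled
SNR in the time domain (which becomes spatially correlated noise in the
time-frequency plane), refits the model from scratch per noisy realization,
and measures amplitude-ignored Fréchet distances to the noise-free
reference model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, firwin

from .distance import frechet_max, frechet_sum, sample_curve
from .exceptions import InvalidArgumentError
from .fitting import FitOptions, FitResult, fit, init_params, refine
from .model import SnaGeParams, pack_params, unpack_params
from .tfr import Signal, TFRGrid, compute_spwvd, preprocess_tfr, restrict_band

__all__ = [
    "NoiseSpec",
    "ExperimentResult",
    "PipelineConfig",
    "make_ata_signal",
    "add_noise",
    "signal_to_tfr",
    "reference_model",
    "run_noise_experiment",
    "extraction_threshold",
    "ridge_frequencies",
    "average_models",
    "SNR_GRID_DEFAULT",
]

#: SNR grid of the robustness experiment: -15 dB to +10 dB in 2.5 dB steps.
SNR_GRID_DEFAULT = np.arange(-15.0, 10.0 + 1e-9, 2.5)


@dataclass(frozen=True)
class NoiseSpec:
    """Band-limited additive Gaussian noise at an exact empirical SNR."""

    snr_db: float
    filter_band: tuple[float, float] = (0.0, 45.0)
    seed: int = 0
    numtaps: int = 101


@dataclass(frozen=True)
class PipelineConfig:
    """Shared settings of the signal -> TFR -> fit pipeline.

    The TFR is restricted to the low-frequency analysis band (default
    0-30 Hz, covering theta and alpha), smoothed with a small mean kernel
    and block-averaged down to roughly a 64x64 grid for smooth, fast cost
    evaluations.
    """

    n_freq_bins: int = 256
    band: tuple[float, float] = (0.0, 30.0)
    smooth_kernel: int = 3
    time_subsample: int = 10
    K0: int = 5
    slope_bound: int = 2
    fit_options: FitOptions = field(default_factory=FitOptions)


@dataclass
class ExperimentResult:
    """Distances and fits of the noise-robustness experiment."""

    table: pd.DataFrame  # snr_db, realization, d_max, d_sum, sse, converged, ...
    summary: pd.DataFrame  # per-SNR mean/std of both distance variants
    reference: FitResult
    models: dict  # (snr_db, realization) -> SnaGeParams


def make_ata_signal(
    fs: float = 250.0,
    duration: float = 2.5,
    freqs: tuple[float, float, float] = (10.0, 4.0, 10.0),
) -> Signal:
    """Three consecutive equal-duration unit sinusoids (alpha-theta-alpha).

    Each segment starts at phase zero.  Segment frequencies must stay below
    the Nyquist frequency.
    """
    if any(f0 >= fs / 2 for f0 in freqs):
        raise InvalidArgumentError("segment frequencies must be below fs/2")
    n_total = int(round(fs * duration))
    bounds = np.round(np.linspace(0, n_total, len(freqs) + 1)).astype(int)
    x = np.empty(n_total)
    for (a, b), f0 in zip(zip(bounds[:-1], bounds[1:]), freqs):
        tt = np.arange(b - a) / fs
        x[a:b] = np.sin(2.0 * np.pi * f0 * tt)
    return Signal(samples=x, fs=fs)


def add_noise(sig: Signal, spec: NoiseSpec) -> Signal:
    """Add band-limited Gaussian noise at an exact signal-to-noise ratio.

    White Gaussian noise is low-pass filtered (zero-phase FIR, so the noise
    remains Gaussian and acquires the temporal correlation that turns into
    smooth interference in the TFR), then scaled so the empirical power
    ratio satisfies ``10 log10(P_signal / P_noise) = snr_db`` exactly.
    """
    x = sig.samples
    p_sig = float(np.mean(x**2))
    if p_sig == 0.0:
        raise InvalidArgumentError("cannot define SNR for a zero-power signal")
    lo, hi = spec.filter_band
    if not (0.0 <= lo < hi < sig.fs / 2):
        raise InvalidArgumentError("filter passband must lie within (0, fs/2)")
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(x.size)
    if lo > 0.0:
        taps = firwin(spec.numtaps, [lo, hi], pass_zero=False, fs=sig.fs)
    else:
        taps = firwin(spec.numtaps, hi, fs=sig.fs)
    noise = filtfilt(taps, 1.0, noise)
    p_noise = float(np.mean(noise**2))
    target = p_sig / 10.0 ** (spec.snr_db / 10.0)
    noise *= np.sqrt(target / p_noise)
    return Signal(samples=x + noise, fs=sig.fs)


def signal_to_tfr(sig: Signal, config: PipelineConfig | None = None) -> TFRGrid:
    """Standard pipeline: SPWVD, band restriction, smoothing + subsampling."""
    cfg = config or PipelineConfig()
    raw = compute_spwvd(sig, n_freq_bins=cfg.n_freq_bins)
    band = restrict_band(raw, *cfg.band)
    return preprocess_tfr(
        band,
        smooth_kernel=cfg.smooth_kernel,
        subsample=(1, cfg.time_subsample),
        clip_negative=True,
    )


def _fit_pipeline(tfr: TFRGrid, cfg: PipelineConfig) -> FitResult:
    """Order-K0 fit from optimal-path initialization plus one refinement step."""
    init = init_params(tfr, K=cfg.K0, k=cfg.slope_bound)
    first = fit(tfr, init, options=cfg.fit_options)
    return refine(tfr, first, K_max=cfg.K0 + 1, options=cfg.fit_options)[-1]


def reference_model(
    tfr: TFRGrid | None = None, config: PipelineConfig | None = None
) -> FitResult:
    """The noise-free reference fit the experiment measures distances to.

    Fits the clean simulated pattern with an order-5 model initialized from
    the optimal path, then performs one refinement step (final order 6).
    """
    cfg = config or PipelineConfig()
    if tfr is None:
        tfr = signal_to_tfr(make_ata_signal(), cfg)
    return _fit_pipeline(tfr, cfg)


def ridge_frequencies(
    m: SnaGeParams,
    t_probe: np.ndarray,
    f_band: tuple[float, float] = (0.0, 30.0),
    n_f: int = 512,
) -> np.ndarray:
    """Frequency at which the model surface peaks, per probe time.

    Evaluates the fitted surface on a dense frequency grid at each probe
    time and returns the argmax frequency.  Probing the surface rather than
    the curve samples makes the readout independent of how the curve of
    peaks happens to be parameterized (fitted curves may double back in
    time while still placing power at the right frequencies).
    """
    from .model import eval_snage_grid

    f_grid = np.linspace(f_band[0], f_band[1], n_f)
    t_probe = np.asarray(t_probe, dtype=float)
    S = eval_snage_grid(m, t_probe, f_grid, polish=False)
    return f_grid[np.argmax(S, axis=0)]


def run_noise_experiment(
    snr_grid: np.ndarray = SNR_GRID_DEFAULT,
    n_real: int = 10,
    master_seed: int = 0,
    config: PipelineConfig | None = None,
    n_curve_samples: int = 100,
) -> ExperimentResult:
    """Refit the model per noisy realization and measure distances.

    For each SNR level and realization: add freshly seeded band-limited
    noise to the clean signal, compute and preprocess the TFR, initialize
    from the optimal path (order 5), fit, refine once, and compute the
    amplitude-ignored discrete Fréchet distances (max and sum variants) to
    the noise-free reference.  Individual fit failures are recorded in the
    table, not raised.  Seeds derive deterministically from ``master_seed``.
    """
    cfg = config or PipelineConfig()
    clean = make_ata_signal()
    ref = reference_model(signal_to_tfr(clean, cfg), cfg)
    from .distance import default_weights

    weights = default_weights(ref.params)
    ref_curve = sample_curve(
        ref.params, M=n_curve_samples, weights=weights, ignore_amplitude=True
    )
    rows = []
    models = {}
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(len(snr_grid) * n_real) % (2**31)
    idx = 0
    for snr in snr_grid:
        for r in range(n_real):
            seed = int(seeds[idx])
            idx += 1
            try:
                noisy = add_noise(clean, NoiseSpec(snr_db=float(snr), seed=seed))
                tfr = signal_to_tfr(noisy, cfg)
                res = _fit_pipeline(tfr, cfg)
                cur = sample_curve(
                    res.params,
                    M=n_curve_samples,
                    weights=weights,
                    ignore_amplitude=True,
                )
                d_max = frechet_max(ref_curve, cur)
                d_sum = frechet_sum(ref_curve, cur)
                models[(float(snr), r)] = res.params
                rows.append(
                    dict(
                        snr_db=float(snr),
                        realization=r,
                        seed=seed,
                        d_max=d_max,
                        d_sum=d_sum,
                        sse=res.sse,
                        r2=res.r2,
                        converged=res.converged,
                        failed=False,
                    )
                )
            except Exception as exc:  # a single bad fit must not kill the sweep
                rows.append(
                    dict(
                        snr_db=float(snr),
                        realization=r,
                        seed=seed,
                        d_max=np.nan,
                        d_sum=np.nan,
                        sse=np.nan,
                        r2=np.nan,
                        converged=False,
                        failed=True,
                    )
                )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("snr_db")[["d_max", "d_sum"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = ["snr_db", "d_max_mean", "d_max_std", "d_sum_mean", "d_sum_std"]
    return ExperimentResult(table=table, summary=summary, reference=ref, models=models)


def extraction_threshold(
    result: ExperimentResult,
    deviation_frac: float = 0.25,
    n_curve_samples: int = 100,
) -> float:
    """Lowest grid SNR at and above which pattern extraction is reliable.

    Reliability is the collapse of the across-realization distance spread:
    no single fit may connect the pattern differently from the reference.
    A level counts as reliable when every realization succeeded and its
    amplitude-ignored max-variant Fréchet distance — the worst deviation
    of the two aligned curves of peaks — stays below ``deviation_frac`` of
    the reference pattern's extent (the weighted bounding-box diagonal of
    its curve; a quarter of the pattern extent separates small distortions
    from qualitatively different peak connections).  The threshold is the
    lowest grid value from which reliability holds for all higher levels;
    NaN if there is none.
    """
    from .distance import default_weights

    ref = result.reference.params
    weights = default_weights(ref)
    pts = sample_curve(
        ref, M=n_curve_samples, weights=weights, ignore_amplitude=True
    ).points * weights
    diag = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    cut = deviation_frac * diag
    levels = np.sort(result.table["snr_db"].unique())
    reliable = []
    for snr in levels:
        sub = result.table[result.table["snr_db"] == snr]
        ok = (not sub["failed"].any()) and bool((sub["d_max"] <= cut).all())
        reliable.append(ok)
    reliable = np.asarray(reliable)
    for i, snr in enumerate(levels):
        if reliable[i:].all():
            return float(snr)
    return float("nan")


def average_models(models: list[SnaGeParams]) -> SnaGeParams:
    """Element-wise mean of same-order flat parameter vectors."""
    if not models:
        raise InvalidArgumentError("need at least one model to average")
    K = models[0].K
    n = models[0].n
    if any(m.K != K or m.n != n for m in models):
        raise InvalidArgumentError("all models must share the same order and dimension")
    vecs = np.stack([pack_params(m) for m in models])
    return unpack_params(vecs.mean(axis=0), K, n)
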