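import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snage import (
    FitResult,
    InvalidArgumentError,
    SnaGeParams,
    TFRGrid,
    UndefinedMetricError,
    eval_snage_grid,
    fit,
    goodness,
    init_params,
    optimal_path,
    refine,
    smooth_path,
    sse,
)
from snage.fitting import OptimalPath

from conftest import random_model
from oracles import enumerate_paths_best


# ---------------------------------------------------------------------- sse

def _grid_from(P, t=None, f=None):
    nf, nt = P.shape
    t = np.arange(nt, dtype=float) if t is None else t
    f = np.arange(nf, dtype=float) if f is None else f
    return TFRGrid(t=t, f=f, P=P)


def test_sse_zero_for_self_generated_data(rng):
    m = random_model(rng, K=3)
    t = np.linspace(0, 2.5, 20)
    f = np.linspace(0, 30, 20)
    P = eval_snage_grid(m, t, f, polish=False)
    assert sse(m, _grid_from(P, t, f)) == pytest.approx(0.0, abs=1e-18)


def test_sse_unit_residual_per_pixel(rng):
    m = random_model(rng, K=2)
    t = np.linspace(0, 2.5, 10)
    f = np.linspace(0, 30, 12)
    P = eval_snage_grid(m, t, f, polish=False) + 1.0
    assert sse(m, _grid_from(P, t, f)) == pytest.approx(120.0, rel=1e-12)


def test_sse_hand_computed_2x2():
    # constant model C=2 vs data [[1,2],[3,4]] -> 1 + 0 + 1 + 4 = 6
    m = SnaGeParams(C=2.0, sigma_diag=[1.0, 1.0], peak_points=[[0.5, 0.5, 0.0]])
    tfr = _grid_from(np.array([[1.0, 2.0], [3.0, 4.0]]))
    assert sse(m, tfr) == pytest.approx(6.0)


# ------------------------------------------------------------- optimal path

def test_single_bright_row():
    P = np.zeros((5, 7))
    P[3] = 1.0
    path = optimal_path(P, k=1)
    assert np.array_equal(path.row_index, np.full(7, 3))
    assert path.total_energy == pytest.approx(7.0)


def test_path_slope_bound_respected(rng):
    P = rng.random((8, 12))
    for k in (0, 1, 2):
        path = optimal_path(P, k=k)
        assert np.max(np.abs(np.diff(path.row_index))) <= k
        assert len(path.row_index) == 12


def test_path_total_matches_traversed_pixels(rng):
    P = rng.random((6, 9))
    path = optimal_path(P, k=2)
    assert path.total_energy == pytest.approx(
        P[path.row_index, np.arange(9)].sum()
    )


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    nr=st.integers(1, 4),
    nc=st.integers(1, 5),
    k=st.integers(0, 2),
    seed=st.integers(0, 2**20),
)
def test_dp_equals_exhaustive_enumeration(nr, nc, k, seed):
    """DP optimality on small matrices with ternary intensities."""
    P = np.random.default_rng(seed).integers(0, 3, size=(nr, nc)).astype(float)
    path = optimal_path(P, k=k)
    best_total, best_paths = enumerate_paths_best(P, k)
    assert path.total_energy == pytest.approx(best_total)
    assert tuple(path.row_index) in best_paths


def test_random_3x4_paths_exhaustive(rng):
    for _ in range(20):
        P = rng.random((3, 4))
        path = optimal_path(P, k=1)
        best_total, best_paths = enumerate_paths_best(P, k=1)
        assert path.total_energy == pytest.approx(best_total)
        assert tuple(path.row_index) in best_paths


# ------------------------------------------------------------- smooth path

def test_smooth_constant_path_unchanged():
    p = OptimalPath(row_index=np.full(20, 4), total_energy=0.0)
    t = np.linspace(0, 1, 20)
    f = np.linspace(0, 30, 10)
    _, fvals, _ = smooth_path(p, t, f, window=5)
    assert np.allclose(fvals, f[4])


def test_smoothing_attenuates_single_spike():
    rows = np.full(21, 3)
    rows[10] = 8
    p = OptimalPath(row_index=rows, total_energy=0.0)
    t = np.linspace(0, 1, 21)
    f = np.arange(10, dtype=float)
    _, fvals, _ = smooth_path(p, t, f, window=5)
    assert fvals.max() - 3.0 < (8.0 - 3.0)


def test_sawtooth_running_mean_oracle():
    rows = np.array([0, 2, 0, 2, 0, 2, 0])
    p = OptimalPath(row_index=rows, total_energy=0.0)
    t = np.arange(7.0)
    f = np.arange(5.0)
    _, fvals, _ = smooth_path(p, t, f, window=3)
    raw = f[rows]
    expected = np.empty(7)
    for i in range(7):  # centered mean, edges replicated ('nearest')
        window = [raw[min(max(j, 0), 6)] for j in (i - 1, i, i + 1)]
        expected[i] = np.mean(window)
    assert np.allclose(fvals, expected)


# -------------------------------------------------------------- init_params

def test_init_spreads_fifth_of_ranges(clean_tfr):
    m = init_params(clean_tfr, K=3)
    t_range = clean_tfr.t[-1] - clean_tfr.t[0]
    f_range = clean_tfr.f[-1] - clean_tfr.f[0]
    assert m.sigma_diag[0] == pytest.approx(t_range / 5.0)
    assert m.sigma_diag[1] == pytest.approx(f_range / 5.0)


def test_init_offset_and_amplitudes(clean_tfr):
    m = init_params(clean_tfr, K=4)
    assert m.C == 0.0
    assert np.allclose(m.peak_points[:, 2], clean_tfr.P.max())


def test_init_even_time_spacing(clean_tfr):
    m = init_params(clean_tfr, K=3)
    expected = np.linspace(clean_tfr.t[0], clean_tfr.t[-1], 3)
    assert np.allclose(m.peak_points[:, 0], expected)


def test_init_rejects_excessive_order(clean_tfr):
    with pytest.raises(InvalidArgumentError):
        init_params(clean_tfr, K=clean_tfr.t.size + 1)


# ---------------------------------------------------------------------- fit

def test_fit_already_optimal_data(rng):
    m = random_model(rng, K=2)
    t = np.linspace(0, 2.5, 24)
    f = np.linspace(0, 30, 24)
    P = eval_snage_grid(m, t, f, grid_density=20, polish=False)
    res = fit(_grid_from(P, t, f), m)
    assert res.sse <= 1e-8
    assert np.allclose(res.params.peak_points, m.peak_points, atol=1e-3)


def test_fit_never_increases_cost(clean_tfr):
    init = init_params(clean_tfr, K=5)
    res = fit(clean_tfr, init)
    assert res.sse <= res.sse_init
    assert res.sse >= 0.0


def test_single_gaussian_recovery_median(rng):
    """20 seeded single-peak truths: median position error < 1 grid spacing."""
    t = np.linspace(0, 2.5, 64)
    f = np.linspace(0, 30, 64)
    dt_sp = t[1] - t[0]
    df_sp = f[1] - f[0]
    tg, fg = np.meshgrid(t, f)
    errors = []
    for trial in range(20):
        r = np.random.default_rng(1000 + trial)
        mu = np.array([r.uniform(0.5, 2.0), r.uniform(6.0, 24.0)])
        sig = np.array([r.uniform(0.02, 0.2), r.uniform(2.0, 30.0)])
        A = r.uniform(1.0, 10.0)
        P = A * np.exp(
            -0.5 * ((tg - mu[0]) ** 2 / sig[0] + (fg - mu[1]) ** 2 / sig[1])
        )
        tfr = _grid_from(P, t, f)
        res = fit(tfr, init_params(tfr, K=1))
        mu_hat = res.params.peak_points[0, :2]
        errors.append(
            max(abs(mu_hat[0] - mu[0]) / dt_sp, abs(mu_hat[1] - mu[1]) / df_sp)
        )
    assert np.median(errors) < 1.0


def test_recovery_degrades_gracefully_with_noise(rng):
    t = np.linspace(0, 2.5, 48)
    f = np.linspace(0, 30, 48)
    tg, fg = np.meshgrid(t, f)
    P = 5.0 * np.exp(-0.5 * ((tg - 1.2) ** 2 / 0.1 + (fg - 12.0) ** 2 / 8.0))
    P_noisy = P + 0.05 * P.max() * rng.standard_normal(P.shape)
    tfr = _grid_from(P_noisy, t, f)
    res = fit(tfr, init_params(tfr, K=1))
    mu_hat = res.params.peak_points[0, :2]
    assert abs(mu_hat[0] - 1.2) < 3 * (t[1] - t[0])
    assert abs(mu_hat[1] - 12.0) < 3 * (f[1] - f[0])
    assert np.isfinite(res.sse)


def test_ata_fit_recovers_three_segment_ridge(clean_tfr):
    from snage.simulation import ridge_frequencies

    init = init_params(clean_tfr, K=5)
    res = fit(clean_tfr, init)
    df_bin = clean_tfr.f[1] - clean_tfr.f[0]
    t_mid = np.array([2.5 / 6, 2.5 / 2, 2.5 * 5 / 6])
    freqs = ridge_frequencies(res.params, t_mid)
    assert np.all(np.abs(freqs - [10.0, 4.0, 10.0]) <= df_bin + 1e-9)


# ------------------------------------------------------------------- refine

def test_refine_degenerate_returns_input(clean_tfr):
    init = init_params(clean_tfr, K=3)
    first = fit(clean_tfr, init)
    out = refine(clean_tfr, first, K_max=3)
    assert len(out) == 1 and out[0] is first


def test_refine_orders_and_sse_trend(clean_tfr):
    init = init_params(clean_tfr, K=3)
    first = fit(clean_tfr, init)
    seq = refine(clean_tfr, first, K_max=7)
    assert [r.params.K for r in seq] == [3, 4, 5, 6, 7]
    for a, b in zip(seq[:-1], seq[1:]):
        assert b.sse <= a.sse * 1.05


def test_refinement_sampling_preserves_curve(clean_tfr):
    """The order-K+1 initial curve reproduces the order-K fit at its sites."""
    init = init_params(clean_tfr, K=4)
    first = fit(clean_tfr, init)
    curve = first.params.curve()
    u_new = np.linspace(1.0, 4.0, 5)
    sampled = curve(u_new)
    for u, p in zip(u_new, sampled):
        assert np.max(np.abs(curve(u) - p)) < 1e-9


# ----------------------------------------------------------------- goodness

def _fitres(sse_val, n_obs, n_params):
    m = SnaGeParams(C=0.0, sigma_diag=[1, 1], peak_points=[[0, 0, 0]])
    return FitResult(
        params=m, sse=sse_val, r2=np.nan, r2_adj=np.nan,
        n_obs=n_obs, n_params=n_params, converged=True,
    )


def test_goodness_perfect_fit():
    tfr = _grid_from(np.array([[1.0, 2.0, 3.0, 4.0]]))
    r2, r2_adj = goodness(_fitres(0.0, 4, 1), tfr)
    assert r2 == pytest.approx(1.0)
    assert r2_adj == pytest.approx(1.0)


def test_goodness_mean_model_zero():
    tfr = _grid_from(np.array([[1.0, 2.0, 3.0, 4.0]]))
    sst = np.sum((tfr.P - tfr.P.mean()) ** 2)
    r2, _ = goodness(_fitres(float(sst), 4, 1), tfr)
    assert r2 == pytest.approx(0.0)


def test_goodness_hand_computed():
    # data [1,2,3,4], model [1,2,3,5]: SSE=1, SST=5 -> R2=0.8, R2_adj=0.7
    tfr = _grid_from(np.array([[1.0, 2.0, 3.0, 4.0]]))
    r2, r2_adj = goodness(_fitres(1.0, 4, 1), tfr)
    assert r2 == pytest.approx(0.8)
    assert r2_adj == pytest.approx(0.7)


def test_goodness_constant_data_undefined():
    tfr = _grid_from(np.full((2, 3), 7.0))
    with pytest.raises(UndefinedMetricError):
        goodness(_fitres(0.0, 6, 1), tfr)
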