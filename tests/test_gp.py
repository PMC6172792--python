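import math

import numpy as np
import pytest

from dynagp import (
    NULL,
    TIME_DEPENDENT,
    ElementSeries,
    FitOptions,
    FittedModel,
    KernelParams,
    fit_model,
    log_marginal_likelihood,
    posterior_predict,
    rbf_cov,
)
from dynagp.gp import lengthscale_lower_bound, noise_lower_bound

from .conftest import draw_gp_series, random_series


def dense_lml_oracle(series, structure, params):
    """Explicit determinant + inverse multivariate-normal log density,
    with the constant mean profiled by the same GLS formula."""
    t, y, v = series.times, series.means, series.fixed_variances
    K = np.diag(params.noise_variance + v)
    if structure == TIME_DEPENDENT:
        K = K + rbf_cov(t, t, params.lengthscale, params.signal_variance)
    Ki = np.linalg.inv(K)
    ones = np.ones_like(y)
    c = (ones @ Ki @ y) / (ones @ Ki @ ones)
    yc = y - c
    _, logdet = np.linalg.slogdet(K)
    return -0.5 * yc @ Ki @ yc - 0.5 * logdet - 0.5 * len(y) * math.log(2 * math.pi)


def test_lml_standard_normal_origin():
    """Two zero observations under a unit covariance give -log(2 pi)."""
    s = ElementSeries("z", [0.0, 1.0], [0.0, 0.0], [0.0, 0.0])
    p = KernelParams(1.0, 0.0, 1.0)
    assert log_marginal_likelihood(s, NULL, p) == pytest.approx(
        -math.log(2 * math.pi), abs=1e-12
    )


def test_lml_closed_form_diagonal_case():
    """Antisymmetric pair centers to itself: -1 - log(2 pi) for unit noise."""
    s = ElementSeries("d", [0.0, 1.0], [1.0, -1.0], [0.0, 0.0])
    p = KernelParams(1.0, 0.0, 1.0)
    assert log_marginal_likelihood(s, NULL, p) == pytest.approx(
        -1.0 - math.log(2 * math.pi), abs=1e-12
    )


@pytest.mark.parametrize("structure", [TIME_DEPENDENT, NULL])
@pytest.mark.parametrize("seed", range(10))
def test_lml_matches_dense_oracle(structure, seed):
    series, params = random_series(seed)
    ours = log_marginal_likelihood(series, structure, params)
    assert ours == pytest.approx(dense_lml_oracle(series, structure, params), abs=1e-8)


def test_lml_matches_sklearn_gpr():
    """Independent route: sklearn's GP regressor at matched hyper-parameters."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    series, params = random_series(7)
    t, y, v = series.times, series.means, series.fixed_variances
    K = rbf_cov(t, t, params.lengthscale, params.signal_variance) + np.diag(
        params.noise_variance + v
    )
    Ki = np.linalg.inv(K)
    ones = np.ones_like(y)
    c = (ones @ Ki @ y) / (ones @ Ki @ ones)
    kernel = ConstantKernel(params.signal_variance, "fixed") * RBF(
        params.lengthscale, "fixed"
    ) + WhiteKernel(params.noise_variance, "fixed")
    gpr = GaussianProcessRegressor(kernel=kernel, alpha=v, optimizer=None)
    gpr.fit(t[:, None], y - c)
    assert log_marginal_likelihood(series, TIME_DEPENDENT, params) == pytest.approx(
        gpr.log_marginal_likelihood_value_, abs=1e-8
    )


@pytest.mark.parametrize("seed", range(10))
def test_posterior_predict_matches_conditional_gaussian_oracle(seed):
    series, _ = random_series(seed, n_max=6)
    model = fit_model(series, TIME_DEPENDENT)
    q = np.linspace(series.times[0] - 1, series.times[-1] + 1, 9)
    mean, var = posterior_predict(series, model, q)
    p = model.params
    t, v = series.times, series.fixed_variances
    Ktr = rbf_cov(t, t, p.lengthscale, p.signal_variance) + np.diag(p.noise_variance + v)
    Ks = rbf_cov(t, q, p.lengthscale, p.signal_variance)
    Kss = rbf_cov(q, q, p.lengthscale, p.signal_variance)
    Ki = np.linalg.inv(Ktr)
    yc = series.means - model.centering_offset
    np.testing.assert_allclose(mean, Ks.T @ Ki @ yc + model.centering_offset, atol=1e-8)
    np.testing.assert_allclose(var, np.diag(Kss - Ks.T @ Ki @ Ks), atol=1e-8)


def test_posterior_interpolates_in_noiseless_limit(fig_grid):
    series = draw_gp_series(11, fig_grid, fixed_variance=0.0)
    Ki = np.linalg.inv(rbf_cov(fig_grid, fig_grid, 1.0, 4.0) + 1e-10 * np.eye(10))
    ones = np.ones(10)
    c = (ones @ Ki @ series.means) / (ones @ Ki @ ones)
    model = FittedModel(
        structure=TIME_DEPENDENT,
        params=KernelParams(1.0, 4.0, 1e-10),
        log_marginal_likelihood=0.0,
        lengthscale_lower_bound=0.0,
        noise_lower_bound=0.0,
        centering_offset=c,
    )
    mean, var = posterior_predict(series, model, series.times)
    np.testing.assert_allclose(mean, series.means, atol=1e-4)
    assert np.all(var < 1e-4)


def test_posterior_reverts_to_prior_far_from_data(fig_grid):
    series = draw_gp_series(12, fig_grid, offset=3.0)
    model = fit_model(series, TIME_DEPENDENT)
    far = np.array([series.times[-1] + 100 * model.params.lengthscale])
    mean, var = posterior_predict(series, model, far)
    assert mean[0] == pytest.approx(model.centering_offset, abs=1e-6)
    assert var[0] == pytest.approx(model.params.signal_variance, rel=1e-6)


@pytest.mark.parametrize("seed", range(8))
def test_null_fit_matches_1d_grid_search(seed):
    series, _ = random_series(seed + 100)
    fit = fit_model(series, NULL)
    bound = fit.noise_lower_bound
    hi = max(1e3 * np.var(series.means), bound * 10)
    grid = np.geomspace(bound, hi, 1000)
    grid_best = max(
        log_marginal_likelihood(
            series, NULL, KernelParams(1.0, 0.0, sn2)
        )
        for sn2 in grid
    )
    assert fit.log_marginal_likelihood >= grid_best - 1e-3


def test_constant_series_gives_matched_models(fig_grid):
    y = np.full(10, 2.5)
    s = ElementSeries("const", fig_grid, y, np.full(10, 0.1))
    dep = fit_model(s, TIME_DEPENDENT)
    null = fit_model(s, NULL)
    assert abs(dep.log_marginal_likelihood - null.log_marginal_likelihood) < 1e-3
    # RBF contributes ~nothing: either no signal or an effectively constant draw
    assert (
        dep.params.signal_variance < 1e-6
        or dep.params.lengthscale > 10 * (fig_grid[-1] - fig_grid[0])
    )


def test_fit_respects_bounds(fig_grid):
    series = draw_gp_series(13, fig_grid)
    opts = FitOptions(noise_bound="min")
    dep = fit_model(series, TIME_DEPENDENT, opts)
    assert dep.params.lengthscale >= lengthscale_lower_bound(fig_grid) - 1e-12
    assert dep.params.noise_variance >= dep.noise_lower_bound - 1e-12
    mean_opts = FitOptions(noise_bound="mean")
    dep2 = fit_model(series, TIME_DEPENDENT, mean_opts)
    assert dep2.noise_lower_bound == pytest.approx(
        float(np.mean(series.fixed_variances))
    )
    assert dep2.params.noise_variance >= dep2.noise_lower_bound - 1e-12


def test_fit_beats_its_initialization_points(fig_grid):
    series = draw_gp_series(14, fig_grid)
    fit = fit_model(series, TIME_DEPENDENT)
    span = fig_grid[-1] - fig_grid[0]
    var_y = float(np.var(series.means))
    init = KernelParams(
        lengthscale=max(lengthscale_lower_bound(fig_grid), span / 2),
        signal_variance=var_y,
        noise_variance=max(fit.noise_lower_bound, 0.1 * var_y),
    )
    assert fit.log_marginal_likelihood >= log_marginal_likelihood(
        series, TIME_DEPENDENT, init
    ) - 1e-9
    assert np.isfinite(fit.log_marginal_likelihood)
    assert fit.diagnostics["n_restarts"] == 3


def test_two_point_series_is_supported():
    s = ElementSeries("tiny", [0.0, 1.5], [1.0, 2.0], [0.1, 0.1])
    fit = fit_model(s, TIME_DEPENDENT)
    assert fit.lengthscale_lower_bound == pytest.approx(1.5)
    assert np.isfinite(fit.log_marginal_likelihood)


def test_single_point_series_is_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        ElementSeries("one", [0.0], [1.0], [0.1])


def test_offset_invariance_of_maximized_lml(fig_grid):
    series = draw_gp_series(15, fig_grid)
    shifted = ElementSeries(
        "s", fig_grid, series.means + 123.456, series.fixed_variances
    )
    for structure in (TIME_DEPENDENT, NULL):
        a = fit_model(series, structure).log_marginal_likelihood
        b = fit_model(shifted, structure).log_marginal_likelihood
        assert abs(a - b) < 1e-6


def test_time_shift_and_rescale_invariance(fig_grid):
    series = draw_gp_series(16, fig_grid)
    base = fit_model(series, TIME_DEPENDENT).log_marginal_likelihood
    shifted = ElementSeries("s", fig_grid + 50.0, series.means, series.fixed_variances)
    scaled = ElementSeries("c", fig_grid * 3.0, series.means, series.fixed_variances)
    assert abs(fit_model(shifted, TIME_DEPENDENT).log_marginal_likelihood - base) < 1e-3
    assert abs(fit_model(scaled, TIME_DEPENDENT).log_marginal_likelihood - base) < 1e-3


def test_nesting_at_matched_parameters(fig_grid):
    """The time-dependent model with zero signal variance reproduces the null."""
    series = draw_gp_series(17, fig_grid, dynamic=False)
    null = fit_model(series, NULL)
    nested = KernelParams(
        lengthscale=1.0,
        signal_variance=0.0,
        noise_variance=null.params.noise_variance,
    )
    assert log_marginal_likelihood(series, TIME_DEPENDENT, nested) == pytest.approx(
        null.log_marginal_likelihood, abs=1e-6
    )


def test_added_noise_decreases_lml_on_null_like_data(fig_grid):
    """For data that a constant explains well, inflating the fixed variances
    at fixed parameters only grows the determinant penalty."""
    rng = np.random.default_rng(18)
    y = 1.0 + 0.05 * rng.standard_normal(10)
    params = KernelParams(1.0, 0.5, 0.1)
    prev = np.inf
    for scale in (1.0, 2.0, 4.0, 8.0):
        s = ElementSeries("m", fig_grid, y, np.full(10, 0.1 * scale))
        lml = log_marginal_likelihood(s, TIME_DEPENDENT, params)
        assert lml < prev
        prev = lml


def test_noise_bound_floor_for_all_zero_variances():
    y = np.array([1.0, 2.0, 0.5, 1.5])
    bound = noise_lower_bound(np.zeros(4), y)
    assert bound == pytest.approx(1e-10 * np.var(y))
    s = ElementSeries("nz", np.arange(4.0), y, np.zeros(4))
    fit = fit_model(s, NULL)
    assert np.isfinite(fit.log_marginal_likelihood)
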