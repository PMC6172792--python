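import numpy as np
import pytest

from dynagp import ElementSeries, KernelParams, rbf_cov
from dynagp.synthetic import default_times


@pytest.fixture
def fig_grid():
    """Transformed 10-point design grid log(5 + [0, 5, ..., 1280])."""
    return default_times()


def draw_gp_series(
    seed: int,
    times: np.ndarray,
    params: KernelParams = KernelParams(1.0, 4.0, 0.01),
    fixed_variance: float = 0.01,
    offset: float = 0.0,
    dynamic: bool = True,
    series_id: str = "sim",
) -> ElementSeries:
    """One series from the generative model with known truth."""
    rng = np.random.default_rng(seed)
    n = len(times)
    if dynamic:
        K = rbf_cov(times, times, params.lengthscale, params.signal_variance)
        f = np.linalg.cholesky(K + 1e-12 * np.eye(n)) @ rng.standard_normal(n)
    else:
        f = np.zeros(n)
    v = np.full(n, fixed_variance)
    y = f + offset + rng.standard_normal(n) * np.sqrt(params.noise_variance + v)
    return ElementSeries(id=series_id, times=times, means=y, fixed_variances=v)


def random_series(seed: int, n_max: int = 12) -> tuple[ElementSeries, KernelParams]:
    """A random short series and random valid hyper-parameters."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    t = np.sort(rng.uniform(0.0, 10.0, n))
    t += np.arange(n) * 1e-3  # guarantee strict increase
    y = rng.normal(rng.uniform(-3, 3), rng.uniform(0.2, 2.0), n)
    v = rng.uniform(0.0, 0.5, n)
    params = KernelParams(
        lengthscale=float(rng.uniform(0.2, 5.0)),
        signal_variance=float(rng.uniform(0.0, 3.0)),
        noise_variance=float(rng.uniform(0.05, 2.0)),
    )
    return ElementSeries(id=f"r{seed}", times=t, means=y, fixed_variances=v), params


@pytest.fixture
def series_factory():
    return draw_gp_series


@pytest.fixture
def random_series_factory():
    return random_series
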