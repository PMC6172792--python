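"""Synthetic collections with known ground truth.

Emulates the typical short, irregular HTS time-series design: ten samples
at t = [0, 5, 10, 20, 40, 80, 160, 320, 640, 1280] minutes analysed on a
log(5 + t) axis.  Dynamic rows are draws from a zero-mean RBF GP plus a
random offset; null rows are the offset alone.  Both receive heteroscedastic
observation noise N(0, sigma_n^2 + v_i), and the returned variance matrix V
holds the true v_i, so ranking quality and calibration can be measured
against the labels.

A second generator produces Pool-seq style allele counts: latent frequency
trajectories (logistic-squashed GP draws for dynamic rows, constant for
null rows) observed through binomial sampling at Poisson-distributed depths.

All randomness flows from one integer seed; each row draws from its own
``SeedSequence`` substream keyed by row index, so a collection is
bit-reproducible and row order is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .kernels import KernelParams, rbf_cov

__all__ = ["SimulationConfig", "simulate_collection", "simulate_counts", "default_times"]

#: the 10-point sampling design in original time units
DESIGN_TIMES = np.array([0.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0, 1280.0])


def default_times() -> np.ndarray:
    """The default grid: log(5 + t) over the 10-point design."""
    return np.log(5.0 + DESIGN_TIMES)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generative settings for one synthetic collection.

    Attributes
    ----------
    n_elements, n_dynamic : int
        Collection size and number of truly dynamic rows (listed first).
    times : ndarray
        Sampling grid; defaults to the log-transformed 10-point design.
    gp_params : KernelParams
        Truth for dynamic rows: length-scale 1.0 on the log-time axis
        (temporal structure resolvable at this sampling density), signal
        variance 4.0, and global noise variance 0.01.
    null_mean_range : (float, float)
        Uniform range for each row's constant offset.
    variance_model : {"constant", "heteroscedastic"}
        Fixed-variance regime: every v_i = base_variance, or spikes of
        ``spike_variance`` at random points with probability ``spike_prob``
        (mimicking time points with poor quantification).
    depth_mean : float
        Mean Poisson sequencing depth for the count generator (min 1).
    seed : int
        Master seed; every row derives its own substream from it.
    """

    n_elements: int = 100
    n_dynamic: int = 10
    times: np.ndarray = field(default_factory=default_times)
    gp_params: KernelParams = field(
        default_factory=lambda: KernelParams(
            lengthscale=1.0, signal_variance=4.0, noise_variance=0.01
        )
    )
    null_mean_range: tuple[float, float] = (-2.0, 2.0)
    variance_model: str = "constant"
    base_variance: float = 0.01
    spike_variance: float = 4.0
    spike_prob: float = 0.2
    depth_mean: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dynamic > self.n_elements or self.n_dynamic < 0:
            raise ValueError(
                f"n_dynamic must be in [0, n_elements], got {self.n_dynamic}/{self.n_elements}"
            )
        if self.variance_model not in ("constant", "heteroscedastic"):
            raise ValueError(f"unknown variance_model {self.variance_model!r}")
        if self.base_variance < 0 or self.spike_variance < 0:
            raise ValueError("variances must be non-negative")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ValueError("spike_prob must be in [0, 1]")
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float).ravel())


def _row_rng(seed: int, row: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(row,)))


def _row_variances(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.times.shape[0]
    v = np.full(n, cfg.base_variance)
    if cfg.variance_model == "heteroscedastic":
        spikes = rng.random(n) < cfg.spike_prob
        v[spikes] = cfg.spike_variance
    return v


def simulate_collection(
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate (Y, V, times, labels) with labels True for dynamic rows."""
    n = cfg.times.shape[0]
    m = cfg.n_elements
    K = rbf_cov(cfg.times, cfg.times, cfg.gp_params.lengthscale, cfg.gp_params.signal_variance)
    L = np.linalg.cholesky(K + 1e-12 * np.eye(n))
    Y = np.empty((m, n))
    V = np.empty((m, n))
    labels = np.zeros(m, dtype=bool)
    labels[: cfg.n_dynamic] = True
    lo, hi = cfg.null_mean_range
    for i in range(m):
        rng = _row_rng(cfg.seed, i)
        offset = rng.uniform(lo, hi)
        v = _row_variances(cfg, rng)
        f = L @ rng.standard_normal(n) if labels[i] else np.zeros(n)
        noise = rng.standard_normal(n) * np.sqrt(cfg.gp_params.noise_variance + v)
        Y[i] = f + offset + noise
        V[i] = v
    return Y, V, cfg.times.copy(), labels


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate Pool-seq style (X, D, times, labels).

    Latent frequencies: a base frequency per row drawn uniformly in
    (0.2, 0.8); dynamic rows add a GP draw on the logit scale before the
    logistic squashing, null rows stay constant.  Depths are
    Poisson(depth_mean) clipped to at least 1; counts are
    Binomial(depth, frequency).
    """
    n = cfg.times.shape[0]
    m = cfg.n_elements
    K = rbf_cov(cfg.times, cfg.times, cfg.gp_params.lengthscale, cfg.gp_params.signal_variance)
    L = np.linalg.cholesky(K + 1e-12 * np.eye(n))
    X = np.empty((m, n), dtype=np.int64)
    D = np.empty((m, n), dtype=np.int64)
    labels = np.zeros(m, dtype=bool)
    labels[: cfg.n_dynamic] = True
    for i in range(m):
        rng = _row_rng(cfg.seed, i)
        base = rng.uniform(0.2, 0.8)
        traj = logit(base) + (L @ rng.standard_normal(n) if labels[i] else 0.0)
        freq = expit(traj) * np.ones(n)
        depth = np.maximum(rng.poisson(cfg.depth_mean, size=n), 1)
        D[i] = depth
        X[i] = rng.binomial(depth, freq)
    return X, D, cfg.times.copy(), labels
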