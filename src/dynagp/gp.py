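"""Zero-mean GP marginal likelihood, bounded fitting, and prediction.

One genomic element contributes a short time series ``(t, y, v)`` where
``v`` holds fixed per-observation variances obtained upstream (probabilistic
quantification or a beta-binomial posterior).  Two model structures are
fitted by maximum marginal likelihood:

* time-dependent: ``K = rbf(t, t) + (sigma_n^2 + v_i) I``
* null (time-independent): ``K = (sigma_n^2 + v_i) I``

Both models carry an explicit constant mean that is profiled out at its
maximum-likelihood value under the model's own covariance,
``c = (1' K^-1 y) / (1' K^-1 1)`` — the GLS mean.  Under the null this is
the precision-weighted average of the observations, so time points with
large fixed variances cannot drag the constant the way an arithmetic mean
would.  Two bounds
keep the likelihood surface well-behaved on short series: the RBF
length-scale is bounded below by the minimum sampling gap, and the global
noise variance is bounded below by an aggregate of the fixed variances
(min by default, mean selectable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize

from .kernels import (
    KernelParams,
    assemble_cov,
    cov_gradients,
    jittered_cholesky,
    rbf_cov,
)

__all__ = [
    "ElementSeries",
    "FitOptions",
    "FittedModel",
    "FittingError",
    "TIME_DEPENDENT",
    "NULL",
    "log_marginal_likelihood",
    "fit_model",
    "posterior_predict",
    "noise_lower_bound",
    "lengthscale_lower_bound",
]

TIME_DEPENDENT = "time_dependent"
NULL = "null"

_LOG_2PI = math.log(2.0 * math.pi)
_EPS = 1e-12  # slack inside the bound reparameterization


class FittingError(RuntimeError):
    """Hyper-parameter optimization failed on all restarts."""


@dataclass(frozen=True)
class ElementSeries:
    """One genomic element's time series.

    Attributes
    ----------
    id : str
        Element identifier (gene, transcript, locus ...).
    times : ndarray, shape (n,)
        Strictly increasing, possibly transformed, time points.
    means : ndarray, shape (n,)
        Estimated mean abundances ``y``.
    fixed_variances : ndarray, shape (n,)
        Non-negative per-observation variances ``v`` (not optimized).
    """

    id: str
    times: np.ndarray
    means: np.ndarray
    fixed_variances: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        y = np.asarray(self.means, dtype=float).ravel()
        v = np.asarray(self.fixed_variances, dtype=float).ravel()
        if t.shape[0] < 2:
            raise ValueError(f"series {self.id!r}: need at least 2 time points")
        if not (t.shape == y.shape == v.shape):
            raise ValueError(
                f"series {self.id!r}: times/means/variances lengths differ "
                f"({t.shape[0]}, {y.shape[0]}, {v.shape[0]})"
            )
        if not (np.isfinite(t).all() and np.isfinite(y).all() and np.isfinite(v).all()):
            raise ValueError(f"series {self.id!r}: non-finite values in input")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"series {self.id!r}: times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError(f"series {self.id!r}: negative fixed variance")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "means", y)
        object.__setattr__(self, "fixed_variances", v)

    @property
    def n(self) -> int:
        return int(self.times.shape[0])


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration for :func:`fit_model`.

    ``noise_bound`` selects how the fixed variances aggregate into the lower
    bound on the global noise variance: ``"min"`` (default, the weakest bound
    consistent with treating them as a floor) or ``"mean"``.
    """

    n_restarts: int = 3
    noise_bound: str = "min"
    max_iter: int = 200
    gtol: float = 1e-6
    restart_factors: tuple[float, ...] = (0.25, 4.0)

    def __post_init__(self) -> None:
        if self.noise_bound not in ("min", "mean"):
            raise ValueError(f"noise_bound must be 'min' or 'mean', got {self.noise_bound!r}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class FittedModel:
    """Optimized hyper-parameters and maximum log marginal likelihood."""

    structure: str
    params: KernelParams
    log_marginal_likelihood: float
    lengthscale_lower_bound: float
    noise_lower_bound: float
    centering_offset: float
    diagnostics: dict = field(default_factory=dict)


def lengthscale_lower_bound(times: np.ndarray) -> float:
    """Minimum sampling gap, the lower bound on the RBF length-scale."""
    t = np.asarray(times, dtype=float).ravel()
    return float(np.min(np.diff(t)))


def noise_lower_bound(
    fixed_variances: np.ndarray, means: np.ndarray, method: str = "min"
) -> float:
    """Lower bound on the global noise variance from the fixed variances.

    When every fixed variance is zero the bound would vanish; a floor of
    ``1e-10 * var(y)`` (or 1e-12 for a constant series) avoids an exactly
    singular covariance in that degenerate case.
    """
    v = np.asarray(fixed_variances, dtype=float).ravel()
    bound = float(np.min(v) if method == "min" else np.mean(v))
    if bound <= 0.0:
        var_y = float(np.var(np.asarray(means, dtype=float)))
        bound = 1e-10 * var_y if var_y > 0 else 1e-12
    return bound


def _structure_cov(series: ElementSeries, structure: str, params: KernelParams) -> np.ndarray:
    if structure == TIME_DEPENDENT:
        return assemble_cov(series.times, params, series.fixed_variances, include_rbf=True)
    if structure == NULL:
        return assemble_cov(series.times, params, series.fixed_variances, include_rbf=False)
    raise ValueError(f"unknown model structure {structure!r}")


def _profiled_centering(
    y: np.ndarray, L: np.ndarray
) -> tuple[float, np.ndarray]:
    """ML constant mean under covariance ``K = L L'`` and the residual solve.

    ``c = (1' K^-1 y) / (1' K^-1 1)``; returns ``(c, alpha)`` with
    ``alpha = K^-1 (y - c)``.  Reduces to the arithmetic mean for an
    isotropic diagonal covariance and to the precision-weighted mean under
    the null structure.
    """
    ones = np.ones_like(y)
    Kinv_y = cho_solve((L, True), y)
    Kinv_1 = cho_solve((L, True), ones)
    c = float(ones @ Kinv_y) / float(ones @ Kinv_1)
    return c, Kinv_y - c * Kinv_1


def log_marginal_likelihood(
    series: ElementSeries, structure: str, params: KernelParams
) -> float:
    """Log marginal likelihood log N(y - c | 0, K) via Cholesky.

    ``K`` is the structure's covariance at ``params`` and ``c`` the
    profiled (maximum-likelihood) constant mean under that covariance.
    """
    K = _structure_cov(series, structure, params)
    L, _ = jittered_cholesky(K)
    c, alpha = _profiled_centering(series.means, L)
    yc = series.means - c
    return float(
        -0.5 * yc @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * series.n * _LOG_2PI
    )


def _lml_and_grad(
    series: ElementSeries,
    structure: str,
    params: KernelParams,
) -> tuple[float, dict[str, float], float]:
    """Profiled log marginal likelihood, its gradient, and the offset.

    grad_theta = 0.5 * (alpha' dK/dtheta alpha - tr(K^-1 dK/dtheta)) with
    ``alpha = K^-1 (y - c)``.  Because the offset ``c`` is profiled
    (d lml / d c = 0 at the optimum), its implicit dependence on the kernel
    parameters contributes nothing to the gradient (envelope theorem).
    """
    K = _structure_cov(series, structure, params)
    L, _ = jittered_cholesky(K)
    c, alpha = _profiled_centering(series.means, L)
    yc = series.means - c
    n = series.n
    lml = float(-0.5 * yc @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * _LOG_2PI)
    Linv = solve_triangular(L, np.eye(n), lower=True)
    Kinv = Linv.T @ Linv
    grads: dict[str, float] = {}
    if structure == TIME_DEPENDENT:
        dK = cov_gradients(series.times, params, series.fixed_variances)
        for name, dKd in dK.items():
            grads[name] = float(0.5 * (alpha @ dKd @ alpha - np.sum(Kinv * dKd)))
    else:
        # dK/d noise_variance = I
        grads["noise_variance"] = float(0.5 * (alpha @ alpha - np.trace(Kinv)))
    return lml, grads, c


def _clip_exp(u: np.ndarray | float) -> np.ndarray | float:
    return np.exp(np.clip(u, -700.0, 60.0))


def _dep_params_from_u(u: np.ndarray, l_bound: float, n_bound: float) -> KernelParams:
    # clamp at the bound: the -eps slack may otherwise undershoot by ~1e-13
    return KernelParams(
        lengthscale=max(l_bound, l_bound - _EPS + _clip_exp(u[0])),
        signal_variance=float(_clip_exp(u[1])),
        noise_variance=max(n_bound, n_bound - _EPS + _clip_exp(u[2])),
    )


def _null_params_from_u(u: np.ndarray, l_bound: float, n_bound: float) -> KernelParams:
    return KernelParams(
        lengthscale=l_bound,
        signal_variance=0.0,
        noise_variance=max(n_bound, n_bound - _EPS + _clip_exp(u[0])),
    )


def fit_model(
    series: ElementSeries,
    structure: str,
    options: FitOptions | None = None,
) -> FittedModel:
    """Bounded maximum-marginal-likelihood fit of one model structure.

    Free parameters are optimized on a log scale relative to their lower
    bounds (``log(l - bound + eps)`` etc.), which enforces the bounds
    smoothly; L-BFGS with analytic gradients, a deterministic restart
    schedule, and the best optimum over restarts (including the evaluated
    starting points) is reported.
    """
    opts = options or FitOptions()
    y = series.means
    var_y = float(np.var(y))
    l_bound = lengthscale_lower_bound(series.times)
    n_bound = noise_lower_bound(series.fixed_variances, y, opts.noise_bound)
    span = float(series.times[-1] - series.times[0])

    sn2_init = max(n_bound, 0.1 * var_y) if var_y > 0 else max(n_bound, 1e-8)
    sf2_base = var_y if var_y > 0 else 1e-8
    ell_base = max(l_bound, span / 2.0)

    if structure == NULL:
        n_free = 1

        def make_u0(factor: float) -> np.ndarray:
            sn2 = max(n_bound + _EPS * 2, sn2_init * factor)
            return np.array([math.log(sn2 - n_bound + _EPS)])

        starts = [make_u0(1.0)]
        for f in opts.restart_factors[: opts.n_restarts - 1]:
            starts.append(make_u0(f))
        params_from_u = _null_params_from_u
        grad_names = ["noise_variance"]
    elif structure == TIME_DEPENDENT:
        n_free = 3

        def make_u0_dep(f_ell: float, f_sf: float) -> np.ndarray:
            ell = max(l_bound + _EPS * 2, ell_base * f_ell)
            sf2 = max(1e-12, sf2_base * f_sf)
            return np.array(
                [
                    math.log(ell - l_bound + _EPS),
                    math.log(sf2),
                    math.log(max(sn2_init, n_bound + _EPS * 2) - n_bound + _EPS),
                ]
            )

        starts = [make_u0_dep(1.0, 1.0)]
        for f in opts.restart_factors[: opts.n_restarts - 1]:
            starts.append(make_u0_dep(f, f))
        params_from_u = _dep_params_from_u
        grad_names = ["lengthscale", "signal_variance", "noise_variance"]
    else:
        raise ValueError(f"unknown model structure {structure!r}")

    def objective(u: np.ndarray) -> tuple[float, np.ndarray]:
        params = params_from_u(u, l_bound, n_bound)
        lml, grads, _ = _lml_and_grad(series, structure, params)
        # chain rule: d theta / d u = exp(u) for each reparameterized theta
        g = np.empty(n_free)
        exps = _clip_exp(u)
        if structure == TIME_DEPENDENT:
            for k, name in enumerate(grad_names):
                g[k] = grads[name] * exps[k]
        else:
            g[0] = grads["noise_variance"] * exps[0]
        return -lml, -g

    best_u: np.ndarray | None = None
    best_f = np.inf
    best_diag: dict = {}
    errors: list[str] = []
    for i, u0 in enumerate(starts):
        try:
            f0, _ = objective(u0)
            if f0 < best_f:
                best_f, best_u = f0, u0
                best_diag = {"n_iter": 0, "converged": False, "restart": i}
            res = minimize(
                objective,
                u0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": opts.max_iter, "gtol": opts.gtol},
            )
            if np.isfinite(res.fun) and res.fun < best_f:
                best_f, best_u = float(res.fun), np.asarray(res.x)
                best_diag = {
                    "n_iter": int(res.nit),
                    "converged": bool(res.success),
                    "restart": i,
                }
        except (np.linalg.LinAlgError, FloatingPointError) as exc:  # pragma: no cover
            errors.append(f"restart {i}: {exc}")
            continue

    if best_u is None:
        raise FittingError(
            f"series {series.id!r}: optimization failed on all restarts: "
            + "; ".join(errors)
        )

    params = params_from_u(best_u, l_bound, n_bound)
    best_diag["n_restarts"] = len(starts)
    _, _, offset = _lml_and_grad(series, structure, params)
    return FittedModel(
        structure=structure,
        params=params,
        log_marginal_likelihood=-best_f,
        lengthscale_lower_bound=l_bound,
        noise_lower_bound=n_bound,
        centering_offset=offset,
        diagnostics=best_diag,
    )


def posterior_predict(
    series: ElementSeries,
    model: FittedModel,
    query_times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance of the latent function at ``query_times``.

    The latent function excludes the observation noise: for the
    time-dependent structure it is the RBF component, so far from the data
    the mean reverts to the centering offset and the variance to the signal
    variance.  For the null structure the latent function is the constant
    offset with zero variance.
    """
    q = np.asarray(query_times, dtype=float).ravel()
    if model.structure == NULL:
        return np.full(q.shape, model.centering_offset), np.zeros(q.shape)
    params = model.params
    yc = series.means - model.centering_offset
    K = _structure_cov(series, TIME_DEPENDENT, params)
    L, _ = jittered_cholesky(K)
    Ks = rbf_cov(series.times, q, params.lengthscale, params.signal_variance)
    alpha = cho_solve((L, True), yc)
    mean = Ks.T @ alpha + model.centering_offset
    A = solve_triangular(L, Ks, lower=True)
    var = params.signal_variance - np.sum(A * A, axis=0)
    return mean, np.maximum(var, 0.0)
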