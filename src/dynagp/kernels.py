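"""Covariance functions for the two competing model structures.

The time-dependent model places a squared-exponential (RBF) prior on the
latent temporal profile and adds white noise plus fixed, per-observation
variances on the diagonal.  The time-independent null model keeps only the
diagonal part, so observations are independent around a constant.

All kernels operate on (possibly transformed) real-valued time vectors and
return dense ``numpy`` arrays; series are short, so no structure is
exploited beyond the Cholesky factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "InvalidParameterError",
    "rbf_cov",
    "diag_cov",
    "assemble_cov",
    "cov_gradients",
    "jittered_cholesky",
]


class InvalidParameterError(ValueError):
    """A kernel hyper-parameter violates its domain constraint."""


@dataclass(frozen=True)
class KernelParams:
    """RBF + noise hyper-parameters.

    Parameters
    ----------
    lengthscale : float
        RBF length-scale, in the units of the (transformed) time axis.
        Must be strictly positive.
    signal_variance : float
        RBF signal variance, in abundance² units.  Zero is allowed and
        degenerates the time-dependent model toward the null.
    noise_variance : float
        Global white-noise variance, in abundance² units; the fixed
        per-observation variances are added on top of it.
    """

    lengthscale: float
    signal_variance: float
    noise_variance: float

    def __post_init__(self) -> None:
        for name in ("lengthscale", "signal_variance", "noise_variance"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise InvalidParameterError(f"{name} must be finite, got {val!r}")
        if self.lengthscale <= 0:
            raise InvalidParameterError(
                f"lengthscale must be > 0, got {self.lengthscale!r}"
            )
        if self.signal_variance < 0:
            raise InvalidParameterError(
                f"signal_variance must be >= 0, got {self.signal_variance!r}"
            )
        if self.noise_variance < 0:
            raise InvalidParameterError(
                f"noise_variance must be >= 0, got {self.noise_variance!r}"
            )


def _sq_dists(t_a: np.ndarray, t_b: np.ndarray) -> np.ndarray:
    t_a = np.asarray(t_a, dtype=float).ravel()
    t_b = np.asarray(t_b, dtype=float).ravel()
    d = t_a[:, None] - t_b[None, :]
    return d * d


def rbf_cov(
    t_a: np.ndarray,
    t_b: np.ndarray,
    lengthscale: float,
    signal_variance: float,
) -> np.ndarray:
    """Squared-exponential covariance sigma_f^2 * exp(-(ta-tb)^2 / (2 l^2))."""
    if not (np.isfinite(lengthscale) and lengthscale > 0):
        raise InvalidParameterError(f"lengthscale must be > 0, got {lengthscale!r}")
    if signal_variance < 0:
        raise InvalidParameterError(
            f"signal_variance must be >= 0, got {signal_variance!r}"
        )
    return signal_variance * np.exp(-_sq_dists(t_a, t_b) / (2.0 * lengthscale**2))


def diag_cov(
    n: int, noise_variance: float, fixed_variances: np.ndarray
) -> np.ndarray:
    """Diagonal noise covariance with entries ``noise_variance + v_i``."""
    v = np.asarray(fixed_variances, dtype=float).ravel()
    if v.shape[0] != n:
        raise InvalidParameterError(
            f"fixed_variances has length {v.shape[0]}, expected {n}"
        )
    if noise_variance < 0:
        raise InvalidParameterError(
            f"noise_variance must be >= 0, got {noise_variance!r}"
        )
    if np.any(v < 0):
        bad = int(np.argmax(v < 0))
        raise InvalidParameterError(
            f"fixed variance at index {bad} is negative ({v[bad]!r})"
        )
    return np.diag(noise_variance + v)


def assemble_cov(
    t: np.ndarray,
    params: KernelParams,
    fixed_variances: np.ndarray,
    include_rbf: bool = True,
) -> np.ndarray:
    """Sum of the kernel components for one model structure.

    ``include_rbf=True`` gives the time-dependent structure
    (rbf + white + fixedvariance); ``False`` gives the null structure
    (white + fixedvariance).
    """
    t = np.asarray(t, dtype=float).ravel()
    K = diag_cov(t.shape[0], params.noise_variance, fixed_variances)
    if include_rbf:
        K = K + rbf_cov(t, t, params.lengthscale, params.signal_variance)
    return K


def cov_gradients(
    t: np.ndarray,
    params: KernelParams,
    fixed_variances: np.ndarray,
) -> dict[str, np.ndarray]:
    """Analytic gradients of the assembled time-dependent covariance.

    Returns ``dK/d lengthscale``, ``dK/d signal_variance`` and
    ``dK/d noise_variance`` evaluated at ``params``, as a dict keyed by
    parameter name.  Used by the marginal-likelihood optimizer.
    """
    t = np.asarray(t, dtype=float).ravel()
    n = t.shape[0]
    np.asarray(fixed_variances)  # validated by the caller via diag_cov
    d2 = _sq_dists(t, t)
    ell = params.lengthscale
    if not (np.isfinite(ell) and ell > 0):
        raise InvalidParameterError(f"lengthscale must be > 0, got {ell!r}")
    expo = np.exp(-d2 / (2.0 * ell**2))
    return {
        "lengthscale": params.signal_variance * expo * d2 / ell**3,
        "signal_variance": expo,
        "noise_variance": np.eye(n),
    }


#: initial jitter, as a fraction of the mean diagonal
_JITTER_START = 1e-8
#: give up once the jitter fraction exceeds this
_JITTER_MAX = 1e-2


def jittered_cholesky(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower-Cholesky factor with escalating diagonal jitter.

    Starts at 1e-8 * mean(diag) and multiplies by 10 up to 1e-2 * mean(diag);
    raises ``numpy.linalg.LinAlgError`` if the matrix is still not positive
    definite.  Returns ``(L, jitter_added)``.
    """
    try:
        return np.linalg.cholesky(K), 0.0
    except np.linalg.LinAlgError:
        pass
    scale = float(np.mean(np.diag(K)))
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    frac = _JITTER_START
    eye = np.eye(K.shape[0])
    while frac <= _JITTER_MAX:
        jitter = frac * scale
        try:
            return np.linalg.cholesky(K + jitter * eye), jitter
        except np.linalg.LinAlgError:
            frac *= 10.0
    raise np.linalg.LinAlgError(
        "covariance not positive definite after jitter escalation "
        f"(up to {_JITTER_MAX:g} * mean diagonal)"
    )
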