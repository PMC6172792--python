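"""Mean/variance inputs from Pool-seq allele counts via a beta-binomial model.

At each locus and time point, an allele count ``x`` out of sequencing depth
``n_d`` updates a conjugate Beta(a, b) prior on the allele frequency; the
posterior Beta(x + a, n_d - x + b) supplies the mean abundance and its fixed
variance for the GP test.  Deeper sequencing yields smaller variances, so
uncertainty from uneven coverage flows directly into the model.

Externally estimated mean/variance matrices (e.g. from probabilistic
transcript quantification) are accepted as-is; nothing here recomputes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CountObservation",
    "beta_binomial_mean_var",
    "counts_to_matrices",
]


@dataclass(frozen=True)
class CountObservation:
    """Allele count and sequencing depth at one locus/time point."""

    allele_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.allele_count < 0 or self.depth < 0:
            raise ValueError(
                f"counts must be non-negative, got x={self.allele_count}, "
                f"depth={self.depth}"
            )
        if self.allele_count > self.depth:
            raise ValueError(
                f"allele count {self.allele_count} exceeds depth {self.depth}"
            )


def beta_binomial_mean_var(
    obs: CountObservation, prior_a: float = 1.0, prior_b: float = 1.0
) -> tuple[float, float]:
    """Posterior mean and variance of the allele frequency.

    The posterior is Beta(x + a, n_d - x + b) with mean
    ``(x + a) / (n_d + a + b)`` and variance ``mean (1 - mean) / (n_d + a + b + 1)``.
    With the default uniform Beta(1, 1) prior and zero depth this returns the
    prior moments (0.5, 1/12).
    """
    if prior_a <= 0 or prior_b <= 0:
        raise ValueError(f"prior parameters must be positive, got ({prior_a}, {prior_b})")
    total = obs.depth + prior_a + prior_b
    mean = (obs.allele_count + prior_a) / total
    var = mean * (1.0 - mean) / (total + 1.0)
    return float(mean), float(var)


def counts_to_matrices(
    X: np.ndarray,
    D: np.ndarray,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Elementwise beta-binomial moments for count/depth matrices.

    Parameters
    ----------
    X, D : (m, n) integer arrays
        Allele counts and sequencing depths, ``X <= D`` elementwise.
    prior_a, prior_b : float
        Beta prior parameters (uniform prior by default).

    Returns
    -------
    Y, V : (m, n) float arrays
        Posterior means and variances of the allele frequencies.
    zero_depth : (m, n) bool array
        Flags cells with depth 0, which carry only the prior moments.
    """
    if prior_a <= 0 or prior_b <= 0:
        raise ValueError(f"prior parameters must be positive, got ({prior_a}, {prior_b})")
    X = np.asarray(X)
    D = np.asarray(D)
    if X.shape != D.shape:
        raise ValueError(f"count shape {X.shape} != depth shape {D.shape}")
    if np.any(X < 0) or np.any(D < 0):
        raise ValueError("counts and depths must be non-negative")
    if np.any(X > D):
        i, j = np.argwhere(X > D)[0]
        raise ValueError(
            f"allele count exceeds depth at row {i}, column {j} "
            f"({X[i, j]} > {D[i, j]})"
        )
    total = D + prior_a + prior_b
    Y = (X + prior_a) / total
    V = Y * (1.0 - Y) / (total + 1.0)
    return Y.astype(float), V.astype(float), D == 0
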