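"""scikit-learn-style estimators.

:class:`FixedNoiseGP` fits one series under a chosen model structure and
predicts the latent temporal profile; :class:`BayesFactorRanker` runs the
paired-model test over an entire m x n collection and exposes the ranked
results.  Both follow the sklearn conventions (``get_params``/``set_params``
via ``BaseEstimator``, fitted attributes with a trailing underscore) so they
compose with pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .gp import (
    NULL,
    TIME_DEPENDENT,
    ElementSeries,
    FitOptions,
    fit_model,
    posterior_predict,
)
from .ranking import DEFAULT_THRESHOLD, GPTestResult, gp_test, rank_elements

__all__ = ["FixedNoiseGP", "BayesFactorRanker"]


def _as_times(X: np.ndarray) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2:
        if t.shape[1] != 1:
            raise ValueError(f"expected a single time column, got shape {t.shape}")
        t = t[:, 0]
    elif t.ndim != 1:
        raise ValueError(f"times must be 1-d or (n, 1), got shape {t.shape}")
    return t


class FixedNoiseGP(BaseEstimator, RegressorMixin):
    """GP regression on one time series with fixed per-observation variances.

    Parameters
    ----------
    time_dependent : bool, default True
        If True, use the rbf + white + fixed-variance structure; otherwise
        the white + fixed-variance null structure (constant function).
    noise_bound : {"min", "mean"}, default "min"
        Aggregation of the fixed variances into the lower bound on the
        global noise variance.
    n_restarts : int, default 3
        Deterministic optimizer restarts.
    max_iter : int, default 200
        L-BFGS iteration cap per restart.
    gtol : float, default 1e-6
        Gradient-norm convergence tolerance.

    Attributes
    ----------
    model_ : FittedModel
        Optimized structure, parameters and log marginal likelihood.
    log_marginal_likelihood_ : float
    kernel_params_ : KernelParams
    """

    def __init__(
        self,
        time_dependent: bool = True,
        noise_bound: str = "min",
        n_restarts: int = 3,
        max_iter: int = 200,
        gtol: float = 1e-6,
    ):
        self.time_dependent = time_dependent
        self.noise_bound = noise_bound
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.gtol = gtol

    def _options(self) -> FitOptions:
        return FitOptions(
            n_restarts=self.n_restarts,
            noise_bound=self.noise_bound,
            max_iter=self.max_iter,
            gtol=self.gtol,
        )

    def fit(self, X, y, fixed_variances=None):
        """Fit on times ``X`` (shape (n,) or (n, 1)) and abundances ``y``."""
        t = _as_times(X)
        y = np.asarray(y, dtype=float).ravel()
        v = (
            np.zeros_like(t)
            if fixed_variances is None
            else np.asarray(fixed_variances, dtype=float).ravel()
        )
        self.series_ = ElementSeries(id="series", times=t, means=y, fixed_variances=v)
        structure = TIME_DEPENDENT if self.time_dependent else NULL
        self.model_ = fit_model(self.series_, structure, self._options())
        self.log_marginal_likelihood_ = self.model_.log_marginal_likelihood
        self.kernel_params_ = self.model_.params
        self.n_features_in_ = 1
        return self

    def predict(self, X, return_std: bool = False):
        """Posterior mean (and optionally SD) of the latent function."""
        check_is_fitted(self, "model_")
        mean, var = posterior_predict(self.series_, self.model_, _as_times(X))
        if return_std:
            return mean, np.sqrt(var)
        return mean


class BayesFactorRanker(BaseEstimator):
    """Rank the rows of an abundance matrix by GP Bayes factors.

    ``fit`` takes an (m, n) matrix of mean abundances with the matching
    variance matrix and time vector, fits both GP structures per row, and
    stores the ranked results.  Rows are modelled independently; rows whose
    fits fail are collected in ``rejects_`` instead of aborting the run.

    Parameters
    ----------
    threshold : float or None, default 3.0
        ln BF cut-off for the boolean ``pass`` column (strong evidence).
    prior_odds : float, default 1.0
        Prior odds of the time-dependent model for posterior probabilities.
    noise_bound, n_restarts, max_iter, gtol
        Passed to the per-series optimizer (see :class:`FixedNoiseGP`).

    Attributes
    ----------
    results_ : list of GPTestResult, in input row order
    ranking_ : pandas.DataFrame sorted by ln BF descending
    rejects_ : list of dict with ``id`` and ``reason`` for failed rows
    ln_bf_ : ndarray aligned with the successfully fitted input rows of ``results_``
    """

    def __init__(
        self,
        threshold: float | None = DEFAULT_THRESHOLD,
        prior_odds: float = 1.0,
        noise_bound: str = "min",
        n_restarts: int = 3,
        max_iter: int = 200,
        gtol: float = 1e-6,
    ):
        self.threshold = threshold
        self.prior_odds = prior_odds
        self.noise_bound = noise_bound
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.gtol = gtol

    def fit(self, X, y=None, *, V=None, times=None, ids=None):
        """Fit the paired GP test on every row of ``X``.

        Parameters
        ----------
        X : ndarray (m, n)
            Mean abundances, one element per row.
        V : ndarray (m, n), optional
            Fixed per-observation variances; zeros when omitted.
        times : ndarray (n,)
            Time points (required; possibly already transformed).
        ids : sequence of str, optional
            Row identifiers; defaults to ``row0001`` style labels.
        """
        Y = np.atleast_2d(np.asarray(X, dtype=float))
        if times is None:
            raise ValueError("times must be provided")
        t = np.asarray(times, dtype=float).ravel()
        if Y.shape[1] != t.shape[0]:
            raise ValueError(
                f"Y has {Y.shape[1]} columns but times has {t.shape[0]} entries"
            )
        if V is None:
            Vm = np.zeros_like(Y)
        else:
            Vm = np.atleast_2d(np.asarray(V, dtype=float))
        if Vm.shape != Y.shape:
            raise ValueError(f"V shape {Vm.shape} != Y shape {Y.shape}")
        if np.any(Vm < 0):
            raise ValueError("variance matrix has negative entries")
        m = Y.shape[0]
        if ids is None:
            width = max(4, len(str(m)))
            ids = [f"row{i + 1:0{width}d}" for i in range(m)]
        ids = [str(i) for i in ids]
        if len(ids) != m:
            raise ValueError(f"{len(ids)} ids for {m} rows")
        if len(set(ids)) != m:
            raise ValueError("duplicate element ids")

        opts = FitOptions(
            n_restarts=self.n_restarts,
            noise_bound=self.noise_bound,
            max_iter=self.max_iter,
            gtol=self.gtol,
        )
        results: list[GPTestResult] = []
        rejects: list[dict] = []
        for i in range(m):
            series = None
            try:
                series = ElementSeries(
                    id=ids[i], times=t, means=Y[i], fixed_variances=Vm[i]
                )
                results.append(gp_test(series, opts))
            except Exception as exc:
                rejects.append({"id": ids[i], "reason": str(exc)})
        self.results_ = results
        self.rejects_ = rejects
        self.ln_bf_ = np.array([r.ln_bf for r in results])
        if results:
            self.ranking_ = rank_elements(
                results, threshold=self.threshold, prior_odds=self.prior_odds
            )
        else:
            self.ranking_ = pd.DataFrame(
                columns=["rank", "id", "ln_bf", "posterior_prob"]
            )
        self.n_features_in_ = Y.shape[1]
        return self

    def ranked_ids(self) -> list[str]:
        check_is_fitted(self, "ranking_")
        return list(self.ranking_["id"])
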