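"""Per-element Bayes-factor test and genome-wide ranking.

Each element's series is fitted under the time-dependent and null GP
structures; the natural-log Bayes factor is the difference of the maximum
log marginal likelihoods.  Elements are ranked by ln BF; ln BF > 3 is the
conventional "strong evidence" cut-off, corresponding to roughly 95%
posterior probability for the time-dependent model under equal priors.
Bayes factors are not p-values: no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .gp import NULL, TIME_DEPENDENT, ElementSeries, FitOptions, FittedModel, fit_model

__all__ = [
    "GPTestResult",
    "gp_test",
    "posterior_probability",
    "rank_elements",
    "run_collection",
    "precision_at_k",
    "DEFAULT_THRESHOLD",
]

#: ln BF cut-off for "strong evidence" in favour of the time-dependent model
DEFAULT_THRESHOLD = 3.0


@dataclass(frozen=True)
class GPTestResult:
    """Paired fits and log Bayes factor for one element."""

    id: str
    fit_dep: FittedModel
    fit_null: FittedModel
    ln_bf: float


def gp_test(series: ElementSeries, options: FitOptions | None = None) -> GPTestResult:
    """Fit both model structures and compute ln BF for one series."""
    try:
        fit_dep = fit_model(series, TIME_DEPENDENT, options)
        fit_null = fit_model(series, NULL, options)
    except Exception as exc:
        raise type(exc)(f"element {series.id!r}: {exc}") from exc
    ln_bf = fit_dep.log_marginal_likelihood - fit_null.log_marginal_likelihood
    return GPTestResult(id=series.id, fit_dep=fit_dep, fit_null=fit_null, ln_bf=ln_bf)


def posterior_probability(ln_bf: float | np.ndarray, prior_odds: float = 1.0) -> float | np.ndarray:
    """Posterior probability of the time-dependent model.

    ``prior_odds`` is P(time-dependent)/P(null) a priori; with equal priors
    the result is BF/(1+BF).  Computed through the logistic function so it
    saturates instead of overflowing for |ln BF| up to at least 1e4.
    """
    if prior_odds <= 0:
        raise ValueError(f"prior_odds must be > 0, got {prior_odds!r}")
    out = expit(np.asarray(ln_bf, dtype=float) + np.log(prior_odds))
    return float(out) if np.ndim(ln_bf) == 0 else out


def _result_row(rank: int, r: GPTestResult, prior_odds: float) -> dict:
    pd_, pn = r.fit_dep.params, r.fit_null.params
    return {
        "rank": rank,
        "id": r.id,
        "ln_bf": r.ln_bf,
        "posterior_prob": posterior_probability(r.ln_bf, prior_odds),
        "lengthscale": pd_.lengthscale,
        "signal_variance": pd_.signal_variance,
        "noise_variance_dep": pd_.noise_variance,
        "noise_variance_null": pn.noise_variance,
        "lml_dep": r.fit_dep.log_marginal_likelihood,
        "lml_null": r.fit_null.log_marginal_likelihood,
        "converged_dep": bool(r.fit_dep.diagnostics.get("converged", False)),
        "converged_null": bool(r.fit_null.diagnostics.get("converged", False)),
    }


def rank_elements(
    results: list[GPTestResult],
    threshold: float | None = None,
    prior_odds: float = 1.0,
) -> pd.DataFrame:
    """Order test results by ln BF (descending; ties broken by id).

    Returns a DataFrame with 1-based contiguous ranks; when ``threshold`` is
    given, a boolean ``pass`` column marks ln BF strictly above it.
    """
    if not results:
        raise ValueError("results must be non-empty")
    ids = [r.id for r in results]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate element ids: {dup}")
    ordered = sorted(results, key=lambda r: (-r.ln_bf, r.id))
    table = pd.DataFrame(
        [_result_row(i + 1, r, prior_odds) for i, r in enumerate(ordered)]
    )
    if threshold is not None:
        table["pass"] = table["ln_bf"] > threshold
    return table


def run_collection(
    Y: np.ndarray,
    V: np.ndarray,
    times: np.ndarray,
    ids: list[str] | None = None,
    threshold: float | None = DEFAULT_THRESHOLD,
    options: FitOptions | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the GP test row-wise to an m x n collection.

    Thin wrapper over :class:`dynagp.estimators.BayesFactorRanker`.
    Returns ``(rank_table, rejects)``; rows whose fits fail are reported in
    ``rejects`` with their error reason, never silently dropped.
    """
    from .estimators import BayesFactorRanker

    opts = options or FitOptions()
    ranker = BayesFactorRanker(
        threshold=threshold,
        noise_bound=opts.noise_bound,
        n_restarts=opts.n_restarts,
        max_iter=opts.max_iter,
        gtol=opts.gtol,
    )
    ranker.fit(Y, V=V, times=times, ids=ids)
    return ranker.ranking_, ranker.rejects_


def precision_at_k(ranked_ids: list[str], true_ids: set[str], k: int) -> float:
    """Fraction of truly dynamic elements among the top-k ranked ids."""
    if k <= 0:
        raise ValueError("k must be positive")
    top = ranked_ids[:k]
    return sum(1 for i in top if i in true_ids) / len(top)
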