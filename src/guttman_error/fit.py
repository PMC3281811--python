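"""Item-level fit statistics: the mixture index of fit, its standard error,
the dissimilarity index, and error-free/not classification.

For the deterministic Guttman family the mixture index of fit (pi*) — the
smallest proportion of the population that must be set aside so the rest is
consistent with the model — reduces to the observed proportion of forbidden
patterns.  An LP formulation of the same quantity is kept as an independent
oracle.  The dissimilarity index compares observed pattern frequencies with
those expected under the fitted restricted latent class model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import linprog
from sklearn.base import BaseEstimator

from .ingest import EmptyTableError, PatternTable
from .lcm import ProctorScalingModel, tabulate_matrix

__all__ = [
    "LCMEstimate",
    "FitResult",
    "FitFlags",
    "pi_star",
    "pi_star_oracle_lp",
    "pi_star_se",
    "fit_restricted_lcm",
    "dissimilarity_index",
    "classify_item_fit",
    "fit_item",
    "GuttmanItemAnalyzer",
    "DEFAULT_PI_CUTOFF",
    "DEFAULT_DI_CUTOFF",
]

#: Conventional rule-of-thumb cutoffs: under 10% removable mass for pi*,
#: under 5% reallocated mass for the dissimilarity index.
DEFAULT_PI_CUTOFF = 0.10
DEFAULT_DI_CUTOFF = 0.05


@dataclass(frozen=True, eq=False)
class LCMEstimate:
    """Fitted restricted latent class model for one pattern table."""

    class_weights: np.ndarray
    error_rate: Union[float, np.ndarray]
    log_likelihood: float
    expected_probs: np.ndarray
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    message: str = ""


@dataclass(frozen=True)
class FitFlags:
    """Classification of one item against the fit cutoffs.

    ``fits_di`` is ``None`` (indeterminate) when no dissimilarity index could
    be computed.
    """

    fits_pi: bool
    fits_di: Optional[bool]


@dataclass(frozen=True, eq=False)
class FitResult:
    """Everything measured for one item in one cohort."""

    item: str
    cohort: str
    N: int
    pi_star: float
    pi_star_se: float
    di: Optional[float]
    di_converged: bool
    lcm: Optional[LCMEstimate]
    fits_pi: Optional[bool] = None
    fits_di: Optional[bool] = None
    em_iterations: Optional[int] = None


def pi_star(table: PatternTable) -> float:
    """Mixture index of fit of the Guttman model: the proportion of
    complete-case subjects showing a forbidden (non-monotone) pattern."""
    if table.N < 1:
        raise EmptyTableError(f"item {table.item!r}: empty pattern table")
    return table.forbidden_count / table.N


def pi_star_oracle_lp(table: PatternTable) -> float:
    """Independent linear-programming computation of the mixture index.

    Maximizes the retainable mass q(y) <= p_obs(y) supported on permitted
    patterns and returns 1 minus the optimum.  Agrees with :func:`pi_star`
    to numerical tolerance; kept as a cross-check, not a fast path.
    """
    if table.N < 1:
        raise EmptyTableError(f"item {table.item!r}: empty pattern table")
    p = table.proportions
    mask = table.pattern_set.permitted_mask
    upper = p[mask]
    k = upper.shape[0]
    res = linprog(
        c=-np.ones(k),
        A_ub=np.ones((1, k)),
        b_ub=[1.0],
        bounds=list(zip(np.zeros(k), upper)),
        method="highs",
    )
    if not res.success:  # pragma: no cover - trivial LP always solvable
        raise RuntimeError(f"LP oracle failed: {res.message}")
    return 1.0 + res.fun


def pi_star_se(p: float, N: int) -> float:
    """Binomial standard error sqrt(p(1-p)/N) of the forbidden-pattern
    proportion."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {p}")
    if N < 1:
        raise ValueError(f"sample size must be >= 1, got {N}")
    return math.sqrt(p * (1.0 - p) / N)


def fit_restricted_lcm(
    table: PatternTable,
    error_model: str = "proctor",
    tol: float = 1e-8,
    max_iter: int = 5000,
    init_error_rate: float = 0.1,
) -> LCMEstimate:
    """Fit the permitted-pattern latent class model to a table by EM.

    A single-pattern table yields a non-converged estimate rather than an
    exception, mirroring how such items are reported in practice.
    """
    model = ProctorScalingModel(
        error_model=error_model, tol=tol, max_iter=max_iter, init_error_rate=init_error_rate
    ).fit_counts(table.counts, table.T)
    return LCMEstimate(
        class_weights=model.weights_,
        error_rate=model.error_rate_,
        log_likelihood=model.log_likelihood_,
        expected_probs=model.expected_probs_,
        n_iter=model.n_iter_,
        converged=model.converged_,
        loglik_trace=model.loglik_trace_,
        message=model.convergence_message_,
    )


def dissimilarity_index(table: PatternTable, lcm: LCMEstimate) -> Optional[float]:
    """Half the summed absolute difference between observed and fitted
    pattern proportions; ``None`` when the latent class fit did not converge.
    """
    if not lcm.converged:
        return None
    return 0.5 * float(np.abs(table.proportions - lcm.expected_probs).sum())


def classify_item_fit(
    result: FitResult,
    pi_cutoff: float = DEFAULT_PI_CUTOFF,
    di_cutoff: float = DEFAULT_DI_CUTOFF,
) -> FitFlags:
    """Strict-inequality classification against the two cutoffs."""
    fits_pi = bool(result.pi_star < pi_cutoff)
    if result.di_converged and result.di is not None:
        fits_di: Optional[bool] = bool(result.di < di_cutoff)
    else:
        fits_di = None
    return FitFlags(fits_pi=fits_pi, fits_di=fits_di)


def fit_item(
    table: PatternTable,
    pi_cutoff: float = DEFAULT_PI_CUTOFF,
    di_cutoff: float = DEFAULT_DI_CUTOFF,
    error_model: str = "proctor",
    **em_options,
) -> FitResult:
    """Full per-item analysis: pi* with SE, the restricted LCM, the
    dissimilarity index, and cutoff classification."""
    p = pi_star(table)
    se = pi_star_se(p, table.N)
    lcm = fit_restricted_lcm(table, error_model=error_model, **em_options)
    di = dissimilarity_index(table, lcm)
    result = FitResult(
        item=table.item,
        cohort=table.cohort,
        N=table.N,
        pi_star=p,
        pi_star_se=se,
        di=di,
        di_converged=lcm.converged,
        lcm=lcm,
        em_iterations=lcm.n_iter,
    )
    flags = classify_item_fit(result, pi_cutoff=pi_cutoff, di_cutoff=di_cutoff)
    return dataclasses.replace(result, fits_pi=flags.fits_pi, fits_di=flags.fits_di)


class GuttmanItemAnalyzer(BaseEstimator):
    """Estimator wrapper around :func:`fit_item` for one item.

    ``fit`` takes an (n_subjects, T) complete-case 0/1 response matrix and
    exposes the fit statistics as attributes, so the analysis composes with
    scikit-learn tooling (cloning, parameter grids).

    Attributes
    ----------
    pi_star_, pi_star_se_ : float
    di_ : float or None
    di_converged_ : bool
    fits_pi_ : bool
    fits_di_ : bool or None
    lcm_ : LCMEstimate
    result_ : FitResult
    n_samples_ : int
    """

    def __init__(
        self,
        pi_cutoff: float = DEFAULT_PI_CUTOFF,
        di_cutoff: float = DEFAULT_DI_CUTOFF,
        error_model: str = "proctor",
        tol: float = 1e-8,
        max_iter: int = 5000,
    ):
        self.pi_cutoff = pi_cutoff
        self.di_cutoff = di_cutoff
        self.error_model = error_model
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        counts, T = tabulate_matrix(X)
        table = PatternTable(item="item", cohort="sample", T=T, counts=counts, N=int(counts.sum()))
        res = fit_item(
            table,
            pi_cutoff=self.pi_cutoff,
            di_cutoff=self.di_cutoff,
            error_model=self.error_model,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.result_ = res
        self.pi_star_ = res.pi_star
        self.pi_star_se_ = res.pi_star_se
        self.di_ = res.di
        self.di_converged_ = res.di_converged
        self.fits_pi_ = res.fits_pi
        self.fits_di_ = res.fits_di
        self.lcm_ = res.lcm
        self.n_samples_ = res.N
        self.n_features_in_ = T
        return self
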