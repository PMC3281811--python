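"""Restricted latent class (scaling) model for longitudinal Guttman data.

The model: each subject belongs to one of ``T + 1`` latent classes, one per
permitted pattern ``s_c`` (intact through visit ``k`` then lost, for
``k = T..0``).  Conditional on class, each visit's observed 0/1 response
independently disagrees with the latent state with a single misclassification
probability ``alpha`` (Proctor-type constant error), so

    P(y) = sum_c  w_c * alpha**d(y, s_c) * (1 - alpha)**(T - d(y, s_c))

with ``d`` the Hamming distance.  A per-visit variant replaces the scalar
``alpha`` by ``alpha_t``.  Parameters are estimated from pattern counts by
EM: posteriors of class membership, then closed-form updates of the class
weights and error rate(s).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin

from .patterns import enumerate_patterns

__all__ = ["ProctorScalingModel", "fit_pattern_counts", "tabulate_matrix"]

_W_FLOOR = 1e-300  # guards log(0) for classes driven to zero weight


def tabulate_matrix(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Count an (n, T) 0/1 response matrix into canonical pattern order.

    Returns ``(counts, T)``.  Rows must be complete (no NaN) and binary.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("X must be a non-empty 2-D array of shape (n_subjects, T)")
    if np.isnan(np.asarray(X, dtype=float)).any():
        raise ValueError("X contains missing entries; supply complete cases only")
    Xi = np.asarray(X, dtype=np.int64)
    if not np.isin(Xi, (0, 1)).all() or not np.array_equal(np.asarray(X, dtype=float), Xi):
        raise ValueError("X entries must be 0 or 1")
    T = Xi.shape[1]
    weights = 1 << np.arange(T - 1, -1, -1)
    codes = Xi @ weights
    counts = np.bincount((2**T - 1) - codes, minlength=2**T)
    return counts.astype(np.int64), T


class ProctorScalingModel(DensityMixin, BaseEstimator):
    """Restricted latent class model with permitted-pattern classes and a
    constant response-error rate.

    Parameters
    ----------
    error_model : {"proctor", "per_visit"}
        "proctor" fits one misclassification rate shared by all visits;
        "per_visit" fits one rate per visit.
    tol : float
        EM stops when the relative log-likelihood change falls below this.
    max_iter : int
        Iteration cap; hitting it marks the fit non-converged.
    init_error_rate : float
        Starting value for the error rate(s); class weights start uniform,
        so the fit is deterministic.
    alpha_floor : float
        Lower clip for the error rate (it may approach, but never reach, 0).

    Attributes
    ----------
    weights_ : ndarray of shape (T + 1,)
        Mixing proportions over the permitted patterns, in decreasing-score
        order (all-1 first, all-0 last).
    error_rate_ : float or ndarray of shape (T,)
        Estimated misclassification probability (per visit if requested).
    expected_probs_ : ndarray of shape (2**T,)
        Fitted probability of every pattern, canonical order.
    log_likelihood_ : float
        Multinomial log-likelihood at the estimate.
    loglik_trace_ : ndarray
        Log-likelihood after each EM iteration (non-decreasing).
    n_iter_ : int
    converged_ : bool
        False when the table has a single distinct pattern, the iteration
        cap was hit, or the error rate collapsed to the floor while
        forbidden patterns were observed (a degenerate boundary solution).
    convergence_message_ : str
    pattern_set_ : GuttmanPatternSet
    """

    def __init__(
        self,
        error_model: str = "proctor",
        tol: float = 1e-8,
        max_iter: int = 5000,
        init_error_rate: float = 0.1,
        alpha_floor: float = 1e-10,
    ):
        self.error_model = error_model
        self.tol = tol
        self.max_iter = max_iter
        self.init_error_rate = init_error_rate
        self.alpha_floor = alpha_floor

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit from an (n_subjects, T) complete-case 0/1 response matrix."""
        counts, T = tabulate_matrix(X)
        return self.fit_counts(counts, T)

    def fit_counts(self, counts, T: int):
        """Fit from pattern counts in canonical order (length ``2**T``)."""
        if self.error_model not in ("proctor", "per_visit"):
            raise ValueError(f"unknown error_model {self.error_model!r}")
        counts = np.asarray(counts, dtype=float)
        ps = enumerate_patterns(int(T))
        if counts.shape != (ps.n_patterns,):
            raise ValueError(f"counts must have length {ps.n_patterns}")
        N = counts.sum()
        if N <= 0:
            raise ValueError("empty pattern table")

        Y = np.asarray(ps.all_patterns)          # (P, T)
        S = np.asarray(ps.permitted)             # (C, T), decreasing score
        mism = Y[:, None, :] != S[None, :, :]    # (P, C, T)
        d = mism.sum(axis=2)                     # (P, C)
        per_visit = self.error_model == "per_visit"

        w = np.full(S.shape[0], 1.0 / S.shape[0])
        alpha = (
            np.full(T, float(self.init_error_rate)) if per_visit else float(self.init_error_rate)
        )

        def log_cond(alpha):
            if per_visit:
                la, l1a = np.log(alpha), np.log1p(-alpha)
                return np.einsum("pct,t->pc", mism, la) + np.einsum("pct,t->pc", ~mism, l1a)
            return d * np.log(alpha) + (T - d) * np.log1p(-alpha)

        trace = []
        ll_prev = -np.inf
        converged = False
        message = ""
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            log_joint = np.log(np.maximum(w, _W_FLOOR))[None, :] + log_cond(alpha)
            log_p = logsumexp(log_joint, axis=1)
            ll = float(counts @ log_p)
            trace.append(ll)
            resp = np.exp(log_joint - log_p[:, None])           # (P, C)
            # M-step (closed form)
            w = (counts @ resp) / N
            if per_visit:
                alpha = np.einsum("p,pc,pct->t", counts, resp, mism) / N
                alpha = np.clip(alpha, self.alpha_floor, 0.5)
            else:
                alpha = float((counts[:, None] * resp * d).sum() / (N * T))
                alpha = float(np.clip(alpha, self.alpha_floor, 0.5))
            if np.isfinite(ll_prev):
                rel = abs(ll - ll_prev) / (abs(ll_prev) + 1e-300)
                if rel < self.tol:
                    converged = True
                    break
            ll_prev = ll

        log_joint = np.log(np.maximum(w, _W_FLOOR))[None, :] + log_cond(alpha)
        log_p = logsumexp(log_joint, axis=1)
        expected = np.exp(log_p)

        if not converged:
            message = f"iteration cap {self.max_iter} reached"
        forbidden_observed = counts[~ps.permitted_mask].sum() > 0
        at_floor = bool(np.min(np.atleast_1d(alpha)) <= self.alpha_floor * 1.001)
        if converged and at_floor and forbidden_observed:
            converged = False
            message = "boundary solution: error rate at zero with forbidden patterns observed"
        if np.count_nonzero(counts) < 2:
            converged = False
            message = "single observed pattern: insufficient variability"

        self.pattern_set_ = ps
        self.n_features_in_ = int(T)
        self.n_samples_ = int(N)
        self.weights_ = w
        self.error_rate_ = alpha
        self.expected_probs_ = expected
        self.log_likelihood_ = float(counts @ log_p)
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.convergence_message_ = message or "converged"
        return self

    # -- inference ----------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise AttributeError("model is not fitted yet; call fit or fit_counts first")

    def _log_cond_fitted(self):
        ps = self.pattern_set_
        Y = np.asarray(ps.all_patterns)
        S = np.asarray(ps.permitted)
        mism = Y[:, None, :] != S[None, :, :]
        a = self.error_rate_
        if self.error_model == "per_visit":
            return np.einsum("pct,t->pc", mism, np.log(a)) + np.einsum(
                "pct,t->pc", ~mism, np.log1p(-a)
            )
        d = mism.sum(axis=2)
        return d * np.log(a) + (self.n_features_in_ - d) * np.log1p(-a)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class responsibilities, one row per subject."""
        self._check_fitted()
        counts, T = tabulate_matrix(X)
        if T != self.n_features_in_:
            raise ValueError(f"X has {T} visits, model was fitted with {self.n_features_in_}")
        log_joint = np.log(np.maximum(self.weights_, _W_FLOOR))[None, :] + self._log_cond_fitted()
        resp = np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])
        idx = self._pattern_indices(X)
        return resp[idx]

    def score_samples(self, X) -> np.ndarray:
        """Per-subject log-probability of the observed pattern."""
        self._check_fitted()
        idx = self._pattern_indices(X)
        return np.log(np.maximum(self.expected_probs_, _W_FLOOR))[idx]

    def score(self, X, y=None) -> float:
        return float(np.mean(self.score_samples(X)))

    def sample(self, n_samples: int, random_state=None) -> np.ndarray:
        """Draw an (n, T) response matrix from the fitted (or preset) model."""
        self._check_fitted()
        rng = np.random.default_rng(random_state)
        S = np.asarray(self.pattern_set_.permitted)
        classes = rng.choice(len(self.weights_), size=n_samples, p=self.weights_)
        latent = S[classes]
        a = np.broadcast_to(np.atleast_1d(self.error_rate_), (self.n_features_in_,))
        flips = rng.random(latent.shape) < a[None, :]
        return np.where(flips, 1 - latent, latent)

    def _pattern_indices(self, X) -> np.ndarray:
        Xi = np.asarray(X, dtype=np.int64)
        T = self.n_features_in_
        weights = 1 << np.arange(T - 1, -1, -1)
        return (2**T - 1) - (Xi @ weights)


def fit_pattern_counts(counts, T: int, **params) -> ProctorScalingModel:
    """Convenience wrapper: fit a :class:`ProctorScalingModel` from counts."""
    return ProctorScalingModel(**params).fit_counts(counts, T)
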