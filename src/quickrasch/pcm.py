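"""Partial credit model (polytomous Rasch) calibration.

The partial credit model (PCM) gives the probability that person *n* with
latent trait ``theta`` answers item *i* in category ``k`` (0-based) as

    P(X_i = k | theta) = exp( sum_{j<=k} (theta - delta_ij) ) /
                         sum_h exp( sum_{j<=h} (theta - delta_ih) )

with the empty sum for ``k = 0`` equal to zero.  The ``delta_ij`` are the
item *step difficulties* (Andrich thresholds): the trait values at which
adjacent categories are equally probable.  The model is estimated by
marginal maximum likelihood with a normal latent-trait prior (mean fixed at
0 for identification, SD estimated or fixed) using an EM algorithm on a
fixed quadrature grid — the same estimation strategy as mirt-style IRT
software, re-implemented here from scratch.

:class:`PartialCreditModel` is a scikit-learn style estimator: ``fit`` takes
a persons x items matrix of 0-based category codes (or a
:class:`~quickrasch.response.ResponseMatrix`), ``transform`` returns the
expected-a-posteriori (EAP) trait estimate and its posterior SD for each
person.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .response import DataError, RecodeMap, ResponseMatrix, apply_recode

__all__ = [
    "PartialCreditModel",
    "category_probs",
    "ThresholdReport",
    "andrich_thresholds",
    "auto_collapse",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    pass


def category_probs(theta, delta) -> np.ndarray:
    """PCM category probabilities for one item.

    Parameters
    ----------
    theta : float or ndarray of shape (q,)
        Latent trait value(s) in logits.
    delta : array-like of shape (m,)
        Step difficulties ``delta_i1 .. delta_im`` (the implicit
        ``delta_i0`` is 0); the item has ``m + 1`` categories.

    Returns
    -------
    ndarray of shape (m + 1,) or (q, m + 1)
        Probabilities over categories 0..m, summing to 1.  Computed with
        log-sum-exp stabilisation.
    """
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    scalar = theta.ndim == 0
    th = np.atleast_1d(theta)[:, None]                      # (q, 1)
    k = np.arange(len(delta) + 1)                           # (m+1,)
    cum_delta = np.concatenate([[0.0], np.cumsum(delta)])   # (m+1,)
    logits = k * th - cum_delta                             # (q, m+1)
    logits -= logsumexp(logits, axis=1, keepdims=True)
    p = np.exp(logits)
    return p[0] if scalar else p


def _coerce(X) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Accept a ResponseMatrix or an integer array of 0-based codes."""
    if isinstance(X, ResponseMatrix):
        return X.values, X.n_categories.copy(), list(X.item_ids)
    arr = np.asarray(X)
    if arr.ndim != 2:
        raise DataError("expected a 2-D persons x items matrix")
    if arr.size == 0:
        raise DataError("empty response matrix")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.round(arr)):
            raise DataError("category codes must be integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0:
        raise DataError("category codes must be 0-based non-negative")
    ncat = arr.max(axis=0) + 1
    items = [f"item{j+1}" for j in range(arr.shape[1])]
    return arr.astype(np.int64), ncat.astype(np.int64), items


class PartialCreditModel(TransformerMixin, BaseEstimator):
    """Partial credit model fitted by marginal maximum likelihood (EM).

    Parameters
    ----------
    n_quadrature : int, default 61
        Number of equally spaced quadrature nodes.
    theta_range : tuple of float, default (-6, 6)
        Span of the quadrature grid in logits.
    estimate_prior_sd : bool, default True
        Estimate the latent-trait prior SD; if False it stays at
        ``prior_sd``.  The prior mean is fixed at 0 for identification.
    prior_sd : float, default 1.0
        Initial (or fixed) prior SD in logits.
    tol : float, default 1e-4
        EM stops when the largest absolute parameter change (step
        difficulties and prior SD) falls below this, in logits.
    max_cycles : int, default 500
        Maximum EM cycles; exceeding it sets ``converged_ = False``.

    Attributes
    ----------
    step_difficulties_ : list of ndarray
        Estimated step-difficulty vector per item (length ``m_i``).
    prior_sd_ : float
        Latent prior SD (estimated or fixed).
    loglik_ : float
        Marginal log-likelihood at the solution.
    loglik_path_ : ndarray
        Marginal log-likelihood after each EM cycle (non-decreasing).
    n_cycles_ : int
    converged_ : bool
    nodes_, log_weights_ : ndarray
        Quadrature grid and (log) normalised prior weights.
    n_categories_ : ndarray
        Categories per item.
    item_ids_ : list of str
    """

    def __init__(self, n_quadrature: int = 61, theta_range: tuple = (-6.0, 6.0),
                 estimate_prior_sd: bool = True, prior_sd: float = 1.0,
                 tol: float = 1e-4, max_cycles: int = 500):
        self.n_quadrature = n_quadrature
        self.theta_range = theta_range
        self.estimate_prior_sd = estimate_prior_sd
        self.prior_sd = prior_sd
        self.tol = tol
        self.max_cycles = max_cycles

    # ------------------------------------------------------------------ #

    @classmethod
    def from_parameters(cls, step_difficulties, prior_sd: float = 1.0,
                        item_ids=None, **kwargs) -> "PartialCreditModel":
        """Build an already-'fitted' model from known parameters.

        Useful for simulation oracles and for evaluating fit statistics at
        generating values.  ``n_estimated_parameters_`` is 0.
        """
        self = cls(estimate_prior_sd=False, prior_sd=prior_sd, **kwargs)
        self.step_difficulties_ = [np.asarray(d, dtype=float) for d in step_difficulties]
        self.prior_sd_ = float(prior_sd)
        self.n_categories_ = np.array([len(d) + 1 for d in self.step_difficulties_])
        self.item_ids_ = (list(item_ids) if item_ids is not None
                          else [f"item{j+1}" for j in range(len(self.step_difficulties_))])
        self.nodes_, self.log_weights_ = self._grid(self.prior_sd_)
        self.loglik_ = np.nan
        self.loglik_path_ = np.array([])
        self.n_cycles_ = 0
        self.converged_ = True
        self.n_estimated_parameters_ = 0
        return self

    def _grid(self, sd: float) -> tuple[np.ndarray, np.ndarray]:
        nodes = np.linspace(*self.theta_range, self.n_quadrature)
        logw = norm.logpdf(nodes, scale=sd)
        return nodes, logw - logsumexp(logw)

    def _log_cat_probs(self, deltas) -> list[np.ndarray]:
        """Per item: (q, m_i+1) log category probabilities on the grid."""
        out = []
        for d in deltas:
            p = category_probs(self.nodes_, d)
            out.append(np.log(p))
        return out

    def _pattern_loglik(self, X, log_probs) -> np.ndarray:
        """(n, q) log-likelihood of each response pattern at each node."""
        n, q = X.shape[0], len(self.nodes_)
        ll = np.zeros((n, q))
        for j in range(X.shape[1]):
            ll += log_probs[j][:, X[:, j]].T
        return ll

    # ------------------------------------------------------------------ #

    def fit(self, X, y=None) -> "PartialCreditModel":
        """Estimate step difficulties (and optionally the prior SD)."""
        vals, ncat, items = _coerce(X)
        for j in range(vals.shape[1]):
            counts = np.bincount(vals[:, j], minlength=ncat[j])
            if np.any(counts == 0):
                empty = np.flatnonzero(counts == 0).tolist()
                raise DataError(
                    f"item {items[j]!r}: categories {empty} never observed; "
                    "collapse/recode these categories before fitting")

        self.n_categories_ = ncat
        self.item_ids_ = items
        sd = float(self.prior_sd)
        deltas = [np.zeros(m - 1) for m in ncat]
        self.nodes_, self.log_weights_ = self._grid(sd)

        loglik_path = []
        prev_ll = -np.inf
        converged = False
        for cycle in range(1, self.max_cycles + 1):
            log_probs = self._log_cat_probs(deltas)
            ll_nq = self._pattern_loglik(vals, log_probs) + self.log_weights_
            ll_n = logsumexp(ll_nq, axis=1)
            loglik = float(ll_n.sum())
            post = np.exp(ll_nq - ll_n[:, None])            # (n, q) E-step

            old = np.concatenate(deltas + [[sd]])
            # M-step: per-item expected-count multinomial fit
            new_deltas = []
            for j in range(vals.shape[1]):
                r = np.zeros((ncat[j], len(self.nodes_)))   # (m+1, q)
                np.add.at(r, vals[:, j], post)
                new_deltas.append(self._mstep_item(r, deltas[j]))
            deltas = new_deltas
            if self.estimate_prior_sd:
                sd = self._mstep_sd(post, sd)
                self.nodes_, self.log_weights_ = self._grid(sd)

            loglik_path.append(loglik)
            change = np.max(np.abs(np.concatenate(deltas + [[sd]]) - old))
            if loglik < prev_ll - 1e-8:
                warnings.warn("marginal log-likelihood decreased during EM",
                              ConvergenceWarning)
            prev_ll = loglik
            if change < self.tol:
                converged = True
                break

        # final log-likelihood at the updated parameters
        log_probs = self._log_cat_probs(deltas)
        ll_nq = self._pattern_loglik(vals, log_probs) + self.log_weights_
        loglik_path.append(float(logsumexp(ll_nq, axis=1).sum()))

        self.step_difficulties_ = deltas
        self.prior_sd_ = sd
        self.loglik_ = loglik_path[-1]
        self.loglik_path_ = np.asarray(loglik_path)
        self.n_cycles_ = cycle
        self.converged_ = converged
        self.n_estimated_parameters_ = int(sum(len(d) for d in deltas)
                                           + (1 if self.estimate_prior_sd else 0))
        if not converged:
            warnings.warn(
                f"EM did not converge in {self.max_cycles} cycles "
                f"(last change {change:.2e})", ConvergenceWarning)
        return self

    def _mstep_item(self, r: np.ndarray, start: np.ndarray) -> np.ndarray:
        """Maximise the expected complete-data log-likelihood for one item.

        ``r[k, q]`` are expected counts of category k at node q.  The
        objective is concave in the cumulative parametrisation; BFGS with
        the analytic gradient converges in a handful of iterations from the
        warm start.
        """
        nodes = self.nodes_
        R = r.sum(axis=0)                                   # (q,)
        C = np.cumsum(r[::-1], axis=0)[::-1][1:]            # (m, q): counts >= j

        def nll_grad(delta):
            p = category_probs(nodes, delta)                # (q, m+1)
            logp = np.log(np.clip(p, 1e-300, None))
            f = -float(np.sum(r.T * logp))
            Q = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]   # P(X>=j), (q, m)
            g = C.sum(axis=1) - (Q * R[:, None]).sum(axis=0)
            return f, g

        res = minimize(nll_grad, start, jac=True, method="BFGS",
                       options={"gtol": 1e-9, "maxiter": 200})
        return res.x

    def _mstep_sd(self, post: np.ndarray, sd: float) -> float:
        """Maximise expected prior log-weight over the prior SD."""
        wq = post.sum(axis=0)                               # (q,)
        nodes = np.linspace(*self.theta_range, self.n_quadrature)

        def neg(log_sd):
            s = np.exp(log_sd)
            logw = norm.logpdf(nodes, scale=s)
            logw = logw - logsumexp(logw)
            return -float(wq @ logw)

        res = minimize_scalar(neg, bounds=(np.log(0.05), np.log(10.0)),
                              method="bounded",
                              options={"xatol": 1e-10})
        return float(np.exp(res.x))

    # ------------------------------------------------------------------ #

    def log_likelihood(self, X) -> float:
        """Marginal log-likelihood of data under the fitted parameters."""
        check_is_fitted(self, "step_difficulties_")
        vals, _, _ = _coerce(X)
        log_probs = self._log_cat_probs(self.step_difficulties_)
        ll_nq = self._pattern_loglik(vals, log_probs) + self.log_weights_
        return float(logsumexp(ll_nq, axis=1).sum())

    def posterior(self, X) -> np.ndarray:
        """(n, q) posterior weights of each person over the grid."""
        check_is_fitted(self, "step_difficulties_")
        vals, _, _ = _coerce(X)
        log_probs = self._log_cat_probs(self.step_difficulties_)
        ll_nq = self._pattern_loglik(vals, log_probs) + self.log_weights_
        return np.exp(ll_nq - logsumexp(ll_nq, axis=1, keepdims=True))

    def eap_scores(self, X) -> pd.DataFrame:
        """Expected-a-posteriori trait estimate and posterior SD per person."""
        post = self.posterior(X)
        eap = post @ self.nodes_
        var = post @ self.nodes_ ** 2 - eap ** 2
        se = np.sqrt(np.clip(var, 1e-12, None))
        return pd.DataFrame({"eap": eap, "se": se})

    def transform(self, X) -> np.ndarray:
        """Columns ``[eap, se]`` (logits) for each person."""
        return self.eap_scores(X).to_numpy()

    def score(self, X, y=None) -> float:
        """Mean per-person marginal log-likelihood (sklearn convention)."""
        vals, _, _ = _coerce(X)
        return self.log_likelihood(X) / vals.shape[0]

    def expected_item_scores(self, theta) -> np.ndarray:
        """(q, n_items) model expected score of each item at each theta."""
        check_is_fitted(self, "step_difficulties_")
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        out = np.empty((len(theta), len(self.step_difficulties_)))
        for j, d in enumerate(self.step_difficulties_):
            p = category_probs(theta, d)
            out[:, j] = p @ np.arange(len(d) + 1)
        return out

    def icc_table(self, n_grid: int = 121) -> pd.DataFrame:
        """Long-format category probability curves on a theta grid.

        Columns: theta, item, category, probability — the content of an
        item-characteristic-curve plot.
        """
        check_is_fitted(self, "step_difficulties_")
        grid = np.linspace(*self.theta_range, n_grid)
        rows = []
        for item, d in zip(self.item_ids_, self.step_difficulties_):
            p = category_probs(grid, d)
            for k in range(p.shape[1]):
                rows.append(pd.DataFrame({
                    "theta": grid, "item": item, "category": k,
                    "probability": p[:, k]}))
        return pd.concat(rows, ignore_index=True)

    def to_dict(self) -> dict:
        check_is_fitted(self, "step_difficulties_")
        return {
            "item_ids": self.item_ids_,
            "step_difficulties": [d.tolist() for d in self.step_difficulties_],
            "prior_sd": self.prior_sd_,
            "loglik": self.loglik_,
            "n_cycles": self.n_cycles_,
            "converged": bool(self.converged_),
            "quadrature": {"n": self.n_quadrature,
                           "range": list(self.theta_range)},
        }


# ---------------------------------------------------------------------- #
# Threshold ordering diagnostics and category collapsing
# ---------------------------------------------------------------------- #

@dataclass
class ThresholdReport:
    """Andrich thresholds per item with disorder/closeness flags.

    For an item with steps ``delta_1..delta_m`` the gap
    ``g_k = delta_{k+1} - delta_k`` is *disordered* when ``g_k <= 0`` and
    *close* when ``0 < g_k < tol``.  Each flagged gap carries a recommended
    merge of the two categories it straddles; the single recommended merge
    per item targets the worst (most negative) gap, ties broken toward the
    most severe categories.
    """

    item_ids: list[str]
    thresholds: list[np.ndarray]
    tol: float
    disordered: list[list[int]] = field(default_factory=list)
    close: list[list[int]] = field(default_factory=list)
    merges: list[tuple[int, int] | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.disordered:
            for d in self.thresholds:
                gaps = np.diff(d)
                dis = np.flatnonzero(gaps <= 0).tolist()
                clo = np.flatnonzero((gaps > 0) & (gaps < self.tol)).tolist()
                self.disordered.append(dis)
                self.close.append(clo)
                flagged = sorted(dis + clo)
                if flagged:
                    worst = max(flagged, key=lambda k: (-gaps[k], k))
                    # gap between steps k+1 and k+2 straddles categories
                    # (k+1, k+2) in 0-based category codes
                    self.merges.append((worst + 1, worst + 2))
                else:
                    self.merges.append(None)

    @property
    def any_flags(self) -> bool:
        return any(m is not None for m in self.merges)

    def n_disordered_items(self) -> int:
        return sum(1 for d in self.disordered if d)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for item, th, dis, clo, mg in zip(self.item_ids, self.thresholds,
                                          self.disordered, self.close,
                                          self.merges):
            rows.append({
                "item": item,
                "thresholds": list(np.round(th, 4)),
                "disordered_gaps": dis,
                "close_gaps": clo,
                "recommended_merge": mg,
            })
        return pd.DataFrame(rows)


def andrich_thresholds(fit: PartialCreditModel, tol: float = 0.2) -> ThresholdReport:
    """Threshold-ordering report for a fitted PCM.

    The Andrich thresholds are the step difficulties themselves — the trait
    values where adjacent category-probability curves cross.
    """
    check_is_fitted(fit, "step_difficulties_")
    return ThresholdReport(item_ids=list(fit.item_ids_),
                           thresholds=[d.copy() for d in fit.step_difficulties_],
                           tol=float(tol))


def _merge_map(ncat: int, pair: tuple[int, int]) -> list[int]:
    """Recode vector merging categories ``pair`` (adjacent) of an item."""
    lo = pair[0]
    return [k if k <= lo else k - 1 for k in range(ncat)]


def auto_collapse(m: ResponseMatrix, tol: float = 0.2,
                  pcm_kwargs: dict | None = None
                  ) -> tuple[RecodeMap, PartialCreditModel, ThresholdReport]:
    """Iteratively merge categories until thresholds are ordered.

    Each iteration fits the PCM, flags disordered or close thresholds, and
    merges the single category pair straddling the globally worst gap; it
    stops when no flags remain or items run out of mergeable categories
    (every item floor is 2 categories).

    Returns the cumulative :class:`RecodeMap` (relative to the input
    categories), the final fit and the final threshold report.
    """
    pcm_kwargs = pcm_kwargs or {}
    cumulative = RecodeMap.identity(m)
    current = m
    budget = {item: int(nc) - 2 for item, nc in zip(m.item_ids, m.n_categories)}
    while True:
        fit = PartialCreditModel(**pcm_kwargs).fit(current)
        report = andrich_thresholds(fit, tol=tol)
        candidates = []
        for j, (item, mg) in enumerate(zip(report.item_ids, report.merges)):
            if mg is None or budget[item] <= 0:
                continue
            gaps = np.diff(report.thresholds[j])
            candidates.append((gaps[mg[0] - 1], -mg[0], j, mg))
        if not candidates:
            return cumulative, fit, report
        _, _, j, pair = min(candidates)
        item = report.item_ids[j]
        step = RecodeMap.identity(current)
        step.maps[item] = _merge_map(int(current.n_categories[j]), pair)
        current = apply_recode(current, step)
        cumulative = cumulative.compose(step)
        budget[item] -= 1
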