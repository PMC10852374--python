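"""Item- and scale-level fit assessment for a fitted partial credit model.

Covers the usual Rasch quality-control battery for patient-reported
outcome scales:

- standardized person-item residuals at the EAP trait estimate, the
  substrate for infit/outfit and Yen's Q3;
- infit/outfit mean squares with the (0.5, 1.7) acceptance band;
- a sum-score-based item chi-square (Orlando–Thissen style S-X2): observed
  vs model-expected category frequencies conditional on the rest score,
  with sparse-cell pooling;
- Yen's Q3 residual correlations for local dependence (flag > 0.2);
- Cronbach's alpha (acceptable in (0.7, 0.95));
- limited-information scale-level fit: a quadratic-form chi-square on
  univariate and bivariate margin residuals plus CFI, TLI, RMSEA and SRMR
  with the conventional cutoffs (CFI/TLI >= 0.950, RMSEA < 0.060,
  SRMR <= 0.080);
- smoothed empirical option curves against the model curves, and an
  item-person targeting summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crosswalk import lord_wingersky
from .pcm import PartialCreditModel, category_probs
from .response import ResponseMatrix

__all__ = [
    "ItemFitResult",
    "LDResult",
    "ScaleFitResult",
    "standardized_residuals",
    "infit_outfit",
    "item_chisq",
    "q3_matrix",
    "cronbach_alpha",
    "scale_fit_indices",
    "empirical_option_curves",
    "item_person_map",
    "MEANSQ_BAND",
    "Q3_CUTOFF",
]

MEANSQ_BAND = (0.5, 1.7)
Q3_CUTOFF = 0.2


def _vals(m) -> np.ndarray:
    return m.values if isinstance(m, ResponseMatrix) else np.asarray(m, dtype=np.int64)


def _expected_and_var(fit: PartialCreditModel, theta: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Model mean and variance of each item score at each person's theta."""
    E = np.empty((len(theta), len(fit.step_difficulties_)))
    W = np.empty_like(E)
    for j, d in enumerate(fit.step_difficulties_):
        p = category_probs(theta, d)
        k = np.arange(p.shape[1])
        E[:, j] = p @ k
        W[:, j] = p @ k**2 - E[:, j] ** 2
    return E, W


def _predictive_moments(fit: PartialCreditModel, X: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Item-rest predictive mean and variance of each response.

    For item i the person's posterior is formed from the *other* items
    only, so the response being judged does not inform the trait estimate
    it is compared against.  Given the rest responses, x_ni then has
    predictive mean E and variance W exactly, which keeps the mean-square
    statistics centred at 1 under the model.
    """
    E = np.empty(X.shape, dtype=float)
    W = np.empty_like(E)
    for j, d, post in _rest_posteriors(fit, X):
        p = category_probs(fit.nodes_, d)
        k = np.arange(len(d) + 1)
        E[:, j] = post @ (p @ k)
        W[:, j] = post @ (p @ k**2) - E[:, j] ** 2
    return E, W


def _rest_posteriors(fit: PartialCreditModel, X: np.ndarray):
    """Yield (item index, step difficulties, (n, q) posterior built from
    the other items) for each item in turn."""
    nodes, logw = fit.nodes_, fit.log_weights_
    log_probs = [np.log(category_probs(nodes, d)) for d in fit.step_difficulties_]
    ll_full = np.zeros((X.shape[0], len(nodes)))
    for j in range(X.shape[1]):
        ll_full += log_probs[j][:, X[:, j]].T
    for j, d in enumerate(fit.step_difficulties_):
        ll_rest = ll_full - log_probs[j][:, X[:, j]].T + logw
        post = np.exp(ll_rest - ll_rest.max(axis=1, keepdims=True))
        post /= post.sum(axis=1, keepdims=True)
        yield j, d, post


def _residual_moments(fit: PartialCreditModel, X: np.ndarray, scores,
                      method: str) -> tuple[np.ndarray, np.ndarray]:
    if method == "predictive":
        return _predictive_moments(fit, X)
    if method != "plugin":
        raise ValueError(f"unknown residual method {method!r}")
    if scores is None:
        scores = fit.eap_scores(X)
    return _expected_and_var(fit, np.asarray(scores["eap"]))


def standardized_residuals(fit: PartialCreditModel, m, scores=None,
                           method: str = "predictive") -> np.ndarray:
    """Person x item standardized residuals z = (x - E) / sqrt(W).

    ``method="predictive"`` (default) takes E and W as the item-rest
    predictive moments (the person's posterior built from the remaining
    items), which keeps z centred with unit variance under the model;
    ``method="plugin"`` evaluates the model mean and variance at the EAP
    trait estimate (``scores``), the construction used by classical Rasch
    software, whose mean squares sit below 1 on short scales because the
    trait estimate adapts to the response it is judged against.
    Degenerate entries with model variance ~0 become NaN with a warning.
    """
    X = _vals(m)
    E, W = _residual_moments(fit, X, scores, method)
    tiny = W < 1e-10
    if np.any(tiny):
        warnings.warn(f"{int(tiny.sum())} residual(s) dropped: model variance ~ 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (X - E) / np.sqrt(np.where(tiny, np.nan, W))
    return z


# --------------------------------------------------------------------- #
# Item fit
# --------------------------------------------------------------------- #

@dataclass
class ItemFitResult:
    item_ids: list[str]
    outfit: np.ndarray
    infit: np.ndarray
    chisq: np.ndarray = None        # type: ignore[assignment]
    df: np.ndarray = None           # type: ignore[assignment]
    p_value: np.ndarray = None      # type: ignore[assignment]
    band: tuple = MEANSQ_BAND

    def __post_init__(self) -> None:
        k = len(self.item_ids)
        for name in ("chisq", "df", "p_value"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(k, np.nan))

    @property
    def flagged(self) -> list[str]:
        lo, hi = self.band
        return [it for it, o, i in zip(self.item_ids, self.outfit, self.infit)
                if not (lo < o < hi) or not (lo < i < hi)]

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.band
        return pd.DataFrame({
            "item": self.item_ids,
            "outfit": self.outfit,
            "infit": self.infit,
            "chisq": self.chisq,
            "df": self.df,
            "p_value": self.p_value,
            "meansq_ok": [(lo < o < hi) and (lo < i < hi)
                          for o, i in zip(self.outfit, self.infit)],
        })


def infit_outfit(fit: PartialCreditModel, m, scores=None,
                 method: str = "predictive") -> ItemFitResult:
    """Outfit (unweighted) and infit (information-weighted) mean squares.

    outfit_i = mean_n z_ni^2 ; infit_i = sum_n (x_ni - E_ni)^2 / sum_n W_ni,
    with E and W per :func:`standardized_residuals`.  Values outside
    (0.5, 1.7) are flagged.
    """
    X = _vals(m)
    E, W = _residual_moments(fit, X, scores, method)
    sq = (X - E) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        z2 = sq / W
    outfit = np.nanmean(z2, axis=0)
    infit = sq.sum(axis=0) / W.sum(axis=0)
    return ItemFitResult(list(fit.item_ids_), outfit, infit)


def _pool_sparse(obs: np.ndarray, exp: np.ndarray, min_expected: float = 5.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pool adjacent category cells of one rest-score row until all expected
    counts reach ``min_expected``; returns pooled (obs, exp)."""
    o, e = list(obs.astype(float)), list(exp.astype(float))
    while len(e) > 1 and min(e) < min_expected:
        i = int(np.argmin(e))
        j = i + 1 if i + 1 < len(e) else i - 1
        o[j] += o[i]
        e[j] += e[i]
        del o[i], e[i]
    return np.asarray(o), np.asarray(e)


def item_chisq(fit: PartialCreditModel, m, min_expected: float = 5.0) -> ItemFitResult:
    """Sum-score-based item chi-square (Orlando–Thissen style).

    For each item, persons are grouped by their *rest score* (total minus
    the item).  The model-expected category distribution at each rest score
    comes from the Lord–Wingersky distribution of the remaining items,
    integrated over the latent prior.  Adjacent sparse cells (expected <
    ``min_expected``) are pooled within each rest-score row; rows reduced
    to one cell are dropped.  Degrees of freedom: sum over rows of
    (cells - 1), minus the item's estimated step parameters when the model
    was fitted to data.
    """
    X = _vals(m)
    nodes, w = fit.nodes_, np.exp(fit.log_weights_)
    deltas = fit.step_difficulties_
    n_items = len(deltas)
    mean_sq = infit_outfit(fit, m)
    chisq = np.full(n_items, np.nan)
    dfs = np.full(n_items, np.nan)
    pvals = np.full(n_items, np.nan)

    for i in range(n_items):
        others = [d for j, d in enumerate(deltas) if j != i]
        S_rest = lord_wingersky(others, nodes)          # (q, R+1)
        P_i = category_probs(nodes, deltas[i])          # (q, m+1)
        # joint[r, k] = P(rest = r, X_i = k) under the prior
        joint = np.einsum("q,qr,qk->rk", w, S_rest, P_i)
        rest = X.sum(axis=1) - X[:, i]
        m_i = P_i.shape[1]
        stat, df = 0.0, 0
        for r in np.unique(rest):
            sel = rest == r
            n_r = int(sel.sum())
            cond = joint[r] / joint[r].sum()
            obs = np.bincount(X[sel, i], minlength=m_i).astype(float)
            exp = n_r * cond
            obs_p, exp_p = _pool_sparse(obs, exp, min_expected)
            if len(exp_p) < 2:
                continue
            stat += float(np.sum((obs_p - exp_p) ** 2 / exp_p))
            df += len(exp_p) - 1
        if fit.n_estimated_parameters_ > 0:
            df -= m_i - 1
        if df >= 1:
            chisq[i] = stat
            dfs[i] = df
            pvals[i] = stats.chi2.sf(stat, df)
        else:
            warnings.warn(f"item {fit.item_ids_[i]!r}: too few cells after "
                          "pooling; chi-square undefined")
    return ItemFitResult(list(fit.item_ids_), mean_sq.outfit, mean_sq.infit,
                         chisq, dfs, pvals)


# --------------------------------------------------------------------- #
# Local dependence
# --------------------------------------------------------------------- #

@dataclass
class LDResult:
    item_ids: list[str]
    Q3: np.ndarray
    cutoff: float = Q3_CUTOFF

    @property
    def flagged_pairs(self) -> list[tuple[str, str]]:
        out = []
        k = len(self.item_ids)
        for i in range(k):
            for j in range(i + 1, k):
                if self.Q3[i, j] > self.cutoff:
                    out.append((self.item_ids[i], self.item_ids[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Q3, index=self.item_ids, columns=self.item_ids)


def q3_matrix(residuals: np.ndarray, item_ids=None, cutoff: float = Q3_CUTOFF) -> LDResult:
    """Yen's Q3: Pearson correlations of item residual columns.

    Pairs with Q3 above the cutoff (default 0.2) indicate local dependence.
    """
    z = np.asarray(residuals, dtype=float)
    if item_ids is None:
        item_ids = [f"item{j+1}" for j in range(z.shape[1])]
    mask = ~np.isnan(z).any(axis=1)
    Q3 = np.corrcoef(z[mask].T)
    np.fill_diagonal(Q3, np.nan)
    return LDResult(list(item_ids), Q3, cutoff)


def cronbach_alpha(m) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance).

    Values <= 0.7 suggest poor internal consistency; >= 0.95 can suggest
    item redundancy.
    """
    X = _vals(m)
    k = X.shape[1]
    if k < 2:
        raise ValueError("need at least 2 items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum() / total_var))


# --------------------------------------------------------------------- #
# Scale-level fit
# --------------------------------------------------------------------- #

@dataclass
class ScaleFitResult:
    chisq: float
    df: float
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    alpha: float
    baseline_chisq: float = np.nan
    baseline_df: float = np.nan
    rules: dict = field(default_factory=lambda: {
        "chisq_p": 0.05, "cfi": 0.950, "tli": 0.950,
        "rmsea": 0.060, "srmr": 0.080, "alpha": (0.7, 0.95)})

    def passes(self) -> dict:
        r = self.rules
        return {
            "chisq": bool(self.p_value > r["chisq_p"]),
            "cfi": bool(self.cfi >= r["cfi"]),
            "tli": bool(self.tli >= r["tli"]),
            "rmsea": bool(self.rmsea < r["rmsea"]),
            "srmr": bool(self.srmr <= r["srmr"]),
            "alpha": bool(r["alpha"][0] < self.alpha < r["alpha"][1]),
        }

    def to_dict(self) -> dict:
        d = {k: (None if np.isnan(v) else float(v)) for k, v in [
            ("chisq", self.chisq), ("df", self.df), ("p_value", self.p_value),
            ("cfi", self.cfi), ("tli", self.tli), ("rmsea", self.rmsea),
            ("srmr", self.srmr), ("alpha", self.alpha)]}
        d["passes"] = self.passes()
        return d


def _margin_cells(fit: PartialCreditModel) -> tuple[list, list]:
    """Index layout of the univariate and bivariate free margin cells.

    Category 0 of each item is dropped (probabilities sum to 1), so the
    univariate block has sum(m_i) cells and each pair block m_i * m_j.
    """
    ms = [len(d) for d in fit.step_difficulties_]
    uni = [(i, k) for i, m in enumerate(ms) for k in range(1, m + 1)]
    biv = [(i, k, j, l)
           for i in range(len(ms)) for j in range(i + 1, len(ms))
           for k in range(1, ms[i] + 1) for l in range(1, ms[j] + 1)]
    return uni, biv


def _indicator_matrix(X: np.ndarray, uni: list, biv: list) -> np.ndarray:
    n = X.shape[0]
    U = np.empty((n, len(uni) + len(biv)))
    for c, (i, k) in enumerate(uni):
        U[:, c] = X[:, i] == k
    for c, (i, k, j, l) in enumerate(biv):
        U[:, len(uni) + c] = (X[:, i] == k) & (X[:, j] == l)
    return U


def _model_margins(fit: PartialCreditModel, uni: list, biv: list) -> np.ndarray:
    w = np.exp(fit.log_weights_)
    probs = [category_probs(fit.nodes_, d) for d in fit.step_difficulties_]
    p = np.empty(len(uni) + len(biv))
    for c, (i, k) in enumerate(uni):
        p[c] = w @ probs[i][:, k]
    for c, (i, k, j, l) in enumerate(biv):
        p[len(uni) + c] = w @ (probs[i][:, k] * probs[j][:, l])
    return p


def _quadratic_form(e: np.ndarray, sigma: np.ndarray, n: int,
                    rel_tol: float = 1e-2) -> tuple[float, int]:
    """T = n e' Sigma^+ e via eigen-decomposition with relative truncation.

    Directions with eigenvalues below ``rel_tol`` of the largest are
    poorly estimated from sample-size-limited data and are discarded;
    keeping them inflates the statistic under the model.  Returns the
    statistic and the retained rank (the base degrees of freedom before
    subtracting estimated parameters).
    """
    vals, vecs = np.linalg.eigh(sigma)
    keep = vals > rel_tol * vals.max()
    if not np.any(keep):
        return 0.0, 0
    proj = vecs[:, keep].T @ e
    return float(n * np.sum(proj**2 / vals[keep])), int(keep.sum())


def scale_fit_indices(fit: PartialCreditModel, m) -> ScaleFitResult:
    """Limited-information scale fit: chi-square, CFI, TLI, RMSEA, SRMR, alpha.

    The model chi-square is a quadratic form in the univariate and
    bivariate margin residuals (observed minus model-implied cell
    proportions), weighted by the pseudo-inverse of the pooled empirical
    indicator covariance; degrees of freedom are the retained rank minus
    the number of estimated parameters.  The baseline is the independence
    model with observed univariate margins.  RMSEA, CFI and TLI follow
    their standard definitions; SRMR is the root-mean-square difference
    between observed and model-implied inter-item Pearson correlations
    (model moments via quadrature).
    """
    X = _vals(m)
    n = X.shape[0]
    uni, biv = _margin_cells(fit)
    U = _indicator_matrix(X, uni, biv)
    p_obs = U.mean(axis=0)
    sigma = np.cov(U.T, ddof=0)
    p_model = _model_margins(fit, uni, biv)

    T_m, rank = _quadratic_form(p_obs - p_model, sigma, n)
    df_m = max(rank - fit.n_estimated_parameters_, 1)
    p_val = float(stats.chi2.sf(T_m, df_m))

    # baseline: independence with the observed univariate margins
    e_base = np.zeros_like(p_obs)
    nu = len(uni)
    for c, (i, k, j, l) in enumerate(biv):
        pi = p_obs[uni.index((i, k))]
        pj = p_obs[uni.index((j, l))]
        e_base[nu + c] = p_obs[nu + c] - pi * pj
    T_b, rank_b = _quadratic_form(e_base, sigma, n)
    df_b = max(rank_b - nu, 1)

    rmsea = float(np.sqrt(max(0.0, (T_m - df_m) / (df_m * n))))
    denom = max(T_b - df_b, T_m - df_m)
    cfi = 1.0 if denom <= 0 else float(1 - max(0.0, T_m - df_m) / denom)
    base_ratio = T_b / df_b
    tli = 1.0 if base_ratio <= 1 else float(
        min(1.0, (base_ratio - T_m / df_m) / (base_ratio - 1)))

    srmr = _srmr(fit, X)
    alpha = cronbach_alpha(X)
    return ScaleFitResult(T_m, float(df_m), p_val, cfi, tli, rmsea, srmr,
                          alpha, T_b, float(df_b))


def _srmr(fit: PartialCreditModel, X: np.ndarray) -> float:
    """RMS difference of observed vs model-implied inter-item correlations."""
    w = np.exp(fit.log_weights_)
    E = fit.expected_item_scores(fit.nodes_)            # (q, items)
    mu = w @ E
    second = np.empty_like(mu)
    for j, d in enumerate(fit.step_difficulties_):
        p = category_probs(fit.nodes_, d)
        second[j] = w @ (p @ np.arange(p.shape[1]) ** 2)
    var = second - mu**2
    cov_model = (E - mu).T * w @ (E - mu)
    np.fill_diagonal(cov_model, var)
    dd = np.sqrt(np.diag(cov_model))
    corr_model = cov_model / np.outer(dd, dd)
    corr_obs = np.corrcoef(X.T)
    iu = np.triu_indices(X.shape[1], 1)
    return float(np.sqrt(np.mean((corr_obs[iu] - corr_model[iu]) ** 2)))


# --------------------------------------------------------------------- #
# Graphical diagnostics (as data)
# --------------------------------------------------------------------- #

def empirical_option_curves(fit: PartialCreditModel, m, scores=None,
                            n_grid: int = 61, bandwidth: float | None = None
                            ) -> pd.DataFrame:
    """Smoothed observed option proportions against the model curves.

    For each item the option indicators are smoothed by local-linear
    kernel regression (Silverman bandwidth, floor 0.3 logits) against the
    *item-rest* trait estimate — the EAP built from the remaining items,
    so the response being plotted does not shift its own x-coordinate.
    The ``expected`` column applies the identical smoother to the model's
    predictive category probability given the same rest posterior; under
    the model the two curves therefore superimpose apart from sampling
    noise.  The ``model`` column carries the raw ICC on the grid for
    plotting.

    Returns a long frame: item, category, theta, observed, expected, model.
    """
    X = _vals(m)
    if scores is None:
        scores = fit.eap_scores(X)
    theta = np.asarray(scores["eap"])
    sd = theta.std()
    if sd < 1e-9:
        raise ValueError("all trait estimates identical; cannot smooth")
    if bandwidth is None:
        bandwidth = max(0.3, 1.06 * sd * len(theta) ** (-1 / 5))
    grid = np.linspace(theta.min(), theta.max(), n_grid)

    frames = []
    for j, d, post in _rest_posteriors(fit, X):
        item = fit.item_ids_[j]
        p_grid = category_probs(grid, d)
        p_pred = post @ category_probs(fit.nodes_, d)    # (n, m+1)
        theta_rest = post @ fit.nodes_
        for k in range(len(d) + 1):
            y = (X[:, j] == k).astype(float)
            obs = _local_linear(theta_rest, y, grid, bandwidth)
            exp_ = _local_linear(theta_rest, p_pred[:, k], grid, bandwidth)
            frames.append(pd.DataFrame({
                "item": item, "category": k, "theta": grid,
                "observed": np.clip(obs, 0, 1),
                "expected": np.clip(exp_, 0, 1),
                "model": p_grid[:, k]}))
    return pd.concat(frames, ignore_index=True)


def _local_linear(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                  h: float) -> np.ndarray:
    """Gaussian-kernel local-linear regression of y on x at grid points."""
    out = np.empty(len(grid))
    for g_idx, g in enumerate(grid):
        u = (x - g) / h
        w = np.exp(-0.5 * u**2)
        s0, s1, s2 = w.sum(), (w * u).sum(), (w * u**2).sum()
        b0 = (w * y).sum()
        b1 = (w * u * y).sum()
        denom = s0 * s2 - s1**2
        if abs(denom) < 1e-12:
            out[g_idx] = b0 / s0 if s0 > 0 else np.nan
        else:
            out[g_idx] = (s2 * b0 - s1 * b1) / denom
    return out


def item_person_map(fit: PartialCreditModel, scores, n_bins: int = 30) -> dict:
    """Targeting summary comparing the person distribution to the items.

    Returns the person theta-hat histogram, all item threshold locations,
    the person-minus-threshold mean gap, the sample skewness of theta-hat
    and floor/ceiling percentages (persons at the all-best / all-worst
    response pattern's trait estimate).
    """
    theta = np.asarray(scores["eap"])
    thresholds = np.concatenate(fit.step_difficulties_)
    counts, edges = np.histogram(theta, bins=n_bins)
    ncat = [len(d) + 1 for d in fit.step_difficulties_]
    best = np.zeros((1, len(ncat)), dtype=int)
    worst = np.asarray([[m - 1 for m in ncat]])
    floor_theta = fit.eap_scores(np.vstack([best, worst]))["eap"]
    floor_pct = 100.0 * np.mean(np.abs(theta - floor_theta[0]) < 1e-9)
    ceil_pct = 100.0 * np.mean(np.abs(theta - floor_theta[1]) < 1e-9)
    return {
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
        "thresholds": thresholds.tolist(),
        "person_mean": float(theta.mean()),
        "threshold_mean": float(thresholds.mean()),
        "targeting_gap": float(theta.mean() - thresholds.mean()),
        "skewness": float(stats.skew(theta)) if len(theta) > 2 else np.nan,
        "floor_pct": float(floor_pct),
        "ceiling_pct": float(ceil_pct),
    }
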