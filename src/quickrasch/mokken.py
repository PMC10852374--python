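"""Nonparametric scalability screening via Loevinger's H.

Mokken scale analysis is the pipeline's first gate: before fitting a
parametric Rasch model, the items must show enough common ordering.  For
polytomous items the scalability coefficient of a pair is

    H_ij = cov(X_i, X_j) / cov_max(X_i, X_j)

where ``cov_max`` is the covariance of the comonotonic joint distribution
with the observed marginals — obtained by sorting both margins and pairing
largest with largest (the classical Molenaar–Sijtsma definition).  Item and
scale coefficients are ratios of summed covariances, not means of pairwise
coefficients.  Values above 0.3 are conventionally acceptable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response import ResponseMatrix

__all__ = ["MokkenResult", "pairwise_H", "scale_H"]


@dataclass
class MokkenResult:
    item_ids: list[str]
    H_pair: np.ndarray       # item x item, NaN on the diagonal
    H_item: np.ndarray
    H_scale: float
    threshold: float = 0.3

    @property
    def weak_items(self) -> list[str]:
        return [it for it, h in zip(self.item_ids, self.H_item)
                if not np.isnan(h) and h <= self.threshold]

    @property
    def acceptable(self) -> bool:
        return self.H_scale > self.threshold

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.H_pair, index=self.item_ids, columns=self.item_ids)
        df["H_item"] = self.H_item
        return df


def _cov_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Observed covariance and its comonotonic maximum given both margins."""
    cov = float(np.cov(x, y, ddof=0)[0, 1])
    cov_max = float(np.cov(np.sort(x), np.sort(y), ddof=0)[0, 1])
    return cov, cov_max


def _values(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, ResponseMatrix):
        return m.values, list(m.item_ids)
    arr = np.asarray(m)
    return arr, [f"item{j+1}" for j in range(arr.shape[1])]


def pairwise_H(m, i: int, j: int) -> float:
    """Loevinger H for one item pair (indices into the matrix columns).

    Returns NaN with a warning when either item has zero variance.
    """
    vals, _ = _values(m)
    x, y = vals[:, i], vals[:, j]
    cov, cov_max = _cov_pair(x, y)
    if cov_max <= 0:
        warnings.warn(f"zero-variance item in pair ({i}, {j}); H undefined")
        return np.nan
    return cov / cov_max


def scale_H(m, threshold: float = 0.3) -> MokkenResult:
    """Item and scale scalability coefficients for a full response matrix."""
    vals, items = _values(m)
    k = vals.shape[1]
    if k < 2:
        raise ValueError("need at least 2 items")
    cov = np.zeros((k, k))
    cov_max = np.zeros((k, k))
    degenerate = [bool(np.all(vals[:, j] == vals[0, j])) for j in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            c, cm = _cov_pair(vals[:, i], vals[:, j])
            cov[i, j] = cov[j, i] = c
            cov_max[i, j] = cov_max[j, i] = cm
    if any(degenerate):
        warnings.warn(f"zero-variance item(s) at {np.flatnonzero(degenerate).tolist()}; "
                      "their coefficients are undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        H_pair = np.where(cov_max > 0, cov / np.where(cov_max > 0, cov_max, 1.0), np.nan)
    np.fill_diagonal(H_pair, np.nan)
    H_item = np.full(k, np.nan)
    for i in range(k):
        denom = cov_max[i].sum()
        if denom > 0:
            H_item[i] = cov[i].sum() / denom
    iu = np.triu_indices(k, 1)
    denom = cov_max[iu].sum()
    H_scale = cov[iu].sum() / denom if denom > 0 else np.nan
    return MokkenResult(items, H_pair, H_item, float(H_scale), threshold)
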