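"""Raw-sum to interval-score conversion tables (sum-score EAP crosswalk).

Under the partial credit model the raw sum score is a sufficient statistic
for the latent trait, so every raw sum maps to a single posterior-mean
(EAP) trait value.  The conditional distribution of the sum at a given
trait value is computed with the Lord–Wingersky recursion; the EAP per sum
follows by quadrature over the latent prior.  EAP values are rescaled
linearly so the minimum attainable sum maps to 0 and the maximum to 100,
then rounded half-up to integers — the shape of the published conversion
tables.

The four published QuickDASH tables (CTS / Dupuytren x tasks / symptoms)
ship as packaged reference data, loadable via :func:`load_paper_tables`.
Condition-specific tables are never interchangeable: lookups check the
condition and subscale labels.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pcm import PartialCreditModel, category_probs
from .response import DUPUYTREN_SYMPTOMS_WARNING, DataError

__all__ = [
    "ConversionTable",
    "lord_wingersky",
    "sum_score_distribution",
    "build_crosswalk",
    "apply_conversion",
    "load_paper_tables",
]


@dataclass
class ConversionTable:
    """Raw questionnaire sum -> (EAP trait, rescaled 0-100 score).

    ``theta_eap`` is NaN for tables transcribed from the publication
    (``provenance == "paper"``), which print only the rescaled scores.
    """

    condition: str
    subscale: str
    raw_scores: np.ndarray
    rasch_scores: np.ndarray
    theta_eap: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        self.raw_scores = np.asarray(self.raw_scores, dtype=np.int64)
        self.rasch_scores = np.asarray(self.rasch_scores, dtype=np.int64)
        if self.theta_eap is None:
            self.theta_eap = np.full(len(self.raw_scores), np.nan)
        self.theta_eap = np.asarray(self.theta_eap, dtype=float)
        if not np.array_equal(np.diff(self.raw_scores), np.ones(len(self.raw_scores) - 1)):
            raise DataError("raw scores must be contiguous integers")
        if np.any(np.diff(self.rasch_scores) <= 0):
            raise DataError("rescaled scores must be strictly increasing")
        if self.rasch_scores[0] != 0 or self.rasch_scores[-1] != 100:
            raise DataError("table endpoints must be 0 and 100")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "raw_score": self.raw_scores,
            "theta_eap": self.theta_eap,
            "rasch_score": self.rasch_scores,
        })

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# condition={self.condition} subscale={self.subscale} "
                     f"provenance={self.provenance}\n")
            self.to_frame().to_csv(fh, index=False)


def lord_wingersky(deltas, theta) -> np.ndarray:
    """Sum-score distribution by the Lord–Wingersky recursion.

    Starts from the first item's category probabilities and folds in each
    further item by shifted multiplication.  ``deltas`` is a sequence of
    step-difficulty vectors; ``theta`` may be scalar or an array of trait
    values.  Returns shape ``(max_sum + 1,)`` or ``(len(theta), max_sum + 1)``;
    rows sum to 1.
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    th = np.atleast_1d(theta)
    dist = np.ones((len(th), 1))
    for d in deltas:
        p = category_probs(th, np.asarray(d, dtype=float))  # (q, m+1)
        m = p.shape[1] - 1
        new = np.zeros((len(th), dist.shape[1] + m))
        for k in range(m + 1):
            new[:, k:k + dist.shape[1]] += dist * p[:, [k]]
        dist = new
    return dist[0] if scalar else dist


def sum_score_distribution(fit: PartialCreditModel, theta) -> np.ndarray:
    """Distribution of the internal raw sum at trait value(s) ``theta``
    under a fitted model (see :func:`lord_wingersky`)."""
    return lord_wingersky(fit.step_difficulties_, theta)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def sum_score_eap(fit: PartialCreditModel) -> np.ndarray:
    """EAP trait estimate for every attainable internal sum score."""
    nodes, logw = fit.nodes_, fit.log_weights_
    dist = sum_score_distribution(fit, nodes)           # (q, S+1)
    w = np.exp(logw)
    joint = dist * w[:, None]                           # (q, S+1)
    marg = joint.sum(axis=0)
    return (joint * nodes[:, None]).sum(axis=0) / marg


def build_crosswalk(fit: PartialCreditModel, condition: str = "",
                    subscale: str = "") -> ConversionTable:
    """Sum-score EAP crosswalk on the 0-100 scale for a fitted model.

    The raw-score column is the modified *questionnaire* sum (post-recode):
    internal sum + number of items.
    """
    eap = sum_score_eap(fit)
    if len(eap) < 2:
        raise DataError("degenerate scale: a single attainable sum score")
    scaled = 100.0 * (eap - eap[0]) / (eap[-1] - eap[0])
    n_items = len(fit.step_difficulties_)
    raw = np.arange(len(eap)) + n_items
    return ConversionTable(condition=condition, subscale=subscale,
                           raw_scores=raw, rasch_scores=_round_half_up(scaled),
                           theta_eap=eap, provenance="fitted")


def apply_conversion(raw_scores, table: ConversionTable,
                     condition: str | None = None,
                     subscale: str | None = None) -> np.ndarray:
    """Exact lookup of raw questionnaire sums in a conversion table.

    Passing ``condition``/``subscale`` asserts the table matches — the
    condition-specific scores are not interchangeable.
    """
    if condition is not None and condition != table.condition:
        raise DataError(f"table is for condition {table.condition!r}, "
                        f"not {condition!r}; tables are not interchangeable")
    if subscale is not None and subscale != table.subscale:
        raise DataError(f"table is for subscale {table.subscale!r}, not {subscale!r}")
    raw = np.atleast_1d(np.asarray(raw_scores, dtype=np.int64))
    lo, hi = table.raw_scores[0], table.raw_scores[-1]
    bad = (raw < lo) | (raw > hi)
    if np.any(bad):
        raise DataError(f"raw score(s) {sorted(set(raw[bad].tolist()))} outside "
                        f"the attainable range {lo}..{hi}")
    out = table.rasch_scores[raw - lo]
    return out if np.ndim(raw_scores) else out[0]


def load_paper_tables() -> dict[tuple[str, str], ConversionTable]:
    """The four published conversion tables, keyed by (condition, subscale).

    The Dupuytren symptoms table loads with a warning: those items are not
    recommended for Dupuytren disease.
    """
    ref = importlib.resources.files("quickrasch") / "data" / "conversion_tables.csv"
    with ref.open() as fh:
        df = pd.read_csv(fh)
    out = {}
    for (cond, sub), grp in df.groupby(["condition", "subscale"], sort=False):
        out[(cond, sub)] = ConversionTable(
            condition=cond, subscale=sub,
            raw_scores=grp["raw_score"].to_numpy(),
            rasch_scores=grp["rasch_score"].to_numpy(),
            provenance="paper")
    warnings.warn(DUPUYTREN_SYMPTOMS_WARNING, UserWarning, stacklevel=2)
    return out
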