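"""Ordinal response matrices and QuickDASH condition-specific recoding.

The QuickDASH items analysed here are answered on a five-point Likert scale
("no difficulty", "mild difficulty", "moderate difficulty", "severe
difficulty", "unable").  Internally every item is coded 0-based with 0 the
best (least difficulty) option; questionnaire-facing I/O uses the familiar
1..5 scores.  Two subscales are supported: the task-based items 1-6 and the
symptoms-based items 9-11.

Category merges are expressed as :class:`RecodeMap` objects — per-item,
order-preserving mappings onto a contiguous set of new codes.  The published
condition-specific scoring rules for Dupuytren disease and carpal tunnel
syndrome (CTS) are provided by :func:`quickdash_recode`.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "RecodeMap",
    "ConfigurationError",
    "DataError",
    "read_responses",
    "write_responses",
    "apply_recode",
    "quickdash_recode",
    "raw_sum",
    "TASK_ITEMS",
    "SYMPTOM_ITEMS",
]

#: Canonical item labels for the two subscales.
TASK_ITEMS = [f"DASH{i}" for i in range(1, 7)]
SYMPTOM_ITEMS = [f"DASH{i}" for i in (9, 10, 11)]

DUPUYTREN_SYMPTOMS_WARNING = (
    "The symptoms-based items 9-11 are not recommended for use in patients "
    "with Dupuytren disease; the recode and conversion are provided for "
    "completeness only."
)


class ConfigurationError(ValueError):
    """Bad user configuration (unknown item, condition or subscale)."""


class DataError(ValueError):
    """Input data violate the format contract (range, emptiness)."""


@dataclass
class ResponseMatrix:
    """Persons x items ordinal category codes.

    Parameters
    ----------
    values : ndarray of shape (n_persons, n_items)
        Integer category codes, 0-based, 0 = best option.
    item_ids : list of str
        Ordered item labels.
    n_categories : ndarray of shape (n_items,)
        Number of scoring categories per item (codes run 0..n_categories-1).
    meta : dict
        Optional tags, e.g. ``{"condition": "cts", "subscale": "tasks"}``.
    """

    values: np.ndarray
    item_ids: list[str]
    n_categories: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if self.values.ndim != 2:
            raise DataError("values must be 2-D (persons x items)")
        if self.values.shape[1] != len(self.item_ids):
            raise DataError("item_ids length does not match values")
        if len(self.n_categories) != len(self.item_ids):
            raise DataError("n_categories length does not match items")
        if np.any(self.n_categories < 2):
            raise DataError("every item needs at least 2 categories")
        if self.values.size and (
            self.values.min() < 0 or np.any(self.values.max(axis=0) > self.n_categories - 1)
        ):
            raise DataError("category codes outside 0..n_categories-1")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def category_counts(self, item: int) -> np.ndarray:
        """Observed frequency of each category of one item."""
        return np.bincount(self.values[:, item], minlength=self.n_categories[item])

    def to_frame(self, coding: str = "questionnaire") -> pd.DataFrame:
        offset = 1 if coding == "questionnaire" else 0
        return pd.DataFrame(self.values + offset, columns=self.item_ids)


@dataclass
class RecodeMap:
    """Per-item order-preserving merge of adjacent categories.

    ``maps[item_id]`` sends old 0-based codes to new 0-based codes; each map
    must be monotone non-decreasing with a contiguous image {0..m'}.
    """

    maps: dict[str, list[int]]

    def __post_init__(self) -> None:
        for item, m in self.maps.items():
            m = list(int(v) for v in m)
            self.maps[item] = m
            if any(b < a for a, b in zip(m, m[1:])):
                raise ConfigurationError(f"recode for {item} is not monotone: {m}")
            if sorted(set(m)) != list(range(max(m) + 1)):
                raise ConfigurationError(f"recode for {item} has gaps: {m}")
            if m[0] != 0:
                raise ConfigurationError(f"recode for {item} must start at 0: {m}")

    def is_identity(self) -> bool:
        return all(m == list(range(len(m))) for m in self.maps.values())

    def n_new_categories(self, item: str) -> int:
        return max(self.maps[item]) + 1

    @classmethod
    def identity(cls, m: "ResponseMatrix") -> "RecodeMap":
        return cls({it: list(range(nc)) for it, nc in zip(m.item_ids, m.n_categories)})

    def compose(self, other: "RecodeMap") -> "RecodeMap":
        """self followed by other (other applied to self's output codes)."""
        out = {}
        for item, m in self.maps.items():
            out[item] = [other.maps[item][v] for v in m]
        return RecodeMap(out)

    def to_json(self) -> str:
        return json.dumps({"maps": self.maps}, indent=2, sort_keys=True)


def read_responses(path, subscale: list[str] | None = None,
                   meta: dict | None = None) -> ResponseMatrix:
    """Read a person x item CSV of questionnaire scores (1..5 Likert codes).

    Rows with a blank or out-of-range cell in any requested item are dropped
    (complete-case analysis); the number dropped is recorded in
    ``meta["n_dropped"]``.

    Parameters
    ----------
    path : str or file-like
        CSV with a header of item ids and integer cells in 1..5 (or blank).
    subscale : list of str, optional
        Item ids to keep, in order.  Default: every column.
    """
    df = pd.read_csv(path)
    if subscale is None:
        subscale = list(df.columns)
    missing = [c for c in subscale if c not in df.columns]
    if missing:
        raise ConfigurationError(f"unknown item id(s): {missing}")
    sub = df[subscale].apply(pd.to_numeric, errors="coerce")
    valid = sub.notna().all(axis=1)
    arr = sub[valid].to_numpy()
    if arr.size and (np.any(arr != np.round(arr)) or arr.min() < 1 or arr.max() > 5):
        bad = arr[(arr < 1) | (arr > 5) | (arr != np.round(arr))]
        raise DataError(f"questionnaire codes must be integers in 1..5; saw {bad[:5]}")
    n_dropped = int((~valid).sum())
    if arr.shape[0] == 0:
        raise DataError("no complete rows for the requested items")
    meta = dict(meta or {})
    meta["n_dropped"] = n_dropped
    values = arr.astype(np.int64) - 1
    n_categories = np.full(len(subscale), 5, dtype=np.int64)
    return ResponseMatrix(values, list(subscale), n_categories, meta)


def write_responses(m: ResponseMatrix, path, sidecar: dict | None = None) -> None:
    """Write questionnaire-coded CSV; optional JSON sidecar next to it."""
    m.to_frame("questionnaire").to_csv(path, index=False)
    if sidecar is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)


def apply_recode(m: ResponseMatrix, r: RecodeMap) -> ResponseMatrix:
    """Apply a category merge, renumbering codes and category counts."""
    not_covered = [it for it in m.item_ids if it not in r.maps]
    if not_covered:
        raise ConfigurationError(f"recode does not cover item(s): {not_covered}")
    new_vals = np.empty_like(m.values)
    new_ncat = np.empty_like(m.n_categories)
    for j, item in enumerate(m.item_ids):
        lut = np.asarray(r.maps[item], dtype=np.int64)
        if len(lut) != m.n_categories[j]:
            raise ConfigurationError(
                f"recode for {item} has {len(lut)} entries, item has "
                f"{m.n_categories[j]} categories")
        new_vals[:, j] = lut[m.values[:, j]]
        new_ncat[j] = len(lut) - (len(lut) - 1 - lut[-1])  # = lut[-1] + 1
    return ResponseMatrix(new_vals, list(m.item_ids), new_ncat, dict(m.meta))


def _item_number(item_id: str, position: int, subscale: str) -> int:
    """Questionnaire item number from an id like 'DASH11'; positional fallback."""
    mo = re.search(r"(\d+)$", item_id)
    if mo:
        return int(mo.group(1))
    base = {"tasks": 1, "symptoms": 9}[subscale]
    return base + position


# Published modified scorings, as 0-based recode vectors of a 5-category item.
_MERGE_WORST = [0, 1, 2, 3, 3]   # "severe difficulty" and "unable" scored equally
_MERGE_BEST = [0, 0, 1, 2, 3]    # "no difficulty" and "mild difficulty" scored equally
_MERGE_BOTH = [0, 0, 1, 2, 2]    # both merges (CTS item 11)


def quickdash_recode(m: ResponseMatrix, condition: str,
                     subscale: str) -> tuple[ResponseMatrix, RecodeMap]:
    """Apply the published condition-specific QuickDASH scoring rules.

    Rules
    -----
    - Dupuytren / tasks: on every item the two worst options ("severe
      difficulty", "unable") are scored equally (questionnaire score 4).
    - CTS / tasks: no modification.
    - CTS / symptoms: items 9 and 10 score "mild difficulty" together with
      "no difficulty" (both 1); item 11 additionally scores "unable"
      together with "severe difficulty" (both 3).
    - Dupuytren / symptoms: the two worst options merge on every item;
      a warning is emitted because these items are not recommended for
      Dupuytren disease.

    Returns the recoded matrix and the :class:`RecodeMap` that was applied.
    """
    condition = condition.lower()
    subscale = subscale.lower()
    if condition not in {"dupuytren", "cts"}:
        raise ConfigurationError(f"unknown condition {condition!r}")
    if subscale not in {"tasks", "symptoms"}:
        raise ConfigurationError(f"unknown subscale {subscale!r}")

    maps: dict[str, list[int]] = {}
    for pos, (item, ncat) in enumerate(zip(m.item_ids, m.n_categories)):
        ident = list(range(int(ncat)))
        if int(ncat) != 5:
            # already-collapsed items pass through unchanged
            maps[item] = ident
            continue
        if condition == "cts" and subscale == "tasks":
            maps[item] = ident
        elif condition == "dupuytren":
            maps[item] = list(_MERGE_WORST)
        else:  # cts / symptoms
            number = _item_number(item, pos, subscale)
            maps[item] = list(_MERGE_BOTH if number == 11 else _MERGE_BEST)

    if condition == "dupuytren" and subscale == "symptoms":
        warnings.warn(DUPUYTREN_SYMPTOMS_WARNING, UserWarning, stacklevel=2)

    recode = RecodeMap(maps)
    out = apply_recode(m, recode)
    out.meta.update(condition=condition, subscale=subscale)
    return out, recode


def raw_sum(m: ResponseMatrix, coding: str = "questionnaire") -> np.ndarray:
    """Per-person ordinal sum score.

    ``questionnaire`` coding sums (code + 1) per item so the minimum possible
    sum equals the item count (e.g. 6 for the task items); ``internal`` sums
    the 0-based codes.
    """
    if coding not in {"questionnaire", "internal"}:
        raise ConfigurationError(f"unknown coding {coding!r}")
    s = m.values.sum(axis=1)
    if coding == "questionnaire":
        s = s + m.n_items
    return s
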