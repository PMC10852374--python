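"""Synthetic PCM response cohorts with controllable targeting, threshold
disorder and local dependence.

The study cohorts behind the published QuickDASH calibrations are not
publicly deposited, so every pipeline stage is exercised on simulated
cohorts instead.  The generator draws a latent trait per person (normal or
negatively-skewed skew-normal), optionally adds a shared testlet component
to induce local dependence between chosen items, and samples each item
response from the partial credit model.  Threshold disorder is injected
simply by specifying reversed adjacent step difficulties — the PCM
generates from them directly.

Named fixtures emulate the four published analyses qualitatively:

- ``cts_tasks``: n = 1851, 6 items x 5 categories, trait N(0, 1), item
  thresholds spanning the trait (well targeted, ordered).
- ``dupuytren_tasks``: n = 731, negatively skewed trait, items sitting
  about a logit above the person mean, and the top two steps reversed on
  every item (the "severe difficulty"/"unable" disorder).
- ``cts_symptoms`` / ``dupuytren_symptoms``: 3-item analogues.

Randomness uses one root seed with independent child streams for trait,
testlet and response draws, so toggling testlets does not perturb the
trait draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import skewnorm

from .pcm import category_probs
from .response import ConfigurationError, ResponseMatrix

__all__ = ["SimSpec", "simulate", "paper_like_fixture", "inject_ld", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("cts_tasks", "dupuytren_tasks", "cts_symptoms", "dupuytren_symptoms")


@dataclass(frozen=True)
class SimSpec:
    """Generating parameters for a synthetic cohort.

    Parameters
    ----------
    n : int
        Number of respondents.
    delta : tuple of tuple of float
        Per-item step-difficulty vectors (logits); an item with ``m`` steps
        has ``m + 1`` categories.
    trait : tuple
        ``("normal", mu, sigma)`` or ``("skewnormal", location, scale,
        shape)``; negative shape gives the negatively skewed cohorts.
    testlets : tuple of (items, gamma)
        Optional groupings; the items of a group share an extra standard
        normal person component scaled by loading ``gamma``.
    seed : int
        Root seed; identical specs reproduce identical data bit-for-bit.
    item_ids : tuple of str, optional
        Labels; default item1..itemK.
    """

    n: int
    delta: tuple
    trait: tuple = ("normal", 0.0, 1.0)
    testlets: tuple = ()
    seed: int = 0
    item_ids: tuple = ()
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        object.__setattr__(self, "delta",
                           tuple(tuple(float(x) for x in d) for d in self.delta))
        if any(len(d) < 1 for d in self.delta):
            raise ConfigurationError("every item needs >= 2 categories")
        kind = self.trait[0]
        if kind not in {"normal", "skewnormal"}:
            raise ConfigurationError(f"unknown trait distribution {kind!r}")
        if self.trait[2] <= 0:
            raise ConfigurationError("trait scale must be positive")
        seen: set[int] = set()
        for items, _ in self.testlets:
            if seen & set(items):
                raise ConfigurationError("overlapping testlets")
            seen |= set(items)
        if not self.item_ids:
            object.__setattr__(self, "item_ids",
                               tuple(f"item{j+1}" for j in range(len(self.delta))))

    @property
    def n_items(self) -> int:
        return len(self.delta)


def _draw_trait(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.trait[0] == "normal":
        _, mu, sigma = spec.trait
        return rng.normal(mu, sigma, spec.n)
    _, loc, scale, shape = spec.trait
    return skewnorm.rvs(shape, loc=loc, scale=scale, size=spec.n, random_state=rng)


def simulate(spec: SimSpec) -> ResponseMatrix:
    """Draw a cohort from the spec; deterministic given the seed."""
    trait_ss, testlet_ss, resp_ss = np.random.SeedSequence(spec.seed).spawn(3)
    theta = _draw_trait(spec, np.random.default_rng(trait_ss))

    # effective trait per item: base theta plus any testlet component
    eff = np.tile(theta[:, None], (1, spec.n_items))
    t_rng = np.random.default_rng(testlet_ss)
    for items, gamma in spec.testlets:
        u = t_rng.standard_normal(spec.n)
        for j in items:
            eff[:, j] = theta + gamma * u

    r_rng = np.random.default_rng(resp_ss)
    values = np.empty((spec.n, spec.n_items), dtype=np.int64)
    for j, d in enumerate(spec.delta):
        p = category_probs(eff[:, j], np.asarray(d))
        u = r_rng.random((spec.n, 1))
        values[:, j] = (p.cumsum(axis=1) < u).sum(axis=1)
    ncat = np.array([len(d) + 1 for d in spec.delta])
    meta = dict(spec.meta)
    meta.setdefault("generator", "pcm-simulation")
    meta["seed"] = spec.seed
    return ResponseMatrix(values, list(spec.item_ids), ncat, meta)


def _ordered_steps(location: float, spread: float = 1.5) -> tuple:
    """Four ordered steps (5 categories) centred on ``location``."""
    return tuple(location + s for s in np.linspace(-spread, spread, 4))


def _disordered_steps(location: float) -> tuple:
    """Five-category item whose top two steps are reversed (the worst two
    response options cover almost no distinct range of the trait).

    ``location`` anchors the hard end of the item: the two top steps sit
    above it while the lower steps reach well down, so the lower tail of a
    skewed cohort is still resolved rather than clumped at the floor.
    """
    return (location - 2.8, location - 1.0, location + 1.2, location + 0.55)


def paper_like_fixture(name: str, seed: int = 0) -> SimSpec:
    """A named cohort spec emulating one of the published analyses."""
    if name not in FIXTURE_NAMES:
        raise ConfigurationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    # Negatively skewed trait for the Dupuytren cohorts: skew-normal with
    # shape -10, rescaled so the trait mean is 0 and the SD ~1.1.
    a, sd = -10.0, 1.1
    d = a / np.hypot(1.0, a)
    scale = sd / np.sqrt(1 - 2 * d * d / np.pi)
    loc = -scale * d * np.sqrt(2 / np.pi)
    skewed = ("skewnormal", float(loc), float(scale), a)

    if name == "cts_tasks":
        delta = tuple(_ordered_steps(c) for c in np.linspace(-1.0, 1.0, 6))
        spec = SimSpec(n=1851, delta=delta, trait=("normal", 0.0, 1.0), seed=seed,
                       item_ids=tuple(f"DASH{i}" for i in range(1, 7)),
                       meta={"condition": "cts", "subscale": "tasks"})
    elif name == "dupuytren_tasks":
        delta = tuple(_disordered_steps(1.0 + c) for c in np.linspace(-0.5, 0.5, 6))
        spec = SimSpec(n=731, delta=delta, trait=skewed, seed=seed,
                       item_ids=tuple(f"DASH{i}" for i in range(1, 7)),
                       meta={"condition": "dupuytren", "subscale": "tasks"})
    elif name == "cts_symptoms":
        delta = tuple(_ordered_steps(c) for c in np.linspace(-0.6, 0.6, 3))
        spec = SimSpec(n=1851, delta=delta, trait=("normal", 0.0, 1.0), seed=seed,
                       item_ids=("DASH9", "DASH10", "DASH11"),
                       meta={"condition": "cts", "subscale": "symptoms"})
    else:  # dupuytren_symptoms
        delta = tuple(_disordered_steps(1.0 + c) for c in np.linspace(-0.3, 0.3, 3))
        spec = SimSpec(n=731, delta=delta, trait=skewed, seed=seed,
                       item_ids=("DASH9", "DASH10", "DASH11"),
                       meta={"condition": "dupuytren", "subscale": "symptoms"})
    return spec


def inject_ld(spec: SimSpec, pair: tuple[int, int], gamma: float) -> SimSpec:
    """Spec with the given item pair sharing a testlet of loading gamma."""
    return replace(spec, testlets=spec.testlets + ((tuple(pair), float(gamma)),))
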