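"""Shared fixtures: small deterministic cohorts and pre-fitted models.

Expensive PCM fits are session-scoped so the whole suite reuses them.
"""

import numpy as np
import pytest

from quickrasch.pcm import PartialCreditModel
from quickrasch.simulate import SimSpec, paper_like_fixture, simulate

# Standard generating conditions for calibration checks: six well-spread
# 5-category items and a standard normal trait.
STANDARD_DELTAS = tuple(
    tuple(np.array([-1.5, -0.5, 0.5, 1.5]) + c) for c in np.linspace(-1, 1, 6)
)


@pytest.fixture(scope="session")
def standard_deltas():
    return [np.asarray(d) for d in STANDARD_DELTAS]


@pytest.fixture(scope="session")
def cts_matrix():
    return simulate(paper_like_fixture("cts_tasks", seed=0))


@pytest.fixture(scope="session")
def cts_fit(cts_matrix):
    return PartialCreditModel().fit(cts_matrix)


@pytest.fixture(scope="session")
def dupuytren_matrix():
    return simulate(paper_like_fixture("dupuytren_tasks", seed=0))


@pytest.fixture(scope="session")
def dupuytren_collapse(dupuytren_matrix):
    """(cumulative RecodeMap, final fit, final ThresholdReport)."""
    from quickrasch.pcm import auto_collapse
    return auto_collapse(dupuytren_matrix)


@pytest.fixture(scope="session")
def calib_matrix():
    """Model-consistent cohort at the calibration size (n = 2000)."""
    return simulate(SimSpec(n=2000, delta=STANDARD_DELTAS, seed=42))


@pytest.fixture(scope="session")
def calib_fit(calib_matrix):
    return PartialCreditModel().fit(calib_matrix)


@pytest.fixture(scope="session")
def toy_fit():
    """Tiny 2-item model with known parameters (no fitting)."""
    return PartialCreditModel.from_parameters(
        [np.array([-0.7, 0.4]), np.array([-0.2, 0.9])], prior_sd=1.0)
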