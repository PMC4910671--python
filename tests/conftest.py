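"""Shared fixtures.

The expensive Monte Carlo fixtures (300-replication condition runs) are
session-scoped so the acceptance-style checks that look at different
outcome columns of the same condition share one simulation pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import validitysim as vs
from validitysim import mc_harness as mh

BASE_SEED = 20160616  # arbitrary fixed base seed for the suite
ACCEPT_REPS = 300

# condition indices in the default 20-cell grid (n-major, categories
# ordered 3, 5, 7, continuous); used as seed-stream components
COND_INDEX = {
    (500, 5): 5,
    (500, "continuous"): 7,
    (750, "continuous"): 11,
    (1000, "continuous"): 15,
}


@pytest.fixture(scope="session")
def params():
    return vs.default_params()


@pytest.fixture(scope="session")
def pop_sigma(params):
    return vs.population_sigma(params)


@pytest.fixture(scope="session")
def spec1():
    return vs.model1_spec()


@pytest.fixture(scope="session")
def spec2():
    return vs.model2_spec()


def model2_fits(n, categories, reps, base_seed=BASE_SEED):
    """Model 2 fits to ``reps`` simulated correlation matrices."""
    params = vs.default_params()
    spec2 = vs.model2_spec()
    cond = mh.ConditionSpec(n=n, categories=categories)
    idx = COND_INDEX[(n, categories)]
    fits = []
    for rep in range(reps):
        r, _, _ = mh._simulate_matrix(cond, params, base_seed, idx, rep)
        fits.append(vs.fit(spec2, r, n))
    return fits


@pytest.fixture(scope="session")
def reps_500_continuous(params):
    """300 full replications (both models) at n=500, continuous."""
    cond = mh.ConditionSpec(n=500, categories="continuous")
    idx = COND_INDEX[(500, "continuous")]
    return [
        mh.run_replication(cond, params, BASE_SEED, idx, rep)
        for rep in range(ACCEPT_REPS)
    ]


@pytest.fixture(scope="session")
def m2_fits_750_continuous():
    return model2_fits(750, "continuous", ACCEPT_REPS)


@pytest.fixture(scope="session")
def m2_fits_1000_continuous():
    return model2_fits(1000, "continuous", ACCEPT_REPS)


@pytest.fixture(scope="session")
def m2_fits_500_cat5():
    return model2_fits(500, 5, ACCEPT_REPS)


def binomial_3se_band(observed_pct: float, reps: int) -> float:
    """Half-width (percentage points) of the 3-SE Wald band around a Monte
    Carlo percentage estimated from ``reps`` replications."""
    p = observed_pct / 100.0
    return 300.0 * np.sqrt(p * (1.0 - p) / reps)
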