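"""Shared fixtures.

The two large Australian-like cohorts (with and without an organised
screening programme, simulated under the same root seed so natural-history
channels are paired) are session-scoped: they back the epidemiological
anchor, the survival-ordering, length-time and channel-gating checks without
re-simulating per test.
"""

import pytest
from hypothesis import HealthCheck, settings

from melanosim import default_parameters, default_policy, simulate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BIG_N = 100_000
BIG_SEED = 12345


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def aus_cohort(default_params):
    """No-programme (opportunistic-only) Australian-like cohort, n = 1e5."""
    return simulate_cohort(default_params, BIG_N, BIG_SEED)


@pytest.fixture(scope="session")
def aus_policy_cohort(default_params):
    """Same cohort under the biennial organised programme (same seed, so
    natural-history channels are paired with ``aus_cohort``)."""
    return simulate_cohort(default_params, BIG_N, BIG_SEED,
                           policy=default_policy("organised_biennial"))
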