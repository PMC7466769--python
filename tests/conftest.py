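"""Shared fixtures.

The closed-loop model is fully deterministic, so expensive artifacts (the
baseline 17-beat run, the k_1 multiplier sweep, the full sensitivity
matrix) are computed once per session and shared.
"""

import warnings

import pytest
from hypothesis import settings

from cardioloop import analytics
from cardioloop.config import ConfigDocument
from cardioloop.engine import run_simulation

settings.register_profile("ci", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_config() -> ConfigDocument:
    return ConfigDocument()


@pytest.fixture(scope="session")
def baseline_tc(base_config):
    """The canonical 17-beat baseline run with 60% volume withdrawal."""
    return run_simulation(base_config)


@pytest.fixture(scope="session")
def baseline_metrics(baseline_tc):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analytics.system_properties(timecourse=baseline_tc)


@pytest.fixture(scope="session")
def no_withdrawal_tc(base_config):
    """A closed-loop run with the withdrawal protocol disabled."""
    cfg = base_config.model_copy(deep=True)
    cfg.protocol.withdrawal_fraction = 0.0
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def k1_sweep(base_config):
    """Full-protocol sweep of k_1 over the 9-point multiplier grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analytics.parameter_sweep(base_config, "k_1")


@pytest.fixture(scope="session")
def sensitivity_matrix_full(base_config):
    """The complete relative-sensitivity matrix (24 parameters x 9
    multipliers; the slow fixture of the suite)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analytics.sensitivity_matrix(base_config)
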