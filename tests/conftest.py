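import warnings

import pytest

from terlake import build_experiment1, detect_ter, run_gradient


def pytest_configure(config):
    # Overflow in exp() inside rejected optimizer trial steps is expected.
    warnings.filterwarnings("ignore", message="overflow encountered in exp")


@pytest.fixture(scope="session")
def exp1_scenarios():
    """The four reference supply scenarios at full resolution, keyed by id."""
    return {s.id: s for s in build_experiment1(n_points=100)}


@pytest.fixture(scope="session")
def exp1_curves(exp1_scenarios):
    """Solved response curves for the four reference scenarios (shared, slow)."""
    return {sid: run_gradient(s) for sid, s in exp1_scenarios.items()}


@pytest.fixture(scope="session")
def exp1_estimates(exp1_curves):
    """Threshold estimates for the four reference curves (no mech switch)."""
    return {sid: detect_ter(c) for sid, c in exp1_curves.items()}
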