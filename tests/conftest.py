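import numpy as np
import pytest

from cardioloop import (ScenarioConfig, load_default_parameters,
                        run_to_steady_state)


@pytest.fixture(scope="session")
def default_params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def battery(default_params):
    """Lazy, cached scenario runner shared by integration/acceptance tests.

    Returns ``get(dd, contractility, pleural, clamp, **kwargs)`` yielding
    ``(Trajectory, HemodynamicSummary, converged)``; each distinct
    configuration is simulated once per session.
    """
    cache = {}

    def get(dd="CONTROL", contractility="normal", pleural="fixed_minus5",
            clamp=None, steady_state_tol=0.005, max_time=None):
        key = (dd, contractility, pleural, clamp, steady_state_tol, max_time)
        if key not in cache:
            duration = 56.0 if pleural == "sinusoid" else 60.0
            sc = ScenarioConfig(dd_type=dd, contractility=contractility,
                                pleural_mode=pleural, clamp_neural=clamp,
                                duration=duration,
                                steady_state_tol=steady_state_tol)
            cache[key] = run_to_steady_state(default_params, sc,
                                             max_time=max_time)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
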