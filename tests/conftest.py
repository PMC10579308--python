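import numpy as np
import pytest

from omafit import MechanismParams, make_log_grid, simulate_autoinhibition


@pytest.fixture(scope="session")
def recovery_grid():
    """61 log-spaced concentrations spanning 1e-10 to 1e-2 M."""
    return make_log_grid(-10, -2, 61)


@pytest.fixture(scope="session")
def autoinhibition_curves(recovery_grid):
    """Noiseless auto-inhibition curves, sigma=1, K_A=1e-6 M, tau 0.2-5."""
    taus = [0.2, 0.5, 1.0, 2.0, 5.0]
    curves = {}
    for tau in taus:
        p = MechanismParams("autoinhibition", k_a=1e-6, tau=tau, sigma=1.0)
        curves[tau] = simulate_autoinhibition(recovery_grid, p)
    return curves
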