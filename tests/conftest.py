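import numpy as np
import pytest

from prevclass import MisclassParams, SimulationSpec, simulate_panel

# Reference 3-test operating point used across the recovery suites: a rare-ish
# condition (10%) ascertained by three moderately good database clues.
TRUTH_K3 = MisclassParams(pi=0.10, S=[0.9, 0.85, 0.8], C=[0.95, 0.9, 0.97])
TRUTH_VECTOR = np.array([0.10, 0.9, 0.85, 0.8, 0.95, 0.9, 0.97])


@pytest.fixture(scope="session")
def truth_k3():
    return TRUTH_K3


@pytest.fixture(scope="session")
def panel_k3_large():
    """A large simulated panel at the reference operating point."""
    return simulate_panel(SimulationSpec(params=TRUTH_K3, n=100_000, seed=11))
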