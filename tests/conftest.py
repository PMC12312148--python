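import numpy as np
import pytest

from lipidphase.sans import table_start_params


@pytest.fixture(scope="session")
def truth_params():
    """The default composite-model parameter set used as simulation truth."""
    return table_start_params()


@pytest.fixture(scope="session")
def q_window():
    """Log-spaced q grid spanning the measurement window (Å⁻¹)."""
    return np.geomspace(0.002, 0.221, 120)
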