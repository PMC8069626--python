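import numpy as np
import pytest

from relmech import builtin_conditions, condition_params


@pytest.fixture(scope="session")
def conditions_table():
    return builtin_conditions()


@pytest.fixture(scope="session")
def default_grid():
    return np.linspace(0.0, 100.0, 101)


@pytest.fixture(scope="session")
def pu20_params():
    """Parameter set of the mid drug load at 7.5 mL/s flow."""
    return condition_params("PU-20%DE-Q7.5")
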