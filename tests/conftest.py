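import warnings

import pytest

from tfpi_tmdd.interspecies import HUMAN, RABBIT, allometric_scale
from tfpi_tmdd.parameters import monkey_rank1

# LSODA emits convergence chatter for deliberately pathological parameter
# sets probed by the fitting tests; the code handles failures explicitly.
warnings.filterwarnings("ignore", message=".*Excess work.*")
warnings.filterwarnings("ignore", message=".*convergence failures.*")
warnings.filterwarnings("ignore", message=".*error test failures.*")


@pytest.fixture(scope="session")
def monkey():
    return monkey_rank1()


@pytest.fixture(scope="session")
def human(monkey):
    return allometric_scale(monkey, HUMAN)


@pytest.fixture(scope="session")
def rabbit(monkey):
    return allometric_scale(monkey, RABBIT)
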