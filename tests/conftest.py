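import numpy as np
import pytest

from kprchain import CellContext, RateSchedule
from kprchain.experiments import foreign_schedule, self_schedule


@pytest.fixture
def ctx_saturating() -> CellContext:
    """Saturating ligand numbers: the response-table conditions."""
    return CellContext(T_T=2.0e4, P_T=1.0e7, k_on=5.0e-5)


@pytest.fixture
def ctx_low() -> CellContext:
    """Low-occupancy regime used for time-resolved discrimination."""
    return CellContext(T_T=2.0e4, P_T=100.0, k_on=5.0e-5)


@pytest.fixture
def foreign_n4() -> RateSchedule:
    return foreign_schedule(tau=2.0, N=4)


@pytest.fixture
def self_n4() -> RateSchedule:
    return self_schedule(tau=2.0, N=4)


def random_schedule(rng: np.random.Generator, N: int) -> RateSchedule:
    """Small random chain with rates in a moderate, well-conditioned range."""
    return RateSchedule(
        koff=rng.uniform(0.2, 4.0, size=N + 1),
        kp=rng.uniform(0.2, 4.0, size=N),
    )
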