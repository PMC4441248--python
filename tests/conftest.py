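import math

import numpy as np
import pytest

from msydemog.demography import Epoch, PiecewiseDemography


def constant_demo(N: float) -> PiecewiseDemography:
    return PiecewiseDemography((Epoch(0.0, math.inf, N, N),))


@pytest.fixture
def rng():
    return np.random.default_rng(20150519)


@pytest.fixture(scope="session")
def m1_table_small():
    """Small M1 reference table shared by the ABC contract tests."""
    from msydemog import model_spec, simulate_batch

    return simulate_batch(model_spec("M1"), 600, 20, 1234)
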