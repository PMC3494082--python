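import numpy as np
import pandas as pd
import pytest

from refstable.asc import PriorSpec, discretize_mixture, make_grid
from refstable.counts import CountMatrix, TpmMatrix


@pytest.fixture
def small_counts() -> CountMatrix:
    counts = pd.DataFrame(
        [[10, 0], [90, 50]], index=["g1", "g2"], columns=["A", "B"]
    )
    return CountMatrix(counts, pd.Series({"A": 100, "B": 50}))


@pytest.fixture
def four_condition_tpm() -> TpmMatrix:
    tpm = pd.DataFrame(
        {
            "replete": [50.0, 10.0, 2.4, 2.4],
            "P-limited": [50.0, 20.0, 2.6, 2.4],
            "Fe-limited": [50.0, 30.0, 2.4, 2.4],
            "Co-limited": [50.0, 40.0, 2.4, 2.4],
        },
        index=["const", "ramp", "border", "low"],
    )
    return TpmMatrix(tpm)


@pytest.fixture
def unit_normal_prior() -> PriorSpec:
    """Standard-normal prior discretized on the default grid."""
    grid = make_grid(8.0, 0.05)
    return PriorSpec(grid, discretize_mixture(grid, 0.5, 1.0, 1.0), 0.5, 1.0, 1.0)
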