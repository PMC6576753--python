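import numpy as np
import pandas as pd
import pytest

from invasdm import synthio
from invasdm.griddata import ANTHROPIC, ENVIRONMENTAL, PredictorStack


@pytest.fixture(scope="session")
def small_landscape():
    """A 15x15-cell landscape shared by tests that only need structure."""
    return synthio.default_landscape(seed=7, nx=15, ny=15)


@pytest.fixture
def square_grid():
    """10x10 grid of 5 km cells, full area fractions."""
    return synthio.make_grid(10, 10, 5.0)


@pytest.fixture
def toy_stack(square_grid):
    rng = np.random.default_rng(3)
    n = len(square_grid)
    frame = pd.DataFrame(
        {
            "temp": rng.normal(size=n),
            "rain": rng.normal(size=n),
            "dist_shops": rng.uniform(0, 50, size=n),
        },
        index=square_grid["cell_id"].to_numpy(),
    )
    return PredictorStack(
        frame, {"temp": ENVIRONMENTAL, "rain": ENVIRONMENTAL, "dist_shops": ANTHROPIC}
    )


@pytest.fixture
def separable_Xy():
    """40-point, 2-predictor linearly separable fixture."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        {
            "a": np.r_[rng.uniform(1, 2, 20), rng.uniform(-2, -1, 20)],
            "b": rng.normal(size=40),
        }
    )
    y = np.r_[np.ones(20), np.zeros(20)].astype(int)
    return X, y
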