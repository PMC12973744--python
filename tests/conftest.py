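import numpy as np
import pytest

import wildscape as ws

EXTENT = (0.0, 0.0, 4000.0, 4000.0)
CELL = 100.0


@pytest.fixture(scope="session")
def stack():
    """Small co-registered predictor stack (40x40 cells, 3 layers)."""
    return ws.generate_predictor_stack(11, EXTENT, CELL, 3)


@pytest.fixture(scope="session")
def truth(stack):
    return ws.ScenarioTruth(
        seed=11,
        species_coefficients={
            "wolf": np.array([1.5, 0.0, 0.0]),
            "roe_deer": np.array([1.0, 0.5, 0.0]),
        },
        extent=EXTENT,
        cell_size=CELL,
    )


@pytest.fixture(scope="session")
def occurrences(truth, stack):
    return ws.generate_occurrences(truth, stack, {"wolf": 120, "roe_deer": 80})


@pytest.fixture(scope="session")
def background(stack):
    return ws.sample_background(stack, 800, seed=5)
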