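import numpy as np
import pytest

from activecolony.fields import Grid
from activecolony.synth import GrowthParams, grow_colony, make_defect_field


@pytest.fixture(scope="session")
def small_colony():
    """Agent-based colony grown to ~60 cells (session-scoped: ~1 s)."""
    return grow_colony(GrowthParams(seed=11), n_final=60, record_every=10.0)


@pytest.fixture(scope="session")
def medium_colony():
    """Agent-based colony grown to ~300 cells (session-scoped: ~5 s)."""
    return grow_colony(GrowthParams(seed=7), n_final=300, record_every=5.0)


@pytest.fixture(scope="session")
def defect_pair_field():
    """Analytic +1/2 / -1/2 pair on a 256^2 grid."""
    grid = Grid.centered(20.0, 256)
    return make_defect_field(
        [((-6.0, 0.0), 0.5, 0.0), ((6.0, 0.0), -0.5, 0.0)], grid
    )
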