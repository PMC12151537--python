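import numpy as np
import pandas as pd
import pytest

from fcpg import sim
from fcpg.barcode import MISSING, BarcodeMatrix


def random_matrix(n_cells=6, n_sites=40, missing_rate=0.3, seed=0, brains=("B1",)):
    """Random ternary barcode matrix with i.i.d. states and missingness."""
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 2, size=(n_cells, n_sites)).astype(np.int8)
    values[rng.random((n_cells, n_sites)) < missing_rate] = MISSING
    cells = pd.DataFrame(
        {
            "brain_id": [brains[i % len(brains)] for i in range(n_cells)],
            "major_class": ["inhibitory" if i % 2 else "excitatory" for i in range(n_cells)],
            "subtype": ["Pvalb" if i % 2 else "L2_3" for i in range(n_cells)],
            "region": ["FC" if i % 2 else "TC" for i in range(n_cells)],
        },
        index=pd.Index([f"cell{i:03d}" for i in range(n_cells)], name="cell_id"),
    )
    sites = [f"chrX:{10000 + 2 * j}" for j in range(n_sites)]
    return BarcodeMatrix(values, cells, sites)


@pytest.fixture(scope="session")
def tiny_result():
    return sim.make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def paper_like_result():
    return sim.simulate(sim.paper_like_params(seed=11))
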