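import numpy as np
import pytest

from comseg import ComSegConfig
from comseg import simulate as sim


@pytest.fixture
def cfg10() -> ComSegConfig:
    """D = 10 µm config: r_pe = 5, r_knn = 2.5."""
    return ComSegConfig(mean_cell_diameter=10.0, seed=0)


@pytest.fixture(scope="session")
def grid_sim():
    """4x4 grid tissue with two disjoint-marker cell types and RNAs."""
    s = sim.simulate_grid(4, 4)
    model = sim.ExpressionModel.marker_panel(n_types=2, markers_per_type=5, mean_count=5.0)
    s = sim.sample_expression(s, model, seed=7)
    s = sim.place_rna(s, seed=8)
    return s, model


def lshape_tissue(tissue_seed: int, n_shapes: int = 32, dropout: float = 0.2):
    """Interlocking L-shape tissue, alternating types, nucleus dropout."""
    s = sim.simulate_lshapes(n_shapes, seed=tissue_seed)
    model = sim.ExpressionModel.marker_panel(n_types=2, markers_per_type=5, mean_count=5.0)
    types = np.arange(s.n_cells) % 2  # interlocking partners get distinct types
    s = sim.sample_expression(s, model, seed=tissue_seed + 10, types=types)
    s = sim.place_rna(s, seed=tissue_seed + 20)
    if dropout > 0:
        s = sim.drop_nuclei(s, dropout, seed=tissue_seed + 30)
    return s, model
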