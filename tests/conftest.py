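import numpy as np
import pytest
from hypothesis import settings

from bstmort import model, synthetic_data as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def path_graph():
    """Three nodes in a line: A - B - C."""
    from bstmort import adjacency as adj
    return adj.from_edges(["A", "B", "C"], [(0, 1), (1, 2)])


@pytest.fixture()
def tiny_panel_csv(tmp_path):
    """Complete 2-country x 2-year NMR panel file."""
    p = tmp_path / "panel.csv"
    p.write_text(
        "country,year,indicator,rate\n"
        "AAA,1990,NMR,10.0\nAAA,1991,NMR,9.5\n"
        "BBB,1990,NMR,20.0\nBBB,1991,NMR,19.0\n"
    )
    return p


@pytest.fixture(scope="session")
def fitted_world():
    """One default synthetic world (6x6 lattice, 1990-2019) fitted at desk scale.

    Shared across tests that only read the result.
    """
    graph = sd.make_lattice_graph(6, 6)
    truth = sd.TrueParams(seed=42)
    ds = sd.simulate_panel(truth, graph, range(1990, 2020))
    cfg = model.ModelConfig.desk_scale(seeds=(11, 12))
    samples = model.fit(ds.panel, ds.graph, cfg)
    return ds, samples


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
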