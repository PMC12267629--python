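import numpy as np
import pytest

from hypdisp import Connectome, SyntheticConfig, generate_cohort, load_patients
from hypdisp.pipeline import _load_truths


def connectome_from_edges(edges, node_ids, hemisphere=None):
    """Small labeled graph helper used across test modules."""
    node_ids = list(node_ids)
    if hemisphere is None:
        hemisphere = ["left"] * len(node_ids)
    index = {n: i for i, n in enumerate(node_ids)}
    adj = np.zeros((len(node_ids), len(node_ids)), dtype=int)
    for a, b in edges:
        adj[index[a], index[b]] = adj[index[b], index[a]] = 1
    return Connectome(node_ids, hemisphere, adj)


@pytest.fixture
def path_graph():
    return connectome_from_edges([("A", "B"), ("B", "C")], "ABC", ["left", "left", "right"])


@pytest.fixture
def triangle_graph():
    return connectome_from_edges([("A", "B"), ("B", "C"), ("A", "C")], "ABC")


@pytest.fixture
def star_graph():
    # hub H with three leaves
    return connectome_from_edges([("H", "A"), ("H", "B"), ("H", "C")], ["H", "A", "B", "C"])


SMALL_CONFIG = SyntheticConfig(
    n_nodes=60,
    n_favorable=6,
    n_poor=4,
    n_controls=2,
    avg_degree=8.0,
    resection_size=6,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A reduced synthetic cohort shared by the slower integration tests."""
    d = tmp_path_factory.mktemp("cohort")
    generate_cohort(SMALL_CONFIG, str(d))
    patients, controls = load_patients(str(d))
    truths = _load_truths(str(d))
    return {
        "dir": str(d),
        "config": SMALL_CONFIG,
        "patients": patients,
        "controls": controls,
        "truths": truths,
    }
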