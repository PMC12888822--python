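import numpy as np
import pytest

from btime.celltree import DifferentiationTree, nhs_tree, simulation_tree
from btime.models import CountDataset
from btime.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def nhs():
    return nhs_tree()


@pytest.fixture(scope="session")
def sim_tree():
    return simulation_tree()


@pytest.fixture(scope="session")
def chain2():
    """Two-node chain: root A at distance 1, leaf B one unit further."""
    return DifferentiationTree(
        nodes=["A", "B"],
        parent={"A": None, "B": "A"},
        edge_distance={"A": 0.0, "B": 1.0},
        level={"A": 1, "B": 2},
        root_distance=1.0,
    )


@pytest.fixture(scope="session")
def chain3():
    """Three-node chain with unit distances and unit root distance."""
    return DifferentiationTree(
        nodes=["A", "B", "C"],
        parent={"A": None, "B": "A", "C": "B"},
        edge_distance={"A": 0.0, "B": 1.0, "C": 1.0},
        level={"A": 1, "B": 2, "C": 3},
        root_distance=1.0,
    )


@pytest.fixture(scope="session")
def sim_dataset_60():
    """One 60%-perturbation replicate as a model-ready dataset."""
    cfg = SimConfig(perturb_fraction=0.6, seed=5)
    ds = generate_dataset(cfg, seed=1234)
    return CountDataset.from_frame(
        ds.to_frame(), cell_types=["M1", "M2", "M3", "M4"], covariates=["group"]
    )


def random_tree(rng: np.random.Generator, n_nodes: int) -> DifferentiationTree:
    """Random rooted tree with random non-negative distances and valid levels."""
    names = [f"n{i}" for i in range(n_nodes)]
    parent = {names[0]: None}
    level = {names[0]: 1}
    edge = {names[0]: 0.0}
    for i in range(1, n_nodes):
        p = names[rng.integers(0, i)]
        parent[names[i]] = p
        edge[names[i]] = float(np.round(rng.uniform(0.0, 2.0), 2))
        level[names[i]] = level[p] + int(rng.integers(0, 2)) + (0 if rng.random() < 0.3 else 1)
    # levels must be >= parent's; the construction above guarantees it
    return DifferentiationTree(names, parent, edge, level,
                               root_distance=float(np.round(rng.uniform(0.0, 2.0), 2)))
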