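import hypothesis
import networkx as nx
import numpy as np
import pytest

from phasegraph import ParticleConfiguration

hypothesis.settings.register_profile("deterministic", derandomize=True)
hypothesis.settings.load_profile("deterministic")


def graph_to_adj(graph: nx.Graph) -> np.ndarray:
    nodes = sorted(graph.nodes)
    return nx.to_numpy_array(graph, nodelist=nodes)


@pytest.fixture
def path3():
    """Path a-b-c on nodes 0-1-2."""
    return nx.path_graph(3)


@pytest.fixture
def two_tail_molecules():
    """Two single-tail-site molecules a fixed distance apart along x."""

    def make(distance, box=10.0):
        return ParticleConfiguration(
            positions=[[1.0, 5.0, 5.0], [1.0 + distance, 5.0, 5.0]],
            box=[box] * 3,
            molecule_id=[0, 1],
            site_role=["tail", "tail"],
        )

    return make


def random_configuration(rng, n_sites=60, box=(6.0, 5.0, 7.0)):
    """Random multi-site molecules for neighbour-search property tests."""
    box = np.asarray(box)
    n_mol = n_sites // 3
    positions = rng.uniform(0, 1, (n_mol * 3, 3)) * box
    molecule_id = np.repeat(np.arange(n_mol), 3)
    site_role = np.tile(["head", "tail", "terminal_tail"], n_mol)
    return ParticleConfiguration(positions=positions, box=box,
                                 molecule_id=molecule_id, site_role=site_role)
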