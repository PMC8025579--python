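import numpy as np
import pytest

from hlindex import GeneratorConfig, RoadNetwork, generate_region


@pytest.fixture(scope="session")
def small_region():
    """A 60-meshblock region with the default planted gradient."""
    return generate_region(GeneratorConfig(n_meshblocks=60, seed=11))


@pytest.fixture(scope="session")
def medium_region():
    """A 100-meshblock region used for oracle-equivalence checks."""
    return generate_region(GeneratorConfig(n_meshblocks=100, seed=5))


@pytest.fixture()
def line_network():
    """A--B--C collinear network with two 1000 m edges."""
    return RoadNetwork(
        nodes={"A": (0.0, 0.0), "B": (1000.0, 0.0), "C": (2000.0, 0.0)},
        edges=[("A", "B", 1000.0), ("B", "C", 1000.0)])


def random_geometric_network(n_nodes: int, seed: int,
                             side: float = 5000.0) -> RoadNetwork:
    """Connected random planar network from a Delaunay triangulation."""
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, side, size=(n_nodes, 2))
    tri = Delaunay(pts)
    pairs = set()
    for s in tri.simplices:
        for a in range(3):
            i, j = int(s[a]), int(s[(a + 1) % 3])
            pairs.add((min(i, j), max(i, j)))
    ids = [f"n{k:03d}" for k in range(n_nodes)]
    edges = [(ids[i], ids[j],
              float(np.linalg.norm(pts[i] - pts[j])))
             for i, j in sorted(pairs)]
    return RoadNetwork(nodes={ids[k]: tuple(pts[k]) for k in range(n_nodes)},
                       edges=edges)
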