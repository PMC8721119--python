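"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from fluctnet.pipeline import run_toy_pipeline
from fluctnet.synthetic import (
    SyntheticSpec,
    analytic_correlations,
    build_toy_tetramer,
    sample_frames,
)


@pytest.fixture(scope="session")
def topo():
    """Default 40-bead toy tetramer (10 residues per subunit)."""
    return build_toy_tetramer(10)


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(n_frames=10_000, seed=1234)


@pytest.fixture(scope="session")
def analytic_corr(topo, spec):
    return analytic_correlations(topo, spec)


@pytest.fixture(scope="session")
def sampled_traj(topo, spec):
    """10k-frame sampled trajectory, no rigid motion (already superposed)."""
    return sample_frames(topo, spec)


@pytest.fixture(scope="session")
def analytic_result():
    """Sampling-noise-free pipeline run on the toy tetramer."""
    return run_toy_pipeline(analytic=True)


def random_weighted_graph(rng: np.random.Generator, max_nodes: int = 9):
    """Random connected weighted graph for oracle-equivalence tests."""
    import networkx as nx

    n = int(rng.integers(3, max_nodes + 1))
    p = rng.uniform(0.3, 0.9)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    # ensure connectivity by threading a path through all nodes
    nodes = list(g.nodes)
    rng.shuffle(nodes)
    for a, b in zip(nodes[:-1], nodes[1:]):
        g.add_edge(a, b)
    for u, v in g.edges:
        g.edges[u, v]["weight"] = float(rng.uniform(0.05, 2.0))
    return nx.relabel_nodes(g, {i: f"A:{i + 1}" for i in g.nodes})
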