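import numpy as np
import pandas as pd
import pytest

import mpxtools as mpx


@pytest.fixture(scope="session")
def panel8() -> mpx.PanelConfig:
    """Small 8-marker panel shared across tests."""
    return mpx.generate_panel(8, seed=7)


def small_cell_spec(panel, **kwargs) -> mpx.CellSpec:
    """Desk-scale cell preserving the calibration molecule density.

    150 zones per set at cap radius 0.283 rad (same >=95% coverage as
    the 1,737-zone default) and 1,000 molecules keep ~6.7 molecules per
    zone, the density regime of the full-scale defaults.
    """
    kwargs.setdefault("total_molecules", 1000)
    kwargs.setdefault("n_pixels_a", 150)
    kwargs.setdefault("n_pixels_b", 150)
    kwargs.setdefault("pixel_radius", 0.283)
    return mpx.default_cell_spec(panel, **kwargs)


@pytest.fixture(scope="session")
def small_spec(panel8) -> mpx.CellSpec:
    return small_cell_spec(panel8)


def giant_projection(edge_list: pd.DataFrame, markers) -> mpx.ProjectedGraph:
    """Project the largest called component of an edge list."""
    g = mpx.build_graph(edge_list)
    mpx.call_components(g)
    return mpx.project_a_graph(
        g.edges[g.edges.component == 0], markers=markers, component=0)


def simulate_projection(panel, seed, patterns=None, **kwargs):
    """One simulated cell -> projected giant component."""
    spec = mpx.default_cell_spec(panel, spatial_pattern=patterns or {},
                                 **kwargs)
    truth = mpx.simulate_cell(spec, seed)
    return giant_projection(truth.edge_list(), panel.marker_names), truth


def random_projection(rng, n_nodes=None, markers=("m1",)) -> mpx.ProjectedGraph:
    """Random connected graph wrapped as a ProjectedGraph."""
    import networkx as nx
    import scipy.sparse as sp

    n = n_nodes or int(rng.integers(4, 31))
    while True:
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    adj = sp.csr_matrix(nx.to_scipy_sparse_array(g))
    adj.data[:] = 1
    counts = rng.integers(0, 20, size=(n, len(markers)))
    return mpx.ProjectedGraph(
        node_ids=np.array([f"n{i}" for i in range(n)]),
        adjacency=adj, counts=counts, markers=list(markers))
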