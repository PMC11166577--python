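"""Bipartite UPI graph assembly, component calling and filtering.

The edge list of unique AOC molecules defines a bipartite multigraph
(UPI-A and UPI-B nodes; one parallel edge per distinct UMI). Spurious
edges joining otherwise densely connected communities — technical
doublets and chimeric bridges — are removed with Leiden community
detection; connected components are then called as putative cells,
filtered on size (spline elbow of the edge-rank curve plus a manual
minimum, dropping the largest outliers), and summarised into a
components x markers count matrix with a CLR view. Antibody-aggregate
components are flagged with the Tau skewness metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .panel import PanelConfig


class SizeThresholdError(RuntimeError):
    """No data-driven size threshold is available; use a manual cutoff."""


# ---------------------------------------------------------------------------
# bipartite graph


@dataclass
class BipartiteGraph:
    """Bipartite UPI multigraph backed by the molecule edge list."""

    edges: pd.DataFrame  # columns upia, upib, marker, umi, reads [, component]
    removed_edges: pd.DataFrame | None = None

    @property
    def a_nodes(self) -> np.ndarray:
        return self.edges.upia.unique()

    @property
    def b_nodes(self) -> np.ndarray:
        return self.edges.upib.unique()

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def simple_pairs(self) -> pd.DataFrame:
        """Deduplicated (upia, upib) node pairs."""
        return self.edges[["upia", "upib"]].drop_duplicates()

    def to_igraph(self) -> tuple[ig.Graph, pd.Index, pd.Index]:
        """Simple igraph view; returns (graph, a_index, b_index).

        Vertices 0..nA-1 are UPI-A nodes, nA.. are UPI-B nodes, so the
        graph is 2-colourable by construction.
        """
        pairs = self.simple_pairs()
        a_codes, a_index = pd.factorize(pairs.upia)
        b_codes, b_index = pd.factorize(pairs.upib)
        n_a = len(a_index)
        g = ig.Graph(
            n=n_a + len(b_index),
            edges=np.column_stack([a_codes, b_codes + n_a]).tolist(),
        )
        g.vs["type"] = [False] * n_a + [True] * len(b_index)
        return g, a_index, b_index


def build_graph(edges: pd.DataFrame) -> BipartiteGraph:
    """Wrap a validated edge list as a bipartite graph."""
    missing = {"upia", "upib", "marker", "umi"} - set(edges.columns)
    if missing:
        raise ValueError(f"edge list misses columns {sorted(missing)}")
    df = edges.copy()
    if "reads" not in df.columns:
        df["reads"] = 1
    return BipartiteGraph(edges=df.reset_index(drop=True))


def refine_components(
    g: BipartiteGraph,
    resolution: float = 1.0,
    max_iter: int = 3,
    crossing_max: int = 10,
    seed: int = 0,
) -> BipartiteGraph:
    """Remove spurious inter-community edges with Leiden.

    Per connected component, Leiden (RB-configuration modularity)
    partitions the simple graph into cell-scale communities; for every
    community pair joined by between 1 and ``crossing_max`` distinct
    node-pair edges, those edges (and their PCR-parallel copies) are
    removed. Repeats up to ``max_iter`` times or until no edge is
    removed.

    The Leiden resolution is scale-free: the effective RB resolution
    for a component with m simple edges is
    ``resolution * 2 * crossing_max / m``. For two equal halves joined
    by w edges this makes Leiden keep them as separate communities
    exactly when w is at most about ``resolution * crossing_max``, so
    the community scale is matched to the crossing-edge removal rule at
    every component size. A fixed resolution cannot do this: it either
    fragments large spatially embedded cells into patch communities
    (whose thin mutual interfaces the removal rule would shred) or
    swallows small doublets whole.
    """
    edges = g.edges
    removed = []
    for _ in range(max_iter):
        bg = BipartiteGraph(edges)
        graph, a_index, b_index = bg.to_igraph()
        if graph.ecount() == 0:
            break
        n_a = len(a_index)
        bad_pairs: list[tuple[str, str]] = []
        for comp in graph.connected_components():
            sub = graph.subgraph(comp)
            if sub.ecount() == 0:
                continue
            gamma = resolution * 2.0 * crossing_max / sub.ecount()
            part = leidenalg.find_partition(
                sub,
                leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=gamma,
                seed=seed,
            )
            memb = np.asarray(part.membership)
            if memb.max() == 0:
                continue
            ends = np.asarray(sub.get_edgelist())
            cu, cv = memb[ends[:, 0]], memb[ends[:, 1]]
            crossing = np.flatnonzero(cu != cv)
            if crossing.size == 0:
                continue
            lo = np.minimum(cu[crossing], cv[crossing])
            hi = np.maximum(cu[crossing], cv[crossing])
            counts = (pd.DataFrame({"lo": lo, "hi": hi})
                      .groupby(["lo", "hi"]).size())
            weak = set(counts[counts <= crossing_max].index)
            if not weak:
                continue
            comp_arr = np.asarray(comp)
            for k, e_idx in enumerate(crossing):
                if (lo[k], hi[k]) not in weak:
                    continue
                u, v = ends[e_idx]
                gu, gv = int(comp_arr[u]), int(comp_arr[v])
                if gu > gv:
                    gu, gv = gv, gu
                bad_pairs.append((str(a_index[gu]), str(b_index[gv - n_a])))
        if not bad_pairs:
            break
        drop = pd.MultiIndex.from_frame(edges[["upia", "upib"]]).isin(
            pd.MultiIndex.from_tuples(bad_pairs))
        removed.append(edges[drop])
        edges = edges[~drop].reset_index(drop=True)
    return BipartiteGraph(
        edges=edges,
        removed_edges=(pd.concat(removed, ignore_index=True)
                       if removed else edges.iloc[0:0]),
    )


def call_components(g: BipartiteGraph) -> pd.Series:
    """Label every edge with its connected component.

    Labels are integers assigned in descending component size (edge
    count), ties broken by smallest UPI-A string, so the labelling is
    invariant to input row order.
    """
    graph, a_index, b_index = g.to_igraph()
    membership = np.asarray(graph.connected_components().membership)
    comp_of_edge = membership[a_index.get_indexer(g.edges.upia)]
    sizes = pd.Series(comp_of_edge).value_counts()
    min_a = pd.Series(g.edges.upia.values).groupby(comp_of_edge).min()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], min_a[c]))
    relabel = {c: i for i, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in comp_of_edge],
                       index=g.edges.index, name="component")
    g.edges = g.edges.assign(component=labels)
    return labels


# ---------------------------------------------------------------------------
# size filtering


def size_threshold(component_sizes, min_components: int = 20) -> int:
    """Data-driven minimum component size from the edge-rank curve.

    A GCV-smoothed cubic spline is fitted to (rank, log10 size) with
    sizes sorted descending; the threshold is the size at the rank
    minimising the spline's second derivative — the onset of the sharp
    decline separating cells from debris components.
    """
    from scipy.interpolate import make_smoothing_spline

    sizes = np.sort(np.asarray(list(component_sizes), dtype=float))[::-1]
    if len(sizes) < min_components:
        raise SizeThresholdError(
            f"only {len(sizes)} components (< {min_components}); "
            "use a manual cutoff")
    if sizes[0] == sizes[-1]:
        raise SizeThresholdError("all components share one size; no elbow")
    ranks = np.arange(1, len(sizes) + 1, dtype=float)
    spline = make_smoothing_spline(ranks, np.log10(sizes))
    curvature = spline.derivative(2)(ranks)
    elbow = int(np.argmin(curvature))
    if elbow + 1 < len(sizes) and sizes[elbow + 1] < sizes[elbow]:
        # place the cutoff inside the gap below the elbow component so it
        # separates the modes without changing which components pass
        return int(np.ceil(np.sqrt(sizes[elbow] * sizes[elbow + 1])))
    return int(sizes[elbow])


def filter_components(
    labels: pd.Series,
    threshold: int = 0,
    manual_min: int = 0,
    drop_top_k: int = 10,
) -> tuple[list[int], pd.DataFrame]:
    """Select putative single-cell components.

    Drops the ``drop_top_k`` largest components (size outliers), then
    every component smaller than ``max(threshold, manual_min)``.
    Returns (retained component ids, edge-rank table).
    """
    if manual_min < 0:
        raise ValueError("manual_min must be >= 0")
    sizes = labels.value_counts().sort_values(ascending=False)
    table = pd.DataFrame({
        "rank": np.arange(1, len(sizes) + 1),
        "component": sizes.index,
        "size": sizes.values,
    })
    cutoff = max(threshold, manual_min)
    keep = np.ones(len(table), dtype=bool)
    keep[:drop_top_k] = False
    keep &= table["size"].values >= cutoff
    table["retained"] = keep
    return table.loc[keep, "component"].tolist(), table


# ---------------------------------------------------------------------------
# count matrix


@dataclass
class CountMatrix:
    """Components x markers unique-molecule counts with a CLR view."""

    counts: pd.DataFrame  # rows: component ids; columns: marker names

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def clr(self) -> pd.DataFrame:
        """Per-component centered log ratio: ln(1+x) - mean(ln(1+x))."""
        logs = np.log1p(self.counts.values.astype(float))
        return pd.DataFrame(
            logs - logs.mean(axis=1, keepdims=True),
            index=self.counts.index, columns=self.counts.columns,
        )

    def write_mtx(self, prefix) -> None:
        from scipy.io import mmwrite

        mmwrite(f"{prefix}.mtx", sp.csr_matrix(self.counts.values))
        self.counts.index.to_series().to_csv(
            f"{prefix}.rows.tsv", sep="\t", index=False, header=["component"])
        pd.Series(self.counts.columns).to_csv(
            f"{prefix}.cols.tsv", sep="\t", index=False, header=["marker"])


def count_matrix(
    edges: pd.DataFrame,
    retained: list[int],
    panel: PanelConfig | list[str],
) -> CountMatrix:
    """Sum unique molecules per component per marker (explicit zeros)."""
    markers = (panel.marker_names if isinstance(panel, PanelConfig)
               else list(panel))
    sub = edges[edges.component.isin(retained)]
    tab = (sub.groupby(["component", "marker"]).size().unstack(fill_value=0)
           .reindex(index=retained, columns=markers, fill_value=0))
    tab.index.name = "component"
    return CountMatrix(counts=tab.astype(int))


# ---------------------------------------------------------------------------
# Tau aggregate filter


def tau(counts) -> float:
    """Tau skewness of a marker count vector: sum(1 - x/xmax) / (n-1).

    0 for an even distribution, 1 when all counts sit on one marker.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau requires a vector of >= 2 marker counts")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


def tau_filter(
    m: CountMatrix,
    high_cut: float = 0.995,
    high_iqr: float = 2.0,
    low_iqr: float = 5.0,
) -> pd.DataFrame:
    """Flag aggregate-like components by Tau.

    HighTau: tau above ``high_cut`` or more than ``high_iqr`` IQRs
    above the population median (single-antibody aggregates).
    LowTau: more than ``low_iqr`` IQRs below the median (complex
    aggregates). All-zero components are flagged LowTau.
    """
    taus = np.array([tau(row) for row in m.counts.values])
    finite = taus[np.isfinite(taus)]
    if len(finite) == 0:
        raise ValueError("no component has nonzero counts")
    median = float(np.median(finite))
    iqr = float(np.subtract(*np.percentile(finite, [75, 25])))
    flags = []
    for t in taus:
        if not np.isfinite(t):
            flags.append("LowTau")
        elif t > high_cut or t > median + high_iqr * iqr:
            flags.append("HighTau")
        elif t < median - low_iqr * iqr:
            flags.append("LowTau")
        else:
            flags.append("OK")
    return pd.DataFrame({
        "component": m.counts.index,
        "tau": taus,
        "flag": flags,
    })


# ---------------------------------------------------------------------------
# one-mode projection


@dataclass
class ProjectedGraph:
    """One-mode UPI-A projection of a single cell component.

    A-nodes are linked when they share at least one UPI-B neighbour;
    each node carries the marker count vector of its incident unique
    molecules.
    """

    node_ids: np.ndarray          # UPI-A strings, defines node order
    adjacency: sp.csr_matrix      # binary, no self-loops
    counts: np.ndarray            # n_nodes x n_markers, int
    markers: list[str]
    component: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def marker_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.markers)

    def to_igraph(self) -> ig.Graph:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return ig.Graph(n=self.n_nodes,
                        edges=np.column_stack([coo.row, coo.col]).tolist())

    def is_connected(self) -> bool:
        n, _ = sp.csgraph.connected_components(self.adjacency, directed=False)
        return n <= 1


def project_a_graph(
    component_edges: pd.DataFrame,
    markers: list[str] | None = None,
    component: int | None = None,
) -> ProjectedGraph:
    """Project one component's bipartite edges onto its UPI-A nodes."""
    if "component" in component_edges.columns:
        if component_edges.component.nunique() > 1:
            raise ValueError("edges span multiple components; pass one")
    a_codes, a_index = pd.factorize(component_edges.upia, sort=True)
    b_codes, b_index = pd.factorize(component_edges.upib, sort=True)
    n_a, n_b = len(a_index), len(b_index)

    incidence = sp.csr_matrix(
        (np.ones(len(component_edges), dtype=np.int64), (a_codes, b_codes)),
        shape=(n_a, n_b),
    )
    incidence.data[:] = 1  # dedupe parallel molecules for topology
    adj = (incidence @ incidence.T).tocsr()
    adj.setdiag(0)
    adj.eliminate_zeros()
    adj.data[:] = 1

    if markers is None:
        markers = sorted(component_edges.marker.unique())
    marker_pos = {m: j for j, m in enumerate(markers)}
    counts = np.zeros((n_a, len(markers)), dtype=np.int64)
    mk = component_edges.marker.map(marker_pos).to_numpy()
    np.add.at(counts, (a_codes, mk), 1)

    return ProjectedGraph(
        node_ids=np.asarray(a_index),
        adjacency=adj,
        counts=counts,
        markers=list(markers),
        component=component,
    )
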