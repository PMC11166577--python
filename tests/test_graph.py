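from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mpxtools as mpx

from conftest import small_cell_spec


def edge_frame(rows):
    return pd.DataFrame(rows, columns=["upia", "upib", "marker", "umi", "reads"])


def block_edges(a_prefix, b_prefix, n=20, umi_prefix="u"):
    return [(f"{a_prefix}{i}", f"{b_prefix}{j}", "M",
             f"{umi_prefix}{a_prefix}{i}{b_prefix}{j}", 1)
            for i in range(n) for j in range(n)]


class TestBuildGraph:
    def test_construction_counts(self):
        g = mpx.build_graph(edge_frame([
            ("A1", "B1", "M", "u1", 1),
            ("A1", "B2", "M", "u2", 1),
            ("A2", "B1", "M", "u3", 1)]))
        assert len(g.a_nodes) == 2 and len(g.b_nodes) == 2
        assert g.n_edges == 3

    def test_parallel_edges_kept(self):
        g = mpx.build_graph(edge_frame([
            ("A1", "B1", "M", "u1", 1), ("A1", "B1", "M", "u2", 1)]))
        assert g.n_edges == 2
        assert len(g.simple_pairs()) == 1

    def test_two_colorable(self):
        g = mpx.build_graph(edge_frame(block_edges("a", "b", 5)))
        ig, _, _ = g.to_igraph()
        assert ig.is_bipartite()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            mpx.build_graph(pd.DataFrame({"upia": ["a"]}))


class TestRefineComponents:
    def test_single_bridge_removed(self):
        rows = block_edges("a", "x") + block_edges("c", "y") + \
            [("a0", "y0", "M", "bridge", 1)]
        g = mpx.refine_components(mpx.build_graph(edge_frame(rows)))
        assert len(g.removed_edges) == 1
        assert mpx.call_components(g).nunique() == 2

    def test_thick_interface_retained(self):
        rows = block_edges("a", "x") + block_edges("c", "y") + \
            [(f"a{i}", f"y{i}", "M", f"br{i}", 1) for i in range(15)]
        g = mpx.refine_components(mpx.build_graph(edge_frame(rows)),
                                  crossing_max=10)
        assert len(g.removed_edges) == 0
        assert mpx.call_components(g).nunique() == 1

    def test_single_dense_block_unchanged(self):
        g = mpx.refine_components(mpx.build_graph(edge_frame(
            block_edges("a", "x"))))
        assert len(g.removed_edges) == 0

    def test_no_false_splits_on_simulated_cells(self, small_spec):
        truth, edges = mpx.simulate_sample([(small_spec, 5)], seed=3)
        g = mpx.refine_components(mpx.build_graph(edges))
        assert len(g.removed_edges) == 0
        labels = mpx.call_components(g)
        assert (labels.value_counts() >= 300).sum() == 5

    def test_doublet_split_recovers_both_cells(self, small_spec):
        truth, edges = mpx.simulate_sample(
            [(small_spec, 2)], doublet_fraction=1.0, seed=9)
        before = mpx.call_components(mpx.build_graph(edges))
        assert (before.value_counts() >= 300).sum() == 1  # merged entity
        g = mpx.refine_components(mpx.build_graph(edges))
        after = mpx.call_components(g)
        assert (after.value_counts() >= 300).sum() == 2


class TestComponentCalling:
    def test_labels_partition_edges(self, small_spec):
        truth, edges = mpx.simulate_sample([(small_spec, 3)], seed=1)
        labels = mpx.call_components(mpx.build_graph(edges))
        assert len(labels) == len(edges)
        assert labels.notna().all()

    def test_labels_invariant_to_row_order(self, small_spec):
        truth, edges = mpx.simulate_sample([(small_spec, 3)], seed=2)
        l1 = mpx.call_components(mpx.build_graph(edges))
        shuffled = edges.sample(frac=1, random_state=0).reset_index(drop=True)
        l2 = mpx.call_components(mpx.build_graph(shuffled))
        m1 = dict(zip(edges.umi + edges.upia, l1))
        m2 = dict(zip(shuffled.umi + shuffled.upia, l2))
        assert m1 == m2


class TestSizeThreshold:
    def bimodal(self, seed=1):
        rng = np.random.default_rng(seed)
        big = rng.lognormal(np.log(10_000), 0.1, 500)
        small = rng.lognormal(np.log(50), 0.3, 5000)
        return np.concatenate([big, small])

    def test_threshold_separates_bimodal_sizes(self):
        sizes = self.bimodal()
        thr = mpx.size_threshold(sizes)
        assert sizes[500:].max() < thr < sizes[:500].min()

    def test_equal_sizes_raise_fallback(self):
        with pytest.raises(mpx.SizeThresholdError):
            mpx.size_threshold([100] * 50)

    def test_too_few_components_raise_fallback(self):
        with pytest.raises(mpx.SizeThresholdError):
            mpx.size_threshold([10, 20, 30])

    def test_order_invariance(self):
        sizes = self.bimodal(seed=4)
        rng = np.random.default_rng(0)
        assert mpx.size_threshold(sizes) == \
            mpx.size_threshold(rng.permutation(sizes))


class TestFilterComponents:
    def test_identity_when_disabled(self):
        labels = pd.Series([0] * 10 + [1] * 5 + [2] * 3)
        retained, table = mpx.filter_components(
            labels, threshold=0, manual_min=0, drop_top_k=0)
        assert sorted(retained) == [0, 1, 2]

    def test_drop_top_k_counting(self):
        labels = pd.Series(np.repeat(np.arange(12), np.arange(12, 0, -1)))
        retained, _ = mpx.filter_components(labels, drop_top_k=10)
        assert len(retained) == 2

    def test_manual_minimum_enforced(self):
        labels = pd.Series([0] * 5000 + [1] * 3999 + [2] * 100)
        retained, table = mpx.filter_components(
            labels, manual_min=4000, drop_top_k=0)
        assert retained == [0]
        assert (table.loc[table.retained, "size"] >= 4000).all()

    def test_negative_manual_min_rejected(self):
        with pytest.raises(ValueError):
            mpx.filter_components(pd.Series([0]), manual_min=-1)


class TestCountMatrix:
    def test_counts_and_explicit_zeros(self):
        edges = edge_frame([
            ("A1", "B1", "CD3", f"u{i}", 1) for i in range(5)] + [
            ("A1", "B2", "CD4", f"v{i}", 1) for i in range(2)])
        edges["component"] = 0
        cm = mpx.count_matrix(edges, [0], ["CD3", "CD4", "CD8"])
        assert cm.counts.loc[0, "CD3"] == 5
        assert cm.counts.loc[0, "CD4"] == 2
        assert cm.counts.loc[0, "CD8"] == 0

    def test_row_sums_equal_component_edge_counts(self, small_spec, panel8):
        truth, edges = mpx.simulate_sample([(small_spec, 2)], seed=6)
        g = mpx.build_graph(edges)
        labels = mpx.call_components(g)
        retained, _ = mpx.filter_components(labels, manual_min=300,
                                            drop_top_k=0)
        cm = mpx.count_matrix(g.edges, retained, panel8)
        for comp in retained:
            assert cm.counts.loc[comp].sum() == (labels == comp).sum()

    def test_truth_abundances_recovered(self, small_spec, panel8):
        truth, edges = mpx.simulate_sample([(small_spec, 1)], seed=7)
        g = mpx.build_graph(edges)
        labels = mpx.call_components(g)
        retained, _ = mpx.filter_components(labels, manual_min=300,
                                            drop_top_k=0)
        cm = mpx.count_matrix(g.edges, retained, panel8)
        want = truth.molecules.marker.value_counts()
        got = cm.counts.sum(axis=0)
        # the giant component holds nearly all retained molecules
        for marker in panel8.marker_names:
            assert got[marker] >= 0.9 * want.get(marker, 0)

    def test_clr_rows_center_to_zero(self, small_spec, panel8):
        truth, edges = mpx.simulate_sample([(small_spec, 2)], seed=8)
        g = mpx.build_graph(edges)
        labels = mpx.call_components(g)
        retained, _ = mpx.filter_components(labels, manual_min=300,
                                            drop_top_k=0)
        cm = mpx.count_matrix(g.edges, retained, panel8)
        np.testing.assert_allclose(cm.clr.sum(axis=1), 0, atol=1e-9)


class TestTau:
    def test_even_distribution_gives_zero(self):
        assert mpx.tau([25] * 80) == 0.0

    def test_single_marker_gives_one(self):
        assert mpx.tau([2000] + [0] * 79) == 1.0

    def test_hand_computed_example(self):
        assert mpx.tau([4, 2, 2, 2]) == pytest.approx(0.5)

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=100))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_tau_bounded_in_unit_interval(self, counts):
        t = mpx.tau(counts)
        if max(counts) > 0:
            assert 0.0 <= t <= 1.0
        else:
            assert np.isnan(t)

    def test_tau_filter_flags(self):
        rows = [[10] * 10 for _ in range(30)]       # tau = 0 population
        rows.append([1000] + [0] * 9)               # tau = 1 -> HighTau
        cm = mpx.CountMatrix(pd.DataFrame(rows))
        flags = mpx.tau_filter(cm)
        assert flags.flag.iloc[-1] == "HighTau"
        assert (flags.flag.iloc[:-1] == "OK").all()

    def test_all_zero_component_flagged_low(self):
        cm = mpx.CountMatrix(pd.DataFrame([[5, 5, 5], [0, 0, 0]]))
        flags = mpx.tau_filter(cm)
        assert flags.flag.tolist() == ["OK", "LowTau"]
        assert np.isnan(flags.tau.iloc[1])


class TestProjection:
    def test_path_projection(self):
        pg = mpx.project_a_graph(edge_frame([
            ("A1", "B1", "M", "u1", 1), ("A2", "B1", "M", "u2", 1)]))
        assert pg.n_nodes == 2
        assert pg.adjacency[0, 1] == 1

    def test_star_becomes_clique(self):
        pg = mpx.project_a_graph(edge_frame([
            (f"A{i}", "B1", "M", f"u{i}", 1) for i in range(5)]))
        assert pg.adjacency.nnz == 5 * 4  # directed entries of a 5-clique
        assert pg.adjacency.diagonal().sum() == 0

    def test_count_vector_conservation(self, small_spec, panel8):
        truth = mpx.simulate_cell(small_spec, seed=4)
        edges = truth.edge_list()
        pg = mpx.project_a_graph(edges, markers=panel8.marker_names)
        assert pg.counts.sum() == len(edges)
        want = edges.marker.value_counts()
        got = pg.marker_totals()
        for marker, count in want.items():
            assert got[marker] == count

    def test_matches_brute_force_shared_neighbor_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_a, n_b = rng.integers(2, 25, size=2)
            n_e = int(rng.integers(1, 50))
            rows = [(f"A{rng.integers(n_a)}", f"B{rng.integers(n_b)}",
                     "M", f"u{i}", 1) for i in range(n_e)]
            df = edge_frame(rows).drop_duplicates(["upia", "upib", "umi"])
            pg = mpx.project_a_graph(df)
            # oracle: link two A nodes iff they share a B neighbour
            nbrs = df.groupby("upia").upib.apply(set)
            ids = list(pg.node_ids)
            expect = {(i, j)
                      for i, j in combinations(range(len(ids)), 2)
                      if nbrs[ids[i]] & nbrs[ids[j]]}
            got = {(i, j) for i, j in zip(*pg.adjacency.nonzero()) if i < j}
            assert got == expect
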