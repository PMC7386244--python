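"""Neighbor graphs, spatial-lag autocorrelation, region borders, Wilcoxon DE."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, pearsonr

import spotstack as st
from spotstack.spotgraph import (
    _exact_rank_sum_p,
    _normal_rank_sum_p,
    build_neighbor_graph,
    hex_positions_um,
)


def brute_force_graph(spots, spacing, threshold):
    """Oracle: all-pairs distance scan."""
    pos = hex_positions_um(spots, spacing)
    sec = spots["section_id"].to_numpy()
    edges = set()
    for i in range(len(spots)):
        for j in range(i + 1, len(spots)):
            if sec[i] == sec[j] and np.linalg.norm(pos[i] - pos[j]) <= threshold + 1e-9:
                edges.add((i, j))
    return edges


def brute_force_lag(graph, expr):
    """Oracle: double loop over genes and neighbor lists."""
    lag = np.zeros_like(expr, dtype=float)
    for g in range(expr.shape[0]):
        for i in range(graph.n_nodes):
            for j in graph.neighbors(i):
                lag[g, i] += expr[g, j]
    return lag


def _random_graph_fixture(n_spots, n_genes, seed):
    rng = np.random.default_rng(seed)
    rows = int(np.ceil(np.sqrt(n_spots)))
    spots = st.synth.make_hex_grid(rows, rows)[:n_spots]
    graph = build_neighbor_graph(spots)
    expr = rng.gamma(2.0, 1.0, size=(n_genes, n_spots))
    return graph, expr


class TestNeighborGraph:
    def test_interior_degree_exactly_six(self, hex_10x10):
        graph = build_neighbor_graph(hex_10x10)
        deg = graph.degrees()
        assert deg.max() == 6
        interior = (
            hex_10x10["array_row"].between(1, 8) & hex_10x10["array_col"].between(1, 8)
        ).to_numpy()
        assert (deg[interior] == 6).all()

    def test_matches_all_pairs_scan(self):
        spots = st.synth.make_hex_grid(5, 7)
        graph = build_neighbor_graph(spots)
        assert {tuple(e) for e in graph.edges} == brute_force_graph(spots, 100.0, 150.0)

    def test_threshold_definition(self):
        spots = pd.DataFrame({
            "barcode": ["a", "b"], "section_id": "S", "array_row": [0.0, 0.0],
            "array_col": [0.0, 2.0], "px_x": [0, 200], "px_y": [0, 0],
            "in_tissue": True,
        })
        assert len(build_neighbor_graph(spots).edges) == 0  # 200 um apart
        spots["array_col"] = [0.0, 1.0]  # 100 um apart
        assert len(build_neighbor_graph(spots).edges) == 1

    def test_single_spot_no_edges(self):
        spots = st.synth.make_hex_grid(1, 1)
        assert build_neighbor_graph(spots).edges.shape == (0, 2)

    def test_no_edges_across_sections(self):
        a = st.synth.make_hex_grid(3, 3, section_id="A")
        b = st.synth.make_hex_grid(3, 3, section_id="B")
        graph = build_neighbor_graph(pd.concat([a, b], ignore_index=True))
        sec = pd.concat([a, b], ignore_index=True)["section_id"].to_numpy()
        assert all(sec[i] == sec[j] for i, j in graph.edges)


class TestSpatialLag:
    def test_simple_sum_and_isolated_zero(self):
        spots = st.synth.make_hex_grid(1, 4, spacing_um=100.0)
        # chain 0-1-2-3 plus an isolated spot far away
        iso = pd.DataFrame({"barcode": ["iso"], "section_id": "S1",
                            "array_row": [50.0], "array_col": [50.0],
                            "px_x": [0.0], "px_y": [0.0], "in_tissue": True})
        spots = pd.concat([spots, iso], ignore_index=True)
        graph = build_neighbor_graph(spots)
        expr = np.array([[1.0, 2.0, 3.0, 4.0, 9.0]])
        lag = st.spatial_lag(graph, expr)
        np.testing.assert_allclose(lag[0], [2.0, 1 + 3, 2 + 4, 3.0, 0.0])

    def test_matches_brute_force(self):
        graph, expr = _random_graph_fixture(50, 10, seed=0)
        np.testing.assert_allclose(st.spatial_lag(graph, expr),
                                   brute_force_lag(graph, expr), atol=1e-10)

    def test_dimension_mismatch_rejected(self, hex_10x10):
        graph = build_neighbor_graph(hex_10x10)
        with pytest.raises(ValueError):
            st.spatial_lag(graph, np.zeros((3, 5)))


class TestAutocorrelationRanking:
    def test_matches_textbook_pearson(self):
        graph, expr = _random_graph_fixture(30, 20, seed=1)
        table = st.rank_spatial_autocorrelation(graph, expr)
        lag = brute_force_lag(graph, expr)
        for _, row in table.iterrows():
            g = int(row["gene"].removeprefix("gene"))
            assert row["r"] == pytest.approx(pearsonr(expr[g], lag[g])[0], abs=1e-10)

    def test_constant_gene_undefined_and_last(self):
        graph, expr = _random_graph_fixture(30, 5, seed=2)
        expr[3] = 7.0
        table = st.rank_spatial_autocorrelation(graph, expr)
        assert table.iloc[-1]["gene"] == "gene3"
        assert np.isnan(table.iloc[-1]["r"])

    def test_gradient_beats_its_permutation(self, hex_10x10):
        graph = build_neighbor_graph(hex_10x10)
        pos = hex_positions_um(hex_10x10, 100.0)
        gradient = pos[:, 0] + pos[:, 1]
        rng = np.random.default_rng(3)
        expr = np.vstack([gradient, rng.permutation(gradient)])
        table = st.rank_spatial_autocorrelation(graph, expr, ["grad", "perm"])
        assert list(table["gene"]) == ["grad", "perm"]
        assert table.iloc[0]["r"] > table.iloc[1]["r"]


def brute_force_region_neighbors(graph, is_target):
    inner, outer = set(), set()
    for i in range(graph.n_nodes):
        for j in range(graph.n_nodes):
            if i == j:
                continue
            adjacent = (min(i, j), max(i, j)) in {tuple(e) for e in graph.edges}
            if adjacent and is_target[i] and not is_target[j]:
                inner.add(graph.nodes[i])
                outer.add(graph.nodes[j])
    return inner, outer


class TestRegionNeighbors:
    def test_chain_enumeration(self):
        spots = st.synth.make_hex_grid(1, 5)  # chain a-b-c-d-e
        graph = build_neighbor_graph(spots)
        labels = {node: ("target" if i == 2 else "bg") for i, node in enumerate(graph.nodes)}
        inner, outer = st.region_neighbors(graph, labels, "target")
        assert inner == {graph.nodes[2]}
        assert outer == {graph.nodes[1], graph.nodes[3]}

    def test_all_target_empty_sets(self, hex_10x10):
        graph = build_neighbor_graph(hex_10x10)
        labels = {node: "target" for node in graph.nodes}
        inner, outer = st.region_neighbors(graph, labels, "target")
        assert inner == set() and outer == set()

    def test_unknown_label_rejected(self, hex_10x10):
        graph = build_neighbor_graph(hex_10x10)
        labels = {node: "bg" for node in graph.nodes}
        with pytest.raises(ValueError):
            st.region_neighbors(graph, labels, "missing")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_labelings(self, seed):
        graph, _ = _random_graph_fixture(40, 1, seed=seed)
        rng = np.random.default_rng(seed)
        is_target = rng.random(graph.n_nodes) < 0.3
        if not is_target.any():
            is_target[0] = True
        labels = {node: ("t" if t else "bg") for node, t in zip(graph.nodes, is_target)}
        assert st.region_neighbors(graph, labels, "t") == \
            brute_force_region_neighbors(graph, is_target)


class TestWilcoxon:
    def test_exact_enumeration_worked_example(self):
        p = _exact_rank_sum_p(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        expr = np.array([[3.0, 1, 2, 3, 1, 2]])
        table = st.wilcoxon_de(expr, [0, 1, 2], [3, 4, 5], min_frac=0.0)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_normal_path_matches_scipy_asymptotic_form(self, rng):
        # sanity: large-sample agreement with the standard implementation
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.3, 1, 50)
        mine = _normal_rank_sum_p(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic").pvalue
        assert mine == pytest.approx(ref, abs=5e-3)

    def test_normal_within_0p01_of_exact_small_groups(self, rng):
        worst = 0.0
        for _ in range(30):
            m, n = rng.integers(5, 9, 2)
            a = rng.normal(0, 1, m)
            b = rng.normal(0.8, 1, n)
            worst = max(worst, abs(_exact_rank_sum_p(a, b) - _normal_rank_sum_p(a, b)))
        assert worst < 0.01

    def test_planted_shift_has_smallest_adjusted_p(self, rng):
        n_genes = 100
        expr = rng.normal(0, 1, (n_genes, 60))
        expr[17, 30:] += 3.0  # 3 SD shift in group b
        table = st.wilcoxon_de(expr, list(range(30)), list(range(30, 60)), min_frac=0.0)
        assert table.iloc[0]["gene"] == "gene17"

    def test_bh_adjustment_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        from spotstack.spotgraph import _bh_adjust

        p = rng.random(40)
        np.testing.assert_allclose(_bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_group_preconditions(self):
        expr = np.ones((2, 6))
        with pytest.raises(ValueError):
            st.wilcoxon_de(expr, [0, 1, 2], [2, 3, 4])
        with pytest.raises(ValueError):
            st.wilcoxon_de(expr, [0], [1, 2])

    def test_min_frac_skips_undetected_genes(self):
        expr = np.zeros((2, 8))
        expr[0] = [5, 6, 7, 8, 1, 2, 3, 4]
        table = st.wilcoxon_de(expr, [0, 1, 2, 3], [4, 5, 6, 7], min_frac=0.1)
        assert list(table["gene"]) == ["gene0"]
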