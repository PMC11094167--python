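import networkx as nx
import numpy as np
import pytest

from conftest import make_graph, make_table, random_graph
from oracles import brute_assortativity, brute_homophily, brute_stem_stats
from spherograph import (
    assortativity,
    build_graph,
    compute_stats,
    homophily_ratio,
    stem_subgraph_stats,
)
from spherograph.graph_analysis import CellGraph

S, D = True, False


def path_SDS():
    return make_graph([(0, 0), (1, 0), (2, 0)], [S, D, S], [(0, 1), (1, 2)])


def triangle_SSD():
    return make_graph([(0, 0), (1, 0), (0.5, 1)], [S, S, D], [(0, 1), (1, 2), (0, 2)])


class TestBuildGraph:
    def test_triangle(self):
        table = make_table([(0, 0), (4, 0), (2, 3)], ["stem", "stem", "differentiated"])
        g = build_graph(table)
        assert g.n_edges == 3

    def test_convex_quadrilateral_five_edges(self):
        table = make_table(
            [(0, 0), (10, 0), (10, 10), (0, 10)],
            ["stem", "differentiated", "stem", "differentiated"],
        )
        assert build_graph(table).n_edges == 5

    def test_unclassified_rejected(self):
        table = make_table([(0, 0), (1, 0), (0, 1)], ["unassigned"] * 3)
        with pytest.raises(ValueError, match="unclassified"):
            build_graph(table)

    def test_collinear_rejected(self):
        table = make_table([(0, 0), (1, 1), (2, 2)], ["stem"] * 3)
        with pytest.raises(ValueError, match="degenerate"):
            build_graph(table)

    def test_edges_match_independent_triangulation(self):
        """Edge set equals a re-triangulation through networkx/scipy by an
        independent path (Delaunay via graph adjacency of simplices)."""
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (50, 2))
        table = make_table(pts, ["stem"] * 25 + ["differentiated"] * 25)
        g = build_graph(table)
        from scipy.spatial import Delaunay

        tri = Delaunay(pts)
        expected = set()
        for simplex in tri.simplices:
            for i in range(3):
                a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
                expected.add((a, b))
        got = {tuple(e) for e in g.edges}
        assert got == expected


class TestHandWorkedExamples:
    def test_path_SDS(self):
        g = path_SDS()
        assert assortativity(g) == pytest.approx(-1.0)
        assert homophily_ratio(g) == 0.0
        comps, mean_deg, _ = stem_subgraph_stats(g)
        assert (comps, mean_deg) == (2, 0.0)

    def test_triangle_SSD(self):
        g = triangle_SSD()
        # mixing matrix: e_SS = 1/3, a_S = 2/3 -> r = (1/3 - 5/9)/(1 - 5/9)
        assert assortativity(g) == pytest.approx(-0.5)
        assert homophily_ratio(g) == pytest.approx(1 / 3)
        comps, mean_deg, hist = stem_subgraph_stats(g)
        assert comps == 1 and mean_deg == 1.0
        assert list(hist) == [0, 2]  # both stem nodes have degree 1

    def test_perfect_homophily(self):
        g = make_graph(
            [(0, 0), (1, 0), (5, 0), (6, 0)], [S, S, D, D], [(0, 1), (2, 3)]
        )
        assert assortativity(g) == pytest.approx(1.0)
        assert homophily_ratio(g) == 1.0

    def test_all_stem_triangle(self):
        g = make_graph([(0, 0), (1, 0), (0, 1)], [S, S, S], [(0, 1), (1, 2), (0, 2)])
        assert assortativity(g) is None  # single phenotype: undefined
        assert homophily_ratio(g) == 1.0
        comps, mean_deg, _ = stem_subgraph_stats(g)
        assert comps == 1 and mean_deg == 2.0

    def test_edgeless_graph_undefined(self):
        g = make_graph([(0, 0), (1, 1)], [S, D], np.zeros((0, 2), int))
        with pytest.warns(UserWarning):
            assert assortativity(g) is None
        with pytest.warns(UserWarning):
            assert homophily_ratio(g) is None

    def test_no_stem_cells(self):
        g = make_graph([(0, 0), (1, 0)], [D, D], [(0, 1)])
        with pytest.warns(UserWarning, match="no stem"):
            comps, mean_deg, hist = stem_subgraph_stats(g)
        assert (comps, mean_deg, len(hist)) == (0, 0.0, 0)


class TestAgainstOracles:
    def test_random_small_graphs_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            g = random_graph(rng)
            edges = [tuple(e) for e in g.edges]
            r = assortativity(g) if g.n_edges else None
            assert _close(r, brute_assortativity(g.n_nodes, edges, g.stem))
            h = homophily_ratio(g) if g.n_edges else None
            assert _close(h, brute_homophily(edges, g.stem))
            comps, mean_deg, _ = (
                stem_subgraph_stats(g) if g.n_stem else (0, 0.0, None)
            )
            bc, bd = brute_stem_stats(g.n_nodes, edges, g.stem)
            assert comps == bc and mean_deg == pytest.approx(bd)

    def test_assortativity_matches_networkx(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = random_graph(rng)
            if g.n_edges == 0 or g.n_stem in (0, g.n_nodes):
                continue
            nxg = g.to_networkx()
            expected = nx.attribute_assortativity_coefficient(nxg, "phenotype")
            if np.isnan(expected):
                continue
            assert assortativity(g) == pytest.approx(expected, abs=1e-9)


class TestInvariances:
    def test_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = random_graph(rng)
            if g.n_edges == 0:
                continue
            shuffled = CellGraph(
                cell_ids=rng.permutation(1000)[: g.n_nodes] + 1,
                positions=g.positions,
                stem=g.stem,
                edges=g.edges,
            )
            assert _close(assortativity(g), assortativity(shuffled))
            assert _close(homophily_ratio(g), homophily_ratio(shuffled))

    def test_phenotype_swap_symmetry(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            g = random_graph(rng)
            if g.n_edges == 0:
                continue
            swapped = g.with_stem(~g.stem)
            assert _close(assortativity(g), assortativity(swapped))
            assert _close(homophily_ratio(g), homophily_ratio(swapped))

    def test_adding_ss_edge_monotone(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            g = random_graph(rng)
            stems = np.flatnonzero(g.stem)
            if len(stems) < 2:
                continue
            existing = {tuple(e) for e in g.edges}
            candidates = [
                (a, b)
                for i, a in enumerate(stems)
                for b in stems[i + 1 :]
                if (a, b) not in existing
            ]
            if not candidates:
                continue
            new_edges = np.vstack([g.edges.reshape(-1, 2), candidates[0]])
            g2 = CellGraph(g.cell_ids, g.positions, g.stem, new_edges)
            c1, d1, _ = stem_subgraph_stats(g)
            c2, d2, _ = stem_subgraph_stats(g2)
            assert c2 <= c1
            assert d2 >= d1

    def test_stats_bounds(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            g = random_graph(rng)
            if g.n_edges == 0 or g.n_stem == 0:
                continue
            st = compute_stats(g)
            assert 0 <= st.homophily_ratio <= 1
            assert st.stem_components <= st.n_stem
            assert st.stem_mean_degree <= max(st.n_stem - 1, 0)
            if st.assortativity is not None:
                assert -1 - 1e-9 <= st.assortativity <= 1 + 1e-9


def _close(a, b):
    if a is None or b is None:
        return a is None and b is None
    return abs(a - b) < 1e-9
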