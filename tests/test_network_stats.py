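import itertools
import math

import networkx as nx
import numpy as np
import pytest

from asnet import (
    SimConfig,
    SimilarityMatrix,
    build_asn,
    centralization,
    cluster_coefficient,
    compute_stats,
    connectivity_threshold,
    density,
    distance_matrices,
    interval_stats,
    node_centralities,
    similarity_matrix,
    similarity_radius,
    simulate_assemblage,
    unit_stats,
)


# --- brute-force oracles ----------------------------------------------------

def brute_density(g):
    n = g.number_of_nodes()
    return 2 * g.number_of_edges() / (n * (n - 1))


def brute_transitivity(g):
    nodes = list(g.nodes())
    triangles = sum(
        1
        for a, b, c in itertools.combinations(nodes, 3)
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c)
    )
    triples = sum(
        1
        for a, b, c in itertools.permutations(nodes, 3)
        if g.has_edge(a, b) and g.has_edge(b, c)
    ) / 2
    return 3 * triangles / triples if triples else 0.0


def _all_shortest_paths(g, s, t):
    """All shortest s-t paths by exhaustive simple-path enumeration."""
    best, paths = math.inf, []

    def extend(path):
        nonlocal best, paths
        u = path[-1]
        if u == t:
            if len(path) < best:
                best, paths = len(path), [list(path)]
            elif len(path) == best:
                paths.append(list(path))
            return
        if len(path) >= best:
            return
        for v in g.neighbors(u):
            if v not in path:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_betweenness(g):
    bet = {n: 0.0 for n in g.nodes()}
    for s, t in itertools.combinations(g.nodes(), 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bet[v] += 1.0 / len(paths)
    return bet


def random_graph(rng, n, p=0.4):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(i, j, weight=rng.uniform(0.1, 1.0))
    return g


# --- tests ------------------------------------------------------------------


class TestDensityAndClustering:
    def test_complete_graph(self):
        g = nx.complete_graph(4)
        assert density(g) == 1.0
        assert cluster_coefficient(g, "transitivity") == 1.0
        assert cluster_coefficient(g, "avg_local") == 1.0

    def test_edgeless_and_star(self):
        g = nx.empty_graph(5)
        assert density(g) == 0.0
        star = nx.star_graph(4)
        assert cluster_coefficient(star, "transitivity") == 0.0
        assert cluster_coefficient(star, "avg_local") == 0.0

    def test_density_counts_isolates(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        g.add_edge(0, 1)
        assert density(g) == pytest.approx(1 / 6)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            g = random_graph(rng, int(rng.integers(4, 11)))
            assert density(g) == pytest.approx(brute_density(g))
            assert cluster_coefficient(g, "transitivity") == pytest.approx(
                brute_transitivity(g)
            )


class TestCentralities:
    def test_path_betweenness(self):
        g = nx.path_graph(["A", "B", "C"])
        nx.set_edge_attributes(g, 1.0, "weight")
        cent = node_centralities(g).set_index("node")
        assert cent.loc["B", "betweenness"] == pytest.approx(1.0)
        assert cent.loc["A", "betweenness"] == 0.0

    def test_strength_sums_incident_weights(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.5)
        g.add_edge("A", "C", weight=0.7)
        cent = node_centralities(g).set_index("node")
        assert cent.loc["A", "strength"] == pytest.approx(1.2)

    def test_betweenness_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            g = random_graph(rng, int(rng.integers(4, 11)))
            if g.number_of_edges() == 0:
                continue
            cent = node_centralities(g).set_index("node")
            oracle = brute_betweenness(g)
            for n, b in oracle.items():
                assert cent.loc[n, "betweenness"] == pytest.approx(b, abs=1e-9)

    def test_eigenvector_mean_one_and_scale_invariant(self):
        rng = np.random.default_rng(13)
        g = random_graph(rng, 8, p=0.7)
        cent = node_centralities(g).set_index("node")
        assert cent["eigenvector"].mean() == pytest.approx(1.0)
        g2 = g.copy()
        for u, v in g2.edges():
            g2.edges[u, v]["weight"] *= 3.7
        cent2 = node_centralities(g2).set_index("node")
        assert np.allclose(cent["eigenvector"], cent2["eigenvector"], atol=1e-8)

    def test_eigenvector_undefined_on_edgeless_graph(self):
        with pytest.raises(ValueError):
            node_centralities(nx.empty_graph(3))


class TestCentralization:
    def test_star_graph_degree_is_one(self):
        star = nx.star_graph(5)
        nx.set_edge_attributes(star, 1.0, "weight")
        cent = node_centralities(star)
        assert centralization(cent["strength"], "degree") == pytest.approx(1.0)
        assert centralization(cent["betweenness"], "betweenness") == pytest.approx(1.0)
        assert centralization(cent["eigenvector"], "eigenvector") == pytest.approx(
            1.0, abs=1e-6
        )

    def test_regular_graph_is_zero(self):
        ring = nx.cycle_graph(6)
        nx.set_edge_attributes(ring, 1.0, "weight")
        cent = node_centralities(ring)
        for kind, col in (
            ("degree", "strength"),
            ("eigenvector", "eigenvector"),
            ("betweenness", "betweenness"),
        ):
            assert centralization(cent[col], kind) == pytest.approx(0.0, abs=1e-6)

    def test_bounds_on_random_graphs(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            g = random_graph(rng, 9, p=0.5)
            if g.number_of_edges() == 0:
                continue
            cent = node_centralities(g)
            for kind, col in (
                ("degree", "strength"),
                ("eigenvector", "eigenvector"),
                ("betweenness", "betweenness"),
            ):
                assert 0.0 <= centralization(cent[col], kind) <= 1.0

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError):
            centralization([1.0], "degree")


class TestIntervals:
    def _setup(self, seed=21):
        a = simulate_assemblage(SimConfig(seed=seed))
        sim = similarity_matrix(a)
        dist = distance_matrices(a)
        t = connectivity_threshold(sim).threshold
        return build_asn(sim, t, a), sim, dist

    def test_single_edge_collapses(self):
        net, sim, dist = self._setup()
        u, v = next(iter(net.edges()))
        single = nx.Graph()
        single.add_nodes_from(net.nodes())
        single.add_edge(u, v, weight=net.edges[u, v]["weight"])
        iv = interval_stats(single, dist)
        for name in ("edge_weight", "geo_km", "chrono_years"):
            assert iv[name].min == iv[name].mean == iv[name].max

    def test_min_le_mean_le_max_and_argpairs(self):
        net, sim, dist = self._setup()
        iv = interval_stats(net, dist)
        for name, interval in iv.items():
            assert interval.min <= interval.mean <= interval.max
        w = iv["edge_weight"]
        assert net.edges[w.argmax]["weight"] == pytest.approx(w.max)
        assert net.edges[w.argmin]["weight"] == pytest.approx(w.min)
        # retained edges respect the threshold
        assert w.min >= net.graph["threshold"]

    def test_complete_graph_reproduces_matrix_extrema(self):
        a = simulate_assemblage(SimConfig(seed=22))
        sim = similarity_matrix(a)
        dist = distance_matrices(a)
        net = build_asn(sim, 0.0, a)
        iv = interval_stats(net, dist)
        iu, ju = np.triu_indices(sim.n, k=1)
        assert iv["geo_km"].max == pytest.approx(dist.geo_km[iu, ju].max())
        assert iv["geo_km"].min == pytest.approx(dist.geo_km[iu, ju].min())
        assert iv["chrono_years"].max == pytest.approx(dist.chrono_years[iu, ju].max())
        assert iv["edge_weight"].min == pytest.approx(sim.S[iu, ju].min())

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            interval_stats(nx.empty_graph(3))


class TestUnitStats:
    def test_clique_unit_has_density_one(self):
        g = nx.Graph()
        g.add_edges_from(
            [(a, b, {"weight": 1.0}) for a, b in itertools.combinations("ABC", 2)]
        )
        g.add_node("D")
        assert unit_stats(g, ["A", "B", "C"])["density"] == 1.0

    def test_singleton_unit_rejected(self):
        g = nx.complete_graph(3)
        with pytest.raises(ValueError):
            unit_stats(g, [0])

    def test_induced_subgraph_only(self):
        # D connects A and B from outside the unit; the unit subgraph has no
        # edge, so unit density must be 0
        g = nx.Graph()
        g.add_edge("A", "D", weight=1.0)
        g.add_edge("B", "D", weight=1.0)
        assert unit_stats(g, ["A", "B"])["density"] == 0.0


class TestSimilarityRadius:
    def _pair_setup(self, s, km):
        sim = SimilarityMatrix(
            ids=["A", "B"], S=np.array([[1.0, s], [s, 1.0]]), index="BR"
        )

        class Dist:
            def pair(self, i, j):
                return km, 0.0

        return sim, Dist()

    def test_distance_divided_by_similarity(self):
        sim, dist = self._pair_setup(0.5, 100.0)
        rad = similarity_radius(["A", "B"], sim, dist)
        assert rad == {"min": 200.0, "mean": 200.0, "max": 200.0}

    def test_zero_distance_is_zero_radius(self):
        sim, dist = self._pair_setup(0.3, 0.0)
        assert similarity_radius(["A", "B"], sim, dist)["max"] == 0.0

    def test_zero_similarity_is_infinite_radius(self):
        sim, dist = self._pair_setup(0.0, 50.0)
        rad = similarity_radius(["A", "B"], sim, dist)
        assert rad["max"] == math.inf and rad["mean"] == math.inf

    def test_single_member_unit_degenerate_triple(self):
        sim, dist = self._pair_setup(0.5, 100.0)
        rad = similarity_radius(["A"], sim, dist)
        assert rad["min"] == math.inf
        assert rad["max"] == -math.inf
        assert math.isnan(rad["mean"])

    def test_threshold_scope_bounded_by_full_scope(self):
        a = simulate_assemblage(SimConfig(seed=23))
        sim = similarity_matrix(a)
        dist = distance_matrices(a)
        net = build_asn(sim, connectivity_threshold(sim).threshold, a)
        members = [r.occupation_id for r in a.records if r.culture == "RPC"]
        full = similarity_radius(members, sim, dist)
        thr = similarity_radius(members, sim, dist, network=net)
        if not math.isnan(thr["mean"]):
            assert thr["max"] <= full["max"] + 1e-9
            assert thr["min"] >= full["min"] - 1e-9


class TestComputeStats:
    def test_report_shape_and_consistency(self):
        a = simulate_assemblage(SimConfig(seed=24))
        sim = similarity_matrix(a)
        dist = distance_matrices(a)
        net = build_asn(sim, connectivity_threshold(sim).threshold, a)
        report = compute_stats(net, sim, dist)
        assert len(report.node_level) == a.n
        assert report.network_level["density"] == pytest.approx(density(net))
        assert 0.0 <= report.network_level["cluster_coefficient"] <= 1.0
        for k in ("degree", "eigen", "betweenness"):
            assert 0.0 <= report.network_level[f"centralization_{k}"] <= 1.0
        units = report.unit_level.set_index("unit")
        # synthetic defaults use IMP / RPC / LCE: one per main cultural unit
        assert units.loc["Impressa", "n_members"] == 12
        assert units.loc["Cardial", "n_members"] == 12
        frame = report.network_level_frame()
        assert set(frame.columns) == {"statistic", "value"}
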