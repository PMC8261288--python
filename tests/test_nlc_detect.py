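import math

import networkx as nx
import pytest

from nlcomm import (
    NLCParams,
    assign_noncentral_edges,
    build_central_edge_sets,
    canonical_edge,
    compute_scores,
    edge_distance,
    edge_jaccard_distance,
    edge_link_distance,
    edges_to_node_cover,
    onmi,
    overlap_rate,
    prune_overlaps,
    run_nlc,
    select_central_nodes,
    two_clique_bridge,
)
from nlcomm.synthetic_bench import PlantedConfig, generate_planted

from conftest import random_graph, str_graph


def cover_key(cover):
    return sorted(frozenset(c) for c in cover)


class TestNLCParams:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": -0.1}, {"alpha": 1.5}, {"prune": 2.0}, {"gf": 0.0}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NLCParams(**kwargs)

    def test_gf_defaults_to_edge_node_ratio(self):
        g = str_graph(nx.complete_graph(4))  # 6 edges, 4 nodes
        assert NLCParams().resolve_gf(g) == pytest.approx(1.5)


class TestSelectCentralNodes:
    def test_bridged_triangles_one_seed_each(self, bridged_triangles):
        scores = compute_scores(bridged_triangles)
        cn = select_central_nodes(bridged_triangles, scores, NLCParams(alpha=0.5))
        assert len(cn) == 2
        assert len(set(cn) & {"a", "b", "c"}) == 1
        assert len(set(cn) & {"d", "e", "f"}) == 1

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 0.7, 1.0])
    def test_complete_graph_single_seed(self, alpha):
        g = str_graph(nx.complete_graph(4))
        scores = compute_scores(g)
        cn = select_central_nodes(g, scores, NLCParams(alpha=alpha))
        assert len(cn) == 1

    def test_star_hub_only(self):
        g = str_graph(nx.star_graph(5))
        scores = compute_scores(g)
        assert select_central_nodes(g, scores, NLCParams(alpha=0.5)) == ["0"]

    def test_empty_graph(self):
        assert select_central_nodes(nx.Graph(), compute_scores(nx.Graph()),
                                    NLCParams()) == []


class TestBuildCentralEdgeSets:
    def test_above_average_similarity_edge_selected(self):
        g = nx.Graph()
        scores_obj = compute_scores  # placeholder to keep imports honest
        # central node u with neighbor sims {0.6, 0.2, 0.2}: only the
        # 0.6-edge beats the mean 1/3.  Build via a stub sim table.
        from nlcomm.node_metrics import NodeScoreTable

        g.add_edges_from([("u", "a"), ("u", "b"), ("u", "c")])
        scores = NodeScoreTable(graph=g)
        scores._sim_cache = {
            ("a", "u"): 0.6,
            ("b", "u"): 0.2,
            ("c", "u"): 0.2,
        }
        ces = build_central_edge_sets(g, ["u"], scores)
        assert ces.edge_sets == [{canonical_edge("u", "a")}]

    def test_star_hub_fallback_to_max_sim(self):
        g = str_graph(nx.star_graph(4))
        scores = compute_scores(g)  # all leaf sims are 0
        ces = build_central_edge_sets(g, ["0"], scores)
        assert ces.edge_sets[0] == {canonical_edge("0", str(i)) for i in range(1, 5)}

    def test_central_edges_stay_inside_their_clique(self):
        planted = two_clique_bridge(5)
        g = planted.graph
        scores = compute_scores(g)
        cn = select_central_nodes(g, scores, NLCParams(alpha=0.5))
        ces = build_central_edge_sets(g, cn, scores)
        cliques = [set(c) for c in planted.cover]
        for center, es in zip(ces.centers, ces.edge_sets):
            homes = [c for c in cliques if center in c]
            for u, v in es:
                assert any(u in c and v in c for c in homes)

    def test_no_edge_claimed_twice(self):
        g = random_graph(25, 0.2, seed=8)
        scores = compute_scores(g)
        cn = select_central_nodes(g, scores, NLCParams(alpha=0.8))
        ces = build_central_edge_sets(g, cn, scores)
        all_edges = [e for es in ces.edge_sets for e in es]
        assert len(all_edges) == len(set(all_edges))
        for center, es in zip(ces.centers, ces.edge_sets):
            for e in es:
                assert center in e


class TestEdgeDistances:
    def test_identical_edges(self):
        g = str_graph(nx.path_graph(4))
        e = ("0", "1")
        assert edge_link_distance(g, e, e) == 0.0
        assert edge_jaccard_distance(g, e, e) == 0.0
        assert edge_distance(g, e, e) == 0.0

    def test_adjacent_edges_link_one(self):
        g = str_graph(nx.path_graph(3))
        assert edge_link_distance(g, ("0", "1"), ("1", "2")) == 1.0

    def test_path_end_edges_link_two(self):
        g = str_graph(nx.path_graph(4))
        assert edge_link_distance(g, ("0", "1"), ("2", "3")) == 2.0

    def test_path3_neighborhoods_coincide(self):
        # S(e(0,1)) = S(e(1,2)) = {0,1,2} on a 3-path
        g = str_graph(nx.path_graph(3))
        assert edge_jaccard_distance(g, ("0", "1"), ("1", "2")) == 0.0
        assert edge_distance(g, ("0", "1"), ("1", "2")) == 0.0

    def test_disconnected_pair(self, two_triangles):
        assert edge_jaccard_distance(two_triangles, ("0", "1"), ("3", "4")) == 1.0
        assert math.isinf(edge_link_distance(two_triangles, ("0", "1"), ("3", "4")))
        assert math.isinf(edge_distance(two_triangles, ("0", "1"), ("3", "4")))

    @pytest.mark.parametrize("seed", range(4))
    def test_link_distance_matches_bfs_oracle(self, seed):
        g = random_graph(12, 0.25, seed=seed)
        apsp = dict(nx.all_pairs_shortest_path_length(g))
        edges = [canonical_edge(*e) for e in g.edges()]
        for e1 in edges:
            for e2 in edges:
                got = edge_link_distance(g, e1, e2)
                if e1 == e2:
                    assert got == 0.0
                    continue
                best = min(
                    (
                        apsp[x][y]
                        for x in e1
                        for y in e2
                        if y in apsp.get(x, {})
                    ),
                    default=math.inf,
                )
                assert got == (1.0 + best if best < math.inf else math.inf)

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry_and_identity_of_indiscernibles(self, seed):
        g = random_graph(10, 0.3, seed=seed)
        edges = [canonical_edge(*e) for e in g.edges()]
        for e1 in edges:
            for e2 in edges:
                d = edge_distance(g, e1, e2)
                assert d == edge_distance(g, e2, e1)
                if e1 == e2:
                    assert d == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_link_triangle_inequality_within_one(self, seed):
        """link is a hop metric on the line graph shifted by 1, so
        link(a,c) <= link(a,b) + link(b,c) + 1 on connected triples."""
        g = random_graph(10, 0.35, seed=seed)
        edges = [canonical_edge(*e) for e in g.edges()][:12]
        for ea in edges:
            for eb in edges:
                for ec in edges:
                    dab = edge_link_distance(g, ea, eb)
                    dbc = edge_link_distance(g, eb, ec)
                    dac = edge_link_distance(g, ea, ec)
                    if math.isfinite(dab) and math.isfinite(dbc):
                        assert dac <= dab + dbc + 1.0


class TestAssignNoncentralEdges:
    def _pipeline(self, g, alpha=0.5):
        scores = compute_scores(g)
        cn = select_central_nodes(g, scores, NLCParams(alpha=alpha))
        ces = build_central_edge_sets(g, cn, scores)
        return ces, assign_noncentral_edges(g, ces)

    def test_clique_edges_join_their_clique(self):
        planted = two_clique_bridge(4)
        g = planted.graph
        ces, ec = self._pipeline(g)
        cliques = [set(c) - {"a0", "b0"} for c in planted.cover]
        # map community index -> clique by its central node
        for e, i in ec.items():
            if i is None:
                continue
            u, v = e
            if u.startswith("a") and v.startswith("a"):
                assert ces.centers[i].startswith("a")
            if u.startswith("b") and v.startswith("b"):
                assert ces.centers[i].startswith("b")

    def test_central_edges_keep_their_community(self):
        g = random_graph(20, 0.25, seed=13)
        ces, ec = self._pipeline(g)
        for i, es in enumerate(ces.edge_sets):
            for e in es:
                assert ec[e] == i

    def test_seedless_component_unassigned(self, two_triangles):
        scores = compute_scores(two_triangles)
        from nlcomm.nlc_detect import CentralEdgeSets

        ces = CentralEdgeSets(
            centers=["0"], edge_sets=[{canonical_edge("0", "1")}]
        )
        ec = assign_noncentral_edges(two_triangles, ces)
        for e, i in ec.items():
            if set(e) <= {"3", "4", "5"}:
                assert i is None
            else:
                assert i == 0

    def test_every_edge_appears(self):
        g = random_graph(18, 0.2, seed=21)
        _, ec = self._pipeline(g)
        assert set(ec.keys()) == {canonical_edge(*e) for e in g.edges()}


class TestEdgesToNodeCover:
    def test_single_community_covers_all_edge_endpoints(self):
        g = str_graph(nx.path_graph(5))
        ec = {canonical_edge(*e): 0 for e in g.edges()}
        cover = edges_to_node_cover(g, ec)
        assert cover == [set(g.nodes())]

    def test_bridge_node_overlaps(self):
        g = str_graph(nx.path_graph(3))
        ec = {canonical_edge("0", "1"): 0, canonical_edge("1", "2"): 1}
        cover = edges_to_node_cover(g, ec)
        assert "1" in cover[0] and "1" in cover[1]

    def test_unassigned_edges_ignored(self):
        g = str_graph(nx.path_graph(3))
        ec = {canonical_edge("0", "1"): 0, canonical_edge("1", "2"): None}
        cover = edges_to_node_cover(g, ec)
        assert cover == [{"0", "1"}]


class TestPruneOverlaps:
    def test_weak_membership_dropped(self):
        # node x: 4 edges into community 0's core, 1 into community 1's
        g = nx.Graph()
        c0 = [f"p{i}" for i in range(4)]
        c1 = [f"q{i}" for i in range(4)]
        for grp in (c0, c1):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(grp[i], grp[j])
        for p in c0:
            g.add_edge("x", p)
        g.add_edge("x", "q0")
        cover = [set(c0) | {"x"}, set(c1) | {"x"}]
        out = prune_overlaps(g, cover, NLCParams(prune=0.3))
        assert cover_key(out) == cover_key([set(c0) | {"x"}, set(c1)])

    def test_all_ratios_below_keeps_best_only(self):
        # star-of-cliques: x touches each community's core once -> all
        # ratios 1/3 < prune; x stays only in the lowest-index community
        g = nx.Graph()
        cover = []
        for ci, pref in enumerate("pqr"):
            grp = [f"{pref}{i}" for i in range(3)]
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(grp[i], grp[j])
            g.add_edge("x", grp[0])
            cover.append(set(grp) | {"x"})
        out = prune_overlaps(g, cover, NLCParams(prune=0.5))
        memberships = [i for i, c in enumerate(out) if "x" in c]
        assert memberships == [0]

    def test_small_communities_never_pruned(self):
        g = nx.Graph()
        big = [f"p{i}" for i in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(big[i], big[j])
        for p in big:
            g.add_edge("x", p)
        g.add_edge("x", "tiny")
        cover = [set(big) | {"x"}, {"tiny", "x"}]  # second community size 2
        out = prune_overlaps(g, cover, NLCParams(prune=0.9))
        assert {"tiny", "x"} in out

    def test_zero_denominator_keeps_all(self):
        # both communities are entirely overlapping nodes: no cores exist
        g = nx.Graph([("x", "y"), ("y", "z"), ("x", "z")])
        cover = [{"x", "y", "z"}, {"x", "y", "z"}]
        out = prune_overlaps(g, cover, NLCParams(prune=0.9, min_prune_size=0))
        assert cover_key(out) == cover_key(cover)

    def test_membership_counts_never_increase(self):
        pt = generate_planted(
            PlantedConfig(n=60, k_avg=8, mu=0.2, on=6, om=2, n_comm=6, seed=4)
        )
        cover = run_nlc(pt.graph, NLCParams(alpha=0.3, prune=0.0))
        before = {}
        for c in cover:
            for n in c:
                before[n] = before.get(n, 0) + 1
        out = prune_overlaps(pt.graph, cover, NLCParams(prune=0.6))
        after = {}
        for c in out:
            for n in c:
                after[n] = after.get(n, 0) + 1
        for n, cnt in after.items():
            assert 1 <= cnt <= before[n]
        assert all(len(c) >= 1 for c in out)


class TestRunNLC:
    def test_two_disjoint_triangles(self, two_triangles):
        cover = run_nlc(two_triangles, NLCParams(alpha=0.5, prune=0.3))
        assert cover_key(cover) == [
            frozenset({"0", "1", "2"}),
            frozenset({"3", "4", "5"}),
        ]

    def test_single_clique(self):
        g = str_graph(nx.complete_graph(5))
        cover = run_nlc(g, NLCParams(alpha=0.5))
        assert cover == [set(g.nodes())]

    def test_edgeless_graph_empty_cover(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert run_nlc(g, NLCParams()) == []

    def test_deterministic(self):
        pt = generate_planted(
            PlantedConfig(n=70, k_avg=8, mu=0.15, on=6, om=2, n_comm=7, seed=9)
        )
        params = NLCParams(alpha=0.3, prune=0.3)
        c1 = run_nlc(pt.graph, params)
        c2 = run_nlc(pt.graph, params)
        assert c1 == c2

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_three_communities_recovered(self, seed):
        g = nx.planted_partition_graph(3, 15, 0.9, 0.05, seed=seed)
        truth = [set(map(str, c)) for c in g.graph["partition"]]
        g = str_graph(g)
        cover = run_nlc(g, NLCParams(alpha=0.3, prune=0.3))
        assert onmi(truth, cover, set(g.nodes())) >= 0.9

    def test_degenerate_params_smoke(self):
        pt = generate_planted(
            PlantedConfig(n=50, k_avg=6, mu=0.3, on=5, om=2, n_comm=5, seed=2)
        )
        cover = run_nlc(pt.graph, NLCParams(alpha=1.0, prune=0.0))
        assert cover and all(len(c) >= 1 for c in cover)
        nodes = set(pt.graph.nodes())
        assert all(c <= nodes for c in cover)

    def test_overlap_rate_monotone_in_prune(self):
        pt = generate_planted(
            PlantedConfig(n=80, k_avg=10, mu=0.2, on=8, om=2, n_comm=8, seed=3)
        )
        rates = [
            overlap_rate(run_nlc(pt.graph, NLCParams(alpha=0.3, prune=p)))
            for p in (0.0, 0.15, 0.3, 0.45, 0.6, 0.8)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rates, rates[1:]))
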