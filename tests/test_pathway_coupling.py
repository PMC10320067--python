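"""Residue graph, shortest regulation pathways, hierarchy and coupling.

The shortest-path oracle is exhaustive enumeration of all simple paths;
coupling checks include the hand-worked asymmetric example
({r1..r4} vs {r1,r2,r5}: 0.5 one way, 2/3 the other).
"""

import networkx as nx
import numpy as np
import pytest

from allomap.enm_dynamics import CorrelationMatrix, EnmNetwork, LigandNode
from allomap.errors import UnreachableLigandError, UnreachableSinkError
from allomap.fixtures import make_random_graph
from allomap.pathway_coupling import (
    RegulationPathway,
    build_hierarchy,
    build_residue_graph,
    coupling_matrix,
    export_coupling,
    parse_coupling,
    shortest_pathway,
)
from allomap.structure_io import ResidueId


def _rid(n):
    return ResidueId("A", n, "", "ALA")


ANCHOR = LigandNode("LIG", "A", 900)


def _graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    g.graph["anchor"] = ANCHOR
    return g


def _brute_force_shortest(g, source, sink):
    best = None
    for path in nx.all_simple_paths(g, source, sink):
        cost = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        if best is None or cost < best:
            best = cost
    return best


class TestBuildResidueGraph:
    def _net_and_corr(self, coords, c_vals, with_ligand=True):
        nodes = [_rid(i + 1) for i in range(len(coords) - 1)]
        if with_ligand:
            nodes = nodes + [ANCHOR]
        else:
            nodes = [_rid(i + 1) for i in range(len(coords))]
        net = EnmNetwork(nodes=nodes, coords=np.asarray(coords, float),
                         cutoff=10.0)
        return net, CorrelationMatrix(values=np.asarray(c_vals, float),
                                      nodes=nodes)

    def test_reciprocal_weight(self):
        net, c = self._net_and_corr(
            [[0, 0, 0], [5, 0, 0]], [[1.0, 0.5], [0.5, 1.0]]
        )
        g = build_residue_graph(net, c)
        assert g[_rid(1)][ANCHOR]["weight"] == pytest.approx(2.0)

    def test_negative_correlation_same_weight(self):
        net, c = self._net_and_corr(
            [[0, 0, 0], [5, 0, 0]], [[1.0, -0.5], [-0.5, 1.0]]
        )
        g = build_residue_graph(net, c)
        assert g[_rid(1)][ANCHOR]["weight"] == pytest.approx(2.0)

    def test_non_contact_pair_has_no_edge(self):
        # three nodes in a row; the far pair correlates strongly but is
        # beyond the contact cutoff, so no edge joins it
        net, c = self._net_and_corr(
            [[0, 0, 0], [8, 0, 0], [16, 0, 0]],
            [[1.0, 0.5, 0.99], [0.5, 1.0, 0.5], [0.99, 0.5, 1.0]],
        )
        g = build_residue_graph(net, c)
        assert not g.has_edge(_rid(1), ANCHOR) or net.adjacency[0, 2]
        assert not g.has_edge(net.nodes[0], net.nodes[2])

    def test_epsilon_floors_zero_correlation(self):
        net, c = self._net_and_corr(
            [[0, 0, 0], [5, 0, 0]], [[1.0, 0.0], [0.0, 1.0]]
        )
        g = build_residue_graph(net, c, epsilon=1e-6)
        assert g[_rid(1)][ANCHOR]["weight"] == pytest.approx(1e6)

    def test_isolated_anchor_rejected(self):
        net, c = self._net_and_corr(
            [[0, 0, 0], [50, 0, 0]], [[1.0, 0.0], [0.0, 1.0]]
        )
        with pytest.raises(UnreachableLigandError):
            build_residue_graph(net, c)


class TestShortestPathway:
    def test_two_hop_beats_direct_edge(self):
        a, b = _rid(1), _rid(2)
        g = _graph([(ANCHOR, a, 1.0), (a, b, 1.0), (ANCHOR, b, 3.0)])
        p = shortest_pathway(g, b, site_id=0)
        assert p.route == [ANCHOR, a, b]
        assert p.total_distance == pytest.approx(2.0)

    def test_direct_edge_optimal(self):
        a, b = _rid(1), _rid(2)
        g = _graph([(ANCHOR, a, 0.5), (a, b, 2.0), (ANCHOR, b, 1.0)])
        p = shortest_pathway(g, b, site_id=0)
        assert p.route == [ANCHOR, b]

    def test_lexicographic_tie_break(self):
        a, b, sink = _rid(1), _rid(2), _rid(3)
        g = _graph([(ANCHOR, a, 1.0), (ANCHOR, b, 1.0),
                    (a, sink, 1.0), (b, sink, 1.0)])
        p = shortest_pathway(g, sink, site_id=0)
        assert p.route == [ANCHOR, a, sink]  # residue 1 < residue 2

    def test_unreachable_sink_names_component(self):
        a, b, c = _rid(1), _rid(2), _rid(3)
        g = _graph([(ANCHOR, a, 1.0), (b, c, 1.0)])
        with pytest.raises(UnreachableSinkError) as exc:
            shortest_pathway(g, c, site_id=0)
        assert "A:ALA3" in str(exc.value) or "3" in str(exc.value)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        g = make_random_graph(n_nodes=8, seed=seed)
        anchor = g.graph["anchor"]
        for sink in g.nodes:
            if sink == anchor:
                continue
            p = shortest_pathway(g, sink, site_id=0)
            assert p.total_distance == pytest.approx(
                _brute_force_shortest(g, anchor, sink)
            )
            # the returned route realizes its declared total distance
            cost = sum(g[u][v]["weight"] for u, v in zip(p.route, p.route[1:]))
            assert cost == pytest.approx(p.total_distance, rel=1e-9)


class TestHierarchy:
    def test_identical_routes_share_one_chain(self):
        a, b = _rid(1), _rid(2)
        p1 = RegulationPathway(0, [ANCHOR, a, b], 2.0)
        p2 = RegulationPathway(1, [ANCHOR, a, b], 2.0)
        h = build_hierarchy([p1, p2])
        assert len(h.root.children) == 1
        leaf = h.root.children[0].children[0]
        assert sorted(leaf.site_ids) == [0, 1]

    def test_disjoint_routes_branch_at_root(self):
        p1 = RegulationPathway(0, [ANCHOR, _rid(1), _rid(2)], 2.0)
        p2 = RegulationPathway(1, [ANCHOR, _rid(3), _rid(4)], 2.0)
        h = build_hierarchy([p1, p2])
        assert len(h.root.children) == 2

    def test_shared_prefix_appears_once(self):
        a, b, c, d = _rid(1), _rid(2), _rid(3), _rid(4)
        p1 = RegulationPathway(0, [ANCHOR, a, b, c], 3.0)
        p2 = RegulationPathway(1, [ANCHOR, a, b, d], 3.0)
        h = build_hierarchy([p1, p2])
        assert len(h.root.children) == 1
        node_a = h.root.children[0]
        assert node_a.label == a and len(node_a.children) == 1
        node_b = node_a.children[0]
        assert node_b.label == b and len(node_b.children) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_route_reconstruction_fidelity(self, seed):
        g = make_random_graph(n_nodes=8, seed=seed)
        anchor = g.graph["anchor"]
        sinks = [n for n in g.nodes if n != anchor][:4]
        pathways = [shortest_pathway(g, s, i) for i, s in enumerate(sinks)]
        routes = build_hierarchy(pathways).routes()
        for p in pathways:
            assert routes[p.site_id] == p.route


class TestCoupling:
    def test_hand_worked_asymmetry(self):
        r = {i: _rid(i) for i in range(1, 6)}
        path_a = RegulationPathway(0, [ANCHOR, r[1], r[2], r[3], r[4]], 4.0)
        path_b = RegulationPathway(1, [ANCHOR, r[1], r[2], r[5]], 3.0)
        cm = coupling_matrix([path_a, path_b])
        assert cm.values[0, 1] == pytest.approx(0.5)      # 2 shared of 4
        assert cm.values[1, 0] == pytest.approx(2 / 3)    # 2 shared of 3

    def test_disjoint_pathways_zero(self):
        p1 = RegulationPathway(0, [ANCHOR, _rid(1), _rid(2)], 2.0)
        p2 = RegulationPathway(1, [ANCHOR, _rid(3), _rid(4)], 2.0)
        cm = coupling_matrix([p1, p2])
        assert cm.values[0, 1] == 0.0 and cm.values[1, 0] == 0.0

    def test_identical_pathways_one(self):
        p1 = RegulationPathway(0, [ANCHOR, _rid(1), _rid(2)], 2.0)
        p2 = RegulationPathway(1, [ANCHOR, _rid(1), _rid(2)], 2.0)
        cm = coupling_matrix([p1, p2])
        assert cm.values[0, 1] == 1.0 and cm.values[1, 0] == 1.0

    def test_subset_gives_full_coupling(self):
        p1 = RegulationPathway(0, [ANCHOR, _rid(1), _rid(2)], 2.0)
        p2 = RegulationPathway(1, [ANCHOR, _rid(1), _rid(2), _rid(3)], 3.0)
        cm = coupling_matrix([p1, p2])
        assert cm.values[0, 1] == 1.0  # residues(A) subset of residues(B)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_and_unit_diagonal(self, seed):
        g = make_random_graph(n_nodes=10, seed=seed)
        anchor = g.graph["anchor"]
        sinks = [n for n in g.nodes if n != anchor][:5]
        cm = coupling_matrix(
            [shortest_pathway(g, s, i) for i, s in enumerate(sinks)]
        )
        assert np.all(cm.values >= 0.0) and np.all(cm.values <= 1.0)
        assert np.allclose(np.diag(cm.values), 1.0)

    def test_export_parse_roundtrip(self):
        p1 = RegulationPathway(3, [ANCHOR, _rid(1), _rid(2)], 2.0)
        p2 = RegulationPathway(7, [ANCHOR, _rid(2), _rid(4)], 2.0)
        cm = coupling_matrix([p1, p2])
        back = parse_coupling(export_coupling(cm))
        assert back.site_ids == cm.site_ids
        assert np.allclose(back.values, cm.values)
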