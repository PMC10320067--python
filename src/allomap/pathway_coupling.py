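"""Regulation pathways and site-site couplings on the residue graph.

A residue graph is built on the holo elastic network (residue nodes plus
the ligand anchor): edges join contacting node pairs only, weighted by
the reciprocal of the motion-correlation magnitude,
d_ij = 1 / max(|C_ij|, epsilon) — strongly (anti)correlated contacts are
"close".  A site's regulation pathway is the minimum-total-distance
route from the ligand anchor to the site's highest-RAE residue
(Dijkstra; among equal-cost routes the lexicographically smallest node
sequence is returned for determinism).  Pathways assemble into a prefix
tree rooted at the anchor — the hierarchy of regulation — and the
coupling of site A by site B is the fraction of A's pathway residues
shared with B's pathway (sink and intermediates counted, the ligand
anchor excluded), which is asymmetric by construction and lies in [0, 1]
with unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import networkx as nx
import numpy as np

from .enm_dynamics import CorrelationMatrix, EnmNetwork, LigandNode
from .errors import UnreachableLigandError, UnreachableSinkError
from .structure_io import ResidueId

DEFAULT_EPSILON = 1e-6  # floors |C_ij| so edge weights stay finite


def _node_key(node: Hashable):
    # the ligand anchor sorts before every residue
    if isinstance(node, LigandNode):
        return (0, "", 0, "")
    return (1, node.chain, node.number, node.insertion_code)


def build_residue_graph(
    net: EnmNetwork,
    c: CorrelationMatrix,
    epsilon: float = DEFAULT_EPSILON,
) -> nx.Graph:
    """Weighted contact graph with the ligand anchor recorded in
    ``g.graph['anchor']``."""
    if list(net.nodes) != list(c.nodes):
        raise ValueError("network and correlation matrix disagree on node order")
    anchor_idx = net.ligand_index()
    if anchor_idx is None:
        raise UnreachableLigandError("network has no ligand anchor node")
    if not net.adjacency[anchor_idx].any():
        raise UnreachableLigandError(
            "ligand anchor contacts no residue within the cutoff"
        )
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    ii, jj = np.nonzero(np.triu(net.adjacency))
    for i, j in zip(ii, jj):
        w = 1.0 / max(abs(float(c.values[i, j])), epsilon)
        g.add_edge(net.nodes[i], net.nodes[j], weight=w)
    g.graph["anchor"] = net.nodes[anchor_idx]
    return g


@dataclass
class RegulationPathway:
    site_id: int
    route: list[Hashable]  # anchor first, top-RAE sink last
    total_distance: float

    @property
    def residue_set(self) -> frozenset[ResidueId]:
        """Route nodes excluding the ligand anchor (never empty: the sink
        itself always counts)."""
        return frozenset(n for n in self.route if not isinstance(n, LigandNode))


def shortest_pathway(g: nx.Graph, sink: ResidueId, site_id: int) -> RegulationPathway:
    """Minimum-weight route from the ligand anchor to ``sink``.

    Among equal-cost shortest routes the lexicographically smallest node
    sequence (by residue ordering) is returned.
    """
    anchor = g.graph["anchor"]
    if sink not in g:
        raise UnreachableSinkError(f"sink {sink} is not a node of the graph")
    try:
        total = nx.dijkstra_path_length(g, anchor, sink, weight="weight")
    except nx.NetworkXNoPath:
        comp = sorted(str(n) for n in nx.node_connected_component(g, sink))
        raise UnreachableSinkError(
            f"sink {sink} unreachable from the ligand anchor; its component: "
            f"{', '.join(comp[:8])}{'...' if len(comp) > 8 else ''}"
        ) from None
    best = min(
        nx.all_shortest_paths(g, anchor, sink, weight="weight"),
        key=lambda path: [_node_key(n) for n in path],
    )
    return RegulationPathway(site_id=site_id, route=list(best),
                             total_distance=float(total))


@dataclass
class HierarchyNode:
    label: Hashable
    children: "list[HierarchyNode]" = field(default_factory=list)
    site_ids: list[int] = field(default_factory=list)  # pathways ending here


@dataclass
class PathwayHierarchy:
    """Prefix tree over pathway routes, rooted at the ligand anchor."""

    root: HierarchyNode

    def routes(self) -> dict[int, list[Hashable]]:
        """Reconstruct every site's route by walking root -> leaf."""
        out: dict[int, list[Hashable]] = {}

        def walk(node: HierarchyNode, prefix: list) -> None:
            path = prefix + [node.label]
            for sid in node.site_ids:
                out[sid] = path
            for child in node.children:
                walk(child, path)

        walk(self.root, [])
        return out


def build_hierarchy(pathways: list[RegulationPathway]) -> PathwayHierarchy:
    """Merge routes into a prefix tree; shared prefixes appear once."""
    if not pathways:
        raise ValueError("no pathways to assemble")
    anchors = {p.route[0] for p in pathways}
    if len(anchors) != 1:
        raise ValueError("pathways do not share a single ligand anchor")
    root = HierarchyNode(label=next(iter(anchors)))
    for p in pathways:
        node = root
        for step in p.route[1:]:
            child = next((ch for ch in node.children if ch.label == step), None)
            if child is None:
                child = HierarchyNode(label=step)
                node.children.append(child)
            node = child
        node.site_ids.append(p.site_id)
    return PathwayHierarchy(root=root)


@dataclass
class CouplingMatrix:
    """Entry (A, B): degree of site A coupled by site B, in [0, 1]."""

    site_ids: list[int]
    values: np.ndarray


def coupling_matrix(pathways: list[RegulationPathway]) -> CouplingMatrix:
    """Coupling (A, B) = |residues(A) ∩ residues(B)| / |residues(A)|.

    Generally asymmetric; the diagonal is exactly 1.
    """
    if not pathways:
        raise ValueError("no pathways: coupling undefined")
    n = len(pathways)
    vals = np.zeros((n, n))
    sets = [p.residue_set for p in pathways]
    for a in range(n):
        for b in range(n):
            vals[a, b] = len(sets[a] & sets[b]) / len(sets[a])
    return CouplingMatrix(site_ids=[p.site_id for p in pathways], values=vals)


# ------------------------------------------------------------------- exports

def export_pathways(pathways: list[RegulationPathway]) -> str:
    lines = ["site_id\ttotal_distance\troute"]
    for p in pathways:
        route = ",".join(str(n) for n in p.route)
        lines.append(f"{p.site_id}\t{p.total_distance:.6f}\t{route}")
    return "\n".join(lines) + "\n"


def export_coupling(cm: CouplingMatrix) -> str:
    header = "site\t" + "\t".join(f"site_{s}" for s in cm.site_ids)
    lines = [header]
    for sid, row in zip(cm.site_ids, cm.values):
        lines.append(f"site_{sid}\t" + "\t".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def parse_coupling(text: str) -> CouplingMatrix:
    rows = [line.split("\t") for line in text.strip().splitlines()]
    site_ids = [int(h.removeprefix("site_")) for h in rows[0][1:]]
    vals = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return CouplingMatrix(site_ids=site_ids, values=vals)


def hierarchy_to_graph(h: PathwayHierarchy) -> nx.DiGraph:
    """Directed tree for GraphML export; node ids are path-position strings."""
    g = nx.DiGraph()

    def walk(node: HierarchyNode, node_id: str) -> None:
        g.add_node(node_id, label=str(node.label),
                   sites=",".join(str(s) for s in node.site_ids))
        for k, child in enumerate(node.children):
            child_id = f"{node_id}.{k}"
            walk(child, child_id)
            g.add_edge(node_id, child_id)

    walk(h.root, "0")
    return g
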