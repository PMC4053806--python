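"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's canonical-label machinery: rooted
subgraph equivalence is decided by explicit directed-graph isomorphism
(networkx VF2), and kernel dot products are recomputed by counting matching
paired neighborhoods between two graphs.
"""

from __future__ import annotations

import networkx as nx
from networkx.algorithms.isomorphism import DiGraphMatcher

from rbpgraph.encode import AnnotatedGraph, GROUND_EDGE_LABELS


def directed_distances(g: nx.DiGraph, root, edge_labels, maxdist: int) -> dict:
    """Plain BFS over traversable out-edges with admitted labels."""
    dist = {root: 0}
    frontier = [root]
    d = 0
    while frontier and d < maxdist:
        d += 1
        nxt = []
        for u in frontier:
            for _, v, data in g.out_edges(u, data=True):
                if data["traversable"] and data["label"] in edge_labels and v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def rooted_subgraph(g: nx.DiGraph, root, r: int, edge_labels) -> nx.DiGraph:
    """Induced subgraph on vertices within r directed steps, root marked,
    restricted to admitted traversable edges."""
    keep = set(directed_distances(g, root, edge_labels, r))
    sub = nx.DiGraph()
    for v in keep:
        sub.add_node(v, label=g.nodes[v]["label"], is_root=(v == root))
    for u, v, data in g.edges(data=True):
        if u in keep and v in keep and data["traversable"] and data["label"] in edge_labels:
            sub.add_edge(u, v, label=data["label"])
    return sub


def rooted_isomorphic(a: nx.DiGraph, b: nx.DiGraph) -> bool:
    nm = lambda x, y: x["label"] == y["label"] and x["is_root"] == y["is_root"]
    em = lambda x, y: x["label"] == y["label"]
    return DiGraphMatcher(a, b, node_match=nm, edge_match=em).is_isomorphic()


class IsoClasses:
    """Greedy assignment of isomorphism-class ids to rooted subgraphs."""

    def __init__(self):
        self.buckets: dict = {}

    def class_of(self, sub: nx.DiGraph) -> int:
        key = (sub.number_of_nodes(), sub.number_of_edges(),
               tuple(sorted(d["label"] for _, d in sub.nodes(data=True))))
        reps = self.buckets.setdefault(key, [])
        for cid, rep in reps:
            if rooted_isomorphic(sub, rep):
                return cid
        cid = id(self) + sum(len(v) for v in self.buckets.values())
        reps.append((cid, sub))
        return cid


def paired_neighborhood_counts(graph: AnnotatedGraph, R: int, D: int,
                               classes: IsoClasses,
                               edge_labels=GROUND_EDGE_LABELS) -> dict:
    """Feature counts (r, d, class_u, class_v) by explicit enumeration.

    Ordered root pairs at directed shortest-path distance d <= D with at
    least one root in the viewpoint; both neighborhoods share radius r <= R.
    """
    g = graph.g
    roots = [v for v, d in g.nodes(data=True) if d["kind"] == "nucleotide"]
    sub_cache: dict = {}

    def cls(v, r):
        if (v, r) not in sub_cache:
            sub_cache[(v, r)] = classes.class_of(rooted_subgraph(g, v, r, edge_labels))
        return sub_cache[(v, r)]

    counts: dict = {}
    for u in roots:
        dist = directed_distances(g, u, edge_labels, D)
        for v, d in dist.items():
            if g.nodes[v]["kind"] != "nucleotide":
                continue
            if not (g.nodes[u]["in_viewpoint"] or g.nodes[v]["in_viewpoint"]):
                continue
            for r in range(R + 1):
                key = (r, d, cls(u, r), cls(v, r))
                counts[key] = counts.get(key, 0) + 1
    return counts


def oracle_dot(g1: AnnotatedGraph, g2: AnnotatedGraph, R: int, D: int) -> float:
    """Brute-force unnormalized NSPD dot product of two ground-only graphs."""
    classes = IsoClasses()
    c1 = paired_neighborhood_counts(g1, R, D, classes)
    c2 = paired_neighborhood_counts(g2, R, D, classes)
    return float(sum(v * c2[k] for k, v in c1.items() if k in c2))
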