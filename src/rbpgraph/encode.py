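"""Directed annotated (hyper)graph encoding of a target site.

A site becomes one graph with, per structure hypothesis, a connected
component holding the nucleotide path (backbone edges 5'->3'), base-pair
edges (directed from the 5' partner), and an *abstract* layer: one vertex
per structure element instance (stem, hairpin, internal loop, bulge,
multiloop; external regions one vertex per contiguous run), wired
outer-to-inner by abstract adjacency edges.  Each abstract element is tied to
its member nucleotides through a non-traversable *relation* vertex — the
incident-graph rendering of a hyperedge — so paths can never shortcut
through a loop annotation.

The whole multi-component graph is then duplicated with all edges reversed
and vertex labels prefixed ``r``; the mirrored copy restores the information
lost by committing to a single traversal direction while keeping the 5'->3'
asymmetry discriminative.

Sequence-only mode keeps just the nucleotide path (plus its mirror).
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx

from .folding import StructureHypothesis, helices, structure_elements
from .prep import TargetSite

NUCLEOTIDE = "nucleotide"
ABSTRACT = "abstract_element"
RELATION = "relation"

BACKBONE = "backbone"
BASEPAIR = "basepair"
ABSTRACT_ADJ = "abstract_adjacency"
RELATION_LINK = "relation_link"

GROUND_EDGE_LABELS = frozenset({BACKBONE, BASEPAIR})
ABSTRACT_EDGE_LABELS = frozenset({ABSTRACT_ADJ})


class AnnotatedGraph:
    """Thin typed wrapper around a :class:`networkx.DiGraph`.

    Vertices carry ``label``, ``kind``, optional context ``position``,
    ``in_viewpoint`` and ``copy`` ("main"/"reversed"); edges carry ``label``
    and ``traversable``.
    """

    def __init__(self) -> None:
        self.g = nx.DiGraph()

    # -- construction ------------------------------------------------------
    def add_vertex(self, vid: str, label: str, kind: str, position: int | None = None,
                   in_viewpoint: bool = False, copy: str = "main") -> str:
        if vid in self.g:
            raise ValueError(f"duplicate vertex id {vid!r}")
        self.g.add_node(vid, label=label, kind=kind, position=position,
                        in_viewpoint=bool(in_viewpoint), copy=copy)
        return vid

    def add_edge(self, src: str, dst: str, label: str, traversable: bool = True) -> None:
        if label == RELATION_LINK and traversable:
            raise ValueError("relation links are never traversable")
        self.g.add_edge(src, dst, label=label, traversable=bool(traversable))

    # -- queries -----------------------------------------------------------
    def vertices(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.g.nodes)
        return [v for v, d in self.g.nodes(data=True) if d["kind"] == kind]

    def label(self, vid: str) -> str:
        return self.g.nodes[vid]["label"]

    def kind(self, vid: str) -> str:
        return self.g.nodes[vid]["kind"]

    def position(self, vid: str) -> int | None:
        return self.g.nodes[vid]["position"]

    def in_viewpoint(self, vid: str) -> bool:
        return self.g.nodes[vid]["in_viewpoint"]

    def relation_endpoints(self, rel: str) -> tuple[str, list[str]]:
        """The abstract vertex and nucleotide members linked by a relation
        vertex (works on both the main and the reversed copy)."""
        if self.kind(rel) != RELATION:
            raise ValueError(f"{rel!r} is not a relation vertex")
        nbrs = set(self.g.predecessors(rel)) | set(self.g.successors(rel))
        abstract = [v for v in nbrs if self.kind(v) == ABSTRACT]
        nucs = sorted(v for v in nbrs if self.kind(v) == NUCLEOTIDE)
        if len(abstract) != 1:
            raise ValueError(f"relation vertex {rel!r} must link exactly one abstract element")
        return abstract[0], nucs

    def members(self, abstract_vid: str) -> list[str]:
        """Nucleotide vertices contained in an abstract element."""
        rels = [v for v in (set(self.g.successors(abstract_vid))
                            | set(self.g.predecessors(abstract_vid)))
                if self.kind(v) == RELATION]
        out: list[str] = []
        for rel in rels:
            out.extend(self.relation_endpoints(rel)[1])
        return sorted(set(out))

    def validate(self) -> None:
        for u, v, d in self.g.edges(data=True):
            if d["label"] == RELATION_LINK and d["traversable"]:
                raise ValueError("traversable relation link")
            if d["label"] != RELATION_LINK and (self.kind(u) == RELATION or
                                                self.kind(v) == RELATION):
                raise ValueError("relation vertices admit only relation links")

    # -- serialization -----------------------------------------------------
    def dumps(self) -> str:
        lines = []
        for v in sorted(self.g.nodes):
            d = self.g.nodes[v]
            pos = "-" if d["position"] is None else str(d["position"])
            lines.append(f"v\t{v}\t{d['label']}\t{d['kind']}\t{pos}\t"
                         f"{int(d['in_viewpoint'])}\t{d['copy']}")
        for u, v in sorted(self.g.edges):
            d = self.g.edges[u, v]
            lines.append(f"e\t{u}\t{v}\t{d['label']}\t{int(d['traversable'])}")
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "AnnotatedGraph":
        g = cls()
        for line in text.strip().splitlines():
            parts = line.split("\t")
            if parts[0] == "v":
                _, vid, label, kind, pos, vp, copy = parts
                g.add_vertex(vid, label, kind, None if pos == "-" else int(pos),
                             bool(int(vp)), copy)
            elif parts[0] == "e":
                _, u, v, label, trav = parts
                g.add_edge(u, v, label, bool(int(trav)))
        return g


def add_reversed_copy(graph: AnnotatedGraph) -> AnnotatedGraph:
    """Append the relabeled mirror: every vertex duplicated with prefix ``r``
    and every edge direction inverted.  Positions and viewpoint flags are
    shared with the originals."""
    nodes = list(graph.g.nodes(data=True))
    edges = list(graph.g.edges(data=True))
    for v, d in nodes:
        graph.add_vertex("r" + v, "r" + d["label"], d["kind"], d["position"],
                         d["in_viewpoint"], copy="reversed")
    for u, v, d in edges:
        graph.add_edge("r" + v, "r" + u, d["label"], d["traversable"])
    return graph


def _add_nucleotide_path(graph: AnnotatedGraph, site: TargetSite, prefix: str,
                         lo: int, hi: int) -> dict[int, str]:
    vp_lo, vp_hi = site.viewpoint
    ids: dict[int, str] = {}
    for p in range(lo, hi):
        ids[p] = graph.add_vertex(f"{prefix}{p}", site.context_sequence[p], NUCLEOTIDE,
                                  position=p, in_viewpoint=vp_lo <= p < vp_hi)
    for p in range(lo, hi - 1):
        graph.add_edge(ids[p], ids[p + 1], BACKBONE)
    return ids


def encode_sequence_only(site: TargetSite, add_reverse: bool = True) -> AnnotatedGraph:
    """Path graph over the context nucleotides (no structure), plus mirror."""
    graph = AnnotatedGraph()
    _add_nucleotide_path(graph, site, "n", 0, len(site.context_sequence))
    if add_reverse:
        add_reversed_copy(graph)
    graph.validate()
    return graph


def _element_instances(hyp: StructureHypothesis) -> list[tuple[str, list[int]]]:
    """Structure element instances of a hypothesis as (type, positions).

    Stems are helix instances (both strands of a maximal stack in one
    instance); hairpin/internal/bulge/multiloop instances pool all unpaired
    positions of one loop; external regions are one instance per contiguous
    run.
    """
    lo, hi = hyp.window
    elements = structure_elements(hyp)
    pairs = set(hyp.pairs)
    instances: list[tuple[str, list[int]]] = []

    for helix in helices(pairs):
        positions = sorted(p for ij in helix for p in ij)
        instances.append(("S", positions))

    # loops: unpaired positions grouped by their innermost enclosing pair
    enclosing: dict[int, tuple[int, int]] = {}
    stack: list[tuple[int, int]] = []
    open_at = {i: (i, j) for i, j in pairs}
    close_at = {j for _, j in pairs}
    for p in range(lo, hi):
        if p in open_at:
            stack.append(open_at[p])
        elif p in close_at:
            stack.pop()
        elif stack:
            enclosing[p] = stack[-1]
    by_loop: dict[tuple[int, int], list[int]] = {}
    for p, ij in enclosing.items():
        by_loop.setdefault(ij, []).append(p)
    for ij, positions in sorted(by_loop.items()):
        instances.append((elements[positions[0]], sorted(positions)))

    # external regions: contiguous runs
    run: list[int] = []
    for p in range(lo, hi + 1):
        if p < hi and elements[p] == "E":
            run.append(p)
        elif run:
            instances.append(("E", run))
            run = []
    return instances


def encode_with_structure(site: TargetSite, hypotheses: Sequence[StructureHypothesis],
                          add_reverse: bool = True) -> AnnotatedGraph:
    """One component per structure hypothesis, with the abstract layer.

    Base-pair edges run from the 5' to the 3' partner; abstract adjacency
    edges run outer-to-inner (external region -> stem -> its loop -> inner
    stems -> ... -> hairpin).
    """
    if not hypotheses:
        raise ValueError("need at least one structure hypothesis")
    n_ctx = len(site.context_sequence)
    graph = AnnotatedGraph()
    for h_idx, hyp in enumerate(hypotheses):
        lo, hi = hyp.window
        if not (0 <= lo < hi <= n_ctx):
            raise ValueError(f"hypothesis window {hyp.window} outside context")
        ids = _add_nucleotide_path(graph, site, f"h{h_idx}p", lo, hi)
        for i, j in sorted(hyp.pairs):
            graph.add_edge(ids[i], ids[j], BASEPAIR)

        instances = _element_instances(hyp)
        inst_id: dict[int, str] = {}
        inst_outer: list[tuple[int, str, list[int]]] = []
        for k, (etype, positions) in enumerate(instances):
            aid = graph.add_vertex(f"h{h_idx}a{k}", etype, ABSTRACT,
                                   in_viewpoint=any(graph.in_viewpoint(ids[p])
                                                    for p in positions))
            rid = graph.add_vertex(f"h{h_idx}r{k}", "rel", RELATION)
            graph.add_edge(aid, rid, RELATION_LINK, traversable=False)
            for p in positions:
                graph.add_edge(rid, ids[p], RELATION_LINK, traversable=False)
            inst_id[k] = aid
            inst_outer.append((k, etype, positions))

        _wire_abstract_adjacency(graph, hyp, instances, inst_id)
    if add_reverse:
        add_reversed_copy(graph)
    graph.validate()
    return graph


def _wire_abstract_adjacency(graph: AnnotatedGraph, hyp: StructureHypothesis,
                             instances: list[tuple[str, list[int]]],
                             inst_id: dict[int, str]) -> None:
    """Abstract adjacency edges, directed from the external region inward."""
    pairs = set(hyp.pairs)
    hx = helices(pairs)
    helix_idx: dict[tuple[int, int], int] = {}  # outer pair -> instance index
    loop_idx: dict[tuple[int, int], int] = {}   # enclosing pair -> loop instance index
    e_runs: list[tuple[int, list[int]]] = []
    stem_count = len(hx)
    for k, (etype, positions) in enumerate(instances):
        if etype == "S":
            outer = hx[k][0]  # stems were appended in helices() order
            helix_idx[outer] = k
        elif etype == "E":
            e_runs.append((k, positions))
    # loop instances follow the stems in _element_instances; recover their pair
    enclosing_of_loop: dict[int, tuple[int, int]] = {}
    loop_ks = [k for k, (t, _) in enumerate(instances) if t not in ("S", "E")]
    # recompute the grouping to map loop instance -> enclosing pair
    lo, hi = hyp.window
    stack: list[tuple[int, int]] = []
    open_at = {i: (i, j) for i, j in pairs}
    close_at = {j for _, j in pairs}
    by_loop: dict[tuple[int, int], list[int]] = {}
    for p in range(lo, hi):
        if p in open_at:
            stack.append(open_at[p])
        elif p in close_at:
            stack.pop()
        elif stack:
            by_loop.setdefault(stack[-1], []).append(p)
    for k, ij in zip(loop_ks, sorted(by_loop)):
        loop_idx[ij] = k

    from .folding import _child_pairs  # shared nesting helper

    outer_pairs = set(helix_idx)

    def child_helices(rlo: int, rhi: int) -> list[tuple[int, int]]:
        return _child_pairs(outer_pairs, rlo, rhi)

    # external runs point at the top-level helices they abut
    top = child_helices(lo, hi)
    for k, positions in e_runs:
        a, b = positions[0], positions[-1] + 1
        for ij in top:
            if ij[0] == b or ij[1] == a - 1:
                graph.add_edge(inst_id[k], inst_id[helix_idx[ij]], ABSTRACT_ADJ)

    # helix -> its loop (if the loop has unpaired positions) -> inner helices
    for helix in hx:
        outer, inner = helix[0], helix[-1]
        src = inst_id[helix_idx[outer]]
        ii, jj = inner
        kids = child_helices(ii + 1, jj)
        loop_pair = inner if inner in by_loop else None
        if loop_pair is not None:
            lid = inst_id[loop_idx[loop_pair]]
            graph.add_edge(src, lid, ABSTRACT_ADJ)
            src = lid
        for ij in kids:
            graph.add_edge(src, inst_id[helix_idx[ij]], ABSTRACT_ADJ)


def encode_site(site: TargetSite, hypotheses: Sequence[StructureHypothesis] | None = None,
                mode: str = "sequence", add_reverse: bool = True) -> AnnotatedGraph:
    """Dispatch between sequence-only and full structure encoding."""
    if mode == "sequence":
        return encode_sequence_only(site, add_reverse=add_reverse)
    if mode == "structure":
        if not hypotheses:
            raise ValueError("structure mode requires folding hypotheses")
        return encode_with_structure(site, hypotheses, add_reverse=add_reverse)
    raise ValueError(f"unknown mode {mode!r}")
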