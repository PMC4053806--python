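"""Explicit NSPD-kernel features over annotated site graphs.

A feature is a pair of same-radius neighborhood subgraphs rooted at two
vertices a bounded directed distance apart: for every ordered root pair
(u, v) whose shortest directed path over traversable edges has length
d <= D, and every radius r <= R, the feature ``(set, r, d, N_r(u), N_r(v))``
is counted, where ``N_r`` is a canonical label of the subgraph induced by
the vertices reachable from the root within r directed steps.  Pairs are
kept only when at least one root lies in the viewpoint, so features stay
local to the putative binding site while the context still shapes the
folded structure.

Three feature sets are kept apart: *ground* (nucleotide roots over
backbone/base-pair edges), *abstract* (structure-element roots over abstract
adjacency edges) and *hybrid* (the two endpoints of a hyperedge relation:
structure element paired with one of its member nucleotides), mirroring the
incident-graph treatment of hyperedges.  Relation vertices themselves are
never traversed and never serve as roots.

Canonical labels are hashed to a 2**bits feature space by a stable 64-bit
hash; ``exact_mode`` keys features by the canonical strings instead, which
is what the isomorphism-oracle tests compare against.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy import sparse

from .encode import (ABSTRACT, ABSTRACT_EDGE_LABELS, GROUND_EDGE_LABELS, NUCLEOTIDE,
                     RELATION, AnnotatedGraph)


@dataclass(frozen=True)
class KernelParams:
    R: int = 1
    D: int = 4
    bits: int = 20
    exact_mode: bool = False
    undirected: bool = False  # negative-control mode; production graphs are directed

    def __post_init__(self) -> None:
        if self.R < 0 or self.D < 0:
            raise ValueError("R and D must be non-negative")
        if not self.exact_mode and not (8 <= self.bits <= 30):
            raise ValueError("bits must be within [8, 30]")

    @property
    def dim(self) -> int:
        if self.exact_mode:
            raise ValueError("exact mode has no fixed dimensionality")
        return 1 << self.bits


class SparseFeatureVector:
    """Sparse feature counts with per-(set, r, d) block metadata."""

    __slots__ = ("entries", "blocks", "params", "normalized")

    def __init__(self, entries: dict, blocks: dict, params: KernelParams,
                 normalized: bool = False):
        self.entries = entries
        self.blocks = blocks
        self.params = params
        self.normalized = normalized

    def __len__(self) -> int:
        return len(self.entries)

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.entries.values()))

    def dot(self, other: "SparseFeatureVector") -> float:
        if self.params != other.params:
            raise ValueError("feature vectors built with different kernel parameters")
        a, b = self.entries, other.entries
        if len(b) < len(a):
            a, b = b, a
        return sum(v * b[k] for k, v in a.items() if k in b)

    def to_lines(self) -> str:
        """SVM-light style sparse text: sorted ``feature_id:value`` tokens."""
        return " ".join(f"{k}:{self.entries[k]:.6g}"
                        for k in sorted(self.entries, key=str))


def stable_hash(text: str, bits: int) -> int:
    h = hashlib.blake2b(text.encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") & ((1 << bits) - 1)


# ---------------------------------------------------------------------------
# traversal and canonical neighborhood labels

def _bfs(graph: AnnotatedGraph, root: str, maxdist: int,
         edge_labels: frozenset, undirected: bool) -> dict[str, int]:
    """Distances of vertices reachable from ``root`` within ``maxdist``
    traversable edges of the given labels, following edge orientation
    (or ignoring it in undirected mode)."""
    g = graph.g
    dist = {root: 0}
    frontier = [root]
    d = 0
    while frontier and d < maxdist:
        d += 1
        nxt = []
        for u in frontier:
            nbrs = []
            for _, v, data in g.out_edges(u, data=True):
                if data["traversable"] and data["label"] in edge_labels:
                    nbrs.append(v)
            if undirected:
                for v, _, data in g.in_edges(u, data=True):
                    if data["traversable"] and data["label"] in edge_labels:
                        nbrs.append(v)
            for v in nbrs:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def neighborhood(graph: AnnotatedGraph, root: str, r: int,
                 edge_labels: frozenset = GROUND_EDGE_LABELS,
                 undirected: bool = False) -> str:
    """Canonical label of the radius-``r`` neighborhood subgraph of ``root``.

    The label is a deterministic isomorphism invariant: the sorted multiset
    of per-vertex signatures (distance from root, vertex label, sorted
    multiset of incident traversable edge descriptors restricted to the
    induced subgraph).  Edge descriptors carry the edge label, the neighbor
    label, the neighbor distance and — in directed mode — the orientation.
    """
    if graph.kind(root) == RELATION:
        raise ValueError("relation vertices cannot root a neighborhood")
    dist = _bfs(graph, root, r, edge_labels, undirected)
    g = graph.g
    sigs = []
    for v, dv in dist.items():
        edesc = []
        for _, w, data in g.out_edges(v, data=True):
            if w in dist and data["traversable"] and data["label"] in edge_labels:
                tag = "" if undirected else "o"
                edesc.append((tag, data["label"], graph.label(w), dist[w]))
        for w, _, data in g.in_edges(v, data=True):
            if w in dist and data["traversable"] and data["label"] in edge_labels:
                tag = "" if undirected else "i"
                edesc.append((tag, data["label"], graph.label(w), dist[w]))
        sigs.append((dv, graph.label(v), tuple(sorted(edesc))))
    return repr(sorted(sigs))


# ---------------------------------------------------------------------------
# feature enumeration

_SETS = (("ground", NUCLEOTIDE, GROUND_EDGE_LABELS),
         ("abstract", ABSTRACT, ABSTRACT_EDGE_LABELS))


def _occurrences(graph: AnnotatedGraph, params: KernelParams
                 ) -> Iterator[tuple[tuple, tuple[str, ...], list[tuple[str, float]]]]:
    """Yield one record per feature occurrence.

    Each record is ``(block, key, attribution)`` where ``block`` is the
    ``(set, r, d)`` normalization block, ``key`` the canonical feature tuple
    and ``attribution`` the (vertex, share) list used for per-nucleotide
    profiles (shares sum to 1 per occurrence).
    """
    label_cache: dict[tuple[str, int, frozenset], str] = {}

    def nlabel(v: str, r: int, edges: frozenset) -> str:
        k = (v, r, edges)
        if k not in label_cache:
            label_cache[k] = neighborhood(graph, v, r, edges, params.undirected)
        return label_cache[k]

    for set_name, kind, edges in _SETS:
        roots = graph.vertices(kind)
        if not roots:
            continue
        for u in roots:
            dists = _bfs(graph, u, params.D, edges, params.undirected)
            u_vp = graph.in_viewpoint(u)
            for v, d in dists.items():
                if graph.kind(v) != kind:
                    continue
                if not (u_vp or graph.in_viewpoint(v)):
                    continue
                attribution = ([(u, 1.0)] if u == v else [(u, 0.5), (v, 0.5)])
                for r in range(params.R + 1):
                    key = (set_name, str(r), str(d), nlabel(u, r, edges),
                           nlabel(v, r, edges))
                    yield (set_name, r, d), key, attribution
    # hybrid set: endpoints of each hyperedge relation
    for rel in graph.vertices(RELATION):
        a, nucs = graph.relation_endpoints(rel)
        for n in nucs:
            if not graph.in_viewpoint(n):
                continue
            for r in range(params.R + 1):
                key = ("hybrid", str(r), "rel",
                       nlabel(a, r, ABSTRACT_EDGE_LABELS),
                       nlabel(n, r, GROUND_EDGE_LABELS))
                yield ("hybrid", r, "rel"), key, [(n, 0.5), (a, 0.5)]


def _feature_id(key: tuple[str, ...], params: KernelParams):
    text = "\x1f".join(key)
    if params.exact_mode:
        return text
    return stable_hash(text, params.bits)


def _block_scales(counts: dict, blocks: dict) -> tuple[dict, float]:
    """Per-block L2 scales plus the final global L2 scale."""
    block_sq: dict[tuple, float] = {}
    for fid, c in counts.items():
        block_sq[blocks[fid]] = block_sq.get(blocks[fid], 0.0) + c * c
    scale = {b: (1.0 / math.sqrt(s) if s > 0 else 1.0) for b, s in block_sq.items()}
    total_sq = sum((c * scale[blocks[fid]]) ** 2 for fid, c in counts.items())
    g = 1.0 / math.sqrt(total_sq) if total_sq > 0 else 1.0
    return scale, g


def extract_features(graph: AnnotatedGraph, params: KernelParams,
                     normalize: bool = True) -> SparseFeatureVector:
    """NSPD feature vector of a graph (viewpoint-restricted, block-normalized).

    With ``normalize=False`` raw occurrence counts are returned, which is the
    quantity the brute-force isomorphism oracle reproduces.
    """
    counts: dict = {}
    blocks: dict = {}
    for block, key, _ in _occurrences(graph, params):
        fid = _feature_id(key, params)
        counts[fid] = counts.get(fid, 0.0) + 1.0
        if fid not in blocks:
            blocks[fid] = block
    if not normalize:
        return SparseFeatureVector(counts, blocks, params, normalized=False)
    scale, g = _block_scales(counts, blocks)
    entries = {fid: c * scale[blocks[fid]] * g for fid, c in counts.items()}
    return SparseFeatureVector(entries, blocks, params, normalized=True)


def position_attribution(graph: AnnotatedGraph, params: KernelParams
                         ) -> tuple[SparseFeatureVector, dict[int, dict]]:
    """Normalized vector plus, per context position, its share of each feature.

    Shares of a feature occurrence go half to each root (all to the root of a
    self-pair).  A share landing on an abstract element is spread equally over
    the element's member nucleotides; mirrored vertices map back to their
    original context position.  Per feature id the position shares sum to the
    occurrence count, so profiles conserve the margin exactly.
    """
    counts: dict = {}
    blocks: dict = {}
    pos_share: dict[int, dict] = {}
    member_cache: dict[str, list[str]] = {}

    def spread(vid: str, share: float, fid) -> None:
        kind = graph.kind(vid)
        if kind == NUCLEOTIDE:
            targets = [(graph.position(vid), share)]
        else:  # abstract element: distribute over member nucleotides
            if vid not in member_cache:
                member_cache[vid] = graph.members(vid)
            mem = member_cache[vid]
            if not mem:
                return
            targets = [(graph.position(m), share / len(mem)) for m in mem]
        for pos, s in targets:
            if pos is None:
                continue
            d = pos_share.setdefault(pos, {})
            d[fid] = d.get(fid, 0.0) + s

    for block, key, attribution in _occurrences(graph, params):
        fid = _feature_id(key, params)
        counts[fid] = counts.get(fid, 0.0) + 1.0
        if fid not in blocks:
            blocks[fid] = block
        for vid, share in attribution:
            spread(vid, share, fid)

    scale, g = _block_scales(counts, blocks)
    entries = {fid: c * scale[blocks[fid]] * g for fid, c in counts.items()}
    vec = SparseFeatureVector(entries, blocks, params, normalized=True)
    # convert raw occurrence shares to normalized-feature shares
    for pos, d in pos_share.items():
        for fid in d:
            d[fid] *= scale[blocks[fid]] * g
    return vec, pos_share


# ---------------------------------------------------------------------------
# vector collections

def vectors_to_csr(vectors: Iterable[SparseFeatureVector],
                   params: KernelParams) -> sparse.csr_matrix:
    """Stack hashed feature vectors into a CSR design matrix of width 2**bits."""
    if params.exact_mode:
        raise ValueError("CSR stacking requires hashed feature ids")
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    n = 0
    for vec in vectors:
        if vec.params != params:
            raise ValueError("mixed kernel parameters in vector collection")
        items = sorted(vec.entries.items())
        indices.extend(k for k, _ in items)
        data.extend(v for _, v in items)
        indptr.append(len(indices))
        n += 1
    return sparse.csr_matrix((np.asarray(data), np.asarray(indices, dtype=np.int64),
                              np.asarray(indptr, dtype=np.int64)),
                             shape=(n, params.dim))
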