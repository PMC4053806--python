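from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from rbpgraph.encode import AnnotatedGraph, BACKBONE, BASEPAIR, NUCLEOTIDE
from rbpgraph.prep import TargetSite

BASES = "ACGU"


def random_site(rng: np.random.Generator, n: int = 20,
                viewpoint: tuple[int, int] | None = None) -> TargetSite:
    seq = "".join(BASES[i] for i in rng.integers(0, 4, n))
    if viewpoint is None:
        lo = int(rng.integers(0, n - 1))
        hi = int(rng.integers(lo + 1, n + 1))
        viewpoint = (lo, hi)
    return TargetSite("rand", seq, viewpoint)


def random_directed_graph(rng: np.random.Generator, max_nodes: int = 10,
                          edge_prob: float = 0.25) -> AnnotatedGraph:
    """Random labeled directed graph posing as a ground-only site graph."""
    n = int(rng.integers(2, max_nodes + 1))
    g = AnnotatedGraph()
    for i in range(n):
        g.add_vertex(f"v{i}", BASES[int(rng.integers(0, 4))], NUCLEOTIDE,
                     position=i, in_viewpoint=True)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < edge_prob:
                label = BACKBONE if rng.random() < 0.7 else BASEPAIR
                g.add_edge(f"v{i}", f"v{j}", label)
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
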