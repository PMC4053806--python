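"""Representative secondary structures (shreps) for site contexts.

The folding context of each site is scanned with overlapping windows
(150 nt, step 37 by default).  Each window is folded and its low-energy
structures are grouped into *shape* classes — simplified bracket strings that
ignore stem lengths and, at higher abstraction levels, loop details.  Per
shape class the minimum-free-energy structure is kept as the representative
("shrep"); up to three shreps within 10% of the window MFE are returned, so a
site is represented by a small population of plausible structures rather than
a single error-prone MFE prediction.

Two interchangeable backends satisfy the ``candidates(seq, band)`` contract:

* :class:`ViennaRNABackend` — thermodynamic MFE + suboptimal structures via
  the ViennaRNA bindings (energies in kcal/mol); used by default when the
  ``RNA`` module is importable.
* :class:`NussinovBackend` — a self-contained maximum-scoring folder
  (base-pair scores GC=3, AU=2, GU=1 as a crude stacking-strength proxy,
  minimum hairpin loop 3) with best-first suboptimal enumeration; energies
  are in arbitrary units (negated score).  It keeps the whole test suite
  independent of any thermodynamics engine.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np

STRUCTURE_ELEMENTS = "SEHIMB"


@dataclass(frozen=True)
class FoldingParams:
    window_len: int = 150
    step: int = 37
    max_shreps_per_window: int = 3
    energy_band: float = 0.10
    abstraction_level: int = 3

    def __post_init__(self) -> None:
        if not (self.window_len >= self.step >= 1):
            raise ValueError("require window_len >= step >= 1")
        if not (0.0 < self.energy_band < 1.0):
            raise ValueError("energy_band must be in (0, 1)")
        if self.max_shreps_per_window < 1:
            raise ValueError("max_shreps_per_window must be >= 1")
        if self.abstraction_level not in (1, 3, 5):
            raise ValueError("abstraction_level must be one of {1, 3, 5}")


@dataclass(frozen=True)
class StructureHypothesis:
    """One shrep of one folding window; ``pairs`` are context-relative."""

    window: tuple[int, int]
    pairs: frozenset[tuple[int, int]]
    shape: str
    energy: float

    def __post_init__(self) -> None:
        lo, hi = self.window
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (lo <= i < j < hi):
                raise ValueError(f"pair ({i},{j}) outside window [{lo},{hi})")
            if i in seen or j in seen:
                raise ValueError("a position participates in more than one pair")
            seen.update((i, j))
        for (i, j), (k, l) in itertools.combinations(sorted(self.pairs), 2):
            if i < k < j < l:
                raise ValueError("crossing pairs (pseudoknot) not allowed")


def enumerate_windows(context_len: int, params: FoldingParams) -> list[tuple[int, int]]:
    """Sliding windows over the context; a final window flush with the 3' end
    is appended so trailing positions are always folded."""
    if context_len < 1:
        raise ValueError("context_len must be >= 1")
    w, step = params.window_len, params.step
    windows: list[tuple[int, int]] = []
    k = 0
    while k * step + w <= context_len:
        windows.append((k * step, k * step + w))
        k += 1
    if not windows:
        return [(0, context_len)]  # context shorter than one window
    if windows[-1][1] < context_len:
        windows.append((context_len - w, context_len))
    return windows


# ---------------------------------------------------------------------------
# structure geometry helpers

def parse_dotbracket(db: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = set()
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.add((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return frozenset(pairs)


def to_dotbracket(pairs: Iterable[tuple[int, int]], lo: int, hi: int) -> str:
    out = ["."] * (hi - lo)
    for i, j in pairs:
        out[i - lo] = "("
        out[j - lo] = ")"
    return "".join(out)


def helices(pairs: Iterable[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into maximal stacks: (i,j) and (i+1,j-1) share a helix."""
    ps = set(pairs)
    out = []
    for i, j in sorted(ps):
        if (i - 1, j + 1) in ps:
            continue  # not the outer pair of its helix
        helix = [(i, j)]
        while (i + 1, j - 1) in ps:
            i, j = i + 1, j - 1
            helix.append((i, j))
        out.append(helix)
    return out


def _child_pairs(pairs: set[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    """Top-level pairs strictly inside [lo, hi)."""
    tops = []
    cover = -1
    for i, j in sorted(pairs):
        if i < lo or j >= hi:
            continue
        if i > cover:
            tops.append((i, j))
            cover = j
    return tops


def structure_elements(hyp: StructureHypothesis) -> dict[int, str]:
    """Assign every window position to one structure element.

    Paired positions are stems (S).  Unpaired positions take the type of
    their enclosing loop: hairpin (H), internal loop (I), bulge (B),
    multiloop (M), or external region (E) when no pair encloses them.
    """
    lo, hi = hyp.window
    pairs = set(hyp.pairs)
    partner: dict[int, int] = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    elements: dict[int, str] = {}
    loop_type_cache: dict[tuple[int, int], str] = {}

    def loop_type(ij: tuple[int, int]) -> str:
        if ij not in loop_type_cache:
            i, j = ij
            kids = _child_pairs(pairs, i + 1, j)
            if not kids:
                t = "H"
            elif len(kids) >= 2:
                t = "M"
            else:
                a, b = kids[0]
                left, right = a - i - 1, j - b - 1
                t = "I" if (left > 0 and right > 0) else "B"
            loop_type_cache[ij] = t
        return loop_type_cache[ij]

    stack: list[tuple[int, int]] = []
    open_at = {i: (i, j) for i, j in pairs}
    close_at = {j: (i, j) for i, j in pairs}
    for p in range(lo, hi):
        if p in partner:
            elements[p] = "S"
            if p in open_at:
                stack.append(open_at[p])
            else:
                stack.pop()
        else:
            elements[p] = loop_type(stack[-1]) if stack else "E"
    return elements


# ---------------------------------------------------------------------------
# shape abstraction

def shape_string(pairs: Iterable[tuple[int, int]], lo: int, hi: int, level: int = 3) -> str:
    """Abstract shape of a structure: stem lengths always ignored.

    level 1  — every helix is a bracket pair and every maximal unpaired run
               is an underscore;
    level 3  — helices only (bulges/internal loops survive as extra bracket
               pairs because they break helices);
    level 5  — helix arrangement only: chains of helices separated by
               internal loops/bulges collapse to a single bracket pair.
    """
    hx = helices(pairs)
    if not hx:
        return "_"
    outer = {h[0]: h for h in hx}  # outer pair -> helix
    inner = {h[0]: h[-1] for h in hx}
    pairset = {h[0] for h in hx}  # outer pairs only define nesting

    def children_of_region(rlo: int, rhi: int) -> list[tuple[int, int]]:
        return _child_pairs(pairset, rlo, rhi)

    def s13(rlo: int, rhi: int) -> str:
        kids = children_of_region(rlo, rhi)
        toks: list[str] = []
        pos = rlo
        for i, j in kids:
            if level == 1 and i > pos:
                toks.append("_")
            ii, jj = inner[(i, j)]
            toks.append("[" + s13(ii + 1, jj) + "]")
            pos = j + 1
        if level == 1 and pos < rhi:
            toks.append("_")
        return "".join(toks)

    def s5(ij: tuple[int, int]) -> str:
        kids = children_of_region(inner[ij][0] + 1, inner[ij][1])
        while len(kids) == 1:
            ij = kids[0]
            kids = children_of_region(inner[ij][0] + 1, inner[ij][1])
        return "[" + "".join(s5(k) for k in kids) + "]"

    if level in (1, 3):
        return s13(lo, hi)
    return "".join(s5(k) for k in children_of_region(lo, hi))


# ---------------------------------------------------------------------------
# folding backends

_PAIR_SCORE = {("G", "C"): 3.0, ("C", "G"): 3.0, ("A", "U"): 2.0,
               ("U", "A"): 2.0, ("G", "U"): 1.0, ("U", "G"): 1.0}
MIN_HAIRPIN = 3


class NussinovBackend:
    """Deterministic maximum-scoring folder with suboptimal enumeration.

    Scores base pairs by strength (GC=3, AU=2, GU=1; ``scoring='pairs'``
    scores every pair 1 for maximum-pairing mode) and reports ``energy`` as
    the negated score in arbitrary units.  Suboptimal structures are
    enumerated best-first with an exact bound, so structures are produced in
    non-increasing score order until the energy band or the candidate cap is
    exhausted.
    """

    name = "builtin"

    def __init__(self, scoring: str = "stack", max_candidates: int = 200):
        if scoring not in ("stack", "pairs"):
            raise ValueError("scoring must be 'stack' or 'pairs'")
        self.scoring = scoring
        self.max_candidates = max_candidates

    def _score(self, a: str, b: str) -> float:
        s = _PAIR_SCORE.get((a, b), 0.0)
        if self.scoring == "pairs":
            return 1.0 if s > 0 else 0.0
        return s

    def candidates(self, seq: str, band: float) -> list[tuple[frozenset, float]]:
        n = len(seq)
        if n == 0:
            raise ValueError("empty window")
        # M[i][j]: best score on inclusive interval [i, j]
        M = np.zeros((n + 1, n + 1))
        for span in range(MIN_HAIRPIN + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = M[i][j - 1]
                for k in range(i, j - MIN_HAIRPIN):
                    sc = self._score(seq[k], seq[j])
                    if sc > 0:
                        left = M[i][k - 1] if k > i else 0.0
                        cand = left + sc + M[k + 1][j - 1]
                        if cand > best:
                            best = cand
                M[i][j] = best

        def bound(intervals: tuple, score: float) -> float:
            return score + sum(M[i][j] for i, j in intervals)

        mfe_score = M[0][n - 1]
        threshold = (1.0 - band) * mfe_score if mfe_score > 0 else 0.0

        # best-first enumeration: state = (-bound, tiebreak, intervals, pairs)
        out: list[tuple[frozenset, float]] = []
        counter = itertools.count()
        heap = [(-mfe_score, next(counter), ((0, n - 1),) if n > 1 else (), ())]
        while heap and len(out) < self.max_candidates:
            negb, _, intervals, pairs = heapq.heappop(heap)
            if -negb < threshold - 1e-9:
                break
            if not intervals:
                out.append((frozenset(pairs), -negb))  # store the score
                continue
            (i, j), rest = intervals[0], intervals[1:]
            score_partial = -negb - bound(intervals, 0.0)
            if j - i < MIN_HAIRPIN + 1:
                # interval cannot hold a pair: resolve it as unpaired
                heapq.heappush(heap, (-bound(rest, score_partial), next(counter), rest, pairs))
                continue
            # j unpaired
            ni = ((i, j - 1),) + rest if j - 1 >= i else rest
            heapq.heappush(heap, (-bound(ni, score_partial), next(counter), ni, pairs))
            # j paired with k
            for k in range(i, j - MIN_HAIRPIN):
                sc = self._score(seq[k], seq[j])
                if sc <= 0:
                    continue
                ni = tuple(iv for iv in (((i, k - 1) if k > i else None),
                                         (k + 1, j - 1)) if iv is not None) + rest
                heapq.heappush(heap, (-bound(ni, score_partial + sc), next(counter),
                                      ni, pairs + ((k, j),)))
        if not out:
            out = [(frozenset(), 0.0)]
        # energies: negated scores, arbitrary units
        return [(p, -s) for p, s in out]


class ViennaRNABackend:
    """Thermodynamic backend over the ViennaRNA bindings (kcal/mol)."""

    name = "vienna"

    def __init__(self, max_candidates: int = 2000):
        import RNA  # deferred so the package imports without the bindings
        self._RNA = RNA
        self.max_candidates = max_candidates

    def candidates(self, seq: str, band: float) -> list[tuple[frozenset, float]]:
        if not seq:
            raise ValueError("empty window")
        if not any(_PAIR_SCORE.get((a, b)) for a in set(seq) for b in set(seq)):
            return [(frozenset(), 0.0)]
        fc = self._RNA.fold_compound(seq)
        ss, mfe = fc.mfe()
        if mfe >= 0:
            return [(parse_dotbracket(ss), float(mfe))]
        delta = max(1, int(round(band * abs(mfe) * 100)))
        sols = fc.subopt(delta)
        cands = sorted(((s.structure, float(s.energy)) for s in sols), key=lambda t: t[1])
        cands = cands[: self.max_candidates]
        return [(parse_dotbracket(db), e) for db, e in cands]


def default_backend():
    try:
        return ViennaRNABackend()
    except ImportError:  # pragma: no cover - bindings present in supported envs
        return NussinovBackend()


# ---------------------------------------------------------------------------
# shrep selection

def fold_window(seq_window: str, params: FoldingParams, backend=None,
                offset: int = 0) -> list[StructureHypothesis]:
    """Fold one window and return its shreps.

    Keeps at most ``max_shreps_per_window`` hypotheses with distinct shapes at
    the configured abstraction level, each within the energy band of the
    window MFE (for negative MFE: ``E <= (1 - band) * MFE``); the MFE
    structure itself is always retained.  Results are sorted by energy
    ascending.  Windows that cannot pair (for example all-N) yield a single
    zero-pair, all-external hypothesis.
    """
    if not seq_window:
        raise ValueError("empty window")
    backend = backend or default_backend()
    try:
        cands = backend.candidates(seq_window, params.energy_band)
    except Exception as exc:  # noqa: BLE001 - re-raise naming the window
        raise RuntimeError(f"folding backend failed on window at offset {offset}: {exc}") from exc
    cands = sorted(cands, key=lambda t: t[1])
    mfe = cands[0][1]
    threshold = (1.0 - params.energy_band) * mfe if mfe < 0 else mfe
    n = len(seq_window)
    chosen: list[StructureHypothesis] = []
    seen_shapes: set[str] = set()
    for pairs, energy in cands:
        if energy > threshold + 1e-9 and chosen:
            break
        shape = shape_string(pairs, 0, n, params.abstraction_level)
        if shape in seen_shapes:
            continue
        seen_shapes.add(shape)
        chosen.append(StructureHypothesis(
            window=(offset, offset + n),
            pairs=frozenset((i + offset, j + offset) for i, j in pairs),
            shape=shape, energy=energy))
        if len(chosen) >= params.max_shreps_per_window:
            break
    return chosen


def fold_context(context: str, params: FoldingParams | None = None,
                 backend=None) -> list[StructureHypothesis]:
    """All shreps of all windows of a site context, in context coordinates."""
    params = params or FoldingParams()
    backend = backend or default_backend()
    out: list[StructureHypothesis] = []
    for lo, hi in enumerate_windows(len(context), params):
        out.extend(fold_window(context[lo:hi], params, backend, offset=lo))
    return out
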