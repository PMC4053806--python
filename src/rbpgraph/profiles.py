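"""Per-nucleotide prediction profiles, site calling and motif matrices.

A trained model scores whole sites through the margin; to localize the
signal, each feature occurrence's contribution (weight times normalized
value) is attributed to the context positions of its root vertices — half
per root, a root's share spread over an abstract element's member
nucleotides, mirrored vertices mapped back to their original position.  The
positionwise sum therefore reproduces margin - bias exactly.

Binding-site calls average the profile over sliding 12-mers, keep the top
1% of windows across the whole collection and merge overlapping or abutting
selections.  Motifs pool, per folding hypothesis of each site, the
highest-scoring viewpoint 12-mer together with its structure-element string;
the 1000 best yield logo-ready sequence (A/C/G/U) and structure (S/E/H/I/M/B)
frequency matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .encode import AnnotatedGraph, encode_site, encode_with_structure
from .folding import STRUCTURE_ELEMENTS, StructureHypothesis, structure_elements
from .kernel import KernelParams, position_attribution
from .learn import LinearModel
from .prep import TargetSite

RNA_BASES = "ACGU"


@dataclass
class PredictionProfile:
    site_id: str
    values: np.ndarray  # one margin contribution per context position

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class Motif:
    kmers: list[tuple[str, str, float]]  # (sequence k-mer, element string, score)
    sequence_matrix: np.ndarray          # 4 x k frequencies over A,C,G,U
    structure_matrix: np.ndarray         # 6 x k frequencies over S,E,H,I,M,B

    def sequence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sequence_matrix, index=list(RNA_BASES))

    def structure_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.structure_matrix, index=list(STRUCTURE_ELEMENTS))


def nucleotide_profile(model: LinearModel, graph: AnnotatedGraph,
                       params: KernelParams | None = None,
                       context_len: int | None = None,
                       site_id: str = "") -> PredictionProfile:
    """Margin decomposition over context positions (sums to margin - bias)."""
    params = params or model.kernel_params
    if params != model.kernel_params:
        raise ValueError("profile parameters differ from the model's")
    _, pos_share = position_attribution(graph, params)
    if context_len is None:
        positions = [graph.position(v) for v in graph.vertices()
                     if graph.position(v) is not None]
        context_len = (max(positions) + 1) if positions else 0
    values = np.zeros(context_len)
    w = model.weights
    for pos, shares in pos_share.items():
        values[pos] = sum(w[fid] * s for fid, s in shares.items())
    return PredictionProfile(site_id, values)


def profile_site(model: LinearModel, site: TargetSite,
                 hypotheses: Sequence[StructureHypothesis] | None = None
                 ) -> PredictionProfile:
    graph = encode_site(site, hypotheses, mode=model.mode)
    return nucleotide_profile(model, graph, context_len=len(site.context_sequence),
                              site_id=site.site_id)


def window_scores(profile: PredictionProfile, w: int = 12) -> list[tuple[int, float]]:
    """Mean profile value of every sliding w-mer (step 1)."""
    v = profile.values
    if v.size < w:
        return []
    means = np.convolve(v, np.ones(w) / w, mode="valid")
    return [(i, float(means[i])) for i in range(means.size)]


def call_sites(scored_windows: Mapping[str, Sequence[tuple[int, float]]],
               top_fraction: float = 0.01, w: int = 12
               ) -> list[tuple[str, int, int, float]]:
    """High-affinity site calls from pooled window scores.

    Selects the ceil(top_fraction * N) highest-scoring windows across all
    sequences (ties broken by sequence id then position), then merges
    overlapping and directly abutting selections on the same sequence into
    one site scored by its best member window.
    """
    flat = [(seq_id, start, score)
            for seq_id, wins in scored_windows.items()
            for start, score in wins]
    if not flat:
        raise ValueError("no windows to select from")
    n_keep = math.ceil(top_fraction * len(flat))
    flat.sort(key=lambda t: (-t[2], t[0], t[1]))
    chosen = flat[:n_keep]

    by_seq: dict[str, list[tuple[int, float]]] = {}
    for seq_id, start, score in chosen:
        by_seq.setdefault(seq_id, []).append((start, score))
    out: list[tuple[str, int, int, float]] = []
    for seq_id in sorted(by_seq):
        wins = sorted(by_seq[seq_id])
        cur_start, cur_end, cur_score = wins[0][0], wins[0][0] + w, wins[0][1]
        for start, score in wins[1:]:
            if start <= cur_end:  # overlap or directly abutting
                cur_end = max(cur_end, start + w)
                cur_score = max(cur_score, score)
            else:
                out.append((seq_id, cur_start, cur_end, cur_score))
                cur_start, cur_end, cur_score = start, start + w, score
        out.append((seq_id, cur_start, cur_end, cur_score))
    return out


def extract_motif(model: LinearModel, sites: Sequence[TargetSite],
                  hypotheses: Sequence[Sequence[StructureHypothesis]],
                  k: int = 12, top_n: int = 1000,
                  max_sites: int = 2000) -> Motif:
    """Sequence/structure motif from the best k-mer of each folding hypothesis.

    Per (site, hypothesis) the hypothesis-restricted profile is computed, the
    highest-scoring k-mer fully inside the viewpoint is recorded with its
    structure-element string, the pooled k-mers are ranked (stable ties) and
    the ``top_n`` best become column-frequency matrices.
    """
    records: list[tuple[float, str, str, str, int]] = []
    for site, hyps in list(zip(sites, hypotheses))[:max_sites]:
        lo, hi = site.viewpoint
        if hi - lo < k:
            warnings.warn(f"viewpoint of {site.site_id} shorter than {k}; skipped")
            continue
        for hyp in hyps:
            graph = encode_with_structure(site, [hyp])
            prof = nucleotide_profile(model, graph,
                                      context_len=len(site.context_sequence),
                                      site_id=site.site_id)
            elements = structure_elements(hyp)
            wlo, whi = hyp.window
            best: tuple[float, int] | None = None
            for start in range(max(lo, wlo), min(hi, whi) - k + 1):
                score = float(prof.values[start:start + k].mean())
                if best is None or score > best[0]:
                    best = (score, start)
            if best is None:
                continue
            score, start = best
            seq_kmer = site.context_sequence[start:start + k]
            elem_kmer = "".join(elements.get(p, "E") for p in range(start, start + k))
            records.append((score, seq_kmer, elem_kmer, site.site_id, start))

    if not records:
        raise ValueError("no k-mers extracted")
    # stable: score desc, then site id, then position
    order = sorted(range(len(records)),
                   key=lambda i: (-records[i][0], records[i][3], records[i][4]))
    top = [records[i] for i in order[:top_n]]

    seq_mat = np.zeros((len(RNA_BASES), k))
    struct_mat = np.zeros((len(STRUCTURE_ELEMENTS), k))
    for score, seq_kmer, elem_kmer, _, _ in top:
        for col, (b, e) in enumerate(zip(seq_kmer, elem_kmer)):
            if b in RNA_BASES:
                seq_mat[RNA_BASES.index(b), col] += 1
            struct_mat[STRUCTURE_ELEMENTS.index(e), col] += 1
    seq_mat /= np.maximum(seq_mat.sum(axis=0, keepdims=True), 1e-12)
    struct_mat /= np.maximum(struct_mat.sum(axis=0, keepdims=True), 1e-12)
    return Motif([(s, e, sc) for sc, s, e, _, _ in top], seq_mat, struct_mat)


# ---------------------------------------------------------------------------
# writers

def write_profiles(profiles: Iterable[PredictionProfile], path) -> None:
    """bedGraph-style TSV: sequence_id, start, end, value."""
    with open(path, "w") as fh:
        for p in profiles:
            for i, v in enumerate(p.values):
                fh.write(f"{p.site_id}\t{i}\t{i + 1}\t{v:.6g}\n")


def write_called_sites(calls: Sequence[tuple[str, int, int, float]], path) -> None:
    """Called high-affinity sites as BED6."""
    with open(path, "w") as fh:
        for i, (seq_id, start, end, score) in enumerate(calls):
            fh.write(f"{seq_id}\t{start}\t{end}\tsite_{i}\t{score:.6g}\t+\n")


def write_motif(motif: Motif, prefix: str) -> None:
    """Plain top-k-mer list (WebLogo-ready) plus TRANSFAC-like matrices."""
    with open(f"{prefix}.kmers.txt", "w") as fh:
        for seq_kmer, elem_kmer, score in motif.kmers:
            fh.write(f"{seq_kmer}\t{elem_kmer}\t{score:.6g}\n")
    for name, frame in (("sequence", motif.sequence_frame()),
                        ("structure", motif.structure_frame())):
        with open(f"{prefix}.{name}.mat", "w") as fh:
            fh.write("PO\t" + "\t".join(str(i + 1) for i in range(frame.shape[1])) + "\n")
            for row in frame.index:
                vals = "\t".join(f"{v:.4f}" for v in frame.loc[row])
                fh.write(f"{row}\t{vals}\n")
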