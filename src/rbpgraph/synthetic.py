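"""Synthetic binding-site data with known ground truth.

Emulates the two experimental data sources the models are trained on: CLIP
style bound/unbound site sets (binary labels) and RNAcompete-style graded
affinities.  Positives carry an implanted recognition motif subject to
per-position mutation; in ``hairpin_loop`` context the motif is presented in
the loop of a designed stem so that the discriminative signal is partly
structural.  Affinities are a linear function of motif match quality plus
Gaussian noise.

Everything is driven by one seed and is byte-reproducible.  The generated
sites double as FASTA/BED inputs for the preparation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .prep import TargetSite, reverse_complement

RNA_BASES = "ACGU"
MOTIF_CONTEXTS = ("anywhere", "hairpin_loop", "stem_flanked")


@dataclass(frozen=True)
class SyntheticSpec:
    n_pos: int = 500
    n_neg: int = 500
    seq_len: int = 60
    motif: str = "ACGUACGU"
    motif_context: str = "anywhere"
    mutation_rate: float = 0.1
    affinity_noise_sd: float = 0.05
    seed: int = 0
    stem_len: int = 8          # designed stem length for structured contexts
    max_affinity_mutations: int = 2  # graded motif damage resolved by the assay
    decoy_motif: bool | None = None  # None: auto (True for hairpin_loop)
    markov_background: bool = False

    def __post_init__(self) -> None:
        if len(self.motif) >= self.seq_len:
            raise ValueError("motif must be shorter than the sequence")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.motif_context not in MOTIF_CONTEXTS:
            raise ValueError(f"motif_context must be one of {MOTIF_CONTEXTS}")
        if self.motif_context == "hairpin_loop" and \
                len(self.motif) + 2 * self.stem_len >= self.seq_len:
            raise ValueError("sequence too short to host stem + motif hairpin")

    @property
    def use_decoy(self) -> bool:
        if self.decoy_motif is None:
            return self.motif_context == "hairpin_loop"
        return self.decoy_motif


def _background(rng: np.random.Generator, n: int, markov: bool) -> str:
    if n <= 0:
        return ""
    if not markov:
        return "".join(np.array(list(RNA_BASES))[rng.integers(0, 4, n)])
    # simple first-order Markov chain with mild self-transition preference
    trans = np.full((4, 4), 0.2)
    np.fill_diagonal(trans, 0.4)
    out = [int(rng.integers(0, 4))]
    for _ in range(n - 1):
        out.append(int(rng.choice(4, p=trans[out[-1]])))
    return "".join(RNA_BASES[i] for i in out)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            others = [b for b in RNA_BASES if b != chars[i]]
            chars[i] = others[int(rng.integers(0, 3))]
    return "".join(chars)


def _implant(rng: np.random.Generator, spec: SyntheticSpec, structured: bool
             ) -> tuple[str, int]:
    """One sequence with the (mutated) motif implanted; returns (seq, motif_pos)."""
    motif = _mutate(rng, spec.motif, spec.mutation_rate)
    if structured:
        stem5 = _background(rng, spec.stem_len, False)
        insert = stem5 + motif + reverse_complement(stem5)
    else:
        insert = motif
    free = spec.seq_len - len(insert)
    pos = int(rng.integers(0, free + 1))
    left = _background(rng, pos, spec.markov_background)
    right = _background(rng, free - pos, spec.markov_background)
    seq = left + insert + right
    motif_pos = pos + (spec.stem_len if structured else 0)
    return seq, motif_pos


def match_score(seq: str, motif: str) -> float:
    """Best sliding-window identity between the motif and the sequence."""
    k = len(motif)
    if len(seq) < k:
        return 0.0
    return max(sum(a == b for a, b in zip(seq[i:i + k], motif)) / k
               for i in range(len(seq) - k + 1))


def generate_classification_set(spec: SyntheticSpec) -> list[TargetSite]:
    """Bound (+1) sites with the implanted motif and unbound (-1) sites.

    ``hairpin_loop`` positives present the motif in the loop of a designed
    stem; by default negatives then carry the motif in an unstructured
    context (``decoy_motif``), so the classes differ by structural
    presentation rather than mere motif presence.  Plain ``anywhere``
    negatives are pure background.
    """
    rng = np.random.default_rng(spec.seed)
    structured = spec.motif_context in ("hairpin_loop", "stem_flanked")
    sites: list[TargetSite] = []
    for i in range(spec.n_pos):
        seq, _ = _implant(rng, spec, structured)
        sites.append(TargetSite(f"pos_{i}", seq, (0, len(seq)), label=1))
    for i in range(spec.n_neg):
        if spec.use_decoy:
            seq, _ = _implant(rng, spec, structured=False)
        else:
            seq = _background(rng, spec.seq_len, spec.markov_background)
        sites.append(TargetSite(f"neg_{i}", seq, (0, len(seq)), label=-1))
    return sites


def generate_affinity_set(spec: SyntheticSpec) -> list[TargetSite]:
    """Graded-affinity sites: affinity = motif match score + Gaussian noise.

    ``n_pos`` sequences carry the motif implanted with a *graded* mutation
    load (the per-sequence number of mutated motif positions is uniform over
    0..``max_affinity_mutations``), emulating an affinity assay's spread of
    strong to moderate binders; ``n_neg`` background sequences sit at the
    non-binder floor, as heavily damaged motifs do in a real pull-down.  The
    true affinity is the best sliding match to the clean motif plus seeded
    Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    structured = spec.motif_context in ("hairpin_loop", "stem_flanked")
    sites: list[TargetSite] = []
    k = len(spec.motif)
    for i in range(spec.n_pos + spec.n_neg):
        if i < spec.n_pos:
            n_mut = int(rng.integers(0, spec.max_affinity_mutations + 1))
            graded = replace(spec, mutation_rate=n_mut / k)
            seq, _ = _implant(rng, graded, structured)
        else:
            seq = _background(rng, spec.seq_len, spec.markov_background)
        affinity = match_score(seq, spec.motif) + rng.normal(0.0, spec.affinity_noise_sd)
        sites.append(TargetSite(f"aff_{i}", seq, (0, len(seq)), affinity=float(affinity)))
    return sites


# ---------------------------------------------------------------------------
# pipeline dog-fooding: emit the formats the prep module consumes

def write_fasta_bed(sites: Sequence[TargetSite], fasta_path, bed_path) -> None:
    """Each site becomes a 'transcript' plus a BED record of its viewpoint."""
    with open(fasta_path, "w") as ff, open(bed_path, "w") as bf:
        for s in sites:
            ff.write(f">{s.site_id}\n{s.context_sequence}\n")
            lo, hi = s.viewpoint
            score = 0 if s.label is None else max(0, s.label)
            bf.write(f"{s.site_id}\t{lo}\t{hi}\t{s.site_id}\t{score}\t+\n")
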