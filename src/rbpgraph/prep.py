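"""Preparation of binding-site training data.

Reads transcript sequences (FASTA) and CLIP-derived binding-site intervals
(BED6), applies protocol-specific adjustments (iCLIP single-nucleotide sites
are widened by 15 nt on each side), removes sites longer than 75 nt, draws
matched unbound sites by shuffling coordinates within occupied genes, and
builds :class:`TargetSite` objects carrying the +-150 nt folding context with
the original site marked as the *viewpoint*.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: upstream/downstream widening applied to single-nucleotide iCLIP cross-link sites
ICLIP_EXTENSION = 15
#: maximum training-site length; longer CLIP peaks are too diffuse to anchor a viewpoint
MAX_SITE_LEN = 75
#: symmetric sequence context added around each site so folding sees the site's surroundings
CONTEXT_LEN = 150

PROTOCOLS = ("HITS-CLIP", "PAR-CLIP", "iCLIP", "generic")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval on a named sequence (0-based, half-open)."""

    sequence_id: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TargetSite:
    """A candidate binding site with folding context and viewpoint.

    ``context_sequence`` is the site plus flanking context (RNA alphabet);
    ``viewpoint`` delimits the original site within the context, 0-based
    half-open.  Training sites carry either a binary ``label`` (+1 bound,
    -1 unbound) or a continuous ``affinity``, never both.
    """

    site_id: str
    context_sequence: str
    viewpoint: tuple[int, int]
    label: int | None = None
    affinity: float | None = None
    source: GenomicInterval | None = None

    def __post_init__(self) -> None:
        lo, hi = self.viewpoint
        if not (0 <= lo < hi <= len(self.context_sequence)):
            raise ValueError(f"viewpoint {self.viewpoint} outside context of length "
                             f"{len(self.context_sequence)}")
        bad = set(self.context_sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-RNA characters in context: {sorted(bad)}")
        if self.label is not None and self.affinity is not None:
            raise ValueError("a training site carries a label or an affinity, not both")
        if self.label is not None and self.label not in (1, -1):
            raise ValueError("label must be +1 (bound) or -1 (unbound)")

    @property
    def viewpoint_sequence(self) -> str:
        lo, hi = self.viewpoint
        return self.context_sequence[lo:hi]


def sanitize_rna(seq: str) -> str:
    """Uppercase, convert T->U and validate against the RNA alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(source) -> dict[str, str]:
    """Read a (multi-)FASTA file into ``{id: RNA sequence}`` (T converted to U)."""
    records = SeqIO.parse(str(source), "fasta") if isinstance(source, (str, Path)) \
        else SeqIO.parse(source, "fasta")
    return {rec.id: sanitize_rna(str(rec.seq)) for rec in records}


def read_bed(source) -> list[GenomicInterval]:
    """Read BED6 (or BED3/4/5) intervals; missing strand defaults to '+'."""
    df = pd.read_csv(source, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("BED input needs at least 3 columns")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[3]) if df.shape[1] > 3 and not pd.isna(row[3]) else f"site_{i}"
        strand = str(row[5]) if df.shape[1] > 5 and str(row[5]) in ("+", "-") else "+"
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand, name))
    return out


def load_sites(bed_source, fasta_source, protocol: str = "generic") -> list[GenomicInterval]:
    """Load intervals and apply protocol rules against the reference sequences.

    iCLIP identifies single cross-linked nucleotides, so iCLIP intervals are
    enlarged by 15 nt on each side (clipped at sequence bounds) before any
    other processing; other protocols pass through unchanged.  Intervals
    extending past the end of their sequence are dropped with a warning;
    intervals on unknown sequences are an error.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    seqs = fasta_source if isinstance(fasta_source, Mapping) else read_fasta(fasta_source)
    intervals = bed_source if isinstance(bed_source, list) else read_bed(bed_source)
    out: list[GenomicInterval] = []
    for iv in intervals:
        if iv.sequence_id not in seqs:
            raise KeyError(f"interval references unknown sequence {iv.sequence_id!r}")
        seq_len = len(seqs[iv.sequence_id])
        if iv.end > seq_len:
            warnings.warn(f"interval {iv.name} [{iv.start},{iv.end}) beyond end of "
                          f"{iv.sequence_id} (len {seq_len}); skipped")
            continue
        if protocol == "iCLIP":
            iv = replace(iv, start=max(0, iv.start - ICLIP_EXTENSION),
                         end=min(seq_len, iv.end + ICLIP_EXTENSION))
        out.append(iv)
    return out


def filter_sites(sites: Sequence[GenomicInterval],
                 max_len: int = MAX_SITE_LEN) -> list[GenomicInterval]:
    """Drop sites longer than ``max_len`` nucleotides (order preserved)."""
    return [s for s in sites if len(s) <= max_len]


def make_negatives(positives: Sequence[GenomicInterval],
                   gene_bounds: Mapping[str, tuple[int, int]],
                   seed: int,
                   max_attempts: int = 1000,
                   same_gene: bool = True) -> list[GenomicInterval]:
    """Draw unbound sites by shuffling bound-site coordinates within occupied genes.

    One negative per positive, of the same length and strand, with a start
    drawn uniformly at random inside the bounds of an occupied gene.  Draws
    overlapping any positive interval are rejected (up to ``max_attempts``);
    a gene too saturated to host a non-overlapping negative drops that
    negative with a warning.  With ``same_gene=False`` the host gene is drawn
    uniformly from all occupied genes instead of being the source gene.
    """
    rng = np.random.default_rng(seed)
    occupied = sorted({p.sequence_id for p in positives})
    by_seq: dict[str, list[GenomicInterval]] = {}
    for p in positives:
        lo, hi = gene_bounds[p.sequence_id]
        if not (lo <= p.start and p.end <= hi):
            raise ValueError(f"positive {p.name} outside its gene bounds")
        by_seq.setdefault(p.sequence_id, []).append(p)

    negatives: list[GenomicInterval] = []
    for idx, p in enumerate(positives):
        length = len(p)
        placed = False
        for _ in range(max_attempts):
            gene = p.sequence_id if same_gene else occupied[rng.integers(len(occupied))]
            lo, hi = gene_bounds[gene]
            if hi - lo < length:
                continue
            start = int(rng.integers(lo, hi - length + 1))
            cand = GenomicInterval(gene, start, start + length, p.strand, f"neg_{idx}")
            if any(cand.start < q.end and q.start < cand.end for q in by_seq.get(gene, [])):
                continue
            negatives.append(cand)
            placed = True
            break
        if not placed:
            warnings.warn(f"could not place a non-overlapping negative for {p.name}; dropped")
    return negatives


def build_target_site(site: GenomicInterval, fasta_source,
                      context: int = CONTEXT_LEN) -> TargetSite:
    """Extend ``site`` by ``context`` nt on each side (clipped to the transcript)
    and mark the original interval as the viewpoint.

    On the minus strand the context is reverse-complemented and the viewpoint
    is re-expressed from the 5' end of the returned strand.
    """
    seqs = fasta_source if isinstance(fasta_source, Mapping) else read_fasta(fasta_source)
    seq = seqs[site.sequence_id]
    cstart = max(0, site.start - context)
    cend = min(len(seq), site.end + context)
    ctx = seq[cstart:cend]
    if site.strand == "-":
        ctx = reverse_complement(ctx)
        vp = (cend - site.end, cend - site.start)
    else:
        vp = (site.start - cstart, site.end - cstart)
    return TargetSite(site_id=site.name or f"{site.sequence_id}:{site.start}-{site.end}",
                      context_sequence=ctx, viewpoint=vp, source=site)


def filter_utrs(sequences: Mapping[str, str], min_len: int = 100,
                max_len: int = 3000) -> dict[str, str]:
    """Optional 3'-UTR selection utility: keep sequences within [min_len, max_len],
    sorted longest first (longer UTRs preferred)."""
    kept = {k: v for k, v in sequences.items() if min_len <= len(v) <= max_len}
    return dict(sorted(kept.items(), key=lambda kv: (-len(kv[1]), kv[0])))


def write_sites_tsv(sites: Iterable[TargetSite], path) -> None:
    rows = []
    for s in sites:
        rows.append({
            "site_id": s.site_id, "context": s.context_sequence,
            "viewpoint_start": s.viewpoint[0], "viewpoint_end": s.viewpoint[1],
            "label": "" if s.label is None else s.label,
            "affinity": "" if s.affinity is None else repr(s.affinity),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[TargetSite]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        label = int(row.label) if row.label != "" else None
        affinity = float(row.affinity) if row.affinity != "" else None
        out.append(TargetSite(row.site_id, row.context,
                              (int(row.viewpoint_start), int(row.viewpoint_end)),
                              label=label, affinity=affinity))
    return out


def write_viewpoint_fasta(sites: Iterable[TargetSite], path) -> None:
    """FASTA with the viewpoint uppercase and flanking context lowercase."""
    with open(path, "w") as fh:
        for s in sites:
            lo, hi = s.viewpoint
            seq = (s.context_sequence[:lo].lower() + s.context_sequence[lo:hi]
                   + s.context_sequence[hi:].lower())
            fh.write(f">{s.site_id}\n{seq}\n")


def read_viewpoint_fasta(source) -> list[TargetSite]:
    """Inverse of :func:`write_viewpoint_fasta` (uppercase run = viewpoint)."""
    out = []
    for rec in SeqIO.parse(str(source), "fasta"):
        raw = str(rec.seq)
        upper = [i for i, c in enumerate(raw) if c.isupper()]
        if not upper:
            raise ValueError(f"record {rec.id} has no uppercase viewpoint")
        out.append(TargetSite(rec.id, sanitize_rna(raw),
                              (upper[0], upper[-1] + 1)))
    return out
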