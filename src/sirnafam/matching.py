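"""Exact and Hamming-bounded matching of short reads against a gene family.

Reads are matched on both strands of every family member.  Exact matching
uses a k-mer seed table with full verification, so it is complete (every
occurrence is reported, none invented); Hamming matching is a vectorised
sliding-window scan over the whole family, complete by construction.  Both
report hits in a single convention: 0-based half-open offsets on the gene's
sense strand, with antisense occurrences expressed as the matching sense
interval.

An N never matches anything, including another N: exact matching of a read
containing N returns the empty set, and in Hamming mode every N position
(read or gene) counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family import GeneFamily, revcomp

SENSE = "sense"
ANTISENSE = "antisense"

DEFAULT_SEED_K = 12

# distinct non-matching codes for N on the two sides of a comparison
_READ_ENC = bytes.maketrans(b"N", bytes([1]))
_GENE_ENC = bytes.maketrans(b"N", bytes([2]))


@dataclass(frozen=True, order=True)
class MatchHit:
    """One gapless occurrence of a read on a family member.

    ``offset`` is the 0-based start of the half-open interval
    ``[offset, offset + read_len)`` on the gene's sense sequence, for both
    strands.
    """

    gene_id: str
    strand: str
    offset: int
    mismatches: int = 0


def _encode_gene(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(_GENE_ENC), dtype=np.uint8)


def _encode_read(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(_READ_ENC), dtype=np.uint8)


@dataclass
class FamilyIndex:
    """Seed table plus encoded sequences for one gene family.

    The table maps every N-free sense-strand k-mer to its (gene, offset)
    occurrences.  ``k`` is a performance knob only: any legal value yields
    identical query results (seeds are always verified in full).
    """

    family: GeneFamily
    k: int
    seeds: dict[str, list[tuple[str, int]]] = field(repr=False)
    _arrays: dict[str, np.ndarray] = field(repr=False)


def build_index(family: GeneFamily, k: int = DEFAULT_SEED_K) -> FamilyIndex:
    """Index both strands of every gene for seed-and-verify lookup."""
    if k < 8:
        raise ValueError("k must be >= 8")
    shortest = min(len(g) for g in family)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest gene length {shortest}")
    seeds: dict[str, list[tuple[str, int]]] = {}
    arrays: dict[str, np.ndarray] = {}
    for gene in family:
        seq = gene.sequence
        arrays[gene.gene_id] = _encode_gene(seq)
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if "N" in kmer:
                continue
            seeds.setdefault(kmer, []).append((gene.gene_id, off))
    return FamilyIndex(family, k, seeds, arrays)


def match_exact(read_sequence: str, index: FamilyIndex) -> set[MatchHit]:
    """All zero-mismatch occurrences of a read, both strands, all genes.

    A sense hit is a literal occurrence of the read in the gene; an
    antisense hit is an occurrence of the read's reverse complement, i.e.
    the read was processed from the opposite strand of that interval.
    """
    read = read_sequence.upper()
    if not read or "N" in read:
        return set()
    hits: set[MatchHit] = set()
    L, k = len(read), index.k
    for strand, query in ((SENSE, read), (ANTISENSE, revcomp(read))):
        if L >= k:
            for gene_id, off in index.seeds.get(query[:k], ()):
                seq = index.family.get(gene_id).sequence
                if seq[off : off + L] == query:
                    hits.add(MatchHit(gene_id, strand, off, 0))
        else:  # reads shorter than the seed: direct scan, still complete
            for gene in index.family:
                start = gene.sequence.find(query)
                while start != -1:
                    hits.add(MatchHit(gene.gene_id, strand, start, 0))
                    start = gene.sequence.find(query, start + 1)
    return hits


def match_hamming(
    read_sequence: str, index: FamilyIndex, max_mm: int
) -> set[MatchHit]:
    """All gapless occurrences within ``max_mm`` mismatches, both strands.

    Every position of every gene is examined, so the hit set is exhaustive.
    With ``max_mm=0`` the result equals :func:`match_exact` for N-free reads
    (an all-N read can never qualify since N always mismatches).
    """
    if not 0 <= max_mm <= 3:
        raise ValueError("max_mm must be in [0, 3]")
    read = read_sequence.upper()
    if not read:
        return set()
    L = len(read)
    queries = {
        SENSE: _encode_read(read),
        ANTISENSE: _encode_read(revcomp(read)),
    }
    hits: set[MatchHit] = set()
    for gene in index.family:
        arr = index._arrays[gene.gene_id]
        if len(arr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand, q in queries.items():
            mm = (windows != q).sum(axis=1)
            for off in np.flatnonzero(mm <= max_mm):
                hits.add(MatchHit(gene.gene_id, strand, int(off), int(mm[off])))
    return hits


def hits_to_rows(read: str, hits: set[MatchHit]) -> list[tuple]:
    """Flatten hits for a TSV dump (strand as +/-)."""
    return [
        (read, h.gene_id, "+" if h.strand == SENSE else "-", h.offset, h.mismatches)
        for h in sorted(hits)
    ]
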