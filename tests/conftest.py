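"""Shared fixtures: a hand-built toy family and a seeded synthetic family."""

from __future__ import annotations

import numpy as np
import pytest

import sirnafam as sf

# Two 60-nt paralogs sharing one perfect 20-nt block (positions 20-39 of
# each) surrounded by diverged sequence, plus an exact duplicate of the
# first: the minimal family exercising within-group multi-matching,
# cross-group ambiguity and the shared-block length cap.
SHARED20 = "ACGTACGTTGCAGGCTTAAC"  # 20 nt
GENE_A = "TTGACCTGAAGTCCGGATCA" + SHARED20 + "GGATCCTTAGCAACGGTCCA"
GENE_B = "CAGTTCGACTTAGGCCATGC" + SHARED20 + "TCCAGGTTCAACGTAGGACT"


@pytest.fixture(scope="session")
def toy_family() -> sf.GeneFamily:
    recs = [
        sf.GeneRecord("CHS4", GENE_A, "group1"),
        sf.GeneRecord("CHS4b", GENE_A, "group1"),  # identical repeat
        sf.GeneRecord("CHS7", GENE_B, "group2"),
    ]
    return sf.GeneFamily(recs, {"CHS4", "CHS4b"}, {"CHS7"})


@pytest.fixture(scope="session")
def toy_index(toy_family) -> sf.FamilyIndex:
    return sf.build_index(toy_family, k=8)


@pytest.fixture(scope="session")
def synth_family():
    family, report = sf.make_family(sf.SyntheticFamilySpec(), seed=11)
    return family, report


@pytest.fixture(scope="session")
def synth_index(synth_family) -> sf.FamilyIndex:
    return sf.build_index(synth_family[0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def naive_hamming_scan(
    read: str, family: sf.GeneFamily, max_mm: int
) -> set[sf.MatchHit]:
    """Reference matcher: sliding-window character comparison, both strands.

    Independent of the package's index/vectorised paths; N never matches.
    """
    hits: set[sf.MatchHit] = set()
    L = len(read)
    for gene in family:
        seq = gene.sequence
        for strand, query in ((sf.SENSE, read), (sf.ANTISENSE, sf.revcomp(read))):
            for off in range(len(seq) - L + 1):
                mm = sum(
                    1
                    for a, b in zip(query, seq[off : off + L])
                    if a != b or a == "N" or b == "N"
                )
                if mm <= max_mm:
                    hits.add(sf.MatchHit(gene.gene_id, strand, off, mm))
    return hits


def brute_force_lss(a: str, b: str, with_revcomp: bool) -> int:
    """All-substrings enumeration of the longest shared perfect substring."""
    targets = [b] + ([sf.revcomp(b)] if with_revcomp else [])
    best = 0
    for L in range(min(len(a), max(len(t) for t in targets)), 0, -1):
        subs = {
            a[i : i + L] for i in range(len(a) - L + 1) if "N" not in a[i : i + L]
        }
        if any(t[i : i + L] in subs for t in targets for i in range(len(t) - L + 1)):
            return L
    return best
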