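"""Gene-family model and paralog discriminability statistics.

A small-RNA read can only be assigned unambiguously to one paralog (or one
paralog subgroup) if no read-length stretch of sequence is shared perfectly
between the candidates.  This module models the gene family with its
origin/target group partition and computes the two statistics that justify
perfect-match read classification:

* pairwise percent identity under a documented global-alignment scheme, and
* the longest shared perfect substring (LSS) between each gene pair,
  strand-aware, whose length bounds the read length that can ever match both
  genes exactly.  ``min_unique_len = LSS + 1`` is the shortest read length
  guaranteed to discriminate the pair.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

GROUP1 = "group1"
GROUP2 = "group2"
NO_GROUP = "none"

#: Default subgroup partition of the nine-member soybean chalcone-synthase
#: family: the origin cluster genes and close relatives versus the two
#: silencing targets.
DEFAULT_GROUP1_IDS = ("CHS1", "CHS2", "CHS3", "CHS4", "CHS5", "CHS6", "CHS9")
DEFAULT_GROUP2_IDS = ("CHS7", "CHS8")

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One family member: coding-orientation sequence plus its group label."""

    gene_id: str
    sequence: str
    group_id: str = NO_GROUP
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        for pos, base in enumerate(self.sequence):
            if base not in _VALID_BASES:
                raise ValueError(
                    f"gene {self.gene_id!r}: invalid character {base!r} "
                    f"at position {pos}"
                )
        if self.group_id not in (GROUP1, GROUP2, NO_GROUP):
            raise ValueError(f"gene {self.gene_id!r}: bad group {self.group_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFamily:
    """Ordered gene collection with a two-subgroup partition.

    ``group1_ids`` holds the siRNA *origin* genes (the inverted-repeat
    cluster members), ``group2_ids`` the *target* genes whose transcripts
    are silenced in trans.  Genes in neither set carry group ``none`` and are
    still matched against, but do not enter group-level statistics.
    """

    genes: list[GeneRecord]
    group1_ids: frozenset[str] = field(default_factory=frozenset)
    group2_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate gene id(s): {sorted(dupes)}")
        self.group1_ids = frozenset(self.group1_ids)
        self.group2_ids = frozenset(self.group2_ids)
        if self.group1_ids & self.group2_ids:
            raise ValueError(
                f"groups overlap: {sorted(self.group1_ids & self.group2_ids)}"
            )
        known = set(ids)
        missing = (self.group1_ids | self.group2_ids) - known
        if missing:
            raise ValueError(f"group members not in family: {sorted(missing)}")
        # re-label records so record.group_id and the id sets agree
        relabelled = []
        for g in self.genes:
            grp = (
                GROUP1
                if g.gene_id in self.group1_ids
                else GROUP2
                if g.gene_id in self.group2_ids
                else NO_GROUP
            )
            relabelled.append(
                GeneRecord(g.gene_id, g.sequence, grp, g.source_note)
            )
        self.genes = relabelled

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def get(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def group_of(self, gene_id: str) -> str:
        return self.get(gene_id).group_id

    @classmethod
    def from_records(
        cls,
        records: Iterable[GeneRecord],
        group_map: Mapping[str, str] | None = None,
    ) -> "GeneFamily":
        """Build a family, defaulting to the canonical CHS partition.

        With ``group_map=None`` any record id found in the default CHS group
        lists gets that group; everything else gets ``none``.
        """
        records = list(records)
        if group_map is None:
            present = {r.gene_id for r in records}
            g1 = frozenset(DEFAULT_GROUP1_IDS) & present
            g2 = frozenset(DEFAULT_GROUP2_IDS) & present
        else:
            g1 = frozenset(k for k, v in group_map.items() if v == GROUP1)
            g2 = frozenset(k for k, v in group_map.items() if v == GROUP2)
        return cls(records, g1, g2)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f">{g.gene_id}\n")
                for i in range(0, len(g.sequence), 70):
                    fh.write(g.sequence[i : i + 70] + "\n")

    def group_map_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.group_id}\n")


def _open_maybe_gz(source):
    if hasattr(source, "read"):
        return source
    p = Path(source)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``gene_id<TAB>group`` -> mapping; blank lines skipped."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene_id, grp = parts
            if grp not in (GROUP1, GROUP2, NO_GROUP):
                raise ValueError(f"{path}:{lineno}: unknown group {grp!r}")
            out[gene_id] = grp
    return out


def read_family(
    fasta_source, group_map: Mapping[str, str] | str | Path | None = None
) -> GeneFamily:
    """Read family members from FASTA and attach the group partition.

    ``group_map`` may be a mapping, a path to a two-column TSV, or ``None``
    (canonical CHS defaults).  Records absent from the map get group
    ``none``.  Duplicate ids, empty input and non-ACGTN characters raise
    ``ValueError`` naming the offender.
    """
    if isinstance(group_map, (str, Path)):
        group_map = read_group_map(group_map)
    handle = _open_maybe_gz(fasta_source)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene id {rec.id!r} in FASTA")
        seen.add(rec.id)
        records.append(GeneRecord(rec.id, str(rec.seq), source_note=rec.description))
    if not records:
        raise ValueError("no FASTA records found")
    if group_map is not None:
        fam_map = {r.gene_id: group_map.get(r.gene_id, NO_GROUP) for r in records}
        return GeneFamily.from_records(records, fam_map)
    return GeneFamily.from_records(records, None)


# ---------------------------------------------------------------------------
# discriminability statistics


def _make_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity from a global end-to-end alignment.

    Scoring is match +1 / mismatch -1 / gap -2 (linear) by default; identity
    is 100 x identical columns / total alignment columns, unrounded.  An `N`
    never counts as identical, even against another `N`.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aln = _make_aligner(match, mismatch, gap).align(seq_a, seq_b)[0]
    cols = aln.shape[1]
    ident = 0
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        for ca, cb in zip(seq_a[a0:a1], seq_b[b0:b1]):
            if ca == cb and ca != "N":
                ident += 1
    return 100.0 * ident / cols


def _kmer_set(seq: str, k: int) -> set[str]:
    # substrings containing N cannot participate in a perfect shared block
    return {
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i : i + k]
    }


def _lcs_one_strand(seq_a: str, seq_b: str) -> int:
    lo, hi = 0, min(len(seq_a), len(seq_b))
    # binary search on shared-substring length (monotone: a shared k-mer
    # implies a shared (k-1)-mer)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _kmer_set(seq_a, mid) & _kmer_set(seq_b, mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def longest_shared_substring(
    seq_a: str, seq_b: str, with_revcomp: bool = True
) -> int:
    """Length of the longest string occurring contiguously in both sequences.

    With ``with_revcomp`` (the default, because siRNAs derive from both
    strands of a double-stranded precursor) occurrences in the reverse
    complement of ``seq_b`` count too.  Runs of N break shared blocks.
    Returns 0 when not even one base context is shared.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    best = _lcs_one_strand(seq_a, seq_b)
    if with_revcomp:
        best = max(best, _lcs_one_strand(seq_a, revcomp(seq_b)))
    return best


@dataclass
class DiscriminabilityReport:
    """Pairwise identity / shared-substring matrices for a family.

    ``min_unique_len`` is per-pair ``lss_len + 1``: the shortest read length
    at which an exact-matching read can never be attributed to both genes.
    """

    identity_pct: pd.DataFrame
    lss_len: pd.DataFrame
    min_unique_len: pd.DataFrame

    def write(self, outdir: str | Path, prefix: str = "discriminability") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.identity_pct.to_csv(outdir / f"{prefix}_identity_pct.tsv", sep="\t")
        self.lss_len.to_csv(outdir / f"{prefix}_lss_nt.tsv", sep="\t")
        self.min_unique_len.to_csv(
            outdir / f"{prefix}_min_unique_len_nt.tsv", sep="\t"
        )


def discriminability(family: GeneFamily) -> DiscriminabilityReport:
    """All-pairs identity and strand-aware LSS matrices for the family."""
    if len(family) < 2:
        raise ValueError("discriminability needs at least 2 genes")
    ids = family.gene_ids
    n = len(ids)
    ident = pd.DataFrame(0.0, index=ids, columns=ids)
    lss = pd.DataFrame(0, index=ids, columns=ids)
    for i in range(n):
        gi = family.genes[i]
        ident.iloc[i, i] = 100.0
        lss.iloc[i, i] = len(gi)
        for j in range(i + 1, n):
            gj = family.genes[j]
            pid = pairwise_identity(gi.sequence, gj.sequence)
            ell = longest_shared_substring(gi.sequence, gj.sequence, True)
            ident.iloc[i, j] = ident.iloc[j, i] = pid
            lss.iloc[i, j] = lss.iloc[j, i] = ell
    return DiscriminabilityReport(ident, lss, lss + 1)
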