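"""Read classification into origin/target siRNA populations and RPM reports.

Every collapsed read is matched exactly (0 mismatches, both strands) against
the family and labelled by the subgroup partition:

* ``group1_unique`` — matches at least one origin gene and no target gene;
* ``group2_unique`` — the converse;
* ``ambiguous``     — matches genes in both subgroups (possible only for
  reads no longer than the cross-group longest shared substring);
* ``unmatched``     — matches nothing.

Counts are normalised in reads per million (RPM) of the library's total
trimmed reads.  Per-gene profiles attribute each read to every gene it
matches (mirroring per-gene stacked-bar presentations; a ``fractional``
mode splits the count evenly instead), while group-level totals count each
read once and exclude ambiguous reads, which are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .family import GROUP1, GROUP2, GeneFamily
from .matching import FamilyIndex, match_exact, match_hamming

LABELS = ("group1_unique", "group2_unique", "ambiguous", "unmatched")

PER_GENE = "per-gene"
FRACTIONAL = "fractional"


@dataclass
class AssignmentTable:
    """Per-record exact-match gene sets and provenance labels.

    ``df`` columns: sequence, length, count, genes (sorted tuple of matched
    gene ids), label.  The labels partition the library's records.
    """

    library_id: str
    df: pd.DataFrame
    gene_ids: list[str]

    def label_counts(self) -> pd.Series:
        return self.df.groupby("label")["count"].sum().reindex(LABELS, fill_value=0)


def classify(library, family: GeneFamily, index: FamilyIndex) -> AssignmentTable:
    """Label every record of a collapsed library by its exact-match gene set."""
    if not family.group1_ids or not family.group2_ids:
        raise ValueError("classification needs at least one gene in each group")
    g1, g2 = family.group1_ids, family.group2_ids
    rows = []
    for seq, count in library.records.items():
        genes = tuple(sorted({h.gene_id for h in match_exact(seq, index)}))
        in1 = any(g in g1 for g in genes)
        in2 = any(g in g2 for g in genes)
        if in1 and in2:
            label = "ambiguous"
        elif in1:
            label = "group1_unique"
        elif in2:
            label = "group2_unique"
        else:
            label = "unmatched"
        rows.append((seq, len(seq), count, genes, label))
    df = pd.DataFrame(
        rows, columns=["sequence", "length", "count", "genes", "label"]
    )
    return AssignmentTable(library.library_id, df, family.gene_ids)


@dataclass
class ProfileMatrix:
    """Per-gene x read-length RPM matrix for one library.

    ``rpm`` rows are gene ids, columns read lengths of the retention window.
    ``gene_totals`` are row sums; ``group_totals`` count each read once per
    group (ambiguous reads excluded); ``label_rpm`` carries the four label
    totals, so that all label RPMs sum to the library's total RPM.
    """

    library_id: str
    rpm: pd.DataFrame
    gene_totals: pd.Series
    group_totals: dict[str, float]
    label_rpm: dict[str, float]


def profile(
    assignment: AssignmentTable,
    library,
    lengths: Sequence[int] = range(18, 26),
    attribution: str = PER_GENE,
) -> ProfileMatrix:
    """Build the per-gene RPM size profile from an assignment table.

    In ``per-gene`` mode a read matching several genes contributes its full
    RPM to each of them (rows may double-count); in ``fractional`` mode the
    count is split evenly over the matched genes.
    """
    if library.total_trimmed_reads == 0:
        raise ValueError("zero RPM denominator")
    if attribution not in (PER_GENE, FRACTIONAL):
        raise ValueError(f"unknown attribution mode {attribution!r}")
    lengths = list(lengths)
    mat = pd.DataFrame(0.0, index=assignment.gene_ids, columns=lengths)
    scale = 1e6 / library.total_trimmed_reads
    group_counts = {GROUP1: 0, GROUP2: 0}
    label_counts = dict.fromkeys(LABELS, 0)
    for seq, length, count, genes, label in assignment.df.itertuples(index=False):
        label_counts[label] += count
        if label == "group1_unique":
            group_counts[GROUP1] += count
        elif label == "group2_unique":
            group_counts[GROUP2] += count
        if not genes or length not in mat.columns:
            continue
        share = count / len(genes) if attribution == FRACTIONAL else count
        for g in genes:
            mat.loc[g, length] += share * scale
    return ProfileMatrix(
        assignment.library_id,
        mat,
        mat.sum(axis=1),
        {k: v * scale for k, v in group_counts.items()},
        {k: v * scale for k, v in label_counts.items()},
    )


@dataclass
class AmbiguityAudit:
    """Cross-group multi-matching RPM at several mismatch budgets.

    Row ``group1_vs_group2`` is the RPM of reads exactly matching at least
    one origin gene that also match a target gene within ``max_mm``
    mismatches; ``group2_vs_group1`` is the converse.  Monotone in the
    mismatch budget by construction.
    """

    library_id: str
    table: pd.DataFrame  # index: direction, columns: max_mm levels, values RPM


def ambiguity_audit(
    library, family: GeneFamily, index: FamilyIndex, mm_levels: Sequence[int] = (0, 2)
) -> AmbiguityAudit:
    """Re-map each group's exactly-matched reads against the other group."""
    g1, g2 = family.group1_ids, family.group2_ids
    mm_levels = sorted(mm_levels)
    overlap = {
        ("group1_vs_group2", mm): 0 for mm in mm_levels
    } | {("group2_vs_group1", mm): 0 for mm in mm_levels}
    for seq, count in library.records.items():
        exact_genes = {h.gene_id for h in match_exact(seq, index)}
        in1, in2 = bool(exact_genes & g1), bool(exact_genes & g2)
        if not (in1 or in2):
            continue
        max_level = mm_levels[-1]
        relaxed = match_hamming(seq, index, max_level)
        for mm in mm_levels:
            genes_mm = {h.gene_id for h in relaxed if h.mismatches <= mm}
            if in1 and genes_mm & g2:
                overlap[("group1_vs_group2", mm)] += count
            if in2 and genes_mm & g1:
                overlap[("group2_vs_group1", mm)] += count
    table = pd.DataFrame(
        {
            mm: [
                library.rpm(overlap[("group1_vs_group2", mm)]),
                library.rpm(overlap[("group2_vs_group1", mm)]),
            ]
            for mm in mm_levels
        },
        index=["group1_vs_group2", "group2_vs_group1"],
    )
    table.columns.name = "max_mm"
    return AmbiguityAudit(library.library_id, table)


def gene_restricted_counts(
    assignment: AssignmentTable,
    library,
    gene_a: str,
    gene_b: str,
    lengths: Sequence[int] = range(18, 26),
) -> pd.DataFrame:
    """Per-length RPM of reads matching one gene of a pair but not the other.

    Columns ``{gene_a}_only`` and ``{gene_b}_only``; reads matching both are
    excluded from both series.  Other co-matched genes are ignored — the
    restriction is pairwise.
    """
    for g in (gene_a, gene_b):
        if g not in assignment.gene_ids:
            raise KeyError(f"gene {g!r} not in family")
    out = pd.DataFrame(
        0.0, index=list(lengths), columns=[f"{gene_a}_only", f"{gene_b}_only"]
    )
    for _seq, length, count, genes, _label in assignment.df.itertuples(index=False):
        if length not in out.index:
            continue
        has_a, has_b = gene_a in genes, gene_b in genes
        if has_a == has_b:
            continue
        col = f"{gene_a}_only" if has_a else f"{gene_b}_only"
        out.loc[length, col] += library.rpm(count)
    out.index.name = "length"
    return out


@dataclass
class SeriesReport:
    """Stacked per-stage tables for a developmental or tissue series.

    ``transition_stage`` is the label of the first stage at which the
    target-derived (group 2) total RPM exceeds the origin-derived (group 1)
    total; ``None`` when it never does.
    """

    gene_rpm: pd.DataFrame        # rows (stage, gene), column rpm
    size_rpm: pd.DataFrame        # rows (stage, gene, length), column rpm
    exclusive_rpm: pd.DataFrame   # rows (stage, length), two *_only columns
    group_rpm: pd.DataFrame       # rows stage, columns group1/group2/ambiguous
    transition_stage: str | None
    transition_index: int | None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gene_rpm.to_csv(outdir / "gene_rpm.tsv", sep="\t")
        self.size_rpm.to_csv(outdir / "size_rpm.tsv", sep="\t")
        self.exclusive_rpm.to_csv(outdir / "exclusive_pair_rpm.tsv", sep="\t")
        self.group_rpm.to_csv(outdir / "group_rpm.tsv", sep="\t")
        with open(outdir / "transition.tsv", "w") as fh:
            fh.write("transition_stage\ttransition_index\n")
            fh.write(f"{self.transition_stage}\t{self.transition_index}\n")


def _pick_pair(family: GeneFamily, gene_a: str | None, gene_b: str | None):
    if gene_a is None:
        gene_a = "CHS4" if "CHS4" in family.gene_ids else sorted(family.group1_ids)[0]
    if gene_b is None:
        gene_b = "CHS7" if "CHS7" in family.gene_ids else sorted(family.group2_ids)[0]
    for g in (gene_a, gene_b):
        if g not in family.gene_ids:
            raise KeyError(f"gene {g!r} not in family")
    return gene_a, gene_b


def series_report(
    libraries,
    family: GeneFamily,
    index: FamilyIndex,
    lengths: Sequence[int] = range(18, 26),
    attribution: str = PER_GENE,
    gene_a: str | None = None,
    gene_b: str | None = None,
) -> SeriesReport:
    """Classify every library of a series and assemble the stacked tables.

    Libraries are processed in the given order, which defines the stage
    axis; duplicate library ids are rejected.
    """
    libraries = list(libraries)
    if not libraries:
        raise ValueError("empty series")
    ids = [lib.library_id for lib in libraries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library_ids in series")
    gene_a, gene_b = _pick_pair(family, gene_a, gene_b)
    gene_ids = family.gene_ids
    lengths = list(lengths)

    gene_rows, size_rows, excl_frames, group_rows = [], [], [], []
    transition_stage = transition_index = None
    for pos, lib in enumerate(libraries):
        asn = classify(lib, family, index)
        prof = profile(asn, lib, lengths, attribution)
        rpm = prof.rpm.reindex(gene_ids, fill_value=0.0)
        for g in gene_ids:
            gene_rows.append((lib.stage or lib.library_id, g, rpm.loc[g].sum()))
            for L in lengths:
                size_rows.append((lib.stage or lib.library_id, g, L, rpm.loc[g, L]))
        excl = gene_restricted_counts(asn, lib, gene_a, gene_b, lengths)
        excl.insert(0, "stage", lib.stage or lib.library_id)
        excl_frames.append(excl.reset_index())
        grp = {
            "stage": lib.stage or lib.library_id,
            "group1_rpm": prof.group_totals[GROUP1],
            "group2_rpm": prof.group_totals[GROUP2],
            "ambiguous_rpm": prof.label_rpm["ambiguous"],
        }
        group_rows.append(grp)
        if (
            transition_index is None
            and prof.group_totals[GROUP2] > prof.group_totals[GROUP1]
        ):
            transition_stage, transition_index = grp["stage"], pos

    gene_rpm = pd.DataFrame(gene_rows, columns=["stage", "gene", "rpm"]).set_index(
        ["stage", "gene"]
    )
    size_rpm = pd.DataFrame(
        size_rows, columns=["stage", "gene", "length", "rpm"]
    ).set_index(["stage", "gene", "length"])
    exclusive = pd.concat(excl_frames, ignore_index=True).set_index(
        ["stage", "length"]
    )
    group_rpm = pd.DataFrame(group_rows).set_index("stage")
    return SeriesReport(
        gene_rpm, size_rpm, exclusive, group_rpm, transition_stage, transition_index
    )
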