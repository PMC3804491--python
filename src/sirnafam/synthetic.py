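"""Ground-truth simulator for paralog-discriminative siRNA classification.

Generates (a) gene families with the sequence relationships that make
perfect-match classification valid — two subgroups with dispersed
polymorphisms, a configurable between-group identity (~82%) and a hard cap
on any cross-group perfect shared block (20 nt by default, so every read of
21 nt or more discriminates the groups) — and (b) developmental read series
reproducing the primary-to-secondary amplification: a low-abundance,
22-nt-enriched population from the origin genes present throughout, and a
21-nt-dominant population from the target genes that is absent before a
trigger stage, grows geometrically to a peak, then declines.

Everything is driven by explicit seeds; identical seeds give byte-identical
libraries.  Each simulated stage also yields a truth record (realized
primary/secondary read counts and length mixes) against which the
classification output can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .family import (
    DiscriminabilityReport,
    GeneFamily,
    GeneRecord,
    discriminability,
    revcomp,
)
from .read_prep import ReadLibrary

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_G1_NAMES = ("CHS1", "CHS3", "CHS4", "CHS2", "CHS5", "CHS6", "CHS9")
_G2_NAMES = ("CHS7", "CHS8", "CHS10", "CHS11", "CHS12")

#: stage labels of the emulated ten-stage seed developmental series:
#: whole seed early, dissected seed coats from 5-6 mg onward.
DEFAULT_STAGE_LABELS = (
    "4 DAF",
    "12-14 DAF",
    "22-24 DAF",
    "5-6 mg",
    "10-25 mg",
    "25-50 mg",
    "50-75 mg",
    "75-100 mg",
    "200-300 mg",
    "300-400 mg",
)

#: 22-nt-enriched origin (primary) length mix and 21-nt-dominant target
#: (secondary) mix; qualitative synthetic defaults, not measured values.
DEFAULT_PRIMARY_LEN_DIST = {
    18: 0.04, 19: 0.04, 20: 0.04, 21: 0.35, 22: 0.45, 23: 0.04, 24: 0.02, 25: 0.02,
}
DEFAULT_SECONDARY_LEN_DIST = {
    19: 0.02, 20: 0.05, 21: 0.85, 22: 0.05, 23: 0.02, 24: 0.01,
}


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Targets for the generated family's sequence relationships."""

    n_group1: int = 3
    n_group2: int = 2
    gene_len: int = 1170
    within_group_identity: float = 0.95
    between_group_identity: float = 0.82
    max_shared_block: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.within_group_identity <= 1):
            raise ValueError("within_group_identity must be in (0, 1]")
        if not (0 < self.between_group_identity < 1):
            raise ValueError("between_group_identity must be in (0, 1)")
        if self.max_shared_block >= self.gene_len:
            raise ValueError("max_shared_block must be < gene_len")
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("need at least one gene per group")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = seq.copy()
    sites = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in sites:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _break_shared_blocks(
    g1_seqs: dict[str, str],
    g2_arrs: dict[str, np.ndarray],
    cap: int,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> dict[str, str]:
    """Mutate group-2 genes until no cross-group perfect block exceeds cap.

    Shared (cap+1)-mers (on either strand of the group-1 side) are located
    in each group-2 gene and their centre base substituted; bounded retries
    guard against pathological specs.
    """
    k = cap + 1
    g1_kmers: set[str] = set()
    for s in g1_seqs.values():
        for strand in (s, revcomp(s)):
            g1_kmers.update(strand[i : i + k] for i in range(len(strand) - k + 1))
    out = {}
    for gid, arr in g2_arrs.items():
        for _ in range(max_rounds):
            s = _to_str(arr)
            hit = next(
                (j for j in range(len(s) - k + 1) if s[j : j + k] in g1_kmers),
                None,
            )
            if hit is None:
                break
            mid = hit + k // 2
            choices = _BASES[_BASES != arr[mid]]
            arr = arr.copy()
            arr[mid] = rng.choice(choices)
        else:
            raise RuntimeError(
                f"could not break shared blocks in {gid} within {max_rounds} rounds"
            )
        out[gid] = _to_str(arr)
    return out


def make_family(
    spec: SyntheticFamilySpec = SyntheticFamilySpec(), seed: int = 0
) -> tuple[GeneFamily, DiscriminabilityReport]:
    """Generate a family meeting the spec; returns it with achieved stats.

    A random group-1 ancestor is mutated lightly into group-1 members and,
    via a diverged group-2 ancestor, heavily into group-2 members; any
    cross-group perfect block longer than ``max_shared_block`` is then
    broken by point substitution.  Achieved pairwise identities and shared-
    substring lengths are measured on the output, not assumed.
    """
    rng = np.random.default_rng(seed)
    # per-site substitution model (mutation always changes the base):
    # two members of one group agree at a site w.p. e0 = (1-r)^2 + r^2/3;
    # across groups, sites where the ancestors already differ agree w.p.
    # e1 = 2r(1-r)/3 + 2r^2/9.  Solve e0 = within target for the member
    # rate r, then (1-D) e0 + D e1 = between target for the ancestor
    # divergence D.
    w, b = spec.within_group_identity, spec.between_group_identity
    r = (2.0 - np.sqrt(4.0 - 16.0 * (1.0 - w) / 3.0)) / (8.0 / 3.0)
    e0 = (1.0 - r) ** 2 + r**2 / 3.0
    e1 = 2.0 * r * (1.0 - r) / 3.0 + 2.0 * r**2 / 9.0
    d_between = (e0 - b) / (e0 - e1)
    if not 0 < d_between < 1:
        raise ValueError("between_group_identity must be below within_group_identity")
    anc1 = rng.choice(_BASES, size=spec.gene_len)
    anc2 = _mutate(anc1, d_between, rng)
    g1 = {
        _G1_NAMES[i % len(_G1_NAMES)] if i < len(_G1_NAMES) else f"CHSg1_{i}":
            _to_str(_mutate(anc1, r, rng))
        for i in range(spec.n_group1)
    }
    g2_arrs = {
        _G2_NAMES[i % len(_G2_NAMES)] if i < len(_G2_NAMES) else f"CHSg2_{i}":
            _mutate(anc2, r, rng)
        for i in range(spec.n_group2)
    }
    g2 = _break_shared_blocks(g1, g2_arrs, spec.max_shared_block, rng)
    records = [GeneRecord(gid, s, "group1", "synthetic") for gid, s in g1.items()]
    records += [GeneRecord(gid, s, "group2", "synthetic") for gid, s in g2.items()]
    fam = GeneFamily(records, frozenset(g1), frozenset(g2))
    report = discriminability(fam)
    for a in g1:
        for b in g2:
            if report.lss_len.loc[a, b] > spec.max_shared_block:
                raise RuntimeError("shared-block cap violated after repair")
    return fam, report


@dataclass(frozen=True)
class StageSpec:
    """Generative parameters of one library in a series.

    RPM targets are expected reads per million of the library; realized
    counts are a single multinomial draw over (primary, secondary,
    background), where background absorbs the remainder to 10^6 when left
    unset.  ``error_rate`` is a per-base substitution probability applied to
    gene-derived reads (0 by default so classification is noiseless).
    """

    stage_label: str
    primary_rpm: float
    secondary_rpm: float
    primary_len_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PRIMARY_LEN_DIST)
    )
    secondary_len_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SECONDARY_LEN_DIST)
    )
    background_rpm: float | None = None
    library_size: int = 100_000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primary_rpm < 0 or self.secondary_rpm < 0:
            raise ValueError("RPM targets must be >= 0")
        if self.library_size < 1_000:
            raise ValueError("library_size must be >= 1000")
        for dist in (self.primary_len_dist, self.secondary_len_dist):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("length distribution must sum to 1")
        bg = self.background_rpm
        if bg is None:
            bg = 1e6 - self.primary_rpm - self.secondary_rpm
            object.__setattr__(self, "background_rpm", bg)
        if bg < 0 or self.primary_rpm + self.secondary_rpm + bg > 1e6 + 1e-6:
            raise ValueError("combined RPM targets exceed 10^6")


@dataclass
class StageTruth:
    """Realized per-stage ground truth for recovery checks."""

    stage_label: str
    n_primary: int
    n_secondary: int
    n_background: int
    library_size: int
    primary_len_share: dict[int, float]
    secondary_len_share: dict[int, float]

    @property
    def primary_rpm(self) -> float:
        return 1e6 * self.n_primary / self.library_size

    @property
    def secondary_rpm(self) -> float:
        return 1e6 * self.n_secondary / self.library_size


def _draw_gene_reads(
    genes: list[GeneRecord],
    n: int,
    len_dist: dict[int, float],
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[list[str], dict[int, float]]:
    lens = np.array(sorted(len_dist))
    probs = np.array([len_dist[int(l)] for l in lens], dtype=float)
    drawn = rng.choice(lens, size=n, p=probs)
    gene_idx = rng.integers(0, len(genes), size=n)
    strands = rng.random(n) < 0.5
    reads = []
    for L, gi, anti in zip(drawn, gene_idx, strands):
        seq = genes[gi].sequence
        pos = int(rng.integers(0, len(seq) - int(L) + 1))
        read = seq[pos : pos + int(L)]
        if anti:
            read = revcomp(read)
        if error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
            sites = np.flatnonzero(rng.random(len(arr)) < error_rate)
            for i in sites:
                arr[i] = rng.choice(_BASES[_BASES != arr[i]])
            read = _to_str(arr)
        reads.append(read)
    if n:
        uniq, cnt = np.unique(drawn, return_counts=True)
        share = {int(u): float(c) / n for u, c in zip(uniq, cnt)}
    else:
        share = {}
    return reads, share


def _background_reads(n: int, rng: np.random.Generator) -> list[str]:
    lens = rng.integers(18, 26, size=n)
    return [
        _to_str(rng.choice(_BASES, size=int(L))) for L in lens
    ]


def simulate_stage(
    family: GeneFamily,
    stage_spec: StageSpec,
    *,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Draw one stage library from the family.

    Primary reads come from uniformly random positions and strands of the
    group-1 genes with the primary length mix; secondary reads likewise from
    group-2 genes; background reads are uniform random sequence.  Category
    counts are one multinomial draw matching the RPM targets in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(stage_spec.seed)
    g1 = [g for g in family if g.group_id == "group1"]
    g2 = [g for g in family if g.group_id == "group2"]
    probs = np.array(
        [stage_spec.primary_rpm, stage_spec.secondary_rpm, stage_spec.background_rpm]
    ) / 1e6
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    n_p, n_s, n_b, n_rest = rng.multinomial(stage_spec.library_size, probs)
    n_b += n_rest  # residual probability mass is background-like
    primary, p_share = _draw_gene_reads(
        g1, n_p, stage_spec.primary_len_dist, stage_spec.error_rate, rng
    )
    secondary, s_share = _draw_gene_reads(
        g2, n_s, stage_spec.secondary_len_dist, stage_spec.error_rate, rng
    )
    background = _background_reads(n_b, rng)
    lib = ReadLibrary(
        library_id=stage_spec.stage_label,
        stage=stage_spec.stage_label,
        total_trimmed_reads=stage_spec.library_size,
        records=_count(primary + secondary + background),
    )
    if not return_truth:
        return lib
    truth = StageTruth(
        stage_spec.stage_label,
        int(n_p),
        int(n_s),
        int(n_b),
        stage_spec.library_size,
        p_share,
        s_share,
    )
    return lib, truth


def _count(reads: list[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    return counts


@dataclass
class SeriesConfig:
    """A family spec plus the ordered stage specs of a series.

    ``trigger_stage`` is the index at which secondary (target-derived)
    production starts; before it every stage must have ``secondary_rpm`` 0.
    ``amplification_factor`` and ``decline_stage`` document the trajectory
    used to build the stages (geometric growth after the trigger, decay
    after the decline index).
    """

    family_spec: SyntheticFamilySpec
    stages: list[StageSpec]
    trigger_stage: int
    amplification_factor: float = 1.0
    decline_stage: int | None = None

    def __post_init__(self) -> None:
        for i, st in enumerate(self.stages[: self.trigger_stage]):
            if st.secondary_rpm != 0:
                raise ValueError(
                    f"stage {i} ({st.stage_label!r}) precedes the trigger but has "
                    "nonzero secondary_rpm"
                )


def default_series_config(
    seed: int = 0,
    library_size: int = 100_000,
    family_spec: SyntheticFamilySpec = SyntheticFamilySpec(),
) -> SeriesConfig:
    """The packaged ten-stage developmental trajectory.

    Origin-derived abundance is low (<100 RPM) in the three whole-seed
    stages, rises in dissected seed coats; target-derived reads start at the
    fourth stage (the trigger stage) already above the origin level — the
    overtake that defines the transition stage is part of the construction —
    grow geometrically (factor 2.3) to a peak near 8500 RPM at the seventh
    stage, then decay (factor 0.35) as the seed matures.
    """
    primary = [80, 50, 70, 300, 500, 700, 900, 700, 350, 150]
    trigger, ampl, decline, decay = 3, 2.3, 6, 0.35
    secondary = []
    for i in range(len(primary)):
        if i < trigger:
            secondary.append(0.0)
        elif i <= decline:
            secondary.append(700.0 * ampl ** (i - trigger))
        else:
            secondary.append(secondary[-1] * decay)
    seeds = np.random.SeedSequence(seed).generate_state(len(primary) + 1)
    stages = [
        StageSpec(
            stage_label=lbl,
            primary_rpm=float(p),
            secondary_rpm=float(s),
            library_size=library_size,
            seed=int(seeds[i + 1] % (2**31)),
        )
        for i, (lbl, p, s) in enumerate(
            zip(DEFAULT_STAGE_LABELS, primary, secondary)
        )
    ]
    return SeriesConfig(
        family_spec=family_spec,
        stages=stages,
        trigger_stage=trigger,
        amplification_factor=ampl,
        decline_stage=decline,
    )


def simulate_series(
    config: SeriesConfig, seed: int = 0
) -> tuple[GeneFamily, list[ReadLibrary], pd.DataFrame]:
    """Generate the family and every stage library plus the truth table.

    The truth table has one row per stage with realized primary/secondary
    RPM and 21/22-nt shares; per-stage randomness comes from each
    StageSpec's own seed, the family from ``seed``.
    """
    family, _report = make_family(config.family_spec, seed)
    libs, rows = [], []
    for st in config.stages:
        lib, truth = simulate_stage(family, st, return_truth=True)
        libs.append(lib)
        rows.append(
            {
                "stage": truth.stage_label,
                "n_primary": truth.n_primary,
                "n_secondary": truth.n_secondary,
                "n_background": truth.n_background,
                "library_size": truth.library_size,
                "primary_rpm": truth.primary_rpm,
                "secondary_rpm": truth.secondary_rpm,
                "primary_share_21": truth.primary_len_share.get(21, 0.0),
                "primary_share_22": truth.primary_len_share.get(22, 0.0),
                "secondary_share_21": truth.secondary_len_share.get(21, 0.0),
                "secondary_share_22": truth.secondary_len_share.get(22, 0.0),
            }
        )
    return family, libs, pd.DataFrame(rows).set_index("stage")


def write_bundle(
    family: GeneFamily,
    libraries: list[ReadLibrary],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """Write a directly re-analysable bundle: family FASTA + group map,
    per-stage collapsed FASTA, manifest TSV and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    family.to_fasta(outdir / "family.fasta")
    family.group_map_tsv(outdir / "group_map.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("library_id\tpath\tstage\n")
        for i, lib in enumerate(libraries):
            fname = f"stage_{i:02d}.fasta"
            lib.to_collapsed_fasta(outdir / fname)
            fh.write(f"{lib.library_id}\t{fname}\t{lib.stage}\n")
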