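# Methods

## The classification model

The package treats siRNA provenance as a set-membership problem. A gene
family is partitioned into an *origin* subgroup `G₁` (the genes whose
transcript, here an inverted-repeat-derived dsRNA, is diced into primary
siRNAs) and a *target* subgroup `G₂` (genes silenced in trans, whose
mRNAs template RdRP-dependent secondary siRNAs). A read is attributed by
its exact-match gene set on both strands: `group1_unique`, `group2_unique`,
`ambiguous` (matches both subgroups) or `unmatched`. The model's single
substantive assumption is that perfect matching is provenance-informative,
which holds exactly when read length exceeds the longest perfect substring
shared across the subgroup boundary. The discriminability module measures
that quantity rather than assuming it: for each gene pair it reports
percent identity, the strand-aware longest shared substring (LSS), and
`min_unique_len = LSS + 1`, the shortest read length at which cross-group
exact multi-matching is impossible.

Within-subgroup multi-matching (near-identical gene copies, up to the
identical-repeat limit) is expected and is not collapsed away: per-gene
profiles attribute a read to every gene it matches, which mirrors how
per-gene stacked abundance plots are normally drawn but double-counts
multi-matching reads across rows. Group-level totals and the transition
statistic instead count each read once and exclude ambiguous reads. A
`fractional` attribution mode (count split evenly over matched genes) is
available when additive per-gene rows are required.

## Sequence comparison choices

*Percent identity* uses global end-to-end alignment with match +1,
mismatch −1, linear gap −2 (Needleman–Wunsch via Biopython's
`PairwiseAligner`), identity = identical columns / alignment columns. The
scheme is a documented convention, configurable per call; nucleotide
identity over coding sequence is used throughout because the
discriminability question concerns the mature-mRNA sequence a read can
match. Among co-optimal alignments the aligner's first traceback is used;
with gaps costing strictly more than a mismatch this affects only
degenerate layouts. An `N` never counts as identical, even opposite
another `N`.

*Longest shared substring* is computed by binary search over block length
with k-mer set intersection (a shared k-mer implies a shared (k−1)-mer, so
the predicate is monotone). Reverse-complement occurrences count by
default, because siRNAs arise from both strands of a duplex; substrings
containing `N` are excluded. The brute-force all-substrings enumeration is
kept in the test suite as the independent reference.

## Read preparation

3′ adapters are removed by a semi-global scan: each read suffix is
compared with the adapter prefix of matching length; qualifying positions
need ≥ `min_overlap` (default 7) aligned bases with mismatch fraction
≤ `max_error_rate` (default 0.1), and the most-matching (tie: longest)
occurrence is trimmed away to the read end. A read reduced to an empty
insert is discarded. These defaults follow common small-RNA practice;
adapter-trimmer parity with any particular vendor pipeline is not claimed,
which matters when comparing absolute RPM values across tools.

The RPM denominator is the count of **all** trimmed, non-discarded reads
regardless of length; the 18–25-nt retention window (the usual siRNA
analysis range) applies only to the records carried into matching. Reads
containing `N` survive trimming, inflate the denominator, and can never
match. Collapsing to unique sequences with counts is exact: the
collapse → expand round trip restores the in-window multiset.

## The matching engine

Exact matching is seed-and-verify: every N-free k-mer (default k = 12) of
every sense sequence is tabled; a query's first k-mer (and its reverse
complement's) retrieves candidates that are verified by full string
comparison. Any legal k yields identical results — k is a performance
knob, enforced by test. Hamming matching slides the encoded read across
every position of every gene with a vectorised mismatch count, so it is
complete by construction; `N` is encoded to mismatch everything on either
side. Both report 0-based half-open intervals on the sense strand;
antisense hits are the sense interval whose reverse complement equals the
read. Mismatch budgets are gapless by design — the audit question is "how
many reads are within *m* substitutions of the other subgroup", and indels
are out of scope. Both paths are tested for equivalence against a naive
scan on randomized families.

## The simulator

`make_family` emulates the family's divergence structure rather than any
specific phylogeny: a random ancestor, light member-level substitution
within each subgroup, heavier divergence between subgroup ancestors.
Substitution rates are solved from the identity targets with the exact
per-site algebra (member rate r from within-identity = (1−r)² + r²/3;
ancestor divergence D from between-identity = (1−D)·e₀ + D·e₁), so achieved
identities centre on the targets; defaults are 0.95 within / 0.82 between,
1170-nt genes (a typical chalcone-synthase CDS length), three origin and
two target genes. Any cross-group perfect block longer than
`max_shared_block` (default 20 nt, either strand) is then broken by point
substitution, with bounded retries; the achieved statistics are re-measured
on the output and returned, never assumed. `within_group_identity = 1`
is allowed and models identical repeat copies.

Stage libraries draw read counts in one multinomial over
(primary, secondary, background) with probabilities equal to the RPM
targets /10⁶; background absorbs the residual mass. Primary reads are
substrings of uniformly chosen origin genes at uniform positions and
strands with a 22-nt-enriched length mix (22: 0.45, 21: 0.35, remainder
0.20); secondary reads come from target genes with a 21-nt-dominant mix
(21: 0.85). These mixes are explicit synthetic defaults chosen to
reproduce the qualitative size signature of primary versus secondary
siRNA populations, not measured proportions. Background reads are uniform
random 18–25-mers. Per-base sequencing error defaults to 0 so recovery
checks are crisp; it is configurable. Position uniformity is the neutral
choice in the absence of a positional model of dicing or RdRP processivity,
which the package deliberately does not attempt.

The packaged ten-stage series fixes the study conditions: origin-derived
abundance [80, 50, 70, 300, 500, 700, 900, 700, 350, 150] RPM across the
stage labels 4 DAF → 300–400 mg; target-derived production starts at stage
index 3 (the first seed-coat stage) at 700 RPM — already above the origin
level, so the overtake that defines the transition stage is part of the
construction and statistically unambiguous at the default 10⁵ reads per
stage — grows geometrically ×2.3 to ≈8500 RPM at stage index 6, then
decays ×0.35 per stage. Each stage carries its own seed derived from the
series seed; identical seeds give byte-identical libraries. Every
simulated stage also returns realized ground truth (category counts and
length mixes), and the recovery tests compare pipeline output against that
truth table: the only systematic leakage is cross-group-ambiguous ≤20-nt
reads, which the tests bound by the measured ambiguous RPM.

What the simulator does **not** emulate: phased siRNA registers, hairpin
structure, positional hotspots, ligation/PCR bias, quality-score error
profiles, or genomic background with real transcriptome complexity
(background is random sequence, so off-family false matching is
vanishingly rare). Passing recovery tests therefore demonstrates the
correctness of the bookkeeping and the validity of perfect-match
discrimination under the stated sequence relationships — not robustness to
every artefact of real libraries.

## Numerical and degenerate-input conventions

Zero surviving reads, an empty family side, duplicate gene or library ids,
k outside [8, shortest gene], mismatch budgets outside [0, 3], length
distributions not summing to 1, RPM targets exceeding 10⁶ and library
sizes under 10³ all raise immediately with the offending name in the
message. RPM values are floats scaled by 10⁶/N with no rounding inside the
pipeline; tables round only at the CLI/reporting edge. The transition
stage uses a strict inequality (group 2 > group 1) scanned in series
order; ties leave the earlier stages untransitioned.

## Problem sizes

Default verification sizes were chosen as the smallest that make the
statistics informative: randomized-family oracle checks use ≤5 genes ×
600 nt × ~150 reads; recovery runs use the packaged series at 10⁵ reads
per stage (10⁶ reads total), where a 3-SE band on a 300-RPM quantity is
~±50 RPM. The acceptance script uses the same series and finishes in well
under a minute.

## Known limitations

- Absolute RPM comparisons against externally processed libraries inherit
  adapter-trimmer and denominator conventions; both are documented above
  and configurable, but no claim of parity with proprietary pipelines is
  made.
- The identity score behind "percent identity" is convention-dependent at
  the 1% level (gap placement, end-gap treatment); the package fixes one
  documented convention rather than matching any external tool's.
- Hamming-only mismatch tolerance understates cross-group similarity when
  indels would align reads better; for ≤25-nt reads this is a second-order
  effect.
- The matching engine targets gene families (tens of kilobases of
  reference), not genome-scale mapping.
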