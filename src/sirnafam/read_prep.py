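"""Small-RNA read ingestion: 3' adapter trimming, collapsing, size window.

Raw small-RNA reads run past the insert into the 3' sequencing adapter, so
the adapter (or a prefix of it) must be located at the read's 3' end and
removed.  Surviving reads are collapsed to unique sequences with occurrence
counts; the library total of *all* trimmed, non-discarded reads is kept as
the reads-per-million denominator, while the analysis retains only reads in
the configured size window (default 18-25 nt).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

_VALID = frozenset("ACGTN")
_COLLAPSED_HEADER = re.compile(r"^(\S+)_(\d+)$")

#: Illumina TruSeq small-RNA 3' adapter; a documented default, overridable.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class TrimConfig:
    """Parameters of the 3' adapter search.

    The adapter (a prefix of it at the read end) is located by a semi-global
    scan; at least ``min_overlap`` bases must align with mismatch fraction at
    most ``max_error_rate``.
    """

    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 7
    max_error_rate: float = 0.1
    retain_min_len: int = 18
    retain_max_len: int = 25

    def __post_init__(self) -> None:
        if not (0 <= self.max_error_rate < 0.5):
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.retain_min_len > self.retain_max_len:
            raise ValueError("retain_min_len > retain_max_len")
        object.__setattr__(self, "adapter", self.adapter.upper())


def trim_adapter(read_sequence: str, config: TrimConfig = TrimConfig()) -> str | None:
    """Remove the best-scoring 3' adapter occurrence from a read.

    Scans every suffix of the read against the adapter prefix of matching
    length.  Among positions with overlap >= ``min_overlap`` and mismatch
    fraction <= ``max_error_rate``, the one with the most matching bases
    wins (leftmost on ties, i.e. the longest qualifying occurrence).  Returns
    the insert, the unchanged read when no occurrence qualifies, or ``None``
    (discard) when trimming leaves an empty insert.  N never matches.
    """
    read = read_sequence.upper()
    adapter = config.adapter
    n = len(read)
    best_score, best_start = -1, None
    for start in range(n):
        overlap = min(n - start, len(adapter))
        if overlap < config.min_overlap:
            break
        window = read[start : start + overlap]
        mism = sum(
            1
            for a, b in zip(window, adapter)
            if a != b or a == "N"
        )
        if mism / overlap > config.max_error_rate:
            continue
        score = overlap - mism
        if score > best_score:
            best_score, best_start = score, start
    if best_start is None:
        return read
    return read[:best_start] or None


@dataclass
class ReadLibrary:
    """Collapsed unique read sequences with counts plus library metadata.

    ``total_trimmed_reads`` counts every non-discarded trimmed read of any
    length and is the RPM denominator; ``records`` keeps only in-window
    sequences.
    """

    library_id: str
    stage: str
    total_trimmed_reads: int
    records: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_trimmed_reads < 0:
            raise ValueError("negative read total")
        if sum(self.records.values()) > self.total_trimmed_reads:
            raise ValueError("record counts exceed library total")
        if any(c <= 0 for c in self.records.values()):
            raise ValueError("non-positive record count")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def in_window_reads(self) -> int:
        return sum(self.records.values())

    def rpm(self, count: int) -> float:
        return 1e6 * count / self.total_trimmed_reads

    def expand(self) -> Iterator[str]:
        """Stream each retained sequence count-many times (round-trip aid)."""
        for seq, count in self.records.items():
            for _ in range(count):
                yield seq

    def to_collapsed_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (seq, count) in enumerate(self.records.items(), 1):
                fh.write(f">r{i}_{count}\n{seq}\n")


def collapse(
    reads_stream: Iterable[str | None],
    retain_min_len: int = 18,
    retain_max_len: int = 25,
    *,
    library_id: str = "",
    stage: str = "",
) -> ReadLibrary:
    """Aggregate trimmed reads into a :class:`ReadLibrary`.

    ``None`` entries (discards) are dropped entirely; out-of-window reads
    still count toward the RPM denominator but produce no record.
    """
    total = 0
    counts: dict[str, int] = {}
    for read in reads_stream:
        if read is None:
            continue
        total += 1
        if retain_min_len <= len(read) <= retain_max_len:
            counts[read] = counts.get(read, 0) + 1
    if total == 0:
        raise ValueError(f"library {library_id!r}: no surviving reads")
    return ReadLibrary(library_id, stage, total, counts)


def _open_text(source):
    if hasattr(source, "read"):
        return source
    p = Path(source)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p)


def _parse_fastq(handle) -> Iterator[tuple[str, str, int]]:
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise ValueError(f"line {lineno}: FASTQ header must start with '@'")
        seq = handle.readline().rstrip("\n")
        plus = handle.readline().rstrip("\n")
        qual = handle.readline().rstrip("\n")
        if not qual and not plus:
            raise ValueError(f"line {lineno}: truncated FASTQ record")
        if not plus.startswith("+"):
            raise ValueError(f"line {lineno + 2}: expected '+' separator")
        if len(qual) != len(seq):
            raise ValueError(f"line {lineno + 3}: quality length != sequence length")
        lineno += 3
        yield header[1:].split()[0], seq.upper(), 1


def _parse_fasta(handle) -> Iterator[tuple[str, str, int]]:
    name, chunks, lineno, start = None, [], 0, 0
    for line in handle:
        lineno += 1
        line = line.rstrip("\n")
        if line.startswith(">"):
            if name is not None:
                yield _fasta_record(name, chunks, start)
            name, chunks, start = line[1:].split()[0] if line[1:] else "", [], lineno
            if not name:
                raise ValueError(f"line {lineno}: empty FASTA header")
        elif line.startswith("@"):
            raise ValueError(f"line {lineno}: mixed FASTA/FASTQ input")
        else:
            if name is None:
                raise ValueError(f"line {lineno}: sequence before first header")
            chunks.append(line.strip().upper())
    if name is not None:
        yield _fasta_record(name, chunks, start)


def _fasta_record(name: str, chunks: list[str], lineno: int):
    seq = "".join(chunks)
    if not seq:
        raise ValueError(f"line {lineno}: record {name!r} has no sequence")
    m = _COLLAPSED_HEADER.match(name)
    count = int(m.group(2)) if m else 1
    if m and count == 0:
        raise ValueError(f"line {lineno}: record {name!r} has zero count")
    return name, seq, count


def read_library(
    source,
    library_id: str,
    stage: str = "",
    trim_config: TrimConfig | None = TrimConfig(),
) -> ReadLibrary:
    """Read FASTQ or FASTA (optionally gzipped), trim, window, and collapse.

    Pre-collapsed FASTA with ``id_count`` headers is honoured: a record named
    ``read1_57`` contributes 57 occurrences.  ``trim_config=None`` skips
    trimming (input already trimmed) but still applies the default window.
    """
    handle = _open_text(source)
    first = handle.read(1)
    if not first:
        raise ValueError(f"library {library_id!r}: empty input")
    parser = _parse_fastq if first == "@" else _parse_fasta
    if first not in "@>":
        raise ValueError("line 1: input is neither FASTA nor FASTQ")

    class _Chain:
        def __init__(self, head, rest):
            self._head, self._rest = head, rest

        def readline(self):
            if self._head is not None:
                line = self._head + self._rest.readline()
                self._head = None
                return line
            return self._rest.readline()

        def __iter__(self):
            line = self.readline()
            while line:
                yield line
                line = self.readline()

    cfg = trim_config or TrimConfig()

    def stream():
        for _name, seq, count in parser(_Chain(first, handle)):
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"record {_name!r}: invalid character(s) {sorted(bad)}"
                )
            trimmed = trim_adapter(seq, cfg) if trim_config is not None else (seq or None)
            for _ in range(count):
                yield trimmed

    return collapse(
        stream(),
        cfg.retain_min_len,
        cfg.retain_max_len,
        library_id=library_id,
        stage=stage,
    )
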