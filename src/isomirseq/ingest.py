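"""FASTQ ingestion: adapter trimming, quality/length filtering, collapsing.

Small-RNA inserts are short (a mature miRNA is ~22 nt), so each read is
expected to run into the 3' sequencing adapter.  Trimming finds the
leftmost occurrence of the adapter's first 8 nt, allowing one mismatch,
and truncates there.  Filtering keeps reads of 16-36 nt with mean Phred
quality >= 20 by default: the 16 nt floor is the usual small-RNA cutoff
below which reads cannot be assigned to a miRNA, and the mean-quality
rule is this package's explicit stand-in for vendor "low quality read"
removal (the exact vendor rule is typically undocumented; ours is logged
and configurable).

Identical surviving reads are collapsed to (sequence, count) pairs,
which is what the downstream classifier consumes — classification cost
then scales with sequence diversity, not library depth.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 16
DEFAULT_MAX_LEN = 36
DEFAULT_MIN_MEAN_Q = 20.0
_ADAPTER_SEED_LEN = 8


class AdapterConfigError(ValueError):
    """Adapter too short to define a trimming seed."""


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    qualities: tuple[int, ...]  # Phred scores, one per base

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("collapsed read count must be >= 1")


@dataclass
class FilterReport:
    """Per-reason discard tallies from quality/length filtering."""

    kept: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0

    @property
    def discarded(self) -> int:
        return self.too_short + self.too_long + self.low_quality


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a (possibly gzipped) Sanger Phred+33 FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(
                id=title.split()[0],
                sequence=seq.upper().replace("U", "T"),
                qualities=tuple(ord(c) - 33 for c in qual),
            )


def _seed_matches(window: str, seed: str, max_mismatch: int = 1) -> bool:
    mism = 0
    for a, b in zip(window, seed):
        if a != b:
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def trim_adapter(read: RawRead, adapter: str) -> RawRead | None:
    """Truncate a read at the leftmost adapter match; None means discard.

    The match uses the adapter's first 8 nt as a seed with at most one
    mismatch.  Reads without any seed match are returned unchanged; a
    read that is pure adapter (empty insert) is discarded.
    """
    adapter = adapter.upper().replace("U", "T")
    if len(adapter) < _ADAPTER_SEED_LEN:
        raise AdapterConfigError(
            f"adapter must be at least {_ADAPTER_SEED_LEN} nt, got {len(adapter)}"
        )
    seed = adapter[:_ADAPTER_SEED_LEN]
    seq = read.sequence
    cut = None
    for i in range(len(seq) - _ADAPTER_SEED_LEN + 1):
        if _seed_matches(seq[i : i + _ADAPTER_SEED_LEN], seed):
            cut = i
            break
    if cut is None:
        return read
    if cut == 0:
        return None
    return RawRead(read.id, seq[:cut], read.qualities[:cut])


def quality_length_filter(
    reads: Iterable[RawRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    report: FilterReport | None = None,
) -> Iterator[RawRead]:
    """Keep reads with min_len <= length <= max_len and mean Phred >= min_mean_q.

    Pass a :class:`FilterReport` to collect per-reason discard counts.
    """
    for read in reads:
        n = len(read.sequence)
        if n < min_len:
            if report:
                report.too_short += 1
            continue
        if n > max_len:
            if report:
                report.too_long += 1
            continue
        if sum(read.qualities) / n < min_mean_q:
            if report:
                report.low_quality += 1
            continue
        if report:
            report.kept += 1
        yield read


def collapse_reads(reads: Iterable[RawRead], sample_id: str) -> list[CollapsedRead]:
    """Collapse identical sequences to (sequence, count); count-conserving."""
    counts: dict[str, int] = {}
    for read in reads:
        counts[read.sequence] = counts.get(read.sequence, 0) + 1
    return [
        CollapsedRead(seq, n, sample_id)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def ingest_fastq(
    path: str | Path,
    sample_id: str,
    adapter: str | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
) -> tuple[list[CollapsedRead], FilterReport]:
    """Full ingest: FASTQ -> trim -> filter -> collapse."""
    report = FilterReport()

    def trimmed() -> Iterator[RawRead]:
        for read in read_fastq(path):
            if adapter is not None:
                out = trim_adapter(read, adapter)
                if out is None:
                    continue
                read = out
            yield read

    survivors = quality_length_filter(
        trimmed(), min_len=min_len, max_len=max_len, min_mean_q=min_mean_q, report=report
    )
    collapsed = collapse_reads(survivors, sample_id)
    logger.info(
        "ingest %s: kept=%d too_short=%d too_long=%d low_quality=%d distinct=%d "
        "(mean-Phred>=%g rule is this package's low-quality stand-in)",
        sample_id,
        report.kept,
        report.too_short,
        report.too_long,
        report.low_quality,
        len(collapsed),
        min_mean_q,
    )
    return collapsed, report


def write_collapsed_tsv(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\tsample_id\n")
        for c in collapsed:
            fh.write(f"{c.sequence}\t{c.count}\t{c.sample_id}\n")


def read_collapsed_tsv(path: str | Path) -> list[CollapsedRead]:
    out: list[CollapsedRead] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sequence", "count", "sample_id"]:
            raise ValueError(f"unexpected collapsed-read header: {header}")
        for line in fh:
            seq, count, sample = line.rstrip("\n").split("\t")
            out.append(CollapsedRead(seq, int(count), sample))
    return out
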