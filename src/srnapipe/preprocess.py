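"""Read-level preprocessing: 3' adapter trimming and quality/length filters.

The filters mirror a standard bacterial sRNA-Seq screen: reads shorter than
18 nt after trimming are set aside as "short", and reads whose mean Phred
score is below 20 are discarded as low quality.  Size selection to <=200 nt
happens on the gel before sequencing, so no upper length bound is applied to
reads here; oversize handling lives at the transcript-unit level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .genome_io import Read


@dataclass
class PreprocessParams:
    adapter_3p: str = ""
    min_length: int = 18
    min_mean_phred: float = 20.0
    max_length: int = 200  # informational: applied to transcript units, not reads

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not (0 <= self.min_mean_phred <= 60):
            raise ValueError("min_mean_phred must be in [0, 60]")
        if self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


#: Minimum adapter prefix length that counts as a match.
MIN_ADAPTER_MATCH = 5


def trim_adapter(read: Read, adapter_3p: str, min_match: int = MIN_ADAPTER_MATCH) -> Read:
    """Remove a 3' adapter by exact prefix matching.

    The read is truncated at the leftmost position where a prefix of the
    adapter (length >= ``min_match``) matches and runs to the read's 3' end
    (or the full adapter occurs, with sequence after it).  Qualities are
    truncated in lockstep.  Reads without a match pass through unchanged.
    """
    if not adapter_3p:
        raise ValueError("adapter sequence must be non-empty")
    adapter = adapter_3p.upper()
    seq = read.sequence
    n, alen = len(seq), len(adapter)
    for i in range(n - min_match + 1):
        m = min(alen, n - i)
        if seq[i : i + m] == adapter[:m]:
            return Read(id=read.id, sequence=seq[:i], qualities=read.qualities[:i])
    return read


@dataclass
class FilterReport:
    """Counts by outcome; categories are disjoint and partition the input."""

    total: int = 0
    kept: int = 0
    short: int = 0
    low_quality: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"total": self.total, "kept": self.kept,
                "short": self.short, "low_quality": self.low_quality}


def filter_reads(
    reads: Iterable[Read], params: PreprocessParams, report: FilterReport | None = None
) -> Iterator[Read]:
    """Yield reads passing the length and mean-Phred filters.

    Rejection precedence is short -> low_quality: a read failing both counts
    once, as "short", so the report partitions the input exactly.
    Pass a FilterReport to collect counts while streaming.
    """
    if report is None:
        report = FilterReport()
    for read in reads:
        report.total += 1
        if len(read) < params.min_length:
            report.short += 1
        elif read.mean_quality < params.min_mean_phred:
            report.low_quality += 1
        else:
            report.kept += 1
            yield read


def preprocess(
    reads: Iterable[Read], params: PreprocessParams
) -> tuple[list[Read], FilterReport]:
    """Trim the 3' adapter from every read, then apply the read filters."""
    report = FilterReport()
    trimmed = (trim_adapter(r, params.adapter_3p) for r in reads)
    kept = list(filter_reads(trimmed, params, report))
    return kept, report
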