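"""A minimal exact-match short-read mapper.

Lets the whole pipeline run on simulated libraries with no external aligner:
every exact, full-length occurrence of a read (or its reverse complement) in
the genome is reported, with uniqueness flagged from the total occurrence
count.  Real libraries should be mapped with a production aligner and passed
in as SAM; this engine exists so synthetic scenarios are self-contained.

The index is a hash table of fixed-length seeds over the forward strand of
every replicon; a read is looked up by its first seed (the read itself if
shorter than the seed length) and each hit is verified by full comparison.
``N`` in the genome never matches.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genome_io import Alignment, Genome, Read, reverse_complement

DEFAULT_SEED_LENGTH = 14


class GenomeIndex:
    """Seed-table index over the forward strands of a genome."""

    def __init__(self, genome: Genome, seed_length: int = DEFAULT_SEED_LENGTH):
        self.genome = genome
        self.k = seed_length
        # seed -> list of (replicon_id, 0-based offset)
        self._table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for rep in genome.replicons:
            seq = rep.sequence
            for i in range(len(seq) - self.k + 1):
                seed = seq[i : i + self.k]
                if "N" not in seed:
                    self._table[seed].append((rep.id, i))

    def occurrences(self, pattern: str) -> list[tuple[str, int]]:
        """All (replicon_id, 1-based start) exact occurrences on forward strands."""
        if not pattern or "N" in pattern:
            return []
        hits: list[tuple[str, int]] = []
        if len(pattern) < self.k:
            # rare at sRNA read lengths: fall back to a direct scan
            for rep in self.genome.replicons:
                start = rep.sequence.find(pattern)
                while start != -1:
                    hits.append((rep.id, start + 1))
                    start = rep.sequence.find(pattern, start + 1)
            return hits
        seed = pattern[: self.k]
        for rep_id, off in self._table.get(seed, ()):
            seq = self.genome[rep_id].sequence
            if seq[off : off + len(pattern)] == pattern:
                hits.append((rep_id, off + 1))
        return sorted(hits)


def map_reads(
    reads: Iterable[Read],
    genome: Genome | GenomeIndex,
    max_report: int = 10,
    unmapped: list[str] | None = None,
) -> list[Alignment]:
    """Map reads by exact full-length matching on both strands.

    Reverse-complement hits carry strand ``-`` with coordinates on the forward
    axis.  ``is_unique`` is true iff the read occurs exactly once in the whole
    genome (both strands counted), regardless of ``max_report``.  Unmapped read
    ids are appended to ``unmapped`` when a list is supplied.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    alignments: list[Alignment] = []
    for read in reads:
        seq = read.sequence
        if not seq:
            if unmapped is not None:
                unmapped.append(read.id)
            continue
        fwd = index.occurrences(seq)
        rev = index.occurrences(reverse_complement(seq))
        # (replicon, start, strand), sorted for deterministic output
        placements = sorted(
            [(rep, pos, "+") for rep, pos in fwd] + [(rep, pos, "-") for rep, pos in rev]
        )
        if not placements:
            if unmapped is not None:
                unmapped.append(read.id)
            continue
        unique = len(placements) == 1
        for rep_id, pos, strand in placements[:max_report]:
            alignments.append(
                Alignment(read_id=read.id, replicon_id=rep_id, start=pos,
                          end=pos + len(seq) - 1, strand=strand, is_unique=unique)
            )
    return alignments


def write_sam(alignments: Iterable[Alignment], genome: Genome, path: str | Path) -> None:
    """Emit alignments as minimal valid SAM (FLAG, POS, CIGAR=<len>M).

    The first alignment of a multi-mapping read is primary; the rest carry the
    secondary flag.  Output is sorted by (replicon, start, strand, read id).
    """
    alignments = sorted(alignments, key=lambda a: (a.replicon_id, a.start, a.strand, a.read_id))
    seen: set[str] = set()
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for rep in genome.replicons:
            fh.write(f"@SQ\tSN:{rep.id}\tLN:{rep.length}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            if a.read_id in seen:
                flag |= 256
            seen.add(a.read_id)
            seq = genome.fetch(a.replicon_id, a.start, a.end, "+")
            fh.write(
                f"{a.read_id}\t{flag}\t{a.replicon_id}\t{a.start}\t"
                f"{0 if not a.is_unique else 60}\t{a.length}M\t*\t0\t0\t{seq}\t*\n"
            )
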