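"""Unification of near-identical aligned reads into transcript units.

Aligned sRNA reads from the same transcript typically differ by only a few
nucleotides at their ends.  Unification collapses this variation: within each
(replicon, strand), alignments are grouped by exact interval, interval groups
are ranked by multiplicity (ties: leftmost start, then shortest), and each
group not yet absorbed becomes a seed that absorbs every remaining group whose
5' AND 3' ends lie within ``end_tolerance`` of its own.  The unit keeps the
seed's coordinates — the most abundant boundary is the putative TSS/terminus —
and its representative sequence is the genome subsequence of that interval
(reverse-complemented on strand ``-``).

The ranking makes the greedy clustering canonical: the output is invariant
under permutation of the input alignments.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import Alignment, Genome


@dataclass
class UnifyParams:
    end_tolerance: int = 5
    end_tolerance_3p: int | None = None  # None: same as end_tolerance
    max_unit_length: int = 310

    def __post_init__(self) -> None:
        if self.end_tolerance < 0:
            raise ValueError("end_tolerance must be >= 0")

    @property
    def tol5(self) -> int:
        return self.end_tolerance

    @property
    def tol3(self) -> int:
        return self.end_tolerance if self.end_tolerance_3p is None else self.end_tolerance_3p


@dataclass
class TranscriptUnit:
    """A merged cluster of near-identical alignments with read counts."""

    id: str
    replicon_id: str
    strand: str
    start: int
    end: int
    read_count: int           # uniquely aligned reads absorbed
    total_count: int          # all reads absorbed
    representative_sequence: str
    condition: str = ""
    oversize: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"unit {self.id}: start > end")
        if self.read_count > self.total_count:
            raise ValueError(f"unit {self.id}: read_count > total_count")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _five_three(start: int, end: int, strand: str) -> tuple[int, int]:
    """(5' end, 3' end) genomic coordinates of an interval, strand-aware."""
    return (start, end) if strand == "+" else (end, start)


def unify(
    alignments: Iterable[Alignment],
    genome: Genome,
    params: UnifyParams | None = None,
    condition: str = "",
) -> list[TranscriptUnit]:
    """Cluster alignments into transcript units (see module docstring)."""
    params = params or UnifyParams()
    tol5, tol3 = params.tol5, params.tol3

    # multiplicity of each exact placement, split by (replicon, strand)
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    uniques: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for a in alignments:
        key = (a.replicon_id, a.strand)
        groups[key][(a.start, a.end)] += 1
        if a.is_unique:
            uniques[key][(a.start, a.end)] += 1

    units: list[TranscriptUnit] = []
    for key in sorted(groups):
        replicon_id, strand = key
        counter = groups[key]
        # canonical seed order: most abundant, then leftmost, then shortest
        order = sorted(counter, key=lambda iv: (-counter[iv], iv[0], iv[1] - iv[0]))
        # bucket intervals by 5' coordinate for near-neighbour lookup
        by_five: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for iv in order:
            five, _ = _five_three(*iv, strand)
            by_five[five].append(iv)
        absorbed: set[tuple[int, int]] = set()
        for seed in order:
            if seed in absorbed:
                continue
            s5, s3 = _five_three(*seed, strand)
            members: list[tuple[int, int]] = []
            for five in range(s5 - tol5, s5 + tol5 + 1):
                for iv in by_five.get(five, ()):
                    if iv in absorbed:
                        continue
                    _, i3 = _five_three(*iv, strand)
                    if abs(i3 - s3) <= tol3:
                        members.append(iv)
            absorbed.update(members)
            total = sum(counter[iv] for iv in members)
            uniq = sum(uniques[key][iv] for iv in members)
            start, end = seed
            length = end - start + 1
            units.append(
                TranscriptUnit(
                    id="",  # assigned below, after deterministic ordering
                    replicon_id=replicon_id,
                    strand=strand,
                    start=start,
                    end=end,
                    read_count=uniq,
                    total_count=total,
                    representative_sequence=genome.fetch(replicon_id, start, end, strand),
                    condition=condition,
                    oversize=length > params.max_unit_length,
                )
            )

    units.sort(key=lambda u: (u.replicon_id, u.start, u.strand, u.end))
    prefix = f"{condition}_" if condition else ""
    for i, u in enumerate(units, 1):
        u.id = f"{prefix}TU{i:05d}"
    return units


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_units_gff3(units: Sequence[TranscriptUnit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for u in sorted(units, key=lambda u: (u.replicon_id, u.start, u.strand)):
            attrs = (f"ID={u.id};read_count={u.read_count};total_count={u.total_count};"
                     f"condition={u.condition};oversize={str(u.oversize).lower()}")
            fh.write(f"{u.replicon_id}\tsrnapipe\ttranscript_unit\t{u.start}\t{u.end}"
                     f"\t.\t{u.strand}\t.\t{attrs}\n")


def write_units_tsv(units: Sequence[TranscriptUnit], path: str | Path) -> None:
    cols = ["id", "replicon_id", "strand", "start", "end", "length",
            "read_count", "total_count", "condition", "oversize"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for u in sorted(units, key=lambda u: (u.replicon_id, u.start, u.strand)):
            fh.write("\t".join(str(v) for v in (
                u.id, u.replicon_id, u.strand, u.start, u.end, u.length,
                u.read_count, u.total_count, u.condition, u.oversize)) + "\n")
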