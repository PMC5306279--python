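"""Genome, annotation and alignment I/O: the pipeline's coordinate contract.

All coordinates are 1-based inclusive on the forward strand of each replicon,
matching the convention of GFF3 and of published genomic positions.  Antisense
transcripts are represented by strand ``-`` on the same forward axis; sequences
are only reverse-complemented when a nucleotide string is extracted.  BED6 I/O
converts from/to 0-based half-open at the boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("srnapipe")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default mapping from GFF3 feature types to the pipeline's feature kinds.
DEFAULT_TYPE_MAP: Mapping[str, str] = {
    "CDS": "ORF",
    "gene": "ORF",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
}

FEATURE_KINDS = ("ORF", "tRNA", "rRNA")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Replicon:
    """One self-contained DNA molecule (chromosome or plasmid)."""

    id: str
    sequence: str
    kind: str = "chromosome"  # "chromosome" | "plasmid"

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """Ordered collection of replicons with unique ids."""

    replicons: list[Replicon]

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError("a genome needs at least one replicon")
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate replicon ids: {sorted(ids)}")
        self._by_id = {r.id: r for r in self.replicons}

    def __getitem__(self, replicon_id: str) -> Replicon:
        return self._by_id[replicon_id]

    def __contains__(self, replicon_id: str) -> bool:
        return replicon_id in self._by_id

    def fetch(self, replicon_id: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end] (1-based inclusive), reverse-complemented for '-'."""
        rep = self[replicon_id]
        if not (1 <= start <= end <= rep.length):
            raise ValueError(
                f"interval {start}-{end} outside replicon {replicon_id!r} (len {rep.length})"
            )
        seq = rep.sequence[start - 1 : end]
        return reverse_complement(seq) if strand == "-" else seq


@dataclass(frozen=True)
class Feature:
    """Annotated genomic feature (ORF, tRNA or rRNA), 1-based inclusive."""

    id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    kind: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.id}: bad kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass(frozen=True)
class Alignment:
    """A read placed on a replicon interval, with strand and uniqueness flag."""

    read_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"alignment {self.read_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> Genome:
    """Load a (multi-record) FASTA file as a Genome.

    Residues are upper-cased and U is mapped to T.  A record whose description
    contains the word "plasmid" is flagged ``kind="plasmid"``; everything else
    is treated as a chromosome.
    """
    replicons = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        kind = "plasmid" if "plasmid" in rec.description.lower() else "chromosome"
        replicons.append(Replicon(id=rec.id, sequence=seq, kind=kind))
    if not replicons:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(replicons)


def write_genome(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.kind)
        for r in genome.replicons
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            quals = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{quals}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
    genome: Genome,
    type_map: Mapping[str, str] = DEFAULT_TYPE_MAP,
) -> list[Feature]:
    """Load GFF3 features, mapping GFF types to {ORF, tRNA, rRNA}.

    Unknown feature types are skipped with a logged warning.  Features on
    unknown replicons or with out-of-bounds coordinates are hard errors.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[Feature] = []
    for f in db.all_features():
        kind = type_map.get(f.featuretype)
        if kind is None:
            logger.warning("skipping feature of unmapped type %r at %s:%d", f.featuretype, f.seqid, f.start)
            continue
        if f.seqid not in genome:
            raise ValueError(f"feature {f.id!r} on unknown replicon {f.seqid!r}")
        rep = genome[f.seqid]
        if not (1 <= f.start <= f.end <= rep.length):
            raise ValueError(
                f"feature {f.id!r} interval {f.start}-{f.end} outside replicon "
                f"{f.seqid!r} (length {rep.length})"
            )
        features.append(
            Feature(id=f.id, replicon_id=f.seqid, start=f.start, end=f.end,
                    strand=f.strand, kind=kind)
        )
    return features


def write_annotation(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as GFF3, sorted by (replicon, start, strand)."""
    kind_to_type = {"ORF": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.replicon_id, f.start, f.strand)):
            fh.write(
                f"{f.replicon_id}\tsrnapipe\t{kind_to_type[f.kind]}\t{f.start}\t{f.end}"
                f"\t.\t{f.strand}\t.\tID={f.id}\n"
            )


# ---------------------------------------------------------------------------
# Alignments: SAM and BED6
# ---------------------------------------------------------------------------

def _finalize_uniqueness(raw: list[tuple[str, str, int, int, str]],
                         genome: Genome) -> list[Alignment]:
    """A read is unique iff it has exactly one alignment record in the input."""
    placements: dict[str, int] = {}
    for read_id, *_ in raw:
        placements[read_id] = placements.get(read_id, 0) + 1
    out = []
    for read_id, replicon_id, start, end, strand in raw:
        rep = genome[replicon_id]
        if not (1 <= start <= end <= rep.length):
            raise ValueError(
                f"alignment of {read_id!r} at {replicon_id}:{start}-{end} "
                f"outside replicon (length {rep.length})"
            )
        out.append(
            Alignment(read_id=read_id, replicon_id=replicon_id, start=start,
                      end=end, strand=strand, is_unique=placements[read_id] == 1)
        )
    return out


def read_alignments(path: str | Path, genome: Genome) -> list[Alignment]:
    """Load alignments from a SAM (text) or BED6 file.

    SAM end coordinates come from the reference-consuming CIGAR operations
    (M, D, =, X); BED intervals are converted from 0-based half-open.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed6(path, genome)
    return _read_sam(path, genome)


def _read_sam(path: Path, genome: Genome) -> list[Alignment]:
    raw: list[tuple[str, str, int, int, str]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.cigartuples is None or rec.reference_end is None:
                raise ValueError(f"SAM record {rec.query_name!r} has no usable CIGAR")
            strand = "-" if rec.is_reverse else "+"
            # pysam: reference_start 0-based, reference_end 0-based exclusive
            raw.append((rec.query_name, rec.reference_name,
                        rec.reference_start + 1, rec.reference_end, strand))
    return _finalize_uniqueness(raw, genome)


def _read_bed6(path: Path, genome: Genome) -> list[Alignment]:
    raw: list[tuple[str, str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom, start0, end0, name, _score, strand = cols[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            raw.append((name, chrom, int(start0) + 1, int(end0), strand))
    return _finalize_uniqueness(raw, genome)


def write_bed6(alignments: Iterable[Alignment], path: str | Path) -> None:
    rows = sorted(alignments, key=lambda a: (a.replicon_id, a.start, a.strand, a.read_id))
    with open(path, "w") as fh:
        for a in rows:
            fh.write(f"{a.replicon_id}\t{a.start - 1}\t{a.end}\t{a.read_id}\t0\t{a.strand}\n")
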