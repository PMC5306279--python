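"""asRNA/target characterization: CDS-relative mapping, fragment-length
arithmetic and degenerate-motif scanning.

An antisense RNA overlapping its target is expressed in CDS-relative
coordinates, where position 1 is the first base of the start codon counted
along the target's strand — the coordinate system in which validated asRNA
extents are reported.  Fragment lengths between a transcription start site
and a mapped 3' end are inclusive distances (|end - start| + 1), the
convention under which a transcript from position 1,603,634 to 1,603,755
is 122 nt.  Motif scanning matches IUPAC degenerate patterns such as the
RNase E cleavage consensus RAUUW (R = A/G, W = A/U), reporting every
(possibly overlapping) hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from .genome_io import Feature
from .unify import TranscriptUnit

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "W": "AU", "S": "CG",
    "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}


@dataclass(frozen=True)
class AntisenseMap:
    """An asRNA's extent in the coordinates of its target CDS."""

    asrna_id: str
    target_feature_id: str
    cds_start_pos: int
    cds_end_pos: int
    length: int
    fully_contained: bool


@dataclass(frozen=True)
class MotifHit:
    position: int   # 1-based offset within the scanned sequence
    matched: str    # RNA text of pattern length


def antisense_map(asrna: TranscriptUnit, target: Feature) -> AntisenseMap:
    """Express an antisense unit in target-CDS coordinates.

    The unit and target must sit on the same replicon, on opposite strands,
    and overlap.  CDS positions run 1..len(target) from the first base of the
    start codon along the target's strand; unit ends overhanging the CDS clamp
    to the boundary, with ``fully_contained`` false.  ``length`` is the unit's
    own inclusive length.
    """
    if asrna.replicon_id != target.replicon_id:
        raise ValueError("asRNA and target on different replicons")
    if asrna.strand == target.strand:
        raise ValueError("asRNA must be on the strand opposite its target")
    if min(asrna.end, target.end) < max(asrna.start, target.start):
        raise ValueError("asRNA and target do not overlap")

    if target.strand == "+":
        lo = asrna.start - target.start + 1
        hi = asrna.end - target.start + 1
    else:
        lo = target.end - asrna.end + 1
        hi = target.end - asrna.start + 1
    contained = lo >= 1 and hi <= target.length
    return AntisenseMap(
        asrna_id=asrna.id,
        target_feature_id=target.id,
        cds_start_pos=max(1, lo),
        cds_end_pos=min(target.length, hi),
        length=asrna.length,
        fully_contained=contained,
    )


def genomic_interval(amap: AntisenseMap, target: Feature) -> tuple[int, int]:
    """Map CDS-relative positions back to a genomic (start, end) interval."""
    if target.strand == "+":
        return (target.start + amap.cds_start_pos - 1,
                target.start + amap.cds_end_pos - 1)
    return (target.end - amap.cds_end_pos + 1,
            target.end - amap.cds_start_pos + 1)


def fragment_length(tss: int, end3: int) -> int:
    """Inclusive nucleotide distance between a TSS and a 3' end position."""
    return abs(end3 - tss) + 1


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for code in pattern.upper().replace("T", "U"):
        try:
            chars = IUPAC[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern") from None
        parts.append(chars if len(chars) == 1 else f"[{chars}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(
    seq: str,
    pattern: str,
    window: tuple[int, int] | None = None,
) -> list[MotifHit]:
    """All (possibly overlapping) IUPAC-pattern matches in a sequence.

    DNA input is treated as its RNA transcript (T = U).  ``window`` restricts
    the scan to a 1-based inclusive interval of the sequence; reported
    positions stay relative to the full sequence.
    """
    rx = _iupac_regex(pattern)
    rna = seq.upper().replace("T", "U")
    if window is None:
        if not rna:
            return []
        lo, hi = 1, len(rna)
    else:
        lo, hi = window
        if not (1 <= lo <= hi <= len(rna)):
            raise ValueError(f"window {window} outside sequence of length {len(rna)}")
    region = rna[lo - 1 : hi]
    hits = []
    for m in rx.finditer(region):
        matched = m.group(1)
        if m.start() + len(matched) <= len(region):
            hits.append(MotifHit(position=lo + m.start(), matched=matched))
    return hits


def scan_rnase_e_sites(seq: str, window: tuple[int, int] | None = None) -> list[MotifHit]:
    """Scan for the RNase E cleavage consensus RAUUW."""
    return scan_motif(seq, "RAUUW", window)
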