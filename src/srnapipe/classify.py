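"""Genomic-context classification of transcript units and candidate filtering.

Each unit gets exactly one category by the first matching rule, in priority
order:

1. overlaps an rRNA feature on either strand            -> ``rRNA``
2. overlaps a tRNA feature on either strand             -> ``tRNA``
3. overlaps an ORF on the SAME strand by at least
   ``sense_overlap_min_frac`` of the unit's length      -> ``ORF``
4. overlaps an ORF on the OPPOSITE strand by >= 1 nt    -> ``AS``
5. lies on the same strand as a gene and intersects the
   ``upstream_window`` nt immediately 5' of its start   -> ``LR5``
6. otherwise                                            -> ``IGR``

Structural-RNA contamination outranks everything (rRNA/tRNA are removable
background); antisense outranks IGR so asRNAs that only partially overlap an
ORF are not lost.  Candidates are the AS/IGR/LR5 units carrying at least
``min_unique_reads`` uniquely aligned reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import Feature
from .unify import TranscriptUnit

CATEGORIES = ("rRNA", "tRNA", "ORF", "AS", "IGR", "LR5")

#: Category -> sRNA class for candidate units.
CLASS_OF_CATEGORY = {"AS": "asRNA", "IGR": "IGR", "LR5": "LR5"}


@dataclass
class ClassifyParams:
    upstream_window: int = 300
    min_unique_reads: int = 10
    sense_overlap_min_frac: float = 0.5
    lr5_strict_containment: bool = False

    def __post_init__(self) -> None:
        if self.upstream_window < 0:
            raise ValueError("upstream_window must be >= 0")
        if self.min_unique_reads < 1:
            raise ValueError("min_unique_reads must be >= 1")


@dataclass
class Candidate:
    """An sRNA candidate: a classified unit with its class and context gene."""

    unit: TranscriptUnit
    srna_class: str                 # asRNA | IGR | LR5
    associated_feature_id: str = ""

    @property
    def length(self) -> int:
        return self.unit.length


class FeatureIndex:
    """Per-replicon feature lists for overlap queries at annotation scale."""

    def __init__(self, features: Iterable[Feature]):
        self._by_replicon: dict[str, list[Feature]] = defaultdict(list)
        for f in features:
            self._by_replicon[f.replicon_id].append(f)
        for fs in self._by_replicon.values():
            fs.sort(key=lambda f: (f.start, f.id))

    def on(self, replicon_id: str) -> list[Feature]:
        return self._by_replicon.get(replicon_id, [])


def _overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def _upstream_window(gene: Feature, window: int) -> tuple[int, int]:
    """The window of ``window`` nt immediately 5' of the gene start, strand-aware."""
    if gene.strand == "+":
        return gene.start - window, gene.start - 1
    return gene.end + 1, gene.end + window


def classify_unit(
    unit: TranscriptUnit,
    features: FeatureIndex | Iterable[Feature],
    params: ClassifyParams | None = None,
) -> tuple[str, str]:
    """Return (category, associated_feature_id) for one unit.

    The associated feature is the antisense target for ``AS`` (maximal
    overlap, ties broken by leftmost feature start) and the downstream gene
    for ``LR5``; empty for the other categories.
    """
    params = params or ClassifyParams()
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    feats = index.on(unit.replicon_id)

    overlapping = [
        f for f in feats if _overlap_len(unit.start, unit.end, f.start, f.end) > 0
    ]
    if any(f.kind == "rRNA" for f in overlapping):
        return "rRNA", ""
    if any(f.kind == "tRNA" for f in overlapping):
        return "tRNA", ""

    orfs = [f for f in overlapping if f.kind == "ORF"]
    sense = [f for f in orfs if f.strand == unit.strand]
    for f in sense:
        ov = _overlap_len(unit.start, unit.end, f.start, f.end)
        if ov >= params.sense_overlap_min_frac * unit.length:
            return "ORF", ""

    antisense = [f for f in orfs if f.strand != unit.strand]
    if antisense:
        best = max(
            antisense,
            key=lambda f: (_overlap_len(unit.start, unit.end, f.start, f.end), -f.start),
        )
        return "AS", best.id

    # 5' leader: same strand, intersecting the upstream window of a gene
    lr5_hits = []
    for f in feats:
        if f.kind != "ORF" or f.strand != unit.strand:
            continue
        w_start, w_end = _upstream_window(f, params.upstream_window)
        if params.lr5_strict_containment:
            hit = w_start <= unit.start and unit.end <= w_end
        else:
            hit = _overlap_len(unit.start, unit.end, w_start, w_end) > 0
        if hit:
            lr5_hits.append(f)
    if lr5_hits:
        # nearest gene: smallest gap between unit and gene start, ties leftmost
        def gap(f: Feature) -> int:
            return f.start - unit.end if f.strand == "+" else unit.start - f.end
        best = min(lr5_hits, key=lambda f: (gap(f), f.start))
        return "LR5", best.id

    return "IGR", ""


def classify_units(
    units: Iterable[TranscriptUnit],
    features: FeatureIndex | Iterable[Feature],
    params: ClassifyParams | None = None,
) -> list[tuple[TranscriptUnit, str, str]]:
    """Classify every unit; returns (unit, category, associated_feature_id) rows."""
    params = params or ClassifyParams()
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    return [(u, *classify_unit(u, index, params)) for u in units]


def filter_candidates(
    classified: Iterable[tuple[TranscriptUnit, str, str]],
    params: ClassifyParams | None = None,
) -> list[Candidate]:
    """Keep AS/IGR/LR5 units with >= ``min_unique_reads`` uniquely aligned reads."""
    params = params or ClassifyParams()
    out = []
    for unit, category, assoc in classified:
        if category in CLASS_OF_CATEGORY and unit.read_count >= params.min_unique_reads:
            out.append(Candidate(unit=unit, srna_class=CLASS_OF_CATEGORY[category],
                                 associated_feature_id=assoc))
    return out


def category_breakdown(
    classified: Iterable[tuple[TranscriptUnit, str, str]]
) -> pd.DataFrame:
    """Units, summed read totals and read percentage per category.

    Percentages are computed over summed ``total_count`` and sum to 100
    within rounding.
    """
    rows = {c: {"units": 0, "reads": 0} for c in CATEGORIES}
    for unit, category, _ in classified:
        rows[category]["units"] += 1
        rows[category]["reads"] += unit.total_count
    df = pd.DataFrame.from_dict(rows, orient="index")
    total_reads = df["reads"].sum()
    df["read_pct"] = 100.0 * df["reads"] / total_reads if total_reads else 0.0
    df.index.name = "category"
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_GFF_CLASS = {"asRNA": "asRNA", "IGR": "IGR", "LR5": "5pLR"}


def write_candidates_gff3(candidates: Sequence[Candidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(candidates, key=lambda c: (c.unit.replicon_id, c.unit.start, c.unit.strand)):
            u = c.unit
            attrs = f"ID={u.id};class={_GFF_CLASS[c.srna_class]}"
            if c.associated_feature_id:
                attrs += f";target={c.associated_feature_id}"
            attrs += f";read_count={u.read_count};condition={u.condition}"
            fh.write(f"{u.replicon_id}\tsrnapipe\tncRNA\t{u.start}\t{u.end}"
                     f"\t.\t{u.strand}\t.\t{attrs}\n")


def write_candidates_tsv(candidates: Sequence[Candidate], path: str | Path) -> None:
    cols = ["id", "replicon_id", "strand", "start", "end", "length", "srna_class",
            "associated_feature", "read_count", "total_count", "condition"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in sorted(candidates, key=lambda c: (c.unit.replicon_id, c.unit.start, c.unit.strand)):
            u = c.unit
            fh.write("\t".join(str(v) for v in (
                u.id, u.replicon_id, u.strand, u.start, u.end, u.length, c.srna_class,
                c.associated_feature_id, u.read_count, u.total_count, u.condition)) + "\n")
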