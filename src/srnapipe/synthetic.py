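"""Ground-truthed scenario generator for two-condition sRNA-Seq experiments.

Emulates a dRNA-Seq study of a multi-replicon cyanobacterial genome: a random
chromosome plus four plasmids, annotated ORF/tRNA/rRNA features, and two
adapter-bearing FASTQ libraries (normal light, NL, and high light, HL) with
planted antisense (asRNA), intergenic (IGR) and 5' leader (LR5) transcripts
whose lengths follow a truncated Gaussian.  A subset of planted units is
differentially expressed at a known fold change or present in only one
library; rRNA/tRNA/ORF background reads are mixed in at configurable
fractions.  Everything is reproducible from the seed, and the manifest
records the ground truth so pipeline output can be scored exactly.

Geometric clearances are built in so every planted unit has an unambiguous
class under the classifier's priority rules: asRNAs sit strictly inside ORF
bodies on the opposite strand, LR5 units strictly inside the 300-nt upstream
window of their gene, IGR units more than 300 nt from any feature, and
consecutive placements are separated by a 450-nt gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_io import (
    Feature, Genome, Read, Replicon,
    write_annotation, write_fastq, write_genome,
)

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # Illumina small-RNA 3' adapter

_GAP = 450          # nt between consecutive placements (> upstream window + 150)
_MARGIN = 500       # nt kept free at each replicon end
_IGR_CLEARANCE = 301  # minimum distance of an IGR unit from any feature


@dataclass
class ScenarioConfig:
    seed: int = 0
    replicon_lengths: tuple[int, ...] = (200_000, 10_000, 10_000, 10_000, 10_000)
    n_orfs: int = 75
    n_trna: int = 4
    n_rrna: int = 2
    n_asrna: int = 60
    n_igr: int = 20
    n_lr5: int = 10
    length_mean: float = 146.0
    length_sd: float = 55.0
    min_unit_length: int = 18
    max_unit_length: int = 310
    frac_de_up: float = 0.15
    frac_de_down: float = 0.45
    frac_unique_nl: float = 0.15
    frac_unique_hl: float = 0.10
    de_fold: float = 4.0
    depth_per_unit: float = 50.0
    poisson_counts: bool = False
    background_fracs: dict = field(
        default_factory=lambda: {"rRNA": 0.27, "tRNA": 0.25, "ORF": 0.22}
    )
    frac_plasmid: float = 0.11
    adapter_3p: str = DEFAULT_ADAPTER
    read_length: int = 350
    read_error_rate: float = 0.0
    base_quality: int = 35

    def __post_init__(self) -> None:
        fracs = (self.frac_de_up, self.frac_de_down,
                 self.frac_unique_nl, self.frac_unique_hl)
        if any(not (0 <= f <= 1) for f in fracs) or sum(fracs) > 1:
            raise ValueError("DE/unique fractions must lie in [0,1] and sum to <= 1")
        if sum(self.background_fracs.values()) >= 1:
            raise ValueError("background fractions must sum to < 1")
        if self.length_mean <= 0:
            raise ValueError("length_mean must be positive")
        if self.n_orfs < self.n_asrna + self.n_lr5:
            raise ValueError(
                f"need n_orfs >= n_asrna + n_lr5 host genes "
                f"({self.n_orfs} < {self.n_asrna + self.n_lr5})"
            )


@dataclass
class PlantedUnit:
    id: str
    replicon_id: str
    strand: str
    start: int
    end: int
    srna_class: str              # asRNA | IGR | LR5
    associated_feature_id: str
    nl_count: int
    hl_count: int
    de_status: str               # up | down | unchanged | unique_NL | unique_HL

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthManifest:
    seed: int
    adapter: str
    units: list[PlantedUnit]
    background_reads: dict      # condition -> {class: read count}
    library_reads: dict         # condition -> total reads written
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "adapter": self.adapter,
            "units": [asdict(u) for u in self.units],
            "background_reads": self.background_reads,
            "library_reads": self.library_reads,
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            adapter=payload["adapter"],
            units=[PlantedUnit(**u) for u in payload["units"]],
            background_reads=payload["background_reads"],
            library_reads=payload["library_reads"],
            config=payload["config"],
        )


@dataclass
class Scenario:
    genome: Genome
    features: list[Feature]
    nl_reads: list[Read]
    hl_reads: list[Read]
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _draw_length(rng: np.random.Generator, cfg: ScenarioConfig, upper: int) -> int:
    """One unit length from the truncated Gaussian."""
    lo = cfg.min_unit_length
    hi = min(cfg.max_unit_length, upper)
    for _ in range(1000):
        x = int(round(rng.normal(cfg.length_mean, cfg.length_sd)))
        if lo <= x <= hi:
            return x
    return max(lo, min(hi, int(cfg.length_mean)))


@dataclass
class _Block:
    """One placement: a feature, a candidate, or a feature hosting a candidate."""

    kind: str                  # orf | trna | rrna | asrna | lr5 | igr
    length: int                # total footprint on the replicon
    feature_len: int = 0
    feature_strand: str = "+"
    unit_len: int = 0
    unit_offset: int = 0       # offset of the unit start within the block
    unit_strand: str = "+"


def _build_blocks(rng: np.random.Generator, cfg: ScenarioConfig) -> list[_Block]:
    blocks: list[_Block] = []

    def strand() -> str:
        return "+" if rng.integers(0, 2) == 0 else "-"

    for _ in range(cfg.n_asrna):
        ulen = _draw_length(rng, cfg, cfg.max_unit_length)
        flen = ulen + int(rng.integers(20, 200))
        off = int(rng.integers(1, flen - ulen))   # >=1 nt clearance both sides
        blocks.append(_Block("asrna", flen, feature_len=flen, feature_strand=strand(),
                             unit_len=ulen, unit_offset=off,
                             unit_strand=""))      # opposite of feature, set later
    for _ in range(cfg.n_lr5):
        glen = int(rng.integers(400, 1200))
        ulen = _draw_length(rng, cfg, 280)         # must fit the 300-nt window
        s = strand()
        woff = int(rng.integers(1, 300 - ulen))    # >=1 nt inside the window
        blocks.append(_Block("lr5", glen + 300, feature_len=glen, feature_strand=s,
                             unit_len=ulen, unit_offset=woff, unit_strand=s))
    for _ in range(cfg.n_igr):
        ulen = _draw_length(rng, cfg, cfg.max_unit_length)
        blocks.append(_Block("igr", ulen, unit_len=ulen, unit_strand=strand()))
    for _ in range(cfg.n_orfs - cfg.n_asrna - cfg.n_lr5):
        flen = int(rng.integers(400, 1200))
        blocks.append(_Block("orf", flen, feature_len=flen, feature_strand=strand()))
    for _ in range(cfg.n_trna):
        flen = int(rng.integers(70, 90))
        blocks.append(_Block("trna", flen, feature_len=flen, feature_strand=strand()))
    for _ in range(cfg.n_rrna):
        flen = int(rng.integers(1000, 1500))
        blocks.append(_Block("rrna", flen, feature_len=flen, feature_strand=strand()))
    return blocks


def _assign_replicons(
    rng: np.random.Generator, cfg: ScenarioConfig, blocks: list[_Block],
    replicon_ids: list[str],
) -> dict[str, list[_Block]]:
    """Candidate-bearing blocks go to a plasmid with probability ``frac_plasmid``."""
    chrom, plasmids = replicon_ids[0], replicon_ids[1:]
    per: dict[str, list[_Block]] = {rid: [] for rid in replicon_ids}
    for b in blocks:
        if b.kind in ("asrna", "lr5", "igr") and plasmids and rng.random() < cfg.frac_plasmid:
            per[plasmids[rng.integers(0, len(plasmids))]].append(b)
        else:
            per[chrom].append(b)
    lengths = dict(zip(replicon_ids, cfg.replicon_lengths))
    for rid, bl in per.items():
        need = 2 * _MARGIN + sum(b.length for b in bl) + _GAP * max(0, len(bl) - 1)
        if need > lengths[rid]:
            raise ValueError(
                f"placement infeasible on {rid}: need {need} nt, have {lengths[rid]}"
            )
    return per


def generate_scenario(cfg: ScenarioConfig, out_dir: str | Path | None = None) -> Scenario:
    """Generate genome, annotation, two FASTQ libraries and the truth manifest.

    When ``out_dir`` is given, writes genome.fasta, annotation.gff3, NL.fastq,
    HL.fastq and manifest.json there; the same objects are always returned
    in memory.
    """
    rng = np.random.default_rng(cfg.seed)

    replicon_ids = ["chr"] + [f"pSYN{i}" for i in range(1, len(cfg.replicon_lengths))]
    replicons = []
    for rid, length in zip(replicon_ids, cfg.replicon_lengths):
        kind = "chromosome" if rid == "chr" else "plasmid"
        replicons.append(Replicon(id=rid, sequence=_random_sequence(rng, length), kind=kind))
    genome = Genome(replicons)

    blocks = _build_blocks(rng, cfg)
    per_replicon = _assign_replicons(rng, cfg, blocks, replicon_ids)

    features: list[Feature] = []
    planted: list[PlantedUnit] = []
    counters = {"orf": 0, "trna": 0, "rrna": 0, "asrna": 0, "lr5": 0, "igr": 0}

    for rid in replicon_ids:
        cursor = _MARGIN + 1
        for b in per_replicon[rid]:
            counters[b.kind] += 1
            if b.kind in ("orf", "asrna"):
                fid = f"orf{counters['orf'] + counters['asrna']:04d}"
                feat = Feature(fid, rid, cursor, cursor + b.feature_len - 1,
                               b.feature_strand, "ORF")
                features.append(feat)
                if b.kind == "asrna":
                    ustart = cursor + b.unit_offset
                    planted.append(PlantedUnit(
                        id=f"as{counters['asrna']:04d}", replicon_id=rid,
                        strand="-" if b.feature_strand == "+" else "+",
                        start=ustart, end=ustart + b.unit_len - 1,
                        srna_class="asRNA", associated_feature_id=fid,
                        nl_count=0, hl_count=0, de_status=""))
            elif b.kind == "lr5":
                if b.feature_strand == "+":
                    gstart = cursor + 300
                    feat = Feature(f"orf_lr{counters['lr5']:04d}", rid, gstart,
                                   gstart + b.feature_len - 1, "+", "ORF")
                    ustart = cursor + b.unit_offset
                else:
                    feat = Feature(f"orf_lr{counters['lr5']:04d}", rid, cursor,
                                   cursor + b.feature_len - 1, "-", "ORF")
                    ustart = feat.end + b.unit_offset + 1
                features.append(feat)
                planted.append(PlantedUnit(
                    id=f"lr{counters['lr5']:04d}", replicon_id=rid,
                    strand=b.feature_strand, start=ustart,
                    end=ustart + b.unit_len - 1, srna_class="LR5",
                    associated_feature_id=feat.id,
                    nl_count=0, hl_count=0, de_status=""))
            elif b.kind in ("trna", "rrna"):
                kind = "tRNA" if b.kind == "trna" else "rRNA"
                features.append(Feature(f"{b.kind}{counters[b.kind]:02d}", rid, cursor,
                                        cursor + b.feature_len - 1, b.feature_strand, kind))
            elif b.kind == "igr":
                planted.append(PlantedUnit(
                    id=f"igr{counters['igr']:04d}", replicon_id=rid,
                    strand=b.unit_strand, start=cursor, end=cursor + b.unit_len - 1,
                    srna_class="IGR", associated_feature_id="",
                    nl_count=0, hl_count=0, de_status=""))
            cursor += b.length + _GAP

    _assign_expression(rng, cfg, planted)

    nl_reads, nl_bg = _make_library(rng, cfg, genome, features, planted, "NL")
    hl_reads, hl_bg = _make_library(rng, cfg, genome, features, planted, "HL")

    manifest = TruthManifest(
        seed=cfg.seed,
        adapter=cfg.adapter_3p,
        units=planted,
        background_reads={"NL": nl_bg, "HL": hl_bg},
        library_reads={"NL": len(nl_reads), "HL": len(hl_reads)},
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(cfg).items()},
    )
    scenario = Scenario(genome=genome, features=features, nl_reads=nl_reads,
                        hl_reads=hl_reads, manifest=manifest)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome(genome, out / "genome.fasta")
        write_annotation(features, out / "annotation.gff3")
        write_fastq(nl_reads, out / "NL.fastq")
        write_fastq(hl_reads, out / "HL.fastq")
        manifest.to_json(out / "manifest.json")
    return scenario


def _assign_expression(rng: np.random.Generator, cfg: ScenarioConfig,
                       planted: list[PlantedUnit]) -> None:
    """Assign DE statuses and per-library expected counts.

    ``depth_per_unit`` is the expected coverage in a DE unit's lower-expressed
    condition; the higher condition gets ``de_fold`` times that.  Counts are
    rounded expectations unless ``poisson_counts`` is set.
    """
    n = len(planted)
    order = rng.permutation(n)
    n_up = int(np.floor(cfg.frac_de_up * n))
    n_down = int(np.floor(cfg.frac_de_down * n))
    n_unl = int(np.floor(cfg.frac_unique_nl * n))
    n_uhl = int(np.floor(cfg.frac_unique_hl * n))
    statuses = (["up"] * n_up + ["down"] * n_down + ["unique_NL"] * n_unl
                + ["unique_HL"] * n_uhl)
    statuses += ["unchanged"] * (n - len(statuses))

    d = cfg.depth_per_unit
    expected = {
        "up": (d, d * cfg.de_fold),
        "down": (d * cfg.de_fold, d),
        "unique_NL": (d, 0.0),
        "unique_HL": (0.0, d),
        "unchanged": (d, d),
    }
    for idx, status in zip(order, statuses):
        u = planted[idx]
        u.de_status = status
        e_nl, e_hl = expected[status]
        if cfg.poisson_counts:
            u.nl_count = int(rng.poisson(e_nl)) if e_nl > 0 else 0
            u.hl_count = int(rng.poisson(e_hl)) if e_hl > 0 else 0
        else:
            u.nl_count = int(round(e_nl))
            u.hl_count = int(round(e_hl))


def _make_read(rng: np.random.Generator, cfg: ScenarioConfig, read_id: str,
               insert: str) -> Read:
    seq = insert + cfg.adapter_3p
    seq = seq[: cfg.read_length]
    if cfg.read_error_rate > 0:
        bases = list(seq)
        for i in range(len(bases)):
            if rng.random() < cfg.read_error_rate:
                bases[i] = "ACGT"[rng.integers(0, 4)]
        seq = "".join(bases)
    return Read(id=read_id, sequence=seq,
                qualities=tuple([cfg.base_quality] * len(seq)))


def _unit_reads(rng: np.random.Generator, cfg: ScenarioConfig, genome: Genome,
                unit: PlantedUnit, count: int, condition: str) -> list[Read]:
    """Reads for one planted unit: a majority at the exact interval plus
    end-jittered variants, so unification has realistic input while the exact
    interval stays the most abundant (seed) boundary."""
    reads: list[Read] = []
    jitter_ok = unit.length >= cfg.min_unit_length + 6
    n_jit = int(np.floor(0.4 * count)) if jitter_ok else 0
    for k in range(count):
        if k < count - n_jit:
            a = b = 0
        else:
            a, b = int(rng.integers(0, 3)), int(rng.integers(0, 3))
        start, end = unit.start + a, unit.end - b
        insert = genome.fetch(unit.replicon_id, start, end, unit.strand)
        if len(insert) > cfg.read_length:
            # 5'-anchored sequencing of a transcript longer than the read length
            insert = insert[: cfg.read_length]
        reads.append(_make_read(rng, cfg, f"{condition}_{unit.id}_r{k:04d}", insert))
    return reads


def _make_library(rng: np.random.Generator, cfg: ScenarioConfig, genome: Genome,
                  features: list[Feature], planted: list[PlantedUnit],
                  condition: str) -> tuple[list[Read], dict[str, int]]:
    reads: list[Read] = []
    for unit in planted:
        count = unit.nl_count if condition == "NL" else unit.hl_count
        reads.extend(_unit_reads(rng, cfg, genome, unit, count, condition))
    n_candidate = len(reads)

    candidate_frac = 1.0 - sum(cfg.background_fracs.values())
    total = n_candidate / candidate_frac if n_candidate else 0.0
    by_kind: dict[str, list[Feature]] = {"rRNA": [], "tRNA": [], "ORF": []}
    for f in features:
        by_kind[f.kind].append(f)
    bg_counts: dict[str, int] = {}
    for kind, frac in sorted(cfg.background_fracs.items()):
        pool = by_kind[kind]
        n_bg = int(round(frac * total)) if pool else 0
        bg_counts[kind] = n_bg
        for k in range(n_bg):
            feat = pool[rng.integers(0, len(pool))]
            rlen = min(feat.length, int(rng.integers(20, 46)))
            off = int(rng.integers(0, feat.length - rlen + 1))
            insert = genome.fetch(feat.replicon_id, feat.start + off,
                                  feat.start + off + rlen - 1, feat.strand)
            reads.append(_make_read(rng, cfg, f"{condition}_bg_{kind}_{k:05d}", insert))
    return reads, bg_counts


# ---------------------------------------------------------------------------
# Scoring against the truth
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = max(0, min(a_end, b_end) - max(a_start, b_start) + 1)
    if inter == 0:
        return 0.0
    return inter / max(a_end - a_start + 1, b_end - b_start + 1)


def evaluate_against_truth(
    nl_candidates,
    hl_candidates,
    calls,
    manifest: TruthManifest,
    min_recovery_overlap: float = 0.9,
    min_reads: int = 10,
) -> dict:
    """Score pipeline output against the planted truth.

    Returns a report with per-condition unit recall (a planted unit counts as
    recovered when a candidate on the same replicon and strand matches it at
    reciprocal overlap >= ``min_recovery_overlap``), classification accuracy
    over recovered units, and the DE-status confusion matrix with its
    sensitivity (planted up/down called correctly) and specificity (planted
    non-DE not called up/down).
    """
    import pandas as pd

    report: dict = {}
    matched_ids: dict[str, dict[str, str]] = {"NL": {}, "HL": {}}  # planted id -> unit id
    for condition, candidates in (("NL", nl_candidates), ("HL", hl_candidates)):
        expected = [u for u in manifest.units
                    if (u.nl_count if condition == "NL" else u.hl_count) >= min_reads]
        n_rec, n_class_ok = 0, 0
        for u in expected:
            best, best_ov = None, 0.0
            for c in candidates:
                if (c.unit.replicon_id, c.unit.strand) != (u.replicon_id, u.strand):
                    continue
                ov = _reciprocal_overlap(u.start, u.end, c.unit.start, c.unit.end)
                if ov > best_ov:
                    best, best_ov = c, ov
            if best is not None and best_ov >= min_recovery_overlap:
                n_rec += 1
                matched_ids[condition][u.id] = best.unit.id
                if best.srna_class == u.srna_class:
                    n_class_ok += 1
        report[f"{condition}_planted"] = len(expected)
        report[f"{condition}_recall"] = n_rec / len(expected) if expected else 1.0
        report[f"{condition}_class_accuracy"] = n_class_ok / n_rec if n_rec else 1.0

    by_nl = {c.nl_unit_id: c for c in calls if c.nl_unit_id}
    by_hl = {c.hl_unit_id: c for c in calls if c.hl_unit_id}
    rows = []
    for u in manifest.units:
        if max(u.nl_count, u.hl_count) < min_reads:
            continue
        call = (by_nl.get(matched_ids["NL"].get(u.id, ""))
                or by_hl.get(matched_ids["HL"].get(u.id, "")))
        rows.append({"planted": u.de_status,
                     "called": call.status if call else "missing"})
    confusion = (pd.DataFrame(rows).groupby(["planted", "called"]).size()
                 .unstack(fill_value=0)) if rows else pd.DataFrame()
    report["de_confusion"] = confusion

    de = [r for r in rows if r["planted"] in ("up", "down")]
    non_de = [r for r in rows if r["planted"] not in ("up", "down")]
    report["de_sensitivity"] = (
        sum(r["called"] == r["planted"] for r in de) / len(de) if de else 1.0
    )
    report["de_specificity"] = (
        sum(r["called"] not in ("up", "down") for r in non_de) / len(non_de)
        if non_de else 1.0
    )
    report["de_status_accuracy"] = (
        sum(r["called"] == r["planted"] for r in rows) / len(rows) if rows else 1.0
    )
    return report
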