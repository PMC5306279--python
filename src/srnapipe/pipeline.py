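"""End-to-end orchestration: FASTQ libraries in, differential sRNA calls out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .classify import (Candidate, ClassifyParams, classify_units, filter_candidates)
from .diffexpr import DiffCall, DiffParams, diff_calls
from .genome_io import Feature, Genome, Read
from .mapper import GenomeIndex, map_reads
from .preprocess import FilterReport, PreprocessParams, preprocess
from .unify import TranscriptUnit, UnifyParams, unify


@dataclass
class ConditionResult:
    condition: str
    filter_report: FilterReport
    n_mapped: int
    n_unique: int
    units: list[TranscriptUnit]
    classified: list[tuple[TranscriptUnit, str, str]]
    candidates: list[Candidate]


@dataclass
class PipelineResult:
    nl: ConditionResult
    hl: ConditionResult
    calls: list[DiffCall]
    n_dropped: int


def run_condition(
    reads: Sequence[Read],
    genome: Genome,
    features: Sequence[Feature],
    condition: str,
    pp_params: PreprocessParams,
    unify_params: UnifyParams | None = None,
    classify_params: ClassifyParams | None = None,
    index: GenomeIndex | None = None,
) -> ConditionResult:
    """Preprocess, map, unify and classify one condition library."""
    kept, report = preprocess(reads, pp_params)
    index = index or GenomeIndex(genome)
    alignments = map_reads(kept, index)
    unique_ids = {a.read_id for a in alignments if a.is_unique}
    units = unify(alignments, genome, unify_params, condition)
    classified = classify_units(units, features, classify_params)
    candidates = filter_candidates(classified, classify_params)
    return ConditionResult(
        condition=condition,
        filter_report=report,
        n_mapped=len({a.read_id for a in alignments}),
        n_unique=len(unique_ids),
        units=units,
        classified=classified,
        candidates=candidates,
    )


def run_pipeline(
    nl_reads: Sequence[Read],
    hl_reads: Sequence[Read],
    genome: Genome,
    features: Sequence[Feature],
    adapter_3p: str,
    pp_params: PreprocessParams | None = None,
    unify_params: UnifyParams | None = None,
    classify_params: ClassifyParams | None = None,
    diff_params: DiffParams | None = None,
) -> PipelineResult:
    """Run the full two-condition analysis on in-memory reads."""
    pp = pp_params or PreprocessParams(adapter_3p=adapter_3p)
    if not pp.adapter_3p:
        pp.adapter_3p = adapter_3p
    index = GenomeIndex(genome)
    nl = run_condition(nl_reads, genome, features, "NL", pp,
                       unify_params, classify_params, index)
    hl = run_condition(hl_reads, genome, features, "HL", pp,
                       unify_params, classify_params, index)
    dp = diff_params or DiffParams()
    calls, dropped = diff_calls(nl.candidates, hl.candidates, dp,
                                nl_library_size=nl.n_unique,
                                hl_library_size=hl.n_unique)
    return PipelineResult(nl=nl, hl=hl, calls=calls, n_dropped=dropped)
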