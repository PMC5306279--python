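"""Two-condition differential calling on sRNA candidates.

Candidates from the normal-light (NL) and high-light (HL) libraries are
matched one-to-one on the same replicon and strand when their intervals share
at least ``min_overlap_frac`` of the shorter unit's length; matched pairs and
library-unique singletons are then called with a pure threshold filter:
ratio = HL/NL effective counts, status ``up`` when ratio >= ``min_ratio``,
``down`` when ratio <= 1/``min_ratio``, otherwise ``unchanged``; units present
in only one library with enough reads are ``unique_NL`` / ``unique_HL``.
Pairs where neither library reaches ``min_reads`` are dropped (and logged).

No significance test is applied: the method is a deterministic read-count
filter, which keeps the calls reproducible without replicate variance
estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .classify import Candidate

logger = logging.getLogger("srnapipe")

STATUSES = ("up", "down", "unchanged", "unique_NL", "unique_HL")


@dataclass
class DiffParams:
    min_overlap_frac: float = 0.10
    min_ratio: float = 2.0
    min_reads: int = 10
    normalize: bool = False
    reciprocal_overlap: bool = False  # overlap vs BOTH lengths instead of the shorter

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_frac <= 1):
            raise ValueError("min_overlap_frac must be in (0, 1]")
        if self.min_ratio < 1:
            raise ValueError("min_ratio must be >= 1")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")


@dataclass
class DiffCall:
    nl_unit_id: str
    hl_unit_id: str
    srna_class: str
    overlap_frac: float
    nl_count: float
    hl_count: float
    ratio: float          # HL / NL; 0 when either side is absent
    status: str


def _overlap_frac(a: Candidate, b: Candidate, reciprocal: bool) -> float:
    ua, ub = a.unit, b.unit
    inter = max(0, min(ua.end, ub.end) - max(ua.start, ub.start) + 1)
    if inter == 0:
        return 0.0
    denom = max(ua.length, ub.length) if reciprocal else min(ua.length, ub.length)
    return inter / denom


def match_units(
    nl: Sequence[Candidate],
    hl: Sequence[Candidate],
    params: DiffParams | None = None,
) -> tuple[list[tuple[Candidate, Candidate, float]], list[Candidate], list[Candidate]]:
    """Greedy one-to-one matching of NL and HL candidates.

    Pairs require the same replicon and strand and an overlap fraction of at
    least ``min_overlap_frac``; matching proceeds in descending overlap
    fraction (ties: larger summed counts, then leftmost pair).  Returns
    (pairs, unmatched_nl, unmatched_hl).
    """
    params = params or DiffParams()
    edges = []
    for i, a in enumerate(nl):
        for j, b in enumerate(hl):
            if (a.unit.replicon_id, a.unit.strand) != (b.unit.replicon_id, b.unit.strand):
                continue
            frac = _overlap_frac(a, b, params.reciprocal_overlap)
            if frac >= params.min_overlap_frac:
                edges.append((frac, a.unit.read_count + b.unit.read_count,
                              -(a.unit.start + b.unit.start), i, j))
    edges.sort(key=lambda e: (-e[0], -e[1], -e[2], e[3], e[4]))
    used_nl: set[int] = set()
    used_hl: set[int] = set()
    pairs = []
    for frac, _, _, i, j in edges:
        if i in used_nl or j in used_hl:
            continue
        used_nl.add(i)
        used_hl.add(j)
        pairs.append((nl[i], hl[j], frac))
    unmatched_nl = [c for i, c in enumerate(nl) if i not in used_nl]
    unmatched_hl = [c for j, c in enumerate(hl) if j not in used_hl]
    return pairs, unmatched_nl, unmatched_hl


def _effective(count: int, library_size: int | None, normalize: bool) -> float:
    if not normalize:
        return float(count)
    if not library_size:
        raise ValueError("normalize=True requires library sizes")
    return 1e6 * count / library_size


def call_status(
    nl: Candidate | None,
    hl: Candidate | None,
    params: DiffParams | None = None,
    overlap_frac: float = 0.0,
    nl_library_size: int | None = None,
    hl_library_size: int | None = None,
) -> DiffCall | None:
    """Call one pair (or singleton); returns None when below ``min_reads``."""
    params = params or DiffParams()
    if nl is None and hl is None:
        raise ValueError("at least one candidate required")
    nl_raw = nl.unit.read_count if nl else 0
    hl_raw = hl.unit.read_count if hl else 0
    if max(nl_raw, hl_raw) < params.min_reads:
        return None
    nl_eff = _effective(nl_raw, nl_library_size, params.normalize) if nl else 0.0
    hl_eff = _effective(hl_raw, hl_library_size, params.normalize) if hl else 0.0
    srna_class = (nl or hl).srna_class

    if nl is None or nl_eff == 0:
        status, ratio = "unique_HL", 0.0
        if hl_raw < params.min_reads:
            return None
    elif hl is None or hl_eff == 0:
        status, ratio = "unique_NL", 0.0
        if nl_raw < params.min_reads:
            return None
    else:
        ratio = hl_eff / nl_eff
        if ratio >= params.min_ratio:
            status = "up"
        elif ratio <= 1.0 / params.min_ratio:
            status = "down"
        else:
            status = "unchanged"
    return DiffCall(
        nl_unit_id=nl.unit.id if nl else "",
        hl_unit_id=hl.unit.id if hl else "",
        srna_class=srna_class,
        overlap_frac=overlap_frac,
        nl_count=nl_eff,
        hl_count=hl_eff,
        ratio=ratio,
        status=status,
    )


def diff_calls(
    nl: Sequence[Candidate],
    hl: Sequence[Candidate],
    params: DiffParams | None = None,
    nl_library_size: int | None = None,
    hl_library_size: int | None = None,
) -> tuple[list[DiffCall], int]:
    """Match the two candidate sets and call every pair and singleton.

    Returns (calls, n_dropped) where dropped units failed the ``min_reads``
    requirement in both libraries.  Every input candidate lands in exactly one
    of: a pair call, a unique call, or the dropped tally.
    """
    params = params or DiffParams()
    pairs, un_nl, un_hl = match_units(nl, hl, params)
    calls: list[DiffCall] = []
    dropped = 0
    for a, b, frac in pairs:
        call = call_status(a, b, params, frac, nl_library_size, hl_library_size)
        if call is None:
            dropped += 2
        else:
            calls.append(call)
    for a in un_nl:
        call = call_status(a, None, params, 0.0, nl_library_size, hl_library_size)
        if call is None:
            dropped += 1
        else:
            calls.append(call)
    for b in un_hl:
        call = call_status(None, b, params, 0.0, nl_library_size, hl_library_size)
        if call is None:
            dropped += 1
        else:
            calls.append(call)
    if dropped:
        logger.info("diffexpr: %d candidate(s) below min_reads dropped", dropped)
    return calls, dropped


def diff_summary(calls: Iterable[DiffCall]) -> pd.DataFrame:
    """Counts per status, overall and per sRNA class."""
    calls = list(calls)
    if not calls:
        return pd.DataFrame(columns=["status", "srna_class", "count"])
    df = pd.DataFrame([{"status": c.status, "srna_class": c.srna_class} for c in calls])
    by_class = df.groupby(["status", "srna_class"]).size().reset_index(name="count")
    overall = df.groupby("status").size().reset_index(name="count")
    overall["srna_class"] = "all"
    return pd.concat([overall[["status", "srna_class", "count"]], by_class],
                     ignore_index=True)


def fold_change_histogram(calls: Iterable[DiffCall], bins: int = 20) -> pd.DataFrame:
    """Histogram of the HL/NL ratio over matched calls (unique calls excluded)."""
    import numpy as np

    ratios = [c.ratio for c in calls if c.status in ("up", "down", "unchanged")]
    if not ratios:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    counts, edges = np.histogram(ratios, bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def write_calls_tsv(calls: Sequence[DiffCall], path: str | Path) -> None:
    cols = ["nl_unit_id", "hl_unit_id", "srna_class", "overlap_frac",
            "nl_count", "hl_count", "ratio", "status"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in sorted(calls, key=lambda c: (c.nl_unit_id or c.hl_unit_id)):
            fh.write("\t".join(str(getattr(c, k)) for k in cols) + "\n")
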