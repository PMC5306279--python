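"""Descriptive statistics over sRNA candidate sets.

Gaussian parameters are fitted to the unit length distribution by sample
moments (mean, and sd with the n-1 denominator), which for a normal model
coincides with maximum likelihood up to the variance denominator and is
independent of any histogram bin width.  The replicon breakdown reports where
candidates sit across the chromosome and plasmids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import Candidate
from .genome_io import Genome


@dataclass(frozen=True)
class GaussianFit:
    mean: float
    sd: float
    n: int


def _lengths(candidates: Iterable) -> np.ndarray:
    vals = []
    for c in candidates:
        if hasattr(c, "length"):
            vals.append(c.length)
        else:
            vals.append(float(c))
    return np.asarray(vals, dtype=float)


def fit_length_distribution(candidates: Iterable) -> GaussianFit:
    """Fit a Gaussian to candidate lengths by sample moments.

    Accepts Candidate/TranscriptUnit objects or plain numbers.  Requires at
    least two observations (the sd is undefined below that).
    """
    x = _lengths(candidates)
    if x.size < 2:
        raise ValueError(f"need at least 2 lengths to fit, got {x.size}")
    return GaussianFit(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


def length_histogram(candidates: Iterable, bin_width: int = 10) -> pd.DataFrame:
    """Length histogram with fixed-width bins starting at 0."""
    x = _lengths(candidates)
    if x.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    hi = int(np.ceil((x.max() + 1) / bin_width)) * bin_width
    edges = np.arange(0, hi + bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1].astype(int), "bin_right": edges[1:].astype(int), "count": counts}
    )


def replicon_breakdown(candidates: Sequence[Candidate], genome: Genome) -> pd.DataFrame:
    """Candidate counts and percentages per replicon, plus a chromosome-vs-plasmid rollup.

    The rollup rows are labelled ``chromosome`` and ``plasmids`` and follow the
    per-replicon rows.
    """
    counts = {rep.id: 0 for rep in genome.replicons}
    for c in candidates:
        rid = c.unit.replicon_id
        if rid not in counts:
            raise ValueError(f"candidate on unknown replicon {rid!r}")
        counts[rid] += 1
    total = sum(counts.values())
    rows = []
    for rep in genome.replicons:
        rows.append({
            "replicon": rep.id,
            "kind": rep.kind,
            "count": counts[rep.id],
            "percentage": 100.0 * counts[rep.id] / total if total else 0.0,
        })
    for kind, label in (("chromosome", "chromosome"), ("plasmid", "plasmids")):
        n = sum(r["count"] for r in rows if r["kind"] == kind)
        rows.append({
            "replicon": f"all_{label}", "kind": label, "count": n,
            "percentage": 100.0 * n / total if total else 0.0,
        })
    return pd.DataFrame(rows)
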