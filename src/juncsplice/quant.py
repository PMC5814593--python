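"""Per-sample isoform quantification and the isoform expression percentage.

The isoform expression percentage (IEP) of an event is
``n1 / (n1 + n2)`` where ``n1`` and ``n2`` are the junction reads supporting
the inclusion and exclusion isoforms.  Isoforms evidenced by two junctions
(the two flanks of an included exon, or the two boundaries of a retained
intron) contribute the rounded mean of the two junction counts, so that one
molecule is not counted twice relative to single-junction isoforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import JunctionCounts
from .catalog import ASEvent


@dataclass(frozen=True)
class EventQuant:
    event_id: str
    sample_id: str
    n1: int
    n2: int

    @property
    def iep(self) -> float:
        return iep(self.n1, self.n2)


def iep(n1: int, n2: int) -> float:
    """Isoform expression percentage; NaN when no supporting reads at all."""
    if n1 < 0 or n2 < 0:
        raise ValueError("junction read counts must be non-negative")
    total = n1 + n2
    if total == 0:
        return math.nan
    return n1 / total


def _rounded_mean(a: int, b: int) -> int:
    """Mean of two counts rounded half-up, keeping integer read units."""
    return int(math.floor((a + b) / 2 + 0.5))


def quantify_event(event: ASEvent, counts: JunctionCounts, sample: str) -> EventQuant:
    """Isoform supporting-read counts for one event in one sample.

    A junction missing from ``counts`` contributes 0.  For IR and ES the
    two-junction inclusion isoform uses the rounded mean of its junctions.
    """
    c1 = [counts.get(j, sample) for j in event.iso1_junctions]
    c2 = [counts.get(j, sample) for j in event.iso2_junctions]
    n1 = _rounded_mean(c1[0], c1[1]) if len(c1) == 2 else c1[0]
    n2 = _rounded_mean(c2[0], c2[1]) if len(c2) == 2 else c2[0]
    return EventQuant(event.event_id, sample, n1, n2)


def quantify_all(
    events: Iterable[ASEvent],
    counts: JunctionCounts,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of (event_id, sample_id, n1, n2, iep) for all events."""
    samples = list(samples) if samples is not None else list(counts.samples)
    rows = []
    for ev in events:
        for s in samples:
            q = quantify_event(ev, counts, s)
            rows.append(
                {"event_id": q.event_id, "sample_id": s, "n1": q.n1, "n2": q.n2, "iep": q.iep}
            )
    return pd.DataFrame(rows, columns=["event_id", "sample_id", "n1", "n2", "iep"])


def testable_events(
    quants: pd.DataFrame,
    compared_samples: Sequence[str],
    min_total: int = 10,
) -> pd.Series:
    """Eligibility of each event for a comparison over ``compared_samples``.

    Eligible iff n1+n2 > 0 in every compared sample and the pooled total over
    those samples is >= ``min_total``.  Returns a boolean Series indexed by
    event_id.
    """
    sub = quants[quants["sample_id"].isin(compared_samples)].copy()
    sub["total"] = sub["n1"] + sub["n2"]
    grouped = sub.groupby("event_id")["total"]
    n_samples = len(compared_samples)
    eligible = (
        (grouped.count() == n_samples)
        & (grouped.min() > 0)
        & (grouped.sum() >= min_total)
    )
    return eligible


def gene_junction_totals(
    quants: pd.DataFrame,
    event_to_gene: Mapping[str, str],
    samples: Sequence[str] | None = None,
) -> pd.Series:
    """Pooled event junction-read totals per gene (used by the >10-read
    restriction when comparing splicing and expression responses)."""
    sub = quants if samples is None else quants[quants["sample_id"].isin(samples)]
    totals = (sub["n1"] + sub["n2"]).groupby(sub["event_id"].map(event_to_gene)).sum()
    totals.index.name = "gene_id"
    return totals
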