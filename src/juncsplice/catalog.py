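"""Discovery and classification of alternative-splicing events.

Events are found by pairwise comparison of transcript structures within a
gene, in the style of junction-based AS catalogues: intron retention (IR),
exon skipping (ES), and alternative 5'/3' splice sites (Alt5SS / Alt3SS).
Each event binds two isoform junction signatures; by convention isoform 1 is
the inclusion form (retained intron, included exon, or the variant keeping
more exonic sequence) and isoform 2 the exclusion form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotation import (
    EXON_EXON,
    EXON_INTRON_3P,
    EXON_INTRON_5P,
    Junction,
    TranscriptModel,
    ValidationError,
    group_by_gene,
)

logger = logging.getLogger(__name__)

EVENT_TYPES = ("IR", "ES", "Alt5SS", "Alt3SS")


@dataclass(frozen=True)
class ASEvent:
    """A classified AS event: two disjoint isoform junction signatures."""

    event_id: str
    gene_id: str
    type: str
    chrom: str
    strand: str
    iso1_junctions: tuple[Junction, ...]
    iso2_junctions: tuple[Junction, ...]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.type!r}")
        if set(self.iso1_junctions) & set(self.iso2_junctions):
            raise ValidationError(f"event {self.event_id}: isoform junction sets overlap")


def _alt_type(strand: str, varies_at_start: bool) -> str:
    """Strand-aware donor/acceptor role: on + the intron start is the donor."""
    if varies_at_start:
        return "Alt5SS" if strand == "+" else "Alt3SS"
    return "Alt3SS" if strand == "+" else "Alt5SS"


def _retained(junction: Junction, retained: set[Junction] | None) -> bool:
    return retained is None or junction in retained


def detect_events(
    models: Iterable[TranscriptModel] | Mapping[str, list[TranscriptModel]],
    retained_junctions: set[Junction] | None = None,
) -> list[ASEvent]:
    """Detect IR / ES / Alt5SS / Alt3SS events from transcript structures.

    Only events whose exon_exon junctions all pass the retention filter
    (``retained_junctions``; None disables filtering) are emitted.  Genes with
    transcripts on conflicting strands are skipped with a warning.  The result
    is deterministic and invariant to transcript input order.
    """
    genes = models if isinstance(models, Mapping) else group_by_gene(models)
    events: list[ASEvent] = []

    for gene_id in sorted(genes):
        txs = genes[gene_id]
        strands = {t.strand for t in txs}
        if len(strands) > 1:
            logger.warning("gene %s has transcripts on conflicting strands; skipped", gene_id)
            continue
        strand = strands.pop()
        chrom = txs[0].chrom

        intron_sets = [set(t.introns()) for t in txs]
        all_introns = sorted(set().union(*intron_sets)) if intron_sets else []
        all_exons = sorted({ex for t in txs for ex in t.exons})

        def ee(s: int, e: int) -> Junction:
            return Junction(chrom, strand, EXON_EXON, s, e)

        # --- exon skipping: consecutive introns (a,b),(c,d) flanking one
        # exon in one transcript, skip junction (a,d) in another.
        es_patterns: list[tuple[int, int, int, int]] = []
        for t, t_introns in zip(txs, intron_sets):
            ivs = t.introns()
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if (a, d) in set().union(*intron_sets) and (a, d) not in t_introns:
                    es_patterns.append((a, b, c, d))
        es_patterns = sorted(set(es_patterns))
        # junction pairs explained by skipping, excluded from Alt typing
        es_explained = set()
        for a, b, c, d in es_patterns:
            es_explained.add(frozenset({(a, d), (a, b)}))
            es_explained.add(frozenset({(a, d), (c, d)}))

        # --- intron retention: an intron fully interior to an exon of
        # another transcript of the same gene.
        for s, e in all_introns:
            if any(a < s and e < b for a, b in all_exons):
                if not _retained(ee(s, e), retained_junctions):
                    continue
                iso1 = (
                    Junction(chrom, strand, EXON_INTRON_5P, s, e),
                    Junction(chrom, strand, EXON_INTRON_3P, s, e),
                )
                events.append(
                    ASEvent(
                        event_id=f"{gene_id}|IR|{chrom}:{s}-{e}",
                        gene_id=gene_id,
                        type="IR",
                        chrom=chrom,
                        strand=strand,
                        iso1_junctions=iso1,
                        iso2_junctions=(ee(s, e),),
                        span=(s, e),
                    )
                )

        for a, b, c, d in es_patterns:
            needed = [ee(a, b), ee(c, d), ee(a, d)]
            if not all(_retained(j, retained_junctions) for j in needed):
                continue
            events.append(
                ASEvent(
                    event_id=f"{gene_id}|ES|{chrom}:{a}-{b}^{c}-{d}",
                    gene_id=gene_id,
                    type="ES",
                    chrom=chrom,
                    strand=strand,
                    iso1_junctions=(ee(a, b), ee(c, d)),
                    iso2_junctions=(ee(a, d),),
                    span=(a, d),
                )
            )

        # --- alternative splice sites: junction pairs sharing exactly one
        # boundary, not explained by exon skipping.
        for i, (s1, e1) in enumerate(all_introns):
            for s2, e2 in all_introns[i + 1 :]:
                shares_start = s1 == s2 and e1 != e2
                shares_end = e1 == e2 and s1 != s2
                if not (shares_start or shares_end):
                    continue
                if frozenset({(s1, e1), (s2, e2)}) in es_explained:
                    continue
                # iso1 keeps more exonic sequence = the shorter intron
                short, long_ = sorted(((s1, e1), (s2, e2)), key=lambda iv: iv[1] - iv[0])
                if not all(
                    _retained(ee(*iv), retained_junctions) for iv in (short, long_)
                ):
                    continue
                etype = _alt_type(strand, varies_at_start=shares_end)
                events.append(
                    ASEvent(
                        event_id=(
                            f"{gene_id}|{etype}|{chrom}:"
                            f"{short[0]}-{short[1]}/{long_[0]}-{long_[1]}"
                        ),
                        gene_id=gene_id,
                        type=etype,
                        chrom=chrom,
                        strand=strand,
                        iso1_junctions=(ee(*short),),
                        iso2_junctions=(ee(*long_),),
                        span=(min(s1, s2), max(e1, e2)),
                    )
                )

    events.sort(key=lambda ev: ev.event_id)
    return events


def default_subgenome(event: ASEvent) -> str:
    """Subgenome from the trailing A/B/D of the chromosome name, else
    the trailing letter of the gene id, else 'unassigned'."""
    for candidate in (event.chrom[-1:], event.gene_id[-1:]):
        if candidate in ("A", "B", "D"):
            return candidate
    return "unassigned"


def summarize_catalog(
    events: Iterable[ASEvent],
    gene_to_subgenome: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Event counts and within-subgenome type proportions."""
    rows = []
    for ev in events:
        if gene_to_subgenome is not None:
            sub = gene_to_subgenome.get(ev.gene_id, "unassigned")
        else:
            sub = default_subgenome(ev)
        rows.append({"subgenome": sub, "type": ev.type})
    if not rows:
        return pd.DataFrame(columns=["subgenome", "type", "count", "proportion"])
    df = pd.DataFrame(rows).groupby(["subgenome", "type"]).size().rename("count").reset_index()
    df["proportion"] = df["count"] / df.groupby("subgenome")["count"].transform("sum")
    return df


# ---------------------------------------------------------------------------
# Catalog TSV serialization

def _junctions_to_str(junctions: tuple[Junction, ...]) -> str:
    return ";".join(f"{j.kind}:{j.intron_start}-{j.intron_end}" for j in junctions)


def _junctions_from_str(text: str, chrom: str, strand: str) -> tuple[Junction, ...]:
    out = []
    for part in text.split(";"):
        kind, iv = part.split(":")
        s, e = iv.split("-")
        out.append(Junction(chrom, strand, kind, int(s), int(e)))
    return tuple(out)


def events_to_frame(events: Iterable[ASEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "type": ev.type,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "span_start": ev.span[0],
            "span_end": ev.span[1],
            "iso1_junctions": _junctions_to_str(ev.iso1_junctions),
            "iso2_junctions": _junctions_to_str(ev.iso2_junctions),
        }
        for ev in events
    ]
    cols = [
        "event_id", "gene_id", "type", "chrom", "strand",
        "span_start", "span_end", "iso1_junctions", "iso2_junctions",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_catalog(events: Iterable[ASEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> list[ASEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    events = []
    for _, r in df.iterrows():
        events.append(
            ASEvent(
                event_id=r["event_id"],
                gene_id=r["gene_id"],
                type=r["type"],
                chrom=r["chrom"],
                strand=r["strand"],
                iso1_junctions=_junctions_from_str(r["iso1_junctions"], r["chrom"], r["strand"]),
                iso2_junctions=_junctions_from_str(r["iso2_junctions"], r["chrom"], r["strand"]),
                span=(int(r["span_start"]), int(r["span_end"])),
            )
        )
    return events
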