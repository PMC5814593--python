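"""Predicted consequences of responsive AS events: PTC, UTR or CDS change.

For each event the gene's representative coding model (longest annotated
CDS) is located; the event region is classified against the CDS span.  For
in-CDS events the alternate isoform sequence is constructed by substituting
the event's isoform structure into the representative model, translated from
the annotated start codon, and scanned for a premature stop.  A stop lying at
least ``nmd_rule_nt`` (default 50) nucleotides upstream of the last
exon-exon junction marks the event as PTC-introducing (an NMD candidate);
otherwise the alteration is a protein (CDS) change.  Events outside the CDS
are UTR effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

from .annotation import EXON_EXON, TranscriptModel, ValidationError, group_by_gene
from .catalog import ASEvent

OUTCOMES = ("PTC", "UTR_effect", "CDS_change")


@dataclass(frozen=True)
class ConsequenceCall:
    event_id: str
    region: str  # {CDS, UTR}
    outcome: str  # {PTC, UTR_effect, CDS_change}
    frame_shift: bool | None = None
    stop_to_last_junction: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "PTC" and self.region != "CDS":
            raise ValidationError("PTC outcome requires a CDS-region event")
        if (self.outcome == "UTR_effect") != (self.region == "UTR"):
            raise ValidationError("UTR_effect outcome iff UTR region")


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Genome slice accessor working for plain dicts and pyfaidx.Fasta."""
    record = genome[chrom]
    piece = record[start:end]
    seq = getattr(piece, "seq", piece)
    return str(seq).upper()


def _ee_introns(event: ASEvent, isoform: int) -> list[tuple[int, int]]:
    juncs = event.iso1_junctions if isoform == 1 else event.iso2_junctions
    return sorted(
        (j.intron_start, j.intron_end) for j in juncs if j.kind == EXON_EXON
    )


def apply_event(
    exons: tuple[tuple[int, int], ...], event: ASEvent, isoform: int
) -> tuple[tuple[int, int], ...]:
    """Exon chain of the chosen isoform substituted into a model's structure.

    Introns of the model overlapping the event span are first merged away,
    then the isoform's exon-exon junctions re-split the merged exon.
    """
    span = event.span
    if not (exons[0][0] <= span[0] and span[1] <= exons[-1][1]):
        raise ValidationError(
            f"event {event.event_id} span {span} outside model span "
            f"({exons[0][0]}, {exons[-1][1]})"
        )
    merged: list[list[int]] = [list(exons[0])]
    for s, e in exons[1:]:
        prev = merged[-1]
        if prev[1] < span[1] and s > span[0]:  # intron overlaps event span
            prev[1] = e
        else:
            merged.append([s, e])
    introns = _ee_introns(event, isoform)
    out: list[tuple[int, int]] = []
    for s, e in merged:
        cur = s
        for a, b in introns:
            if cur < a and b < e:
                out.append((cur, a))
                cur = b
        out.append((cur, e))
    return tuple(out)


def _junction_offsets(exons: tuple[tuple[int, int], ...], strand: str) -> list[int]:
    """Exon-exon junction positions in transcript (5'->3') coordinates."""
    lengths = [e - s for s, e in exons]
    if strand == "-":
        lengths = lengths[::-1]
    offsets, acc = [], 0
    for ln in lengths[:-1]:
        acc += ln
        offsets.append(acc)
    return offsets


def _genomic_to_tx(exons: tuple[tuple[int, int], ...], strand: str, gpos: int) -> int | None:
    acc = 0
    ordered = exons if strand == "+" else exons[::-1]
    for s, e in ordered:
        if s <= gpos < e:
            return acc + (gpos - s if strand == "+" else e - 1 - gpos)
        acc += e - s
    return None


def build_isoform_sequence(
    model: TranscriptModel, event: ASEvent, isoform: int, genome
) -> tuple[str, list[int]]:
    """Spliced sequence of the model with the chosen isoform substituted.

    Returns the transcript sequence (reverse-complemented on -) and the
    exon-exon junction offsets in transcript coordinates.
    """
    exons = apply_event(model.exons, event, isoform)
    seq = "".join(_fetch(genome, model.chrom, s, e) for s, e in exons)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq, _junction_offsets(exons, model.strand)


def representative_model(models: Iterable[TranscriptModel]) -> TranscriptModel | None:
    """Transcript with the longest annotated CDS (ties: lexicographic id)."""
    coding = [m for m in models if m.cds is not None and m.cds_length() > 0]
    if not coding:
        return None
    return max(coding, key=lambda m: (m.cds_length(), m.transcript_id))


def _alternate_isoform(event: ASEvent, rep: TranscriptModel) -> int:
    """The isoform the representative model does NOT realize."""
    rep_introns = set(rep.introns())
    iso2 = set(_ee_introns(event, 2))
    if iso2 and iso2 <= rep_introns:
        return 1
    iso1 = set(_ee_introns(event, 1))
    if iso1 and iso1 <= rep_introns:
        return 2
    # IR retained in rep (no iso1 exon-exon junctions): alternate is spliced
    if event.type == "IR" and not any(
        i == (event.span[0], event.span[1]) for i in rep_introns
    ):
        return 2
    return 1


def classify_consequence(
    event: ASEvent,
    models: Iterable[TranscriptModel] | Mapping[str, list[TranscriptModel]],
    genome,
    nmd_rule_nt: int = 50,
) -> ConsequenceCall:
    """Classify one event as PTC, UTR_effect or CDS_change."""
    genes = models if isinstance(models, Mapping) else group_by_gene(models)
    gene_models = genes.get(event.gene_id, [])
    covering = [
        m
        for m in gene_models
        if m.span[0] <= event.span[0] and event.span[1] <= m.span[1]
    ]
    rep = representative_model(covering) or representative_model(gene_models)
    if rep is None:
        return ConsequenceCall(
            event.event_id, region="UTR", outcome="UTR_effect", flags=("noncoding_gene",)
        )
    cs, ce = rep.cds
    in_cds = event.span[0] < ce and event.span[1] > cs
    if not in_cds:
        return ConsequenceCall(event.event_id, region="UTR", outcome="UTR_effect")

    alt = _alternate_isoform(event, rep)
    try:
        seq, junction_offsets = build_isoform_sequence(rep, event, alt, genome)
        ref_seq, _ = build_isoform_sequence(rep, event, 3 - alt, genome)
    except ValidationError:
        return ConsequenceCall(
            event.event_id, region="CDS", outcome="CDS_change",
            flags=("model_not_covering_event",),
        )
    frame_shift = (len(seq) - len(ref_seq)) % 3 != 0

    alt_exons = apply_event(rep.exons, event, alt)
    start_gpos = cs if rep.strand == "+" else ce - 1
    tx_start = _genomic_to_tx(alt_exons, rep.strand, start_gpos)
    if tx_start is None:
        return ConsequenceCall(
            event.event_id, region="CDS", outcome="CDS_change",
            frame_shift=frame_shift, flags=("start_codon_lost",),
        )
    coding = seq[tx_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    stop_idx = protein.find("*")
    if stop_idx < 0:
        return ConsequenceCall(
            event.event_id, region="CDS", outcome="CDS_change",
            frame_shift=frame_shift, flags=("no_stop_codon",),
        )
    stop_end = tx_start + 3 * (stop_idx + 1)
    if not junction_offsets:
        return ConsequenceCall(
            event.event_id, region="CDS", outcome="CDS_change",
            frame_shift=frame_shift, flags=("no_downstream_junction",),
        )
    distance = max(junction_offsets) - stop_end
    if distance >= nmd_rule_nt:
        return ConsequenceCall(
            event.event_id, region="CDS", outcome="PTC",
            frame_shift=frame_shift, stop_to_last_junction=distance,
        )
    return ConsequenceCall(
        event.event_id, region="CDS", outcome="CDS_change",
        frame_shift=frame_shift, stop_to_last_junction=distance,
    )


def classify_all(
    events: Iterable[ASEvent],
    models: Iterable[TranscriptModel] | Mapping[str, list[TranscriptModel]],
    genome,
    nmd_rule_nt: int = 50,
) -> pd.DataFrame:
    genes = models if isinstance(models, Mapping) else group_by_gene(models)
    rows = []
    for ev in events:
        call = classify_consequence(ev, genes, genome, nmd_rule_nt=nmd_rule_nt)
        rows.append(
            {
                "event_id": call.event_id,
                "region": call.region,
                "outcome": call.outcome,
                "frame_shift": call.frame_shift,
                "stop_to_last_junction": call.stop_to_last_junction,
                "flags": ",".join(call.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "region", "outcome", "frame_shift",
            "stop_to_last_junction", "flags",
        ],
    )
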