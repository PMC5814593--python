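"""Transcript models, splice-junction features and junction-read counting.

Coordinates are 0-based half-open everywhere inside the package; GTF input
and output (1-based inclusive) are converted at the boundary.  Junctions come
in three kinds: ``exon_exon`` (a spliced intron), and the two exon–intron
boundaries of the same intron, ``exon_intron_5p`` (donor side) and
``exon_intron_3p`` (acceptor side).  Donor/acceptor are strand-aware: on the
minus strand the donor is the genomically-right boundary.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

EXON_EXON = "exon_exon"
EXON_INTRON_5P = "exon_intron_5p"
EXON_INTRON_3P = "exon_intron_3p"
JUNCTION_KINDS = (EXON_EXON, EXON_INTRON_5P, EXON_INTRON_3P)


class GtfParseError(ValueError):
    """Raised for malformed GTF records; message names the offending line."""


class ValidationError(ValueError):
    """Raised when a domain object violates its structural invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons plus an optional annotated CDS.

    ``exons`` are sorted, non-overlapping, non-adjacent half-open intervals.
    ``cds`` is the genomic span (start, end) of the coding region; the
    per-exon coding segments are the intersection of that span with the
    exons and are exposed via :meth:`cds_segments`.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        if len(self.exons) == 0:
            raise ValidationError(f"transcript {self.transcript_id}: at least one exon required")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValidationError(
                    f"transcript {self.transcript_id}: invalid exon interval [{s},{e})"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons must be sorted with gap >= 1 "
                    f"([{s1},{e1}) then [{s2},{e2}))"
                )
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.exons[0][0] <= cs < ce <= self.exons[-1][1]):
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS span [{cs},{ce}) outside exon span"
                )
            if not self.cds_segments():
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS span overlaps no exon"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    def cds_segments(self) -> tuple[tuple[int, int], ...]:
        if self.cds is None:
            return ()
        cs, ce = self.cds
        segs = []
        for s, e in self.exons:
            a, b = max(s, cs), min(e, ce)
            if a < b:
                segs.append((a, b))
        return tuple(segs)

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments())

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True, order=True)
class Junction:
    """A splice-junction feature tied to one intron interval."""

    chrom: str
    strand: str
    kind: str
    intron_start: int
    intron_end: int

    def __post_init__(self) -> None:
        if self.kind not in JUNCTION_KINDS:
            raise ValidationError(f"unknown junction kind {self.kind!r}")
        if not (0 <= self.intron_start < self.intron_end):
            raise ValidationError(
                f"junction intron [{self.intron_start},{self.intron_end}) invalid"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"junction strand must be + or -, got {self.strand!r}")

    @property
    def boundary(self) -> int | None:
        """Genomic position of the exon–intron boundary (None for exon_exon)."""
        if self.kind == EXON_EXON:
            return None
        donor_left = self.strand == "+"
        if self.kind == EXON_INTRON_5P:
            return self.intron_start if donor_left else self.intron_end
        return self.intron_end if donor_left else self.intron_start


# ---------------------------------------------------------------------------
# GTF reading / writing

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return {k: v for k, v in _ATTR_RE.findall(attr_field)}


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Uses ``exon`` and ``CDS`` features; coordinates are converted from
    1-based inclusive to 0-based half-open, exons sorted ascending regardless
    of strand.  Missing gene_id/transcript_id raises :class:`GtfParseError`
    naming the line.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    declared: list[str] = []  # transcript ids in file order

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS", "transcript"):
                continue
            attr = _parse_attributes(attrs)
            if "gene_id" not in attr:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id attribute")
            if "transcript_id" not in attr:
                raise GtfParseError(f"{path}:{lineno}: missing transcript_id attribute")
            tid = attr["transcript_id"]
            if tid not in meta:
                meta[tid] = (attr["gene_id"], chrom, strand)
                declared.append(tid)
            try:
                iv = (int(start) - 1, int(end))
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feature == "CDS":
                cds.setdefault(tid, []).append(iv)

    models = []
    for tid in declared:
        gene_id, chrom, strand = meta[tid]
        if tid not in exons:
            raise ValidationError(f"transcript {tid}: declared without any exon")
        exon_ivs = tuple(sorted(exons[tid]))
        cds_span = None
        if tid in cds:
            segs = sorted(cds[tid])
            cds_span = (segs[0][0], segs[-1][1])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exon_ivs,
                cds=cds_span,
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write models as GTF (1-based inclusive), deterministically ordered."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tjuncsplice\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for s, e in m.cds_segments():
                fh.write(
                    f"{m.chrom}\tjuncsplice\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def group_by_gene(models: Iterable[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = {}
    for m in models:
        genes.setdefault(m.gene_id, []).append(m)
    return genes


# ---------------------------------------------------------------------------
# Junction extraction

def extract_junctions(models: Iterable[TranscriptModel]) -> set[Junction]:
    """One exon_exon plus the two exon_intron boundary junctions per intron,
    deduplicated across transcripts."""
    out: set[Junction] = set()
    any_model = False
    for m in models:
        any_model = True
        for s, e in m.introns():
            out.add(Junction(m.chrom, m.strand, EXON_EXON, s, e))
            out.add(Junction(m.chrom, m.strand, EXON_INTRON_5P, s, e))
            out.add(Junction(m.chrom, m.strand, EXON_INTRON_3P, s, e))
    if not any_model:
        raise ValidationError("extract_junctions requires at least one transcript model")
    return out


# ---------------------------------------------------------------------------
# Junction counts container

class JunctionCounts:
    """Per-sample uniquely-mapped supporting-read counts per junction."""

    def __init__(
        self,
        counts: Mapping[Junction, Mapping[str, int]] | None = None,
        samples: Sequence[str] = (),
    ) -> None:
        self._counts: dict[Junction, dict[str, int]] = {}
        self.samples: list[str] = list(samples)
        self.qc: dict[str, int] = {}
        if counts:
            for j, per_sample in counts.items():
                for s, c in per_sample.items():
                    self.set(j, s, c)

    def set(self, junction: Junction, sample: str, count: int) -> None:
        if count != int(count) or count < 0:
            raise ValidationError(
                f"count for {junction} sample {sample} must be a non-negative integer"
            )
        if sample not in self.samples:
            self.samples.append(sample)
        self._counts.setdefault(junction, {})[sample] = int(count)

    def add(self, junction: Junction, sample: str, increment: int = 1) -> None:
        cur = self._counts.get(junction, {}).get(sample, 0)
        self.set(junction, sample, cur + increment)

    def get(self, junction: Junction, sample: str) -> int:
        return self._counts.get(junction, {}).get(sample, 0)

    def junctions(self) -> list[Junction]:
        return sorted(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, junction: Junction) -> bool:
        return junction in self._counts

    def max_count(self, junction: Junction) -> int:
        per = self._counts.get(junction, {})
        return max(per.values(), default=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in self.junctions():
            row = {
                "chrom": j.chrom,
                "strand": j.strand,
                "kind": j.kind,
                "intron_start": j.intron_start,
                "intron_end": j.intron_end,
            }
            for s in self.samples:
                row[s] = self.get(j, s)
            rows.append(row)
        cols = ["chrom", "strand", "kind", "intron_start", "intron_end"] + list(self.samples)
        return pd.DataFrame(rows, columns=cols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JunctionCounts):
            return NotImplemented
        if set(self.samples) != set(other.samples):
            return False
        juncs = set(self._counts) | set(other._counts)
        return all(
            self.get(j, s) == other.get(j, s) for j in juncs for s in self.samples
        )


KEY_COLUMNS = ["chrom", "strand", "kind", "intron_start", "intron_end"]


def write_junction_counts(counts: JunctionCounts, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def read_junction_counts(
    path: str | Path, design_samples: Sequence[str] | None = None
) -> JunctionCounts:
    """Read the junction-count TSV; round-trip with write is lossless.

    When ``design_samples`` is given, every sample column must appear in it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "kind": str})
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing key columns {missing}")
    sample_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    if design_samples is not None:
        unknown = [s for s in sample_cols if s not in set(design_samples)]
        if unknown:
            raise ValidationError(f"{path}: samples {unknown} not present in design table")
    counts = JunctionCounts(samples=sample_cols)
    for _, rec in df.iterrows():
        j = Junction(
            str(rec["chrom"]), str(rec["strand"]), str(rec["kind"]),
            int(rec["intron_start"]), int(rec["intron_end"]),
        )
        for s in sample_cols:
            fval = float(rec[s])
            if fval < 0 or fval != int(fval):
                raise ValidationError(f"{path}: negative or non-integer count {rec[s]!r} for {s}")
            counts.set(j, s, int(fval))
    return counts


def filter_junctions(counts: JunctionCounts, min_reads: int = 5) -> set[Junction]:
    """Junctions supported by >= min_reads uniquely-mapped reads in >= 1 sample."""
    return {j for j in counts.junctions() if counts.max_count(j) >= min_reads}


# ---------------------------------------------------------------------------
# Counting junction support from spliced alignments

def _aligned_segments(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Contiguous reference segments of the alignment, split at N (intron) ops."""
    segments: list[tuple[int, int]] = []
    pos = read.reference_start
    seg_start = pos
    open_segment = False
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference contiguously
            if not open_segment:
                seg_start = pos
                open_segment = True
            pos += length
        elif op == 3:  # N: intron gap
            if open_segment:
                segments.append((seg_start, pos))
                open_segment = False
            pos += length
        # I, S, H, P consume no reference
    if open_segment:
        segments.append((seg_start, pos))
    return segments


def _is_unique(read: pysam.AlignedSegment) -> bool:
    """Uniqueness from the NH tag when present, else mapping quality > 0."""
    if read.has_tag("NH"):
        return read.get_tag("NH") == 1
    return read.mapping_quality > 0


def count_junctions_from_alignments(
    alignments: Mapping[str, str | Path],
    junctions: Iterable[Junction],
    min_overhang: int = 5,
    unique_only: bool = True,
) -> JunctionCounts:
    """Count junction-supporting reads per sample from SAM/BAM files.

    ``alignments`` maps sample id to alignment file path.  An exon_exon
    junction is supported by a read with an alignment gap exactly matching its
    intron and >= ``min_overhang`` aligned bases on both sides; an exon_intron
    junction by a read aligned contiguously across its boundary with
    >= ``min_overhang`` bases on each side.  Multi-mapped reads are excluded
    when ``unique_only``; unparseable records are skipped and tallied in
    ``counts.qc``.
    """
    junctions = list(junctions)
    ee_index: dict[tuple[str, int, int], list[Junction]] = {}
    boundary_pos: dict[str, list[int]] = {}
    boundary_index: dict[str, list[list[Junction]]] = {}
    tmp: dict[str, dict[int, list[Junction]]] = {}
    for j in junctions:
        if j.kind == EXON_EXON:
            ee_index.setdefault((j.chrom, j.intron_start, j.intron_end), []).append(j)
        else:
            tmp.setdefault(j.chrom, {}).setdefault(j.boundary, []).append(j)
    for chrom, by_pos in tmp.items():
        positions = sorted(by_pos)
        boundary_pos[chrom] = positions
        boundary_index[chrom] = [by_pos[p] for p in positions]

    counts = JunctionCounts(samples=list(alignments))
    qc = {"skipped_records": 0, "multimapped_excluded": 0, "reads_seen": 0}
    for sample, path in alignments.items():
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for read in fh:
                try:
                    if read.is_unmapped or read.is_secondary or read.is_supplementary:
                        continue
                    qc["reads_seen"] += 1
                    if unique_only and not _is_unique(read):
                        qc["multimapped_excluded"] += 1
                        continue
                    segments = _aligned_segments(read)
                except Exception:  # malformed record: skip, keep going
                    qc["skipped_records"] += 1
                    logger.warning("skipping unparseable alignment record in %s", path)
                    continue
                chrom = read.reference_name
                # exon-exon support: gaps between consecutive segments
                for (s1, e1), (s2, e2) in zip(segments, segments[1:]):
                    for j in ee_index.get((chrom, e1, s2), []):
                        if e1 - s1 >= min_overhang and e2 - s2 >= min_overhang:
                            counts.add(j, sample)
                # exon-intron support: contiguous span across the boundary
                positions = boundary_pos.get(chrom)
                if positions:
                    for s, e in segments:
                        lo = bisect_left(positions, s + min_overhang)
                        hi = bisect_right(positions, e - min_overhang)
                        for idx in range(lo, hi):
                            for j in boundary_index[chrom][idx]:
                                counts.add(j, sample)
        # make sure every requested junction exists even if unsupported
        for j in junctions:
            if counts.get(j, sample) == 0:
                counts.set(j, sample, 0)
    counts.qc = qc
    return counts
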