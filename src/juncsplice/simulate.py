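"""Synthetic miniature genome, annotation and counts with known ground truth.

The generator emulates the study design the pipeline targets: three
"subgenome" chromosomes (A, B, D) carrying homeolog triplets, a planted AS
event of known type per alternatively-spliced gene (two transcript isoforms
with valid GT..AG splice dinucleotides and an annotated CDS), and a
16-sample design of 2 biological replicates x {CK, DS, HS, HD} x {1 h, 6 h}.
Per-sample junction counts are drawn by giving each event a negative-
binomial total depth and binomial inclusion reads at the condition's true
IEP, then decomposing to junction counts as the exact inverse of the
quantification rules (both flanks of an included exon and both boundaries of
a retained intron receive the inclusion draw).  Gene expression counts are
negative binomial with planted fold changes.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import (
    EXON_EXON,
    Junction,
    JunctionCounts,
    TranscriptModel,
    ValidationError,
    extract_junctions,
    group_by_gene,
    write_gtf,
    write_junction_counts,
)
from .catalog import ASEvent, detect_events

CONDITIONS = ("CK", "DS", "HS", "HD")
TIMEPOINTS = ("1h", "6h")
DEFAULT_TYPE_MIX = {"IR": 0.38, "ES": 0.26, "Alt3SS": 0.22, "Alt5SS": 0.14}
DEFAULT_RESPONSIVE_PROBS = {"DS": 0.05, "HS": 0.35, "HD": 0.40}

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
)


def default_design() -> pd.DataFrame:
    """Balanced 16-sample design: 2 reps x 4 conditions x 2 timepoints."""
    rows = [
        {
            "sample_id": f"{cond}_{tp}_r{rep}",
            "condition": cond,
            "timepoint": tp,
            "replicate": rep,
        }
        for cond in CONDITIONS
        for tp in TIMEPOINTS
        for rep in (1, 2)
    ]
    return pd.DataFrame(rows)


@dataclass
class SimAnnotation:
    """Planted genome + annotation plus the ground-truth tables."""

    genome: dict[str, str]
    models: list[TranscriptModel]
    events: list[ASEvent]  # detected from the planted annotation, 1 per AS gene
    truth_events: pd.DataFrame  # event-level truth: type, IEPs, responsiveness
    truth_genes: pd.DataFrame  # gene-level truth: expression effects
    triplets: pd.DataFrame
    gene2go: pd.DataFrame


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _coding_seq(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _gene_segments(rng: np.random.Generator, event_type: str | None) -> list[tuple[str, str, int]]:
    """Sense-orientation segment layout: list of (label, kind, length)."""
    e1 = int(rng.integers(150, 240))
    e2 = int(rng.integers(150, 240))
    i1 = int(rng.integers(90, 180))
    if event_type is None:
        return [("E1", "exon", e1), ("I1", "intron", i1), ("E2", "exon", e2)]
    if event_type == "IR":
        return [("E1", "exon", e1), ("I1", "intron", i1), ("E2", "exon", e2)]
    if event_type == "ES":
        ec = int(rng.integers(60, 140))
        i2 = int(rng.integers(90, 180))
        return [
            ("E1", "exon", e1), ("I1", "intron", i1), ("EC", "cassette", ec),
            ("I2", "intron", i2), ("E2", "exon", e2),
        ]
    if event_type == "Alt5SS":
        ext = int(rng.integers(30, 90))
        return [
            ("E1", "exon", e1), ("X", "extension", ext), ("I1", "intron", i1),
            ("E2", "exon", e2),
        ]
    if event_type == "Alt3SS":
        ext = int(rng.integers(30, 90))
        return [
            ("E1", "exon", e1), ("I1", "intron", i1), ("X", "extension", ext),
            ("E2", "exon", e2),
        ]
    raise ValidationError(f"unknown event type {event_type!r}")


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    locus_start: int,
    event_type: str | None,
) -> tuple[str, list[TranscriptModel], dict | None]:
    """Build one gene locus: sense sequence, transcripts, planted-event spec.

    The exclusion (fully spliced) isoform carries a clean reading frame:
    5' UTR, ATG, stop-free sense codons, TAA stop, 3' UTR.  Inclusion-only
    segments (retained intron, cassette exon, splice-site extensions) are
    random sequence, so their translational consequences vary realistically.
    """
    segments = _gene_segments(rng, event_type)
    # sense offsets per segment
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for label, _, length in segments:
        offsets[label] = (pos, pos + length)
        pos += length
    locus_len = pos

    # exclusion-isoform exons in sense coordinates
    if event_type == "Alt5SS":
        excl_labels = ["E1", "E2"]
        incl_exons_sense = [(offsets["E1"][0], offsets["X"][1]), offsets["E2"]]
    elif event_type == "Alt3SS":
        excl_labels = ["E1", "E2"]
        incl_exons_sense = [offsets["E1"], (offsets["X"][0], offsets["E2"][1])]
    elif event_type == "ES":
        excl_labels = ["E1", "E2"]
        incl_exons_sense = [offsets["E1"], offsets["EC"], offsets["E2"]]
    elif event_type == "IR":
        excl_labels = ["E1", "E2"]
        incl_exons_sense = [(offsets["E1"][0], offsets["E2"][1])]
    else:
        excl_labels = ["E1", "E2"]
        incl_exons_sense = None
    excl_exons_sense = [offsets[lb] for lb in excl_labels]

    # --- sequence assembly (sense orientation)
    utr5, utr3 = 30, 45
    excl_len = sum(e - s for s, e in excl_exons_sense)
    coding_len = excl_len - utr5 - utr3
    coding_len -= coding_len % 3
    cds_seq = "ATG" + _coding_seq(rng, coding_len // 3 - 2) + "TAA"
    spliced = _random_seq(rng, utr5) + cds_seq + _random_seq(rng, excl_len - utr5 - coding_len)
    seq = [""] * len(segments)
    cursor = 0
    for i, (label, kind, length) in enumerate(segments):
        if label in excl_labels:
            seq[i] = spliced[cursor : cursor + length]
            cursor += length
        elif kind == "intron":
            seq[i] = "GT" + _random_seq(rng, length - 4) + "AG"
        else:
            seq[i] = _random_seq(rng, length)
    # splice dinucleotides for the composite introns of the exclusion form
    by_label = dict(zip([s[0] for s in segments], range(len(segments))))
    if event_type == "Alt5SS":  # extension X is intronic in the exclusion form
        i = by_label["X"]
        seq[i] = "GT" + seq[i][2:]
    if event_type == "Alt3SS":
        i = by_label["X"]
        seq[i] = seq[i][:-2] + "AG"
    locus_seq = "".join(seq)

    # CDS sense-locus span: from ATG within E1 to the stop within the last exon
    cds_sense_start = excl_exons_sense[0][0] + utr5
    remaining = utr5 + coding_len
    for s, e in excl_exons_sense:
        if remaining <= e - s:
            cds_sense_end = s + remaining
            break
        remaining -= e - s

    def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
        if strand == "+":
            return (locus_start + iv[0], locus_start + iv[1])
        return (locus_start + locus_len - iv[1], locus_start + locus_len - iv[0])

    genomic_seq = locus_seq if strand == "+" else _revcomp(locus_seq)
    cds_span = to_genomic((cds_sense_start, cds_sense_end))

    def make_model(
        tid: str, exons_sense: list[tuple[int, int]], with_cds: bool
    ) -> TranscriptModel:
        exons = tuple(sorted(to_genomic(iv) for iv in exons_sense))
        cs = (max(cds_span[0], exons[0][0]), min(cds_span[1], exons[-1][1]))
        return TranscriptModel(
            transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
            exons=exons, cds=cs if with_cds and cs[0] < cs[1] else None,
        )

    # CDS annotated on the fully spliced isoform only: it carries the clean
    # reading frame, so it is the gene's representative coding model.
    models = [make_model(f"{gene_id}.t1", excl_exons_sense, True)]
    spec = None
    if event_type is not None:
        models.append(make_model(f"{gene_id}.t2", incl_exons_sense, False))
        spec = {"gene_id": gene_id, "type": event_type}
    return genomic_seq, models, spec


def simulate_annotation(
    n_genes: int = 60,
    frac_as: float = 0.6,
    type_mix: Mapping[str, float] = DEFAULT_TYPE_MIX,
    n_triplets: int = 10,
    seed: int = 0,
    effect_size: float = 0.40,
    responsive_probs: Mapping[str, float] = DEFAULT_RESPONSIVE_PROBS,
    deg_fold: float = 4.0,
    deg_prob_coupled: float = 0.5,
    deg_prob_uncoupled: float = 0.12,
    n_go_terms: int = 15,
) -> SimAnnotation:
    """Generate a miniature three-subgenome annotation with planted events.

    Each AS gene (a ``frac_as`` fraction) carries exactly one planted event
    drawn from ``type_mix``; responsive events shift their true IEP by
    ``effect_size`` under the planted conditions at both timepoints.  A
    subset of genes additionally receives ``deg_fold`` expression shifts,
    co-occurring with AS responses with probability ``deg_prob_coupled``.
    """
    if n_genes < 3 * n_triplets:
        raise ValidationError("n_genes must be >= 3 * n_triplets")
    if abs(sum(type_mix.values()) - 1.0) > 1e-9:
        raise ValidationError("type_mix must sum to 1")
    rng = np.random.default_rng(seed)

    # gene ids: triplet genes share a numeric prefix across subgenomes
    gene_specs: list[tuple[str, str]] = []  # (gene_id, subgenome)
    for t in range(n_triplets):
        for sub in "ABD":
            gene_specs.append((f"g{t + 1:04d}{sub}", sub))
    extra = n_genes - 3 * n_triplets
    for i in range(extra):
        sub = "ABD"[i % 3]
        gene_specs.append((f"g{n_triplets + i + 1:04d}{sub}", sub))

    n_as = int(round(frac_as * n_genes))
    types = list(type_mix)
    type_draw = rng.choice(len(types), size=n_as, p=[type_mix[t] for t in types])
    as_flags = np.zeros(n_genes, dtype=bool)
    as_flags[rng.permutation(n_genes)[:n_as]] = True

    chrom_seqs: dict[str, list[str]] = {f"chr{s}": [] for s in "ABD"}
    chrom_pos: dict[str, int] = {f"chr{s}": 0 for s in "ABD"}
    spacer = 50
    models: list[TranscriptModel] = []
    planted: list[dict] = []
    as_i = 0
    for gi, (gene_id, sub) in enumerate(gene_specs):
        chrom = f"chr{sub}"
        etype = None
        if as_flags[gi]:
            etype = types[type_draw[as_i]]
            as_i += 1
        strand = "+" if rng.random() < 0.5 else "-"
        pad = _random_seq(rng, spacer)
        chrom_seqs[chrom].append(pad)
        chrom_pos[chrom] += spacer
        gseq, gmodels, spec = _build_gene(
            rng, gene_id, chrom, strand, chrom_pos[chrom], etype
        )
        chrom_seqs[chrom].append(gseq)
        chrom_pos[chrom] += len(gseq)
        models.extend(gmodels)
        if spec is not None:
            planted.append(spec)
    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}

    # detected events on the planted annotation: exactly one per AS gene
    events = detect_events(group_by_gene(models))
    by_gene = {}
    for ev in events:
        by_gene.setdefault(ev.gene_id, []).append(ev)
    for spec in planted:
        got = by_gene.get(spec["gene_id"], [])
        if len(got) != 1 or got[0].type != spec["type"]:
            raise ValidationError(
                f"planted {spec['type']} event in {spec['gene_id']} not uniquely "
                f"recovered ({[e.type for e in got]})"
            )
        spec["event_id"] = got[0].event_id

    # --- event-level truth: baseline IEPs and planted condition responses
    truth_rows = []
    for spec in planted:
        base = float(rng.uniform(0.2, 0.6))
        row = {
            "event_id": spec["event_id"],
            "gene_id": spec["gene_id"],
            "type": spec["type"],
            "subgenome": spec["gene_id"][-1],
        }
        responsive_conditions = []
        for cond in CONDITIONS:
            if cond == "CK":
                iep_c = base
            elif rng.random() < responsive_probs.get(cond, 0.0):
                up_ok = base + effect_size <= 0.95
                down_ok = base - effect_size >= 0.05
                if up_ok and down_ok:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                else:
                    sign = 1.0 if up_ok else -1.0
                iep_c = base + sign * effect_size
                responsive_conditions.append(cond)
            else:
                iep_c = base
            for tp in TIMEPOINTS:
                row[f"iep_{cond}_{tp}"] = iep_c
        for cond in CONDITIONS[1:]:
            row[f"responsive_{cond}"] = cond in responsive_conditions
        truth_rows.append(row)
    truth_events = pd.DataFrame(truth_rows)

    # --- gene-level truth: expression baselines and planted fold changes
    as_resp: dict[str, set[str]] = {}
    for r in truth_rows:
        conds = {c for c in CONDITIONS[1:] if r[f"responsive_{c}"]}
        as_resp[r["gene_id"]] = conds
    gene_rows = []
    for gene_id, sub in gene_specs:
        base_expr = float(rng.lognormal(mean=np.log(300.0), sigma=0.5))
        row = {"gene_id": gene_id, "subgenome": sub, "base_expr": base_expr}
        for cond in CONDITIONS[1:]:
            coupled = cond in as_resp.get(gene_id, set())
            p_deg = deg_prob_coupled if coupled else deg_prob_uncoupled
            if rng.random() < p_deg:
                direction = 1.0 if rng.random() < 0.5 else -1.0
                row[f"fc_{cond}"] = deg_fold if direction > 0 else 1.0 / deg_fold
            else:
                row[f"fc_{cond}"] = 1.0
        gene_rows.append(row)
    truth_genes = pd.DataFrame(gene_rows)

    triplets = pd.DataFrame(
        [
            {
                "gene_A": f"g{t + 1:04d}A",
                "gene_B": f"g{t + 1:04d}B",
                "gene_D": f"g{t + 1:04d}D",
            }
            for t in range(n_triplets)
        ],
        columns=["gene_A", "gene_B", "gene_D"],
    )

    # --- gene -> GO mapping: one stress-coupled term plus random terms
    go_rows = []
    stress_genes = [g for g, conds in as_resp.items() if conds]
    for g in stress_genes:
        go_rows.append({"gene_id": g, "term_id": "GO:stress"})
    all_gene_ids = [g for g, _ in gene_specs]
    for k in range(n_go_terms):
        size = int(rng.integers(3, max(4, n_genes // 4)))
        for g in rng.choice(all_gene_ids, size=size, replace=False):
            go_rows.append({"gene_id": g, "term_id": f"GO:{k + 1:07d}"})
    gene2go = pd.DataFrame(go_rows, columns=["gene_id", "term_id"]).drop_duplicates()

    return SimAnnotation(
        genome=genome,
        models=models,
        events=events,
        truth_events=truth_events,
        truth_genes=truth_genes,
        triplets=triplets,
        gene2go=gene2go,
    )


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """Negative binomial with var = mean + dispersion * mean^2 (Poisson at 0)."""
    if mean <= 0:
        raise ValidationError("mean depth must be positive")
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_counts(
    ann: SimAnnotation,
    design: pd.DataFrame | None = None,
    mean_depth: float = 100.0,
    dispersion: float = 0.1,
    seed: int = 0,
    retention_noise: float = 0.03,
    expression_dispersion: float = 0.05,
) -> tuple[JunctionCounts, pd.DataFrame]:
    """Draw per-sample junction counts and a gene expression table.

    Event counts invert the quantification convention: the inclusion draw is
    written to both flanking (ES) or both boundary (IR) junctions, the
    exclusion draw to the spliced/skip junction.  Constitutive introns get a
    negative-binomial spliced depth plus a small binomial retention noise at
    their boundaries.  Expression counts use their own (milder) biological
    dispersion: the junction-depth dispersion never affects the splicing
    test, which conditions on totals, whereas the exact-test DEG caller
    assumes near-Poisson sampling.
    """
    if design is None:
        design = default_design()
    rng = np.random.default_rng(seed)
    samples = list(design["sample_id"])
    sample_cond_tp = {
        str(r.sample_id): (str(r.condition), str(r.timepoint)) for r in design.itertuples()
    }
    counts = JunctionCounts(samples=samples)
    truth = ann.truth_events.set_index("event_id")

    event_junctions: set[Junction] = set()
    for ev in sorted(ann.events, key=lambda e: e.event_id):
        event_junctions.update(ev.iso1_junctions)
        event_junctions.update(ev.iso2_junctions)
        for s in samples:
            cond, tp = sample_cond_tp[s]
            true_iep = float(truth.at[ev.event_id, f"iep_{cond}_{tp}"])
            depth = int(_nb_draw(rng, mean_depth, dispersion))
            n1 = int(rng.binomial(depth, true_iep)) if depth > 0 else 0
            n2 = depth - n1
            for j in ev.iso1_junctions:
                counts.set(j, s, n1)
            for j in ev.iso2_junctions:
                counts.set(j, s, n2)

    all_junctions = extract_junctions(ann.models)
    constitutive_ee = sorted(
        j for j in all_junctions if j.kind == EXON_EXON and j not in event_junctions
    )
    boundary_of: dict[tuple[str, int, int], list[Junction]] = {}
    for j in all_junctions:
        if j.kind != EXON_EXON and j not in event_junctions:
            boundary_of.setdefault((j.chrom, j.intron_start, j.intron_end), []).append(j)
    for j in constitutive_ee:
        for s in samples:
            depth = int(_nb_draw(rng, mean_depth, dispersion))
            counts.set(j, s, depth)
            for bj in sorted(boundary_of.get((j.chrom, j.intron_start, j.intron_end), [])):
                counts.set(bj, s, int(rng.binomial(depth, retention_noise)))
    # orphan boundary junctions (e.g. IR exon-intron pairs already covered)
    for j in sorted(all_junctions):
        for s in samples:
            if counts.get(j, s) == 0:
                counts.set(j, s, 0)

    # --- expression counts
    genes = ann.truth_genes.set_index("gene_id")
    expr = pd.DataFrame(index=sorted(genes.index), columns=samples, dtype=float)
    for g in expr.index:
        base = float(genes.at[g, "base_expr"])
        for s in samples:
            cond, _tp = sample_cond_tp[s]
            fc = 1.0 if cond == "CK" else float(genes.at[g, f"fc_{cond}"])
            expr.at[g, s] = float(_nb_draw(rng, base * fc, expression_dispersion))
    expr.index.name = "gene_id"
    return counts, expr


# ---------------------------------------------------------------------------
# Writers: emit exactly the formats the pipeline reads

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_simulation(
    ann: SimAnnotation,
    counts: JunctionCounts,
    expr: pd.DataFrame,
    outdir: str | Path,
    design: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write FASTA/GTF/TSV inputs plus truth tables; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = default_design()
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "design": outdir / "design.tsv",
        "junction_counts": outdir / "junction_counts.tsv",
        "triplets": outdir / "triplets.tsv",
        "gene2go": outdir / "gene2go.tsv",
        "expression": outdir / "expression.tsv",
        "truth_events": outdir / "truth_events.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
    }
    write_fasta(ann.genome, paths["fasta"])
    write_gtf(ann.models, paths["gtf"])
    design.to_csv(paths["design"], sep="\t", index=False)
    write_junction_counts(counts, paths["junction_counts"])
    ann.triplets.to_csv(paths["triplets"], sep="\t", index=False)
    ann.gene2go.to_csv(paths["gene2go"], sep="\t", index=False)
    expr.to_csv(paths["expression"], sep="\t")
    ann.truth_events.to_csv(paths["truth_events"], sep="\t", index=False)
    ann.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return paths
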