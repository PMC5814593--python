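"""End-to-end orchestration: catalog -> quantify -> call -> compare.

Stages run in dependency order on the inputs named by a flat key/value
config; all intermediates are TSV/JSON files, and reruns on identical inputs
produce byte-identical outputs.  A manifest records the package version,
seed, thresholds and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    ValidationError,
    count_junctions_from_alignments,
    extract_junctions,
    filter_junctions,
    group_by_gene,
    read_gtf,
    read_junction_counts,
)
from .catalog import detect_events, events_to_frame, summarize_catalog, write_catalog
from .consequence import classify_all
from .diffsplice import call_responsive, collect_dsgs, read_design
from .downstream import (
    classify_triplets,
    delta_iep_matrix,
    fuzzy_cmeans,
    go_enrichment,
    read_gene2go,
    read_triplets,
)
from .expression import (
    call_degs,
    deg_sets,
    dsg_enrichment_in_degs,
    overlap_dsg_deg,
    read_deg_table,
)
from .quant import gene_junction_totals, quantify_all

logger = logging.getLogger(__name__)

_THRESHOLDS = {
    "min_junction_reads": 5,
    "min_overhang": 5,
    "fdr": 0.05,
    "min_delta": 0.30,
    "fc": 2.0,
    "event_min_total": 10,
    "gene_junction_min": 10,
    "clusters": 12,
    "fuzzifier": 1.25,
    "nmd_nt": 50,
    "expressed_min": 1.0,
}


@dataclass
class PipelineConfig:
    gtf: str
    design: str
    expression: str
    junction_counts: str | None = None
    alignments: str | None = None  # TSV: sample_id <tab> path
    fasta: str | None = None
    triplets: str | None = None
    gene2go: str | None = None
    deg_table: str | None = None
    truth_events: str | None = None
    truth_genes: str | None = None
    seed: int = 0
    min_junction_reads: int = 5
    min_overhang: int = 5
    fdr: float = 0.05
    min_delta: float = 0.30
    fc: float = 2.0
    event_min_total: int = 10
    gene_junction_min: int = 10
    clusters: int = 12
    fuzzifier: float = 1.25
    nmd_nt: int = 50
    expressed_min: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.junction_counts is None and self.alignments is None:
            raise ValidationError("config needs junction_counts or alignments")
        for key in ("gtf", "design", "expression", "junction_counts", "alignments",
                    "fasta", "triplets", "gene2go", "deg_table", "truth_events",
                    "truth_genes"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ValidationError(f"config path {key}={val} does not exist")
        for key in _THRESHOLDS:
            if getattr(self, key) <= 0:
                raise ValidationError(f"threshold {key} must be positive")


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the in-memory results bundle."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    models = read_gtf(config.gtf)
    genes = group_by_gene(models)
    design = read_design(config.design)

    if config.junction_counts is not None:
        counts = read_junction_counts(config.junction_counts, design["sample_id"])
    else:
        amap = pd.read_csv(config.alignments, sep="\t", dtype=str)
        junctions = extract_junctions(models)
        counts = count_junctions_from_alignments(
            dict(zip(amap["sample_id"], amap["path"])),
            junctions,
            min_overhang=config.min_overhang,
        )

    retained = filter_junctions(counts, min_reads=config.min_junction_reads)
    events = detect_events(genes, retained)
    write_catalog(events, outdir / "catalog.tsv")
    summarize_catalog(events).to_csv(outdir / "catalog_summary.tsv", sep="\t", index=False)

    quants = quantify_all(events, counts, list(design["sample_id"]))
    quants.to_csv(outdir / "quants.tsv", sep="\t", index=False)

    results, summary = call_responsive(
        quants,
        design,
        fdr_threshold=config.fdr,
        min_delta=config.min_delta,
        min_total=config.event_min_total,
    )
    results.to_csv(outdir / "diff_results.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "diff_summary.tsv", sep="\t", index=False)

    event_to_gene = {ev.event_id: ev.gene_id for ev in events}
    dsgs_by_cond, dsgs_by_tp = collect_dsgs(summary, event_to_gene)
    pd.DataFrame(
        [
            {"condition": cond, "gene_id": g}
            for cond in sorted(dsgs_by_cond)
            for g in sorted(dsgs_by_cond[cond])
        ],
        columns=["condition", "gene_id"],
    ).to_csv(outdir / "dsgs.tsv", sep="\t", index=False)

    expr = pd.read_csv(config.expression, sep="\t", index_col="gene_id")
    if config.deg_table is not None:
        degs = read_deg_table(config.deg_table)
    else:
        degs = call_degs(expr, design, fc_threshold=config.fc, fdr=config.fdr)
    degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
    degs_by_cond = deg_sets(degs)

    totals = gene_junction_totals(quants, event_to_gene)
    overlap_rows = []
    for cond in sorted(set(dsgs_by_cond) | set(degs_by_cond)):
        dsg = dsgs_by_cond.get(cond, set())
        deg = degs_by_cond.get(cond, set())
        row = {"condition": cond}
        row.update(overlap_dsg_deg(dsg, deg))
        if dsg and len(totals):
            try:
                row.update(
                    dsg_enrichment_in_degs(
                        dsg, deg, totals, min_junction_reads=config.gene_junction_min
                    )
                )
            except ValidationError:
                pass
        overlap_rows.append(row)
    overlap = pd.DataFrame(overlap_rows)
    overlap.to_csv(outdir / "dsg_deg_overlap.tsv", sep="\t", index=False)

    responsive_ids = sorted(set(summary.loc[summary["responsive"], "event_id"]))
    consequences = pd.DataFrame()
    if config.fasta is not None and responsive_ids:
        import pyfaidx

        genome = pyfaidx.Fasta(config.fasta)
        resp_events = [ev for ev in events if ev.event_id in set(responsive_ids)]
        consequences = classify_all(resp_events, genes, genome, nmd_rule_nt=config.nmd_nt)
        consequences.to_csv(outdir / "consequences.tsv", sep="\t", index=False)

    expressed = set(expr.index[expr.mean(axis=1) >= config.expressed_min])
    triplet_classes = pd.DataFrame()
    if config.triplets is not None:
        triplet_classes = classify_triplets(
            read_triplets(config.triplets), dsgs_by_cond, expressed
        )
        triplet_classes.to_csv(outdir / "triplet_classes.tsv", sep="\t", index=False)

    matrix = delta_iep_matrix(summary)
    memberships = pd.DataFrame()
    if len(matrix) >= config.clusters:
        memberships, _ = fuzzy_cmeans(
            matrix, c=config.clusters, m=config.fuzzifier, seed=config.seed
        )
        memberships.to_csv(outdir / "clusters.tsv", sep="\t")
    else:
        logger.info(
            "clustering skipped: %d profiles < %d clusters", len(matrix), config.clusters
        )

    enrichment = pd.DataFrame()
    if config.gene2go is not None:
        gene2go = read_gene2go(config.gene2go)
        background = set(expr.index.astype(str))
        enr_frames = []
        for cond in sorted(dsgs_by_cond):
            study = dsgs_by_cond[cond] & background
            if not study:
                continue
            enr = go_enrichment(study, background, gene2go)
            enr.insert(0, "condition", cond)
            enr_frames.append(enr)
        if enr_frames:
            enrichment = pd.concat(enr_frames, ignore_index=True)
            enrichment.to_csv(outdir / "go_enrichment.tsv", sep="\t", index=False)

    truth_report = None
    if config.truth_events is not None:
        truth_report = evaluate_against_truth(
            summary, degs, pd.read_csv(config.truth_events, sep="\t"),
            pd.read_csv(config.truth_genes, sep="\t") if config.truth_genes else None,
        )
        _write_json(truth_report, outdir / "truth_report.json")

    inputs = {
        k: {"path": str(getattr(config, k)), "md5": _md5(getattr(config, k))}
        for k in ("gtf", "design", "expression", "junction_counts", "alignments",
                  "fasta", "triplets", "gene2go")
        if getattr(config, k) is not None
    }
    manifest = {
        "package": "juncsplice",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: getattr(config, k) for k in _THRESHOLDS},
        "inputs": inputs,
    }
    _write_json(manifest, outdir / "manifest.json")

    return {
        "events": events,
        "catalog": events_to_frame(events),
        "quants": quants,
        "results": results,
        "summary": summary,
        "dsgs_by_condition": dsgs_by_cond,
        "dsgs_by_timepoint": dsgs_by_tp,
        "degs": degs,
        "overlap": overlap,
        "consequences": consequences,
        "triplet_classes": triplet_classes,
        "cluster_memberships": memberships,
        "enrichment": enrichment,
        "truth_report": truth_report,
    }


def evaluate_against_truth(
    summary: pd.DataFrame,
    degs: pd.DataFrame,
    truth_events: pd.DataFrame,
    truth_genes: pd.DataFrame | None,
) -> dict:
    """Sensitivity and observed FDR of responsive-event and DEG calls
    against the generator's planted truth, pooled over stress conditions."""
    conditions = sorted(
        c.split("_", 1)[1] for c in truth_events.columns if c.startswith("responsive_")
    )
    called: set[tuple[str, str]] = set()
    hits = summary[summary["responsive"]]
    for r in hits.itertuples():
        called.add((r.event_id, r.condition))
    tp = fp = fn = 0
    for r in truth_events.itertuples():
        for cond in conditions:
            truly = bool(getattr(r, f"responsive_{cond}"))
            was_called = (r.event_id, cond) in called
            tp += truly and was_called
            fp += was_called and not truly
            fn += truly and not was_called
    event_sens = tp / (tp + fn) if tp + fn else float("nan")
    event_fdr = fp / (tp + fp) if tp + fp else 0.0

    report = {
        "responsive_true_positives": tp,
        "responsive_false_positives": fp,
        "responsive_false_negatives": fn,
        "responsive_sensitivity": event_sens,
        "responsive_fdr": event_fdr,
    }
    if truth_genes is not None:
        deg_called: set[tuple[str, str]] = set()
        for r in degs[degs["status"] != "ns"].itertuples():
            deg_called.add((r.gene_id, r.condition))
        dtp = dfp = dfn = 0
        fc_cols = [c for c in truth_genes.columns if c.startswith("fc_")]
        for r in truth_genes.itertuples():
            for col in fc_cols:
                cond = col.split("_", 1)[1]
                truly = abs(getattr(r, col) - 1.0) > 1e-9
                was_called = (r.gene_id, cond) in deg_called
                dtp += truly and was_called
                dfp += was_called and not truly
                dfn += truly and not was_called
        report.update(
            {
                "deg_true_positives": dtp,
                "deg_false_positives": dfp,
                "deg_false_negatives": dfn,
                "deg_sensitivity": dtp / (dtp + dfn) if dtp + dfn else float("nan"),
                "deg_fdr": dfp / (dtp + dfp) if dtp + dfp else 0.0,
            }
        )
    return report
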