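"""Differential gene expression stand-in caller and DSG/DEG comparison.

The DEG caller is a deliberately simple exact-test caller: per gene and
comparison, log2 fold change is computed from replicate means (with a
pseudocount) and a two-sided Fisher's exact test compares the gene's pooled
counts against the remaining library between control and stress; BH
adjustment is applied within each comparison.  A gene is called up (down)
when the fold change exceeds the threshold and the adjusted p is below the
FDR cut.  An externally produced DEG table in the same format is accepted
interchangeably.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import ValidationError
from .diffsplice import CONTROL_CONDITION, bh_adjust, comparisons, fisher_exact_2x2


def call_degs(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr: float = 0.05,
    pseudocount: float = 1.0,
    control: str = CONTROL_CONDITION,
) -> pd.DataFrame:
    """Call DEGs per (condition, timepoint) from a gene x sample count table.

    Returns a table with gene_id, condition, timepoint, log2fc, p, q and
    status in {up, down, ns}.  ``up`` requires log2fc >= log2(fc_threshold)
    and q < fdr; ``down`` is symmetric.
    """
    if (expr < 0).any().any():
        raise ValidationError("expression values must be non-negative")
    log2_thr = math.log2(fc_threshold)
    out_rows = []
    for cond, tp in comparisons(design, control):
        ctrl_samples = design.loc[
            (design["condition"] == control) & (design["timepoint"] == tp), "sample_id"
        ].tolist()
        str_samples = design.loc[
            (design["condition"] == cond) & (design["timepoint"] == tp), "sample_id"
        ].tolist()
        if not ctrl_samples or not str_samples:
            raise ValidationError(f"comparison ({cond}, {tp}) lacks samples on one side")
        ctrl = expr[ctrl_samples]
        stress = expr[str_samples]
        mean_c = ctrl.mean(axis=1)
        mean_s = stress.mean(axis=1)
        log2fc = np.log2((mean_s + pseudocount) / (mean_c + pseudocount))
        lib_c = int(round(float(ctrl.to_numpy().sum())))
        lib_s = int(round(float(stress.to_numpy().sum())))
        pooled_c = ctrl.sum(axis=1).round().astype(int)
        pooled_s = stress.sum(axis=1).round().astype(int)
        pvals = [
            fisher_exact_2x2(gc, lib_c - gc, gs, lib_s - gs)
            for gc, gs in zip(pooled_c, pooled_s)
        ]
        qvals = bh_adjust(pvals)
        for gene, fc, p, q in zip(expr.index, log2fc, pvals, qvals):
            if q < fdr and fc >= log2_thr:
                status = "up"
            elif q < fdr and fc <= -log2_thr:
                status = "down"
            else:
                status = "ns"
            out_rows.append(
                {
                    "gene_id": gene,
                    "condition": cond,
                    "timepoint": tp,
                    "log2fc": float(fc),
                    "p": float(p),
                    "q": float(q),
                    "status": status,
                }
            )
    return pd.DataFrame(
        out_rows, columns=["gene_id", "condition", "timepoint", "log2fc", "p", "q", "status"]
    )


def deg_sets(degs: pd.DataFrame) -> dict[str, set[str]]:
    """DEG gene sets per condition (significant at either timepoint)."""
    sets: dict[str, set[str]] = {}
    hits = degs[degs["status"] != "ns"]
    for r in hits.itertuples():
        sets.setdefault(r.condition, set()).add(r.gene_id)
    return sets


def overlap_dsg_deg(dsgs: set[str], degs: set[str]) -> dict[str, float]:
    """Partition of DSG u DEG into DSG-specific / overlap / DEG-specific."""
    overlap = dsgs & degs
    summary = {
        "dsg_specific": len(dsgs - degs),
        "overlap": len(overlap),
        "deg_specific": len(degs - dsgs),
        "overlap_pct_of_dsgs": 100.0 * len(overlap) / len(dsgs) if dsgs else math.nan,
    }
    return summary


def dsg_enrichment_in_degs(
    dsgs: set[str],
    degs: set[str],
    gene_junction_totals: Mapping[str, int] | pd.Series,
    min_junction_reads: int = 10,
) -> dict[str, float]:
    """Compare the proportion of DSGs among DEGs vs non-DEGs.

    The universe is restricted to genes with pooled junction support above
    ``min_junction_reads`` (strictly greater).  Returns the two proportions
    and a two-sided Fisher p for the {DSG, non-DSG} x {DEG, non-DEG} table.
    """
    totals = pd.Series(gene_junction_totals)
    universe = set(totals.index[totals > min_junction_reads])
    if not universe:
        raise ValidationError("no genes pass the junction-read filter")
    dsg_u = dsgs & universe
    deg_u = degs & universe
    a = len(dsg_u & deg_u)
    b = len(deg_u - dsg_u)
    c = len(dsg_u - deg_u)
    d = len(universe - dsg_u - deg_u)
    p = fisher_exact_2x2(a, b, c, d)
    prop_deg = a / len(deg_u) if deg_u else math.nan
    non_deg = universe - deg_u
    prop_non = c / len(non_deg) if non_deg else math.nan
    return {
        "n_universe": len(universe),
        "dsg_in_deg": a,
        "dsg_in_non_deg": c,
        "prop_dsg_in_degs": prop_deg,
        "prop_dsg_in_non_degs": prop_non,
        "fisher_p": p,
    }


def read_deg_table(path: str | Path) -> pd.DataFrame:
    degs = pd.read_csv(path, sep="\t")
    required = {"gene_id", "condition", "timepoint", "log2fc", "p", "q", "status"}
    missing = required - set(degs.columns)
    if missing:
        raise ValidationError(f"{path}: DEG table missing columns {sorted(missing)}")
    return degs
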