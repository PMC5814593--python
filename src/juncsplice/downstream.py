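"""Homeolog-triplet partitioning, soft clustering of splicing-change
profiles, and GO term enrichment.

Triplets pair one homeologous gene from each of the A, B and D subgenomes of
an allohexaploid; a triplet with all three members expressed is classified
per condition as ``consistent`` (all three differentially spliced),
``partitioned`` (one or two) or ``none``.  Profiles of |dIEP| across the six
stress x timepoint comparisons are clustered with fuzzy c-means (soft
memberships, Mfuzz-style).  GO enrichment uses a one-sided hypergeometric
test against the whole-background gene set with a fold-enrichment cut.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ValidationError
from .diffsplice import bh_adjust

logger = logging.getLogger(__name__)

SUBGENOMES = ("A", "B", "D")


# ---------------------------------------------------------------------------
# Homeolog triplets

def read_triplets(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_A", "gene_B", "gene_D"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: triplet table missing columns {sorted(missing)}")
    return df


def classify_triplets(
    triplets: pd.DataFrame,
    dsg_sets: Mapping[str, set[str]],
    expressed_genes: set[str],
) -> pd.DataFrame:
    """Per-condition triplet classes over triplets with all members expressed.

    Returns one row per retained triplet and condition with the three dsg
    flags and the class in {none, partitioned, consistent}.
    """
    cols = [f"gene_{s}" for s in SUBGENOMES]
    genes = triplets[cols].to_numpy().ravel()
    dupes = pd.Series(genes).value_counts()
    dupes = dupes[dupes > 1]
    if len(dupes):
        raise ValidationError(f"genes appear in multiple triplets: {sorted(dupes.index)}")
    rows = []
    for r in triplets.itertuples(index=False):
        members = [getattr(r, c) for c in cols]
        if not all(g in expressed_genes for g in members):
            continue
        for cond in sorted(dsg_sets):
            flags = [g in dsg_sets[cond] for g in members]
            n = sum(flags)
            cls = "consistent" if n == 3 else ("partitioned" if n in (1, 2) else "none")
            rows.append(
                {
                    "gene_A": members[0],
                    "gene_B": members[1],
                    "gene_D": members[2],
                    "condition": cond,
                    "dsg_A": flags[0],
                    "dsg_B": flags[1],
                    "dsg_D": flags[2],
                    "class": cls,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_A", "gene_B", "gene_D", "condition", "dsg_A", "dsg_B", "dsg_D", "class"],
    )


# ---------------------------------------------------------------------------
# |dIEP| profile matrix and fuzzy c-means

def delta_iep_matrix(summary: pd.DataFrame) -> pd.DataFrame:
    """Event x comparison matrix of |dIEP| (mean over replicates),
    row-standardized to mean 0 / sd 1, for events responsive to >= 1
    comparison.  Zero-variance rows are dropped with a log message."""
    responsive_events = set(summary.loc[summary["responsive"], "event_id"])
    sub = summary[summary["event_id"].isin(responsive_events)].copy()
    sub["abs_delta"] = (sub["delta_rep1"].abs() + sub["delta_rep2"].abs()) / 2
    sub["comparison"] = sub["condition"].astype(str) + "_" + sub["timepoint"].astype(str)
    mat = sub.pivot_table(
        index="event_id", columns="comparison", values="abs_delta", aggfunc="mean"
    ).fillna(0.0)
    mat = mat.sort_index()
    sd = mat.std(axis=1, ddof=0)
    zero_var = sd[sd == 0].index
    if len(zero_var):
        logger.info("dropping %d zero-variance profiles", len(zero_var))
        mat = mat.drop(index=zero_var)
        sd = sd.drop(index=zero_var)
    return mat.sub(mat.mean(axis=1), axis=0).div(sd, axis=0)


def fuzzy_cmeans(
    matrix: pd.DataFrame | np.ndarray,
    c: int = 12,
    m: float = 1.25,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fuzzy c-means soft clustering (alternating membership/centroid
    updates until the maximum centroid shift is below ``tol``).

    Returns (memberships, centroids); memberships carry a ``cluster`` column
    with the argmax hard assignment (ties resolved to the lowest index).
    Deterministic for a fixed seed.
    """
    X = np.asarray(matrix, dtype=float)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(X))
    n = X.shape[0]
    if n < c:
        raise ValidationError(f"need at least c={c} rows, got {n}")
    if m <= 1:
        raise ValidationError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(c), size=n)  # n x c memberships
    centroids = np.zeros((c, X.shape[1]))
    for _ in range(max_iter):
        W = U**m
        new_centroids = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - new_centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        exponent = 1.0 / (m - 1.0)
        inv = d2 ** (-exponent)
        U = inv / inv.sum(axis=1, keepdims=True)
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            break
    memberships = pd.DataFrame(
        U, index=index, columns=[f"cluster_{k + 1}" for k in range(c)]
    )
    memberships["cluster"] = U.argmax(axis=1) + 1
    return memberships, centroids


# ---------------------------------------------------------------------------
# GO enrichment

def read_gene2go(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "term_id"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: gene2go table missing columns {sorted(missing)}")
    return df


def go_enrichment(
    study_genes: set[str],
    background_genes: set[str],
    gene2go: pd.DataFrame,
    p_threshold: float = 0.05,
    fold_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-term one-sided hypergeometric enrichment of the study set against
    the whole background, with fold = (k/n)/(K/N).  Significant terms need
    p < ``p_threshold`` and fold >= ``fold_threshold``; an unadjusted rule,
    with a BH column emitted alongside for transparency."""
    if not study_genes:
        raise ValidationError("study gene set is empty")
    if not study_genes <= background_genes:
        raise ValidationError("study genes must be a subset of the background")
    annot = gene2go[gene2go["gene_id"].isin(background_genes)]
    N = len(background_genes)
    n = len(study_genes)
    rows = []
    for term, genes in annot.groupby("term_id")["gene_id"]:
        term_genes = set(genes)
        K = len(term_genes)
        k = len(term_genes & study_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if K else 0.0
        rows.append(
            {"term_id": term, "k": k, "n": n, "K": K, "N": N, "fold": fold, "p": p}
        )
    out = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "fold", "p"])
    if len(out):
        out["q_bh"] = bh_adjust(out["p"])
        out["significant"] = (out["p"] < p_threshold) & (out["fold"] >= fold_threshold)
        out = out.sort_values(["p", "term_id"]).reset_index(drop=True)
    else:
        out["q_bh"] = []
        out["significant"] = []
    return out
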