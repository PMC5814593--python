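"""Stress-responsive AS event calling and DSG aggregation.

Per (stress condition, timepoint) comparison and per biological replicate, a
two-sided Fisher's exact test is run on the 2x2 table of inclusion /
exclusion junction reads in control vs stress.  P-values are
Benjamini-Hochberg adjusted across all eligible events within each
(comparison, replicate).  An event is called responsive when, in both
replicates, the adjusted p is below the FDR threshold, |dIEP| (stress minus
control) reaches the minimum change, and the sign of the change agrees.
Genes containing at least one responsive event are differentially spliced
genes (DSGs).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .annotation import ValidationError
from .quant import iep, testable_events

CONTROL_CONDITION = "CK"


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for [[a, b], [c, d]].

    Under the hypergeometric model with fixed margins, sums the
    probabilities of all tables no more probable than the observed one
    (tie comparison with a 1e-7 relative tolerance, as is conventional).
    A zero margin is uninformative and returns p = 1.  Computed directly
    from log-binomial coefficients so that calling it for every event in a
    catalogue stays cheap; agrees with scipy.stats.fisher_exact and with
    exact rational enumeration to well below 1e-10.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValidationError("Fisher table entries must be non-negative integers")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    x = np.arange(lo, hi + 1)
    logw = (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
    )
    log_denom = gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)
    obs = logw[a - lo]
    p = float(np.exp(logw[logw <= obs + 1e-7] - log_denom).sum())
    return min(1.0, p)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "timepoint", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValidationError(f"{path}: design table missing columns {sorted(missing)}")
    return design


def comparisons(design: pd.DataFrame, control: str = CONTROL_CONDITION) -> list[tuple[str, object]]:
    """(condition, timepoint) pairs compared against the timepoint-matched control."""
    out = []
    for cond in sorted(design["condition"].unique()):
        if cond == control:
            continue
        for tp in sorted(design.loc[design["condition"] == cond, "timepoint"].unique()):
            out.append((cond, tp))
    return out


def _sample_of(design: pd.DataFrame, condition: str, timepoint, replicate) -> str:
    rows = design[
        (design["condition"] == condition)
        & (design["timepoint"] == timepoint)
        & (design["replicate"] == replicate)
    ]
    if len(rows) != 1:
        raise ValidationError(
            f"design must contain exactly one sample for "
            f"({condition}, {timepoint}, rep {replicate}); found {len(rows)}"
        )
    return str(rows["sample_id"].iloc[0])


def call_responsive(
    quants: pd.DataFrame,
    design: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_delta: float = 0.30,
    min_total: int = 10,
    control: str = CONTROL_CONDITION,
    pool_replicates: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call stress-responsive events for every (condition, timepoint).

    Returns ``(results, summary)``: a long per-replicate table with counts,
    p, BH-adjusted q and dIEP, and a per-event summary with the responsive
    flag.  Each comparison requires exactly two replicates; the alternative
    ``pool_replicates`` mode sums replicate counts and tests once.
    """
    long_rows: list[dict] = []
    summary_rows: list[dict] = []
    qmat = quants.set_index(["event_id", "sample_id"])[["n1", "n2"]]

    for cond, tp in comparisons(design, control):
        reps = sorted(
            design.loc[
                (design["condition"] == cond) & (design["timepoint"] == tp), "replicate"
            ].unique()
        )
        if len(reps) != 2:
            raise ValidationError(
                f"comparison ({cond}, {tp}) requires exactly 2 replicates, found {len(reps)}"
            )
        pairs = [
            (_sample_of(design, control, tp, r), _sample_of(design, cond, tp, r)) for r in reps
        ]
        compared = [s for pair in pairs for s in pair]
        eligible = testable_events(quants, compared, min_total=min_total)
        event_ids = sorted(eligible.index[eligible])
        if not event_ids:
            continue

        per_rep: list[pd.DataFrame] = []
        for r, (ctrl_s, str_s) in zip(reps, pairs):
            rows = []
            for ev in event_ids:
                n1c, n2c = (int(v) for v in qmat.loc[(ev, ctrl_s)])
                n1s, n2s = (int(v) for v in qmat.loc[(ev, str_s)])
                rows.append(
                    {
                        "event_id": ev,
                        "condition": cond,
                        "timepoint": tp,
                        "replicate": r,
                        "n1_ctrl": n1c,
                        "n2_ctrl": n2c,
                        "n1_str": n1s,
                        "n2_str": n2s,
                        "p": fisher_exact_2x2(n1c, n2c, n1s, n2s),
                        "delta_iep": iep(n1s, n2s) - iep(n1c, n2c),
                    }
                )
            df = pd.DataFrame(rows)
            df["q"] = bh_adjust(df["p"])
            per_rep.append(df)

        if pool_replicates:
            pooled = per_rep[0][["event_id", "condition", "timepoint"]].copy()
            for col in ("n1_ctrl", "n2_ctrl", "n1_str", "n2_str"):
                pooled[col] = per_rep[0][col].to_numpy() + per_rep[1][col].to_numpy()
            pooled["replicate"] = 0
            pooled["p"] = [
                fisher_exact_2x2(r.n1_ctrl, r.n2_ctrl, r.n1_str, r.n2_str)
                for r in pooled.itertuples()
            ]
            pooled["delta_iep"] = [
                iep(r.n1_str, r.n2_str) - iep(r.n1_ctrl, r.n2_ctrl)
                for r in pooled.itertuples()
            ]
            pooled["q"] = bh_adjust(pooled["p"])
            long_rows.extend(pooled.to_dict("records"))
            for r in pooled.itertuples():
                summary_rows.append(
                    {
                        "event_id": r.event_id,
                        "condition": cond,
                        "timepoint": tp,
                        "p_rep1": r.p,
                        "p_rep2": r.p,
                        "q_rep1": r.q,
                        "q_rep2": r.q,
                        "delta_rep1": r.delta_iep,
                        "delta_rep2": r.delta_iep,
                        "responsive": bool(r.q < fdr_threshold and abs(r.delta_iep) >= min_delta),
                    }
                )
            continue

        long_rows.extend(per_rep[0].to_dict("records"))
        long_rows.extend(per_rep[1].to_dict("records"))
        r1 = per_rep[0].set_index("event_id")
        r2 = per_rep[1].set_index("event_id")
        for ev in event_ids:
            d1, d2 = float(r1.at[ev, "delta_iep"]), float(r2.at[ev, "delta_iep"])
            q1, q2 = float(r1.at[ev, "q"]), float(r2.at[ev, "q"])
            responsive = (
                q1 < fdr_threshold
                and q2 < fdr_threshold
                and abs(d1) >= min_delta
                and abs(d2) >= min_delta
                and math.copysign(1, d1) == math.copysign(1, d2)
                and d1 != 0
                and d2 != 0
            )
            summary_rows.append(
                {
                    "event_id": ev,
                    "condition": cond,
                    "timepoint": tp,
                    "p_rep1": float(r1.at[ev, "p"]),
                    "p_rep2": float(r2.at[ev, "p"]),
                    "q_rep1": q1,
                    "q_rep2": q2,
                    "delta_rep1": d1,
                    "delta_rep2": d2,
                    "responsive": bool(responsive),
                }
            )

    long_cols = [
        "event_id", "condition", "timepoint", "replicate",
        "n1_ctrl", "n2_ctrl", "n1_str", "n2_str", "p", "q", "delta_iep",
    ]
    summary_cols = [
        "event_id", "condition", "timepoint",
        "p_rep1", "p_rep2", "q_rep1", "q_rep2",
        "delta_rep1", "delta_rep2", "responsive",
    ]
    results = pd.DataFrame(long_rows, columns=long_cols)
    summary = pd.DataFrame(summary_rows, columns=summary_cols)
    return results, summary


def collect_dsgs(
    summary: pd.DataFrame, event_to_gene: Mapping[str, str]
) -> tuple[dict[str, set[str]], dict[tuple[str, object], set[str]]]:
    """DSG gene sets per condition (responsive at either timepoint) and per
    (condition, timepoint)."""
    by_condition: dict[str, set[str]] = {}
    by_timepoint: dict[tuple[str, object], set[str]] = {}
    hits = summary[summary["responsive"]]
    for r in hits.itertuples():
        gene = event_to_gene[r.event_id]
        by_condition.setdefault(r.condition, set()).add(gene)
        by_timepoint.setdefault((r.condition, r.timepoint), set()).add(gene)
    return by_condition, by_timepoint
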