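"""Nine-quadrant editing x expression integration and enzyme-expression vs
editing-level correlation.

Quadrant numbering: rows = editing state (down, ns, up from bottom), columns
= expression state (down, ns, up from left), index 1-9 row-major from the
bottom-left.  The up/up cell (quadrant 9) holds the candidate genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotatedSite

_STATE = {"down": 0, "ns": 1, "up": 2}


def _axis_state(
    lfc: float, significant: bool, lfc_threshold: float, require_significance: bool
) -> str:
    if not np.isfinite(lfc):
        return "ns"
    if lfc > lfc_threshold and (significant or not require_significance):
        return "up"
    if lfc < -lfc_threshold and (significant or not require_significance):
        return "down"
    return "ns"


def quadrant_index(edit_state: str, expr_state: str) -> int:
    """1-9, row-major from bottom-left of the 3x3 grid."""
    return 3 * _STATE[edit_state] + _STATE[expr_state] + 1


def nine_quadrant(
    editing_results: pd.DataFrame,
    expression_results: pd.DataFrame,
    lfc_threshold_expr: float = 1.0,
    lfc_threshold_edit: float = 0.0,
    require_significance: bool = True,
) -> pd.DataFrame:
    """Joint 3x3 classification of genes present in both result tables.

    Result tables carry columns log2FC and significant (as produced by the
    differential engine).  Genes in only one table are excluded.  Returns
    one row per shared gene with both axis states, the quadrant index and
    the candidate flag (up/up).
    """
    if lfc_threshold_expr < 0 or lfc_threshold_edit < 0:
        raise ValueError("thresholds must be >= 0")
    shared = editing_results.index.intersection(expression_results.index)
    rows = []
    for gid in shared:
        e = editing_results.loc[gid]
        x = expression_results.loc[gid]
        es = _axis_state(
            float(e["log2FC"]), bool(e["significant"]), lfc_threshold_edit, require_significance
        )
        xs = _axis_state(
            float(x["log2FC"]), bool(x["significant"]), lfc_threshold_expr, require_significance
        )
        q = quadrant_index(es, xs)
        rows.append(
            {
                "gene_id": gid,
                "editing_log2fc": float(e["log2FC"]),
                "expression_log2fc": float(x["log2FC"]),
                "editing_significant": bool(e["significant"]),
                "expression_significant": bool(x["significant"]),
                "editing_state": es,
                "expression_state": xs,
                "quadrant": q,
                "candidate": q == 9,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "editing_log2fc",
            "expression_log2fc",
            "editing_significant",
            "expression_significant",
            "editing_state",
            "expression_state",
            "quadrant",
            "candidate",
        ],
    ).set_index("gene_id") if rows else pd.DataFrame(
        columns=[
            "editing_log2fc",
            "expression_log2fc",
            "editing_significant",
            "expression_significant",
            "editing_state",
            "expression_state",
            "quadrant",
            "candidate",
        ]
    ).rename_axis("gene_id")


def gene_maf(annotated: List[AnnotatedSite], gene_id: str, samples: List[str]) -> pd.Series:
    """Per-sample mean editing frequency over a gene's sites ("MAF" in the
    source terminology — mean allele frequency of editing sites, not
    population minor-allele frequency).  NaN when a sample has no valid
    measurement at any site."""
    sites = [a for a in annotated if a.gene_id == gene_id]
    if not sites:
        raise ValueError(f"gene {gene_id} has no annotated sites")
    out = {}
    for s in samples:
        vals = [a.site.frequency[s] for a in sites if a.site.frequency.get(s) is not None]
        out[s] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name=f"maf_{gene_id}")


@dataclass
class CorrelationResult:
    enzyme_gene: str
    target_gene: str
    r: float
    p_value: float
    n: int
    enzyme_expression: pd.Series
    target_maf: pd.Series


def enzyme_correlation(
    enzyme_tpm: pd.Series,
    target_maf: pd.Series,
    enzyme_gene: str = "",
    target_gene: str = "",
) -> CorrelationResult:
    """Pearson correlation between per-sample enzyme expression and target
    mean editing frequency; p from the two-sided t-test on r with n-2 df.
    Pairs with a missing value on either side are dropped; zero variance
    gives r = NaN."""
    df = pd.concat([enzyme_tpm.rename("e"), target_maf.rename("m")], axis=1).dropna()
    n = len(df)
    if n < 3:
        raise ValueError("enzyme correlation needs >= 3 paired samples")
    e, m = df["e"].to_numpy(), df["m"].to_numpy()
    if np.std(e) == 0 or np.std(m) == 0:
        r, p = float("nan"), float("nan")
    else:
        res = stats.pearsonr(e, m)
        r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(
        enzyme_gene=enzyme_gene,
        target_gene=target_gene,
        r=r,
        p_value=p,
        n=n,
        enzyme_expression=df["e"],
        target_maf=df["m"],
    )


def quadrant_counts(assignments: pd.DataFrame) -> pd.Series:
    """Gene counts per quadrant 1-9 (all nine reported, zeros included)."""
    counts = assignments["quadrant"].value_counts()
    return pd.Series(
        {q: int(counts.get(q, 0)) for q in range(1, 10)}, name="n_genes"
    ).rename_axis("quadrant")
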