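"""Hypergeometric over-representation analysis with FDR control.

The enrichment p-value for a pathway is the upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)

with N = universe size, n = candidates in the universe, M = genes
annotated to the pathway, m = candidates in the pathway.  The sum is
evaluated in log space (gammaln) with a log-sum-exp reduction for
numerical stability at large N.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Set

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .differential import bh_adjust

logger = logging.getLogger(__name__)


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """Pr(X >= m) for X ~ Hypergeometric(N, M, n), in log space.

    m = 0 returns exactly 1 (empty subtracted sum).
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError("need 0 <= M <= N and 0 <= n <= N")
    if not 0 <= m <= min(n, M):
        raise ValueError("need 0 <= m <= min(n, M)")
    if m == 0:
        return 1.0
    i = np.arange(m, min(n, M) + 1)
    # drop terms with infeasible n - i > N - M
    i = i[(n - i) <= (N - M)]
    if i.size == 0:
        return 0.0
    log_terms = _log_binom(M, i) + _log_binom(N - M, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def build_universe(
    pathways: pd.DataFrame,
    mode: str = "annotated_only",
    all_genes: Optional[Iterable[str]] = None,
) -> Set[str]:
    """Gene universe for enrichment.

    annotated_only: union of all pathway gene sets (the default);
    all_genes: caller-supplied gene list.
    """
    if pathways.empty:
        raise ValueError("pathway table is empty")
    if mode == "annotated_only":
        return set(pathways["gene_id"])
    if mode == "all_genes":
        if all_genes is None:
            raise ValueError("mode=all_genes requires a gene list")
        return set(all_genes)
    raise ValueError(f"unknown universe mode {mode!r}")


def hypergeometric_enrichment(
    candidates: Set[str],
    pathways: pd.DataFrame,
    universe: Optional[Set[str]] = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``candidates`` in each pathway.

    ``pathways`` has columns pathway_id, gene_id (pathway_name optional).
    Candidates outside the universe are dropped (and counted in the log).
    Returns one row per pathway with N, n, M, m, p_value, fdr, enriched,
    sorted by fdr then p.
    """
    if universe is None:
        universe = build_universe(pathways)
    dropped = len(set(candidates) - universe)
    if dropped:
        logger.info("%d candidate genes outside the universe dropped", dropped)
    cand = set(candidates) & universe
    N, n = len(universe), len(cand)

    names = (
        pathways.drop_duplicates("pathway_id").set_index("pathway_id").get("pathway_name")
        if "pathway_name" in pathways.columns
        else None
    )
    rows = []
    for pid, sub in pathways.groupby("pathway_id", sort=True):
        members = set(sub["gene_id"]) & universe
        M = len(members)
        if M == 0:
            logger.info("pathway %s has no genes in the universe; skipped", pid)
            continue
        m = len(cand & members)
        p = hypergeom_upper_tail(N, M, n, m) if n > 0 else 1.0
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": names.get(pid, "") if names is not None else "",
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["fdr"] = []
        df["enriched"] = []
        return df
    df["fdr"] = bh_adjust(df["p_value"])
    df["enriched"] = df["fdr"] <= fdr_threshold
    return df.sort_values(["fdr", "p_value", "pathway_id"]).reset_index(drop=True)
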