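"""Negative-binomial count differential machinery.

Used for both gene-level differential editing (aggregated alt-read counts)
and differential expression.  The pipeline is median-of-ratios size
factors, moderated method-of-moments dispersion, and a per-feature NB GLM
with a two-group design fit by IRLS, tested with a two-sided Wald test and
Benjamini-Hochberg adjustment.  No fold-change shrinkage, independent
filtering, or outlier replacement is attempted.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotatedSite
from .models import Gene

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors, rescaled to geometric
    mean 1.  Falls back to library-size ratios (with a warning) when no
    feature has all-positive counts."""
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        logx = np.log(x[all_pos])
        log_geo = logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx - log_geo, axis=0))
    else:
        warnings.warn(
            "no feature with all-positive counts; using library-size factors",
            RuntimeWarning,
        )
        lib = x.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("sample with zero total counts")
        sf = lib
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: Optional[pd.Series] = None,
    moderation_weight: float = 0.8,
) -> pd.Series:
    """Per-feature NB dispersion alpha >= 0.

    Method-of-moments on normalized counts, pooling variance within groups
    (so a real group effect does not inflate alpha), then moderated toward
    the across-feature trend mean with ``moderation_weight``.  Features
    with zero mean get NaN (untestable).
    """
    norm = counts.to_numpy(dtype=float) / sf.reindex(counts.columns).to_numpy()
    n_feat, n_samp = norm.shape
    if groups is None:
        groups = pd.Series(["all"] * n_samp, index=counts.columns)
    groups = groups.reindex(counts.columns)

    ss = np.zeros(n_feat)
    df = 0
    for g in groups.unique():
        sub = norm[:, (groups == g).to_numpy()]
        if sub.shape[1] < 2:
            continue
        ss += sub.shape[1] * np.var(sub, axis=1)  # n * biased var = sum sq dev
        df += sub.shape[1] - 1
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = ss / max(df, 1)
        alpha_mom = np.where(mean > 0, np.maximum(0.0, (var - mean) / mean**2), np.nan)
    finite = np.isfinite(alpha_mom)
    trend = float(np.nanmean(alpha_mom[finite])) if finite.any() else 0.0
    alpha = (1.0 - moderation_weight) * alpha_mom + moderation_weight * trend
    alpha = np.where(np.isfinite(alpha), np.maximum(alpha, DISPERSION_FLOOR), np.nan)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity enforcement; NaN
    entries are excluded from m and returned as NaN."""
    p = np.asarray(list(p_values), dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    ps = p[mask]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


RIDGE_SIGMA = 4.0  # natural-log units; wide stabilizer, not a shrinkage prior


def _fit_nb_glm(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: float,
    max_iter: int = 200, tol: float = 1e-8, ridge_sigma: float = RIDGE_SIGMA,
) -> Optional[Tuple[np.ndarray, np.ndarray]]:
    """IRLS fit of an NB GLM with log link, fixed dispersion alpha and
    design [1, x].  A very wide zero-centered ridge (sd ``ridge_sigma`` in
    ln units) on the group coefficient keeps the fit finite when one group
    is all zeros; for ordinary features its effect is negligible.
    Returns (beta, covariance) or None on non-convergence.
    """
    X = np.column_stack([np.ones_like(x), x])
    lam = np.diag([0.0, 1.0 / ridge_sigma**2])
    mu = np.maximum(y / np.exp(offset), 1e-4)
    beta = np.array([np.log(np.mean(mu)), 0.0])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)  # (dmu/deta)^2 / Var
        z = (X @ beta) + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X + lam
        try:
            beta_new = np.linalg.solve(A, XtW @ z)
        except np.linalg.LinAlgError:
            return None
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if not converged:
        return None
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    A = (X.T * w) @ X + lam
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return None
    return beta, cov


def nb_wald_test(
    counts: pd.DataFrame,
    design: pd.Series,
    sf: Optional[pd.Series] = None,
    dispersion: Optional[pd.Series] = None,
    control: Optional[str] = None,
    treatment: Optional[str] = None,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """Two-group NB Wald test per feature.

    ``design`` maps sample -> group; log2fc is treatment over control.
    Features with all-zero counts are excluded from testing (NaN p); BH
    adjustment runs over tested features only.  ``significant`` applies
    padj < ``padj_threshold`` and |log2fc| >= ``lfc_threshold``.
    """
    design = design.reindex(counts.columns)
    if design.isna().any():
        raise ValueError("design does not cover all samples")
    levels = list(dict.fromkeys(design))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    if control is None or treatment is None:
        control, treatment = levels[0], levels[1]
    for g in (control, treatment):
        if (design == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")

    if sf is None:
        sf = size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, sf, groups=design)

    x = (design == treatment).to_numpy(dtype=float)
    offset = np.log(sf.reindex(counts.columns).to_numpy())
    mat = counts.to_numpy(dtype=float)
    norm = mat / np.exp(offset)

    n_feat = mat.shape[0]
    log2fc = np.full(n_feat, np.nan)
    se = np.full(n_feat, np.nan)
    wald = np.full(n_feat, np.nan)
    pval = np.full(n_feat, np.nan)
    base_mean = norm.mean(axis=1)

    for i in range(n_feat):
        y = mat[i]
        if y.sum() == 0:
            continue
        alpha = dispersion.iloc[i]
        if not np.isfinite(alpha):
            continue
        fit = _fit_nb_glm(y, x, offset, float(alpha))
        if fit is None:
            logger.warning("IRLS did not converge for feature %s", counts.index[i])
            continue
        beta, cov = fit
        if (y[x == 1].sum() == 0) or (y[x == 0].sum() == 0):
            # one group all zero: report-only log2fc with +0.5 pseudocount
            m1 = norm[i][x == 1].mean() + 0.5
            m0 = norm[i][x == 0].mean() + 0.5
            log2fc[i] = np.log2(m1 / m0)
        else:
            log2fc[i] = beta[1] / LN2
        s = np.sqrt(max(cov[1, 1], 0.0))
        se[i] = s / LN2
        if s > 0:
            wald[i] = beta[1] / s
            pval[i] = 2.0 * stats.norm.sf(abs(wald[i]))

    padj = bh_adjust(pval)
    significant = (
        np.isfinite(padj)
        & (padj < padj_threshold)
        & (np.abs(np.nan_to_num(log2fc)) >= lfc_threshold)
    )
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "SE": se,
            "stat": wald,
            "pvalue": pval,
            "padj": padj,
            "significant": significant,
        },
        index=counts.index,
    )


def assign_site_gene(
    annotated: List[AnnotatedSite], genes: List[Gene]
) -> Dict[Tuple, str]:
    """Map each site key to at most one gene: the annotating gene when the
    site lies inside a gene body; overlaps resolve to the longest CDS with
    a deterministic gene-id tie-break (already applied upstream)."""
    by_id = {g.gene_id: g for g in genes}
    mapping = {}
    for a in annotated:
        if a.gene_id is None:
            continue
        g = by_id[a.gene_id]
        if g.contains(a.site.pos):
            mapping[a.site.key] = a.gene_id
    return mapping


def aggregate_gene_editing(
    annotated: List[AnnotatedSite], genes: List[Gene], samples: List[str]
) -> pd.DataFrame:
    """Gene x sample matrix of editing-supporting (alt) read counts.

    entry(g, s) = sum over g's sites of alt_depth; samples whose
    measurement is invalid contribute 0.  Genes with no surviving sites
    are absent.
    """
    mapping = assign_site_gene(annotated, genes)
    totals: Dict[str, Dict[str, int]] = {}
    for a in annotated:
        gid = mapping.get(a.site.key)
        if gid is None:
            continue
        row = totals.setdefault(gid, {s: 0 for s in samples})
        for s in samples:
            if a.site.frequency.get(s) is not None:
                row[s] += int(a.site.alt_depth.get(s, 0))
    if not totals:
        return pd.DataFrame(columns=samples, dtype=np.int64).rename_axis("gene_id")
    df = pd.DataFrame.from_dict(totals, orient="index").reindex(columns=samples)
    df.index.name = "gene_id"
    return df.sort_index().astype(np.int64)
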