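"""Expression-side metrics and unsupervised summaries: TPM, sample-sample
correlation, PCA of editing frequencies, frequency histograms and shared
editing-event (Venn) counts."""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and gene lengths (bp).

    rate = count / length; each column is scaled to sum to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ValueError(f"genes without length: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("sample with zero total rate")
    return rate.div(denom, axis=1) * 1e6


def sample_correlation(
    expression: pd.DataFrame, log_transform: bool = True
) -> pd.DataFrame:
    """Sample x sample Pearson correlation, on log2(x+1) by default.
    Zero-variance samples yield NaN for their pairs."""
    x = np.log2(expression + 1.0) if log_transform else expression.astype(float)
    return x.corr(method="pearson")


def editing_pca(
    freq: pd.DataFrame, min_samples_observed: int = 2, n_components: Optional[int] = None
) -> Tuple[pd.DataFrame, pd.Series]:
    """PCA of a site x sample editing-frequency matrix (NaN = unobserved).

    Sites observed in fewer than ``min_samples_observed`` samples are
    dropped; the rest are mean-imputed per site, columns centered, and
    decomposed by SVD.  Sign convention: the largest-magnitude loading of
    each component is positive.  Returns (sample coordinates, % variance).
    """
    observed = freq.notna().sum(axis=1)
    x = freq.loc[observed >= min_samples_observed]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 sites retained for PCA")
    if x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    arr = x.to_numpy(dtype=float)
    site_mean = np.nanmean(arr, axis=1, keepdims=True)
    arr = np.where(np.isnan(arr), site_mean, arr)
    arr = arr - arr.mean(axis=1, keepdims=True)  # center each site
    # samples as observations: rows of arr.T
    u, s, vt = np.linalg.svd(arr.T, full_matrices=False)
    # sign convention on the loading vectors (rows of vt)
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u * s
    var = s**2 / max(arr.shape[1] - 1, 1)
    total_var = var.sum()
    pct = 100.0 * var / total_var if total_var > 0 else np.zeros_like(var)
    k = n_components or min(len(s), arr.shape[1])
    cols = [f"PC{i + 1}" for i in range(k)]
    coords_df = pd.DataFrame(coords[:, :k], index=x.columns, columns=cols)
    pct_s = pd.Series(pct[:k], index=cols, name="pct_variance")
    return coords_df, pct_s


def shared_events(sets_by_group: Dict[str, Set]) -> pd.DataFrame:
    """Two-set Venn counts over site keys.

    Returns rows: common, unique_<group1>, unique_<group2>.
    """
    if len(sets_by_group) != 2:
        raise ValueError("shared_events expects exactly 2 groups")
    (g1, s1), (g2, s2) = sets_by_group.items()
    rows = [
        {"region": "common", "count": len(s1 & s2)},
        {"region": f"unique_{g1}", "count": len(s1 - s2)},
        {"region": f"unique_{g2}", "count": len(s2 - s1)},
    ]
    return pd.DataFrame(rows)


def group_site_sets(
    freq: pd.DataFrame, design: pd.Series
) -> Dict[str, Set]:
    """Site membership per group: a site belongs to a group when >= 1
    sample of that group has a valid (non-NaN) measurement."""
    out: Dict[str, Set] = {}
    for g in dict.fromkeys(design):
        samples = design.index[design == g]
        cols = [s for s in samples if s in freq.columns]
        mask = freq[cols].notna().any(axis=1)
        out[g] = set(freq.index[mask])
    return out


def frequency_histogram(
    freq: pd.DataFrame, design: pd.Series, bins: Iterable[float] = None
) -> pd.DataFrame:
    """Per-group histogram of all defined frequency measurements.

    ``bins`` are increasing edges partitioning [0, 1]; last bin inclusive
    on the right (numpy convention).
    """
    if bins is None:
        bins = np.linspace(0.0, 1.0, 11)
    edges = np.asarray(list(bins), dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bins must be strictly increasing edges")
    rows = {}
    for g in dict.fromkeys(design):
        samples = [s for s in design.index[design == g] if s in freq.columns]
        vals = freq[samples].to_numpy(dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        counts, _ = np.histogram(vals, bins=edges)
        rows[g] = counts
    idx = [f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in range(len(edges) - 1)]
    return pd.DataFrame(rows, index=pd.Index(idx, name="bin"))
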