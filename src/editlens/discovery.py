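"""Two-stage editing-site discovery filter cascade.

Stage 1 (hard filters) removes candidates failing any of the QC
inequalities (QD, FS, MQRankSum, ReadPosRankSum, MQ, SOR) or the
cohort-relative mean-depth window.  Stage 2 (editing filters) keeps
biallelic, high-base-quality sites and computes per-sample editing
frequencies, keeping the site when at least one sample has a valid
measurement (depth >= 5, alt depth >= 3, frequency inside [0.10, 1.00]).

Rule evaluation order is fixed (QD, FS, MQRankSum, ReadPosRankSum, MQ,
SOR, depth window) so removal-attribution counts are reproducible; the
survivor set itself is order-independent.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, List, Optional, Set, Tuple

import pandas as pd

from .models import EditingSite, VariantCandidate

logger = logging.getLogger(__name__)

HARD_RULES = ("QD", "FS", "MQRankSum", "ReadPosRankSum", "MQ", "SOR", "depth_window")
EDIT_RULES = ("base_quality", "allele_count", "known_snp", "no_valid_sample")


@dataclass(frozen=True)
class FilterThresholds:
    """All cutoffs of the two filter stages; boundary values pass."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    mq_min: float = 40.0
    sor_max: float = 3.0
    depth_ratio_low: float = 1.0 / 3.0
    depth_ratio_high: float = 3.0
    base_quality_min: float = 25.0
    depth_min: int = 5
    alt_depth_min: int = 3
    freq_min: float = 0.10
    freq_max: float = 1.00
    max_alleles: int = 2

    def __post_init__(self):
        if not self.freq_min < self.freq_max:
            raise ValueError("freq_min must be < freq_max")
        for name in ("qd_min", "fs_max", "mq_rank_sum_min", "read_pos_rank_sum_min",
                     "mq_min", "sor_max", "base_quality_min"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")


def editing_frequency(alt_depth: int, total_depth: int) -> float:
    """Fraction of reads supporting the edited base.

    Raises on zero total depth: an unmeasured site is undefined, not 0.
    """
    if total_depth <= 0:
        raise ValueError("editing frequency undefined at zero total depth")
    if not 0 <= alt_depth <= total_depth:
        raise ValueError("alt depth must lie in [0, total depth]")
    return alt_depth / total_depth


def _hard_failure(
    c: VariantCandidate, thr: FilterThresholds, cohort_mean: float
) -> Optional[str]:
    """First failing hard rule (fixed order), or None when all pass.
    A non-finite QC metric fails its own rule."""
    checks = [
        ("QD", c.qd >= thr.qd_min),
        ("FS", c.fs <= thr.fs_max),
        ("MQRankSum", c.mq_rank_sum >= thr.mq_rank_sum_min),
        ("ReadPosRankSum", c.read_pos_rank_sum >= thr.read_pos_rank_sum_min),
        ("MQ", c.mq >= thr.mq_min),
        ("SOR", c.sor <= thr.sor_max),
    ]
    for rule, ok in checks:
        # NaN comparisons are False, so missing metrics fail here too
        if not ok:
            return rule
    if cohort_mean > 0:
        md = c.mean_depth()
        if not (cohort_mean * thr.depth_ratio_low <= md <= cohort_mean * thr.depth_ratio_high):
            return "depth_window"
    return None


def apply_hard_filters(
    candidates: Iterable[VariantCandidate],
    thr: FilterThresholds = FilterThresholds(),
) -> Tuple[List[VariantCandidate], "OrderedDict[str, int]"]:
    """Apply the QC hard filters; returns survivors and removal counts
    partitioned by the first failing rule."""
    candidates = list(candidates)
    counts: "OrderedDict[str, int]" = OrderedDict((r, 0) for r in HARD_RULES)
    if not candidates:
        return [], counts
    cohort_mean = sum(c.mean_depth() for c in candidates) / len(candidates)
    survivors = []
    for c in candidates:
        rule = _hard_failure(c, thr, cohort_mean)
        if rule is None:
            survivors.append(c)
        else:
            counts[rule] += 1
            if not all(
                math.isfinite(x)
                for x in (c.qd, c.fs, c.mq_rank_sum, c.read_pos_rank_sum, c.mq, c.sor)
            ):
                logger.warning(
                    "candidate %s:%d removed with non-finite QC metric", c.contig, c.pos
                )
    return survivors, counts


def sample_measurement(
    total_depth: int, alt_depth: int, thr: FilterThresholds
) -> Optional[float]:
    """Valid per-sample editing frequency, or None when the measurement
    fails the depth / alt-depth / frequency-window rules."""
    if total_depth < thr.depth_min or alt_depth < thr.alt_depth_min:
        return None
    f = editing_frequency(alt_depth, total_depth)
    if not thr.freq_min <= f <= thr.freq_max:
        return None
    return f


def apply_editing_filters(
    candidates: Iterable[VariantCandidate],
    thr: FilterThresholds = FilterThresholds(),
    known_snps: Optional[Set[Tuple[str, int]]] = None,
) -> Tuple[List[EditingSite], "OrderedDict[str, int]"]:
    """Editing-specific filters on hard-filtered candidates.

    Returns surviving :class:`EditingSite` objects and per-rule removal
    counts.  Rules, in order: site mean base quality >= threshold; exactly
    one alt allele; not a known SNP; at least one valid sample measurement.
    """
    counts: "OrderedDict[str, int]" = OrderedDict((r, 0) for r in EDIT_RULES)
    sites: List[EditingSite] = []
    for c in candidates:
        if len(c.alt_bases) == 0:
            counts["allele_count"] += 1
            continue
        if not c.site_base_quality >= thr.base_quality_min:  # NaN fails
            counts["base_quality"] += 1
            continue
        if len(c.alt_bases) + 1 > thr.max_alleles:
            counts["allele_count"] += 1
            continue
        if known_snps is not None and (c.contig, c.pos) in known_snps:
            counts["known_snp"] += 1
            continue
        freq = {
            s: sample_measurement(c.total_depth.get(s, 0), c.alt_depth.get(s, 0), thr)
            for s in c.total_depth
        }
        if not any(f is not None for f in freq.values()):
            counts["no_valid_sample"] += 1
            continue
        sites.append(
            EditingSite(
                contig=c.contig,
                pos=c.pos,
                ref_base=c.ref_base,
                alt_base=c.alt_bases[0],
                total_depth=dict(c.total_depth),
                alt_depth=dict(c.alt_depth),
                frequency=freq,
            )
        )
    return sites, counts


def discover_sites(
    candidates: Iterable[VariantCandidate],
    thr: FilterThresholds = FilterThresholds(),
    known_snps: Optional[Set[Tuple[str, int]]] = None,
):
    """Full cascade: hard filters then editing filters.

    Returns ``(sites, report)`` where report is a DataFrame of removal
    counts per rule (stage, rule, removed).
    """
    survivors, hard_counts = apply_hard_filters(candidates, thr)
    sites, edit_counts = apply_editing_filters(survivors, thr, known_snps)
    rows = [{"stage": "hard", "rule": r, "removed": n} for r, n in hard_counts.items()]
    rows += [{"stage": "editing", "rule": r, "removed": n} for r, n in edit_counts.items()]
    rows.append({"stage": "result", "rule": "retained", "removed": len(sites)})
    return sites, pd.DataFrame(rows)


def sites_to_frame(sites: List[EditingSite], samples: List[str]) -> pd.DataFrame:
    """Flatten editing sites to the TSV layout (one row per site)."""
    rows = []
    for s in sites:
        row = {
            "contig": s.contig,
            "pos": s.pos,
            "ref": s.ref_base,
            "alt": s.alt_base,
        }
        for smp in samples:
            row[f"depth_{smp}"] = s.total_depth.get(smp, 0)
            row[f"alt_{smp}"] = s.alt_depth.get(smp, 0)
            f = s.frequency.get(smp)
            row[f"freq_{smp}"] = float("nan") if f is None else f
        rows.append(row)
    cols = ["contig", "pos", "ref", "alt"] + [
        f"{k}_{smp}" for smp in samples for k in ("depth", "alt", "freq")
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_sites(df: pd.DataFrame) -> List[EditingSite]:
    """Inverse of :func:`sites_to_frame`."""
    samples = [c[len("depth_"):] for c in df.columns if c.startswith("depth_")]
    out = []
    for _, row in df.iterrows():
        freq = {}
        for s in samples:
            f = row[f"freq_{s}"]
            freq[s] = None if pd.isna(f) else float(f)
        out.append(
            EditingSite(
                contig=str(row["contig"]),
                pos=int(row["pos"]),
                ref_base=str(row["ref"]),
                alt_base=str(row["alt"]),
                total_depth={s: int(row[f"depth_{s}"]) for s in samples},
                alt_depth={s: int(row[f"alt_{s}"]) for s in samples},
                frequency=freq,
            )
        )
    return out
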