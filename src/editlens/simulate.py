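"""Synthetic study generator.

Produces a fully specified toy dataset — reference, gene models, variant
candidates with QC annotations, expression counts, pathway table and truth
tables — with the statistical structure the downstream analysis assumes:

* per-site editing frequencies spanning roughly 10–90%,
* negative-binomially distributed coverage and expression counts,
* a configurable subset of genes with group-dependent editing and/or
  expression shifts,
* germline-SNP confounders at ~0.5 / ~1.0 frequency in all samples,
* one "editing enzyme" gene whose per-sample expression linearly drives
  the editing frequency of its target genes.

Everything is driven by a single integer seed; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as elio
from .models import COMPLEMENT, Gene, VariantCandidate, revcomp

BASES = ("A", "C", "G", "T")

# QC metric draw ranges: (passing range, violating range). Violations are
# injected independently per rule so each removal is attributable to
# exactly one rule.
_QC_RANGES = {
    "QD": ((5.0, 30.0), (0.0, 1.99)),
    "FS": ((0.0, 30.0), (60.01, 200.0)),
    "MQRankSum": ((-5.0, 5.0), (-30.0, -12.51)),
    "ReadPosRankSum": ((-4.0, 4.0), (-20.0, -8.01)),
    "MQ": ((50.0, 60.0), (10.0, 39.99)),
    "SOR": ((0.2, 2.5), (3.01, 9.0)),
    "BQ": ((28.0, 40.0), (10.0, 24.99)),
}


def _default_qc_rates() -> Dict[str, float]:
    return {k: 0.02 for k in _QC_RANGES}


def _default_type_probs() -> Dict[str, float]:
    return {"A-to-I": 0.6, "C-to-U": 0.2, "other": 0.2}


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study.  All randomness derives from ``seed``."""

    n_genes: int = 200
    n_samples_per_group: int = 3
    groups: Tuple[str, str] = ("CON", "LPS")
    contig: str = "chr1"
    contig_length: Optional[int] = None  # None = auto-size to fit the genes

    # coverage at candidate sites
    mean_depth: float = 150.0
    depth_dispersion: float = 0.05  # NB dispersion alpha of coverage

    # editing-site layout
    editing_sites_per_gene: float = 2.0  # Poisson mean
    baseline_editing_freq_range: Tuple[float, float] = (0.10, 0.90)
    baseline_freq_beta: Tuple[float, float] = (1.2, 2.5)  # shape inside range
    editing_type_probs: Dict[str, float] = field(default_factory=_default_type_probs)
    frac_nonexonic_sites: float = 0.10
    frac_germline_snps: float = 0.05
    frac_noise_sites: float = 0.05

    # group effects
    frac_diff_edited_genes: float = 0.10
    editing_effect_log2fc: float = 2.0
    frac_de_genes: float = 0.10
    expression_effect_log2fc: float = 2.0

    # QC corruption (independent Bernoulli per rule)
    qc_corruption_rates: Dict[str, float] = field(default_factory=_default_qc_rates)
    frac_triallelic: float = 0.01

    # expression model
    mean_expression: float = 300.0
    expression_log_sd: float = 1.0
    expression_dispersion: float = 0.05

    # enzyme -> target editing link
    n_enzyme_targets: int = 3
    enzyme_link_slope: float = 0.8
    enzyme_link_noise_sd: float = 0.02
    enzyme_mean_expression: float = 5000.0
    enzyme_expression_dispersion: float = 0.005

    # gene structure
    frac_ncrna_genes: float = 0.05

    # pathway table
    n_pathways: int = 20
    pathway_size: int = 25

    seed: int = 0

    def validate(self) -> None:
        props = {
            "frac_nonexonic_sites": self.frac_nonexonic_sites,
            "frac_germline_snps": self.frac_germline_snps,
            "frac_noise_sites": self.frac_noise_sites,
            "frac_diff_edited_genes": self.frac_diff_edited_genes,
            "frac_de_genes": self.frac_de_genes,
            "frac_triallelic": self.frac_triallelic,
            "frac_ncrna_genes": self.frac_ncrna_genes,
            **{f"qc_rate[{k}]": v for k, v in self.qc_corruption_rates.items()},
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        lo, hi = self.baseline_editing_freq_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("baseline_editing_freq_range must satisfy 0 <= lo < hi <= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")

    @property
    def samples(self) -> List[str]:
        return [
            f"{g}_{i + 1}" for g in self.groups for i in range(self.n_samples_per_group)
        ]

    def sample_group(self) -> Dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples}

    def rng(self, stream: int) -> np.random.Generator:
        # independent, reproducible sub-stream per stage
        return np.random.default_rng([self.seed, stream])


_STREAM_REFERENCE = 0
_STREAM_TRUTH = 1
_STREAM_CANDIDATES = 2
_STREAM_EXPRESSION = 3
_STREAM_PATHWAYS = 4
_STREAM_ENZYME = 5

_STOPS = {"TAA", "TAG", "TGA"}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(BASES)[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) non-stop codons + stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


def _make_gene_parts(rng: np.random.Generator, coding: bool):
    """Build one gene in transcript orientation.

    Returns (assembled_seq, exon_ivs, cds_ivs) where intervals are 0-based
    half-open in the assembled (transcript-orientation, introns included)
    coordinate system.
    """
    if coding:
        utr5 = int(rng.integers(10, 60))
        n_codons = int(rng.integers(40, 150))
        utr3 = int(rng.integers(10, 60))
        transcript = _random_seq(rng, utr5) + _random_cds(rng, n_codons) + _random_seq(rng, utr3)
        cds_t = (utr5, utr5 + 3 * n_codons)
    else:
        transcript = _random_seq(rng, int(rng.integers(300, 800)))
        cds_t = None
    tlen = len(transcript)

    n_introns = int(rng.integers(0, 3))
    cuts = sorted(rng.choice(np.arange(1, tlen), size=n_introns, replace=False).tolist()) if n_introns else []
    pieces, prev = [], 0
    for c in cuts + [tlen]:
        pieces.append(transcript[prev:c])
        prev = c

    assembled_parts: List[str] = []
    exon_ivs: List[Tuple[int, int]] = []  # assembled coords
    exon_t_ivs: List[Tuple[int, int]] = []  # transcript coords
    a_off = t_off = 0
    for i, piece in enumerate(pieces):
        if i > 0:
            intron = _random_seq(rng, int(rng.integers(60, 200)))
            assembled_parts.append(intron)
            a_off += len(intron)
        assembled_parts.append(piece)
        exon_ivs.append((a_off, a_off + len(piece)))
        exon_t_ivs.append((t_off, t_off + len(piece)))
        a_off += len(piece)
        t_off += len(piece)
    assembled = "".join(assembled_parts)

    cds_ivs: List[Tuple[int, int]] = []
    if cds_t is not None:
        c0, c1 = cds_t
        for (a0, _a1), (t0, t1) in zip(exon_ivs, exon_t_ivs):
            s, e = max(t0, c0), min(t1, c1)
            if s < e:
                cds_ivs.append((a0 + (s - t0), a0 + (e - t0)))
    return assembled, exon_ivs, cds_ivs


def generate_reference(config: SimulationConfig):
    """Generate the reference contig and non-overlapping gene models.

    Returns ``(sequences, genes)`` where sequences maps contig -> sequence
    and genes is a list of :class:`Gene` (1-based inclusive intervals).
    Coding genes have a CDS that starts with ATG, ends with a stop codon
    and has length divisible by 3.
    """
    config.validate()
    rng = config.rng(_STREAM_REFERENCE)
    genes: List[Gene] = []
    chunks: List[str] = []
    cursor = 0  # 0-based length so far
    for i in range(config.n_genes):
        gap = int(rng.integers(1500, 3000))
        chunks.append(_random_seq(rng, gap))
        cursor += gap
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() >= config.frac_ncrna_genes
        assembled, exon_ivs, cds_ivs = _make_gene_parts(rng, coding)
        L = len(assembled)
        if strand == "-":
            gene_seq = revcomp(assembled)
            exon_ivs = [(L - b, L - a) for a, b in exon_ivs]
            cds_ivs = [(L - b, L - a) for a, b in cds_ivs]
        else:
            gene_seq = assembled
        chunks.append(gene_seq)
        g_start = cursor  # 0-based
        exons = tuple(sorted((g_start + a + 1, g_start + b) for a, b in exon_ivs))
        cds = tuple(sorted((g_start + a + 1, g_start + b) for a, b in cds_ivs))
        genes.append(
            Gene(
                gene_id=f"gene{i + 1:04d}",
                contig=config.contig,
                start=exons[0][0],
                end=exons[-1][1],
                strand=strand,
                exons=exons,
                cds=cds,
            )
        )
        cursor += L
    tail = int(rng.integers(1500, 3000))
    chunks.append(_random_seq(rng, tail))
    cursor += tail
    if config.contig_length is not None:
        if config.contig_length < cursor:
            raise ValueError(
                f"contig_length={config.contig_length} too short for "
                f"{config.n_genes} genes (need >= {cursor})"
            )
        chunks.append(_random_seq(rng, config.contig_length - cursor))
    sequence = "".join(chunks)
    return {config.contig: sequence}, genes


# ---------------------------------------------------------------------------
# truth assignment


def assign_truth_genes(config: SimulationConfig, genes: List[Gene]) -> pd.DataFrame:
    """Per-gene truth flags: differential editing, differential expression,
    enzyme designation and enzyme targets.  Enzyme and its targets are kept
    out of the differential pools so each effect is attributable."""
    rng = config.rng(_STREAM_TRUTH)
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    coding = np.array([g.is_coding for g in genes])

    enzyme_idx = -1
    target_idx: List[int] = []
    if config.n_enzyme_targets > 0 and coding.sum() >= config.n_enzyme_targets + 1:
        pool = np.flatnonzero(coding)
        chosen = rng.choice(pool, size=config.n_enzyme_targets + 1, replace=False)
        enzyme_idx, target_idx = int(chosen[0]), [int(x) for x in chosen[1:]]

    reserved = {enzyme_idx, *target_idx} - {-1}
    free = np.array([i for i in range(n) if i not in reserved])

    def pick(frac: float) -> set:
        k = int(round(frac * n))
        k = min(k, len(free))
        return set(int(x) for x in rng.choice(free, size=k, replace=False)) if k else set()

    diff_edit = pick(config.frac_diff_edited_genes)
    de = pick(config.frac_de_genes)

    rows = []
    for i, gid in enumerate(gene_ids):
        ed = i in diff_edit
        dx = i in de
        rows.append(
            {
                "gene_id": gid,
                "diff_edited": ed,
                "edit_direction": int(rng.choice([-1, 1])) if ed else 0,
                "de": dx,
                "de_direction": int(rng.choice([-1, 1])) if dx else 0,
                "is_enzyme": i == enzyme_idx,
                "enzyme_target": i in target_idx,
            }
        )
    return pd.DataFrame(rows)


def enzyme_expression_profile(config: SimulationConfig) -> pd.Series:
    """Per-sample relative expression of the enzyme gene (mean-free scale,
    values in ~[0.25, 1.0]).  Evenly spread with jitter, then shuffled, so
    the enzyme->editing link spans its dynamic range at any sample size."""
    rng = config.rng(_STREAM_ENZYME)
    n = len(config.samples)
    base = np.linspace(0.25, 1.0, n)
    jitter = rng.uniform(-0.03, 0.03, n)
    vals = np.clip(base + jitter, 0.05, 1.2)
    rng.shuffle(vals)
    return pd.Series(vals, index=config.samples, name="enzyme_expression")


# ---------------------------------------------------------------------------
# candidates


def _strand_base(contig_seq: str, pos: int, strand: str) -> str:
    b = contig_seq[pos - 1]
    return COMPLEMENT[b] if strand == "-" else b


def _positions_by_strand_base(contig_seq: str, gene: Gene, flank: int = 500):
    """Candidate site positions grouped by (region kind, strand-adjusted base)."""
    exonic, nonexonic = {b: [] for b in BASES}, {b: [] for b in BASES}
    exon_pos = set()
    for s, e in gene.exons:
        exon_pos.update(range(s, e + 1))
    lo = max(1, gene.start - flank)
    hi = min(len(contig_seq), gene.end + flank)
    for pos in range(lo, hi + 1):
        b = _strand_base(contig_seq, pos, gene.strand)
        if b not in exonic:
            continue
        (exonic if pos in exon_pos else nonexonic)[b].append(pos)
    return exonic, nonexonic


_OTHER_PAIRS = [
    (r, a)
    for r in BASES
    for a in BASES
    if r != a and (r, a) not in (("A", "G"), ("C", "T"))
]


def simulate_candidates(config: SimulationConfig, sequences: Dict[str, str], genes: List[Gene], truth_genes: Optional[pd.DataFrame] = None):
    """Simulate variant candidates plus the per-site truth table.

    Returns ``(candidates, truth_sites, truth_genes)``.  The truth table
    has one row per emitted candidate with its true status and per-sample
    true frequency.
    """
    config.validate()
    if truth_genes is None:
        truth_genes = assign_truth_genes(config, genes)
    rng = config.rng(_STREAM_CANDIDATES)
    contig_seq = sequences[config.contig]
    samples = config.samples
    group_of = config.sample_group()
    treatment = config.groups[1]
    enzyme_expr = enzyme_expression_profile(config)

    tg = truth_genes.set_index("gene_id")
    lo, hi = config.baseline_editing_freq_range
    a_shape, b_shape = config.baseline_freq_beta

    type_names = list(config.editing_type_probs)
    type_p = np.array([config.editing_type_probs[t] for t in type_names], dtype=float)
    type_p = type_p / type_p.sum()

    used_positions: set = set()
    records = []  # (pos, candidate, truth_row)

    for gene in genes:
        n_sites = int(rng.poisson(config.editing_sites_per_gene))
        if tg.loc[gene.gene_id, "enzyme_target"]:
            n_sites = max(n_sites, 1)
        if n_sites == 0:
            continue
        exonic, nonexonic = _positions_by_strand_base(contig_seq, gene)

        for _ in range(n_sites):
            u = rng.random()
            if u < config.frac_germline_snps:
                status = "germline_snp"
            elif u < config.frac_germline_snps + config.frac_noise_sites:
                status = "noise"
            else:
                status = "editing"

            # mismatch pair in strand-adjusted (transcript) space
            if status == "editing":
                t = type_names[rng.choice(len(type_names), p=type_p)]
                if t == "A-to-I":
                    ref_t, alt_t = "A", "G"
                elif t == "C-to-U":
                    ref_t, alt_t = "C", "T"
                else:
                    ref_t, alt_t = _OTHER_PAIRS[rng.integers(0, len(_OTHER_PAIRS))]
            else:
                ref_t = BASES[rng.integers(0, 4)]
                alts = [b for b in BASES if b != ref_t]
                alt_t = alts[rng.integers(0, 3)]

            pool_kind = nonexonic if rng.random() < config.frac_nonexonic_sites else exonic
            pool = [p for p in pool_kind[ref_t] if p not in used_positions]
            if not pool:
                pool = [p for p in exonic[ref_t] if p not in used_positions]
            if not pool:
                continue
            pos = int(pool[rng.integers(0, len(pool))])
            used_positions.add(pos)

            ref_g = contig_seq[pos - 1]
            alt_g = COMPLEMENT[alt_t] if gene.strand == "-" else alt_t

            # per-sample true frequency
            if status == "germline_snp":
                f = 1.0 if rng.random() < 0.5 else 0.5
                freqs = {s: f for s in samples}
            elif status == "noise":
                f = float(rng.uniform(0.0, 0.08))
                freqs = {s: f for s in samples}
            elif tg.loc[gene.gene_id, "enzyme_target"]:
                noise = rng.normal(0.0, config.enzyme_link_noise_sd, len(samples))
                vals = 0.10 + config.enzyme_link_slope * enzyme_expr.values + noise
                freqs = {
                    s: float(np.clip(v, 0.02, 0.98)) for s, v in zip(samples, vals)
                }
            else:
                f0 = lo + (hi - lo) * float(rng.beta(a_shape, b_shape))
                d = int(tg.loc[gene.gene_id, "edit_direction"])
                ft = f0
                if tg.loc[gene.gene_id, "diff_edited"]:
                    ft = float(np.clip(f0 * 2.0 ** (d * config.editing_effect_log2fc), 0.02, 0.98))
                freqs = {s: (ft if group_of[s] == treatment else f0) for s in samples}

            # depths
            alpha = config.depth_dispersion
            mu = config.mean_depth
            if alpha > 0:
                total = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu), len(samples))
            else:
                total = rng.poisson(mu, len(samples))
            total_depth = {s: int(t) for s, t in zip(samples, total)}
            alt_depth = {
                s: int(rng.binomial(total_depth[s], freqs[s])) for s in samples
            }

            # QC metrics, independently corrupted per rule
            qc = {}
            for rule, (ok, bad) in _QC_RANGES.items():
                rate = config.qc_corruption_rates.get(rule, 0.0)
                r = bad if rng.random() < rate else ok
                qc[rule] = float(rng.uniform(*r))

            alt_bases = (alt_g,)
            if rng.random() < config.frac_triallelic:
                extra = [b for b in BASES if b not in (ref_g, alt_g)]
                alt_bases = (alt_g, extra[rng.integers(0, len(extra))])

            cand = VariantCandidate(
                contig=gene.contig,
                pos=pos,
                ref_base=ref_g,
                alt_bases=alt_bases,
                qd=qc["QD"],
                fs=qc["FS"],
                mq_rank_sum=qc["MQRankSum"],
                read_pos_rank_sum=qc["ReadPosRankSum"],
                mq=qc["MQ"],
                sor=qc["SOR"],
                site_base_quality=qc["BQ"],
                total_depth=total_depth,
                alt_depth=alt_depth,
            )
            trow = {
                "contig": gene.contig,
                "pos": pos,
                "ref": ref_g,
                "alt": alt_g,
                "gene_id": gene.gene_id if gene.contains(pos) else "",
                "status": status,
                **{f"freq_{s}": freqs[s] for s in samples},
            }
            records.append((pos, cand, trow))

    records.sort(key=lambda r: r[0])
    candidates = [c for _, c, _ in records]
    truth_sites = pd.DataFrame([t for _, _, t in records]) if records else pd.DataFrame(
        columns=["contig", "pos", "ref", "alt", "gene_id", "status"]
        + [f"freq_{s}" for s in samples]
    )
    # a diff-editing flag is only meaningful when the gene actually emitted
    # an editing site carrying the effect; clear vacuous flags
    edited = set(
        truth_sites.loc[truth_sites["status"] == "editing", "gene_id"]
    ) - {""}
    truth_genes = truth_genes.copy()
    vacuous = truth_genes["diff_edited"] & ~truth_genes["gene_id"].isin(edited)
    truth_genes.loc[vacuous, "diff_edited"] = False
    truth_genes.loc[vacuous, "edit_direction"] = 0
    return candidates, truth_sites, truth_genes


# ---------------------------------------------------------------------------
# expression


def simulate_expression(config: SimulationConfig, genes: List[Gene], truth_genes: pd.DataFrame):
    """Gene x sample NB count matrix plus gene lengths.

    DE genes shift by ``expression_effect_log2fc`` in the treatment group;
    the enzyme gene's per-sample mean follows its expression profile (the
    same profile that drove target-gene editing frequencies).
    """
    config.validate()
    gene_ids = [g.gene_id for g in genes]
    if set(truth_genes["gene_id"]) != set(gene_ids):
        raise ValueError("truth table and gene models disagree on gene ids")
    rng = config.rng(_STREAM_EXPRESSION)
    samples = config.samples
    group_of = config.sample_group()
    treatment = config.groups[1]
    enzyme_expr = enzyme_expression_profile(config)
    tg = truth_genes.set_index("gene_id")

    base_mean = config.mean_expression * np.exp(
        rng.normal(0.0, config.expression_log_sd, len(gene_ids))
    )
    counts = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    for i, gid in enumerate(gene_ids):
        is_enzyme = bool(tg.loc[gid, "is_enzyme"])
        for j, s in enumerate(samples):
            if is_enzyme:
                mu = config.enzyme_mean_expression * float(enzyme_expr[s])
                alpha = config.enzyme_expression_dispersion
            else:
                mu = base_mean[i]
                alpha = config.expression_dispersion
                if tg.loc[gid, "de"] and group_of[s] == treatment:
                    mu *= 2.0 ** (
                        int(tg.loc[gid, "de_direction"]) * config.expression_effect_log2fc
                    )
            if alpha > 0:
                counts[i, j] = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
            else:
                counts[i, j] = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    lengths = pd.Series(
        [g.exon_length for g in genes], index=pd.Index(gene_ids, name="gene_id"), name="length"
    )
    return counts_df, lengths


def simulate_pathways(config: SimulationConfig, genes: List[Gene], truth_genes: pd.DataFrame) -> pd.DataFrame:
    """Pathway membership table.  The first pathway is enriched for truly
    differentially edited genes so enrichment has signal to find."""
    rng = config.rng(_STREAM_PATHWAYS)
    gene_ids = np.array([g.gene_id for g in genes])
    diff = truth_genes.loc[truth_genes["diff_edited"], "gene_id"].to_numpy()
    rows = []
    for k in range(config.n_pathways):
        pid = f"path{k + 1:03d}"
        size = min(config.pathway_size, len(gene_ids))
        if k == 0 and len(diff) > 0:
            n_sig = min(len(diff), size // 2)
            members = set(rng.choice(diff, size=n_sig, replace=False))
            rest = np.setdiff1d(gene_ids, np.array(sorted(members)))
            members |= set(rng.choice(rest, size=size - n_sig, replace=False))
        else:
            members = set(rng.choice(gene_ids, size=size, replace=False))
        for gid in sorted(members):
            rows.append({"pathway_id": pid, "pathway_name": f"synthetic pathway {k + 1}", "gene_id": gid})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundled study


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    sequences: Dict[str, str]
    genes: List[Gene]
    candidates: list
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series
    pathways: pd.DataFrame
    enzyme_expression: pd.Series

    @property
    def design(self) -> pd.DataFrame:
        g = self.config.sample_group()
        return pd.DataFrame(
            {"sample_id": self.config.samples, "group": [g[s] for s in self.config.samples]}
        )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator stage with one shared seed."""
    sequences, genes = generate_reference(config)
    truth_genes = assign_truth_genes(config, genes)
    candidates, truth_sites, truth_genes = simulate_candidates(
        config, sequences, genes, truth_genes
    )
    counts, lengths = simulate_expression(config, genes, truth_genes)
    pathways = simulate_pathways(config, genes, truth_genes)
    return SimulatedStudy(
        config=config,
        sequences=sequences,
        genes=genes,
        candidates=candidates,
        truth_sites=truth_sites,
        truth_genes=truth_genes,
        counts=counts,
        lengths=lengths,
        pathways=pathways,
        enzyme_expression=enzyme_expression_profile(config),
    )


def write_study(study: SimulatedStudy, outdir: str) -> Dict[str, str]:
    """Write every artifact of the study as plain-text files; returns the
    path map."""
    os.makedirs(outdir, exist_ok=True)
    p = {
        "reference": os.path.join(outdir, "reference.fa"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "candidates": os.path.join(outdir, "candidates.vcf"),
        "counts": os.path.join(outdir, "expression_counts.tsv"),
        "lengths": os.path.join(outdir, "gene_lengths.tsv"),
        "pathways": os.path.join(outdir, "pathways.tsv"),
        "design": os.path.join(outdir, "design.tsv"),
        "truth_sites": os.path.join(outdir, "truth_sites.tsv"),
        "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
        "truth_samples": os.path.join(outdir, "truth_samples.tsv"),
        "config": os.path.join(outdir, "sim_config.yaml"),
    }
    elio.write_fasta(study.sequences, p["reference"])
    elio.write_gff3(study.genes, p["genes"])
    elio.write_vcf(study.candidates, study.config.samples, p["candidates"])
    elio.write_tsv(study.counts, p["counts"], "gene x sample raw counts", index=True)
    elio.write_tsv(
        study.lengths.to_frame(), p["lengths"], "gene_id, spliced exon length (bp)", index=True
    )
    elio.write_tsv(study.pathways, p["pathways"], "pathway_id, pathway_name, gene_id")
    elio.write_tsv(study.design, p["design"], "sample_id, group")
    elio.write_tsv(
        study.truth_sites, p["truth_sites"], "per-site truth: status and true per-sample frequency"
    )
    elio.write_tsv(study.truth_genes, p["truth_genes"], "per-gene truth flags")
    elio.write_tsv(
        study.enzyme_expression.rename_axis("sample_id").to_frame(),
        p["truth_samples"],
        "per-sample true enzyme expression profile (relative units)",
        index=True,
    )
    import yaml

    with open(p["config"], "w") as fh:
        yaml.safe_dump(asdict(study.config), fh, sort_keys=True)
    return p
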