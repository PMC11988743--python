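"""End-to-end pipeline runner: configuration, validation, stage execution
and the machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as elio
from . import annotation, differential, discovery, enrich, integrate, metrics

logger = logging.getLogger(__name__)

STAGES = (
    "discover",
    "annotate",
    "diff-edit",
    "diff-expr",
    "summarize",
    "integrate",
    "enrich",
)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.  CLI overrides > file > defaults."""

    vcf: str = ""
    fasta: str = ""
    gff: str = ""
    counts: str = ""
    lengths: str = ""
    pathways: str = ""
    design: str = ""
    known_snps: str = ""  # optional TSV/VCF of germline sites to exclude
    out_dir: str = "editlens_run"

    enzyme_gene: str = ""  # optional: enables enzyme-MAF correlation

    # thresholds
    padj_threshold: float = 0.05
    expr_lfc_threshold: float = 1.0
    edit_lfc_threshold: float = 0.0
    enrichment_fdr: float = 0.05
    upstream_window: int = 1000
    downstream_window: int = 1000
    splice_window: int = 2

    filter_thresholds: Dict = field(default_factory=dict)  # overrides by field name

    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def thresholds(self) -> discovery.FilterThresholds:
        return discovery.FilterThresholds(**self.filter_thresholds)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_known_snps(path: str) -> set:
    """(contig, pos) pairs from a VCF or a TSV with contig/pos columns."""
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return {(c.contig, c.pos) for c in elio.read_vcf(path)}
    df = elio.read_tsv(path)
    if not {"contig", "pos"}.issubset(df.columns):
        raise ValueError("known-SNP table needs contig and pos columns")
    return {(str(r.contig), int(r.pos)) for r in df.itertuples()}


def validate_inputs(config: PipelineConfig) -> List[str]:
    """Pre-flight checks; returns a list of problems (empty = valid)."""
    problems: List[str] = []
    required = {
        "vcf": config.vcf,
        "fasta": config.fasta,
        "gff": config.gff,
        "counts": config.counts,
        "lengths": config.lengths,
        "design": config.design,
    }
    for name, path in required.items():
        if not path:
            problems.append(f"missing required input path: {name}")
        elif not os.path.exists(path):
            problems.append(f"{name} file not found: {path}")
    if problems:
        return problems

    try:
        with __import__("pysam").VariantFile(config.vcf) as vf:
            info_keys = set(vf.header.info)
            fmt_keys = set(vf.header.formats)
            vcf_sample_list = list(vf.header.samples)
    except Exception as exc:  # malformed VCF
        return problems + [f"cannot parse VCF: {exc}"]
    for key in ("QD", "FS", "MQRankSum", "ReadPosRankSum", "MQ", "SOR"):
        if key not in info_keys:
            problems.append(f"VCF missing INFO key {key}")
    for key in ("AD", "DP"):
        if key not in fmt_keys:
            problems.append(f"VCF missing FORMAT key {key}")

    design = elio.read_design(config.design)
    for s in vcf_sample_list:
        if s not in design.index:
            problems.append(f"design missing VCF sample {s}")

    genes = elio.read_gff3(config.gff)
    for g in genes:
        if g.is_coding and g.cds_length % 3 != 0:
            problems.append(f"gene {g.gene_id}: CDS length {g.cds_length} not divisible by 3")

    counts = elio.read_tsv(config.counts, index_col=0)
    for s in counts.columns:
        if s not in design.index:
            problems.append(f"design missing counts sample {s}")
    return problems


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages in order, writing TSV outputs and a JSON manifest
    into ``config.out_dir``.  Reruns with the same config and inputs are
    byte-identical."""
    problems = validate_inputs(config)
    if problems:
        raise ValueError("input validation failed:\n" + "\n".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: Dict = {
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }
    for name in ("vcf", "fasta", "gff", "counts", "lengths", "pathways", "design", "known_snps"):
        path = getattr(config, name)
        if path and os.path.exists(path):
            manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    thr = config.thresholds()
    design = elio.read_design(config.design)
    groups = list(dict.fromkeys(design))
    sequences = elio.read_fasta(config.fasta)
    genes = elio.read_gff3(config.gff)
    out = lambda fname: os.path.join(config.out_dir, fname)

    def _run_stage(stage: str, fn):
        try:
            result = fn()
        except Exception:
            with open(out(f"{stage}.failed"), "w") as fh:
                fh.write("stage failed; see log\n")
            logger.exception("stage %s failed", stage)
            raise
        return result

    # discover -------------------------------------------------------------
    def _discover():
        candidates = elio.read_vcf(config.vcf)
        known = load_known_snps(config.known_snps) if config.known_snps else None
        sites, report = discovery.discover_sites(candidates, thr, known)
        samples = elio.vcf_samples(config.vcf)
        df = discovery.sites_to_frame(sites, samples)
        elio.write_tsv(df, out("sites.tsv"), "high-confidence editing sites; freq NaN = invalid measurement")
        elio.write_tsv(report, out("filter_report.tsv"), "per-rule removal counts")
        return sites, samples, len(candidates)

    sites, samples, n_in = _run_stage("discover", _discover)
    manifest["stages"]["discover"] = {"n_candidates_in": n_in, "n_sites": len(sites)}

    # annotate -------------------------------------------------------------
    def _annotate():
        ann = annotation.annotate_sites(
            sites, genes, sequences,
            config.upstream_window, config.downstream_window, config.splice_window,
        )
        df = annotation.annotated_to_frame(ann, samples)
        elio.write_tsv(df, out("annotated_sites.tsv"), "annotated editing sites")
        summary = annotation.summarize_landscape(ann)
        pieces = []
        for axis, series in summary.items():
            p = series.rename("value").rename_axis("category").reset_index()
            p.insert(0, "axis", axis)
            pieces.append(p)
        elio.write_tsv(pd.concat(pieces, ignore_index=True), out("landscape_summary.tsv"),
                       "editing landscape: proportions by type/region, counts by consequence")
        return ann

    annotated = _run_stage("annotate", _annotate)
    manifest["stages"]["annotate"] = {"n_sites": len(annotated)}

    # diff-edit ------------------------------------------------------------
    def _diff_edit():
        mat = differential.aggregate_gene_editing(annotated, genes, samples)
        elio.write_tsv(mat, out("gene_editing_counts.tsv"), "gene x sample editing-supporting read counts", index=True)
        if mat.empty:
            res = pd.DataFrame(columns=["baseMean", "log2FC", "SE", "stat", "pvalue", "padj", "significant"])
        else:
            res = differential.nb_wald_test(
                mat, design, control=groups[0], treatment=groups[1],
                padj_threshold=config.padj_threshold, lfc_threshold=0.0,
            )
        elio.write_tsv(res, out("diff_editing.tsv"), "gene-level differential editing (NB Wald)", index=True)
        return res

    diff_edit = _run_stage("diff-edit", _diff_edit)
    manifest["stages"]["diff-edit"] = {
        "n_genes": int(len(diff_edit)),
        "n_significant": int(diff_edit["significant"].sum()) if len(diff_edit) else 0,
    }

    # diff-expr ------------------------------------------------------------
    counts = elio.read_tsv(config.counts, index_col=0)
    lengths = elio.read_tsv(config.lengths, index_col=0).iloc[:, 0]

    def _diff_expr():
        res = differential.nb_wald_test(
            counts, design, control=groups[0], treatment=groups[1],
            padj_threshold=config.padj_threshold, lfc_threshold=config.expr_lfc_threshold,
        )
        elio.write_tsv(res, out("diff_expression.tsv"), "differential expression (NB Wald)", index=True)
        return res

    diff_expr = _run_stage("diff-expr", _diff_expr)
    manifest["stages"]["diff-expr"] = {
        "n_genes": int(len(diff_expr)),
        "n_significant": int(diff_expr["significant"].sum()),
    }

    # summarize ------------------------------------------------------------
    def _summarize():
        tpm_mat = metrics.tpm(counts, lengths)
        elio.write_tsv(tpm_mat, out("tpm.tsv"), "TPM matrix", index=True)
        corr = metrics.sample_correlation(tpm_mat)
        elio.write_tsv(corr, out("sample_correlation.tsv"), "Pearson correlation of log2(TPM+1)", index=True)

        freq = _frequency_matrix(annotated, samples)
        n_pcs = 0
        if freq.shape[0] >= 2:
            coords, pct = metrics.editing_pca(freq)
            elio.write_tsv(coords, out("pca_coordinates.tsv"), "sample coordinates in editing-frequency PCA", index=True)
            elio.write_tsv(pct.to_frame(), out("pca_variance.tsv"), "% variance per component", index=True)
            n_pcs = len(pct)
        venn = metrics.shared_events(metrics.group_site_sets(freq, design))
        elio.write_tsv(venn, out("shared_events.tsv"), "editing events per Venn region")
        hist = metrics.frequency_histogram(freq, design)
        elio.write_tsv(hist, out("frequency_histogram.tsv"), "editing-frequency histogram per group", index=True)
        return tpm_mat, n_pcs

    tpm_mat, n_pcs = _run_stage("summarize", _summarize)
    manifest["stages"]["summarize"] = {"n_components": n_pcs}

    # integrate ------------------------------------------------------------
    def _integrate():
        quad = integrate.nine_quadrant(
            diff_edit, diff_expr,
            lfc_threshold_expr=config.expr_lfc_threshold,
            lfc_threshold_edit=config.edit_lfc_threshold,
        )
        elio.write_tsv(quad, out("quadrants.tsv"), "nine-quadrant assignment", index=True)
        cands = quad[quad["candidate"]]
        elio.write_tsv(cands, out("candidates.tsv"), "up/up candidate genes", index=True)
        if config.enzyme_gene and config.enzyme_gene in tpm_mat.index:
            rows = []
            for gid in cands.index:
                try:
                    maf = integrate.gene_maf(annotated, gid, samples)
                    res = integrate.enzyme_correlation(
                        tpm_mat.loc[config.enzyme_gene], maf, config.enzyme_gene, gid
                    )
                    rows.append({"enzyme": res.enzyme_gene, "target": res.target_gene,
                                 "r": res.r, "p_value": res.p_value, "n": res.n})
                except ValueError as exc:
                    logger.info("skipping correlation for %s: %s", gid, exc)
            elio.write_tsv(pd.DataFrame(rows, columns=["enzyme", "target", "r", "p_value", "n"]),
                           out("enzyme_correlation.tsv"), "enzyme expression vs target mean editing frequency")
        return quad, cands

    quad, cands = _run_stage("integrate", _integrate)
    manifest["stages"]["integrate"] = {
        "n_genes": int(len(quad)),
        "n_candidates": int(len(cands)),
    }

    # enrich ---------------------------------------------------------------
    def _enrich():
        if not config.pathways:
            return pd.DataFrame()
        pathways = elio.read_tsv(config.pathways)
        target = set(diff_edit.index[diff_edit["significant"]])
        res = enrich.hypergeometric_enrichment(target, pathways, fdr_threshold=config.enrichment_fdr)
        elio.write_tsv(res, out("enrichment.tsv"), "hypergeometric pathway enrichment of differentially edited genes")
        return res

    enr = _run_stage("enrich", _enrich)
    manifest["stages"]["enrich"] = {
        "n_pathways": int(len(enr)),
        "n_enriched": int(enr["enriched"].sum()) if "enriched" in enr else 0,
    }

    manifest["completed_stages"] = list(STAGES)
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def _frequency_matrix(annotated, samples) -> pd.DataFrame:
    """Site x sample frequency matrix (NaN = invalid measurement), indexed
    by "contig:pos:ref>alt" keys."""
    rows, idx = [], []
    for a in annotated:
        s = a.site
        idx.append(f"{s.contig}:{s.pos}:{s.ref_base}>{s.alt_base}")
        rows.append([np.nan if s.frequency.get(x) is None else s.frequency[x] for x in samples])
    return pd.DataFrame(rows, index=pd.Index(idx, name="site"), columns=samples)
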