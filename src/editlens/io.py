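"""Readers and writers for the standard formats used by the pipeline.

FASTA via Biopython, VCF via pysam, gene models as GFF3, matrices and
tables as TSV.  All TSV outputs carry a commented header line describing
the columns.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Gene, VariantCandidate

VCF_INFO_KEYS = ("QD", "FS", "MQRankSum", "ReadPosRankSum", "MQ", "SOR", "MBQ")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(genes: Iterable[Gene], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig}\teditlens\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.contig}\teditlens\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )
            for s, e in g.cds:
                fh.write(
                    f"{g.contig}\teditlens\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tParent={g.gene_id}\n"
                )


def _parse_gff_attrs(field: str) -> Dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str) -> List[Gene]:
    """Parse the subset of GFF3 produced by :func:`write_gff3` (or any file
    with gene/exon/CDS rows linked by ID/Parent)."""
    genes: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 row: {line!r}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
            start, end = int(start), int(end)
            a = _parse_gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError("gene row without ID attribute")
                genes[gid] = {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                }
                order.append(gid)
            elif ftype in ("exon", "CDS"):
                parent = a.get("Parent")
                if parent not in genes:
                    raise ValueError(f"{ftype} row with unknown Parent {parent!r}")
                key = "exons" if ftype == "exon" else "cds"
                genes[parent][key].append((start, end))
    out = []
    for gid in order:
        d = genes[gid]
        out.append(
            Gene(
                gene_id=gid,
                contig=d["contig"],
                start=d["start"],
                end=d["end"],
                strand=d["strand"],
                exons=tuple(sorted(d["exons"])),
                cds=tuple(sorted(d["cds"])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    candidates: Iterable[VariantCandidate], samples: List[str], path: str
) -> None:
    """Write candidates as uncompressed VCF v4.2 with the QC INFO keys and
    per-sample AD/DP."""
    candidates = list(candidates)
    contigs = sorted({c.contig for c in candidates})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">',
        '##INFO=<ID=MBQ,Number=1,Type=Float,Description="Mean base quality of alt-supporting bases">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for c in candidates:
        info = (
            f"QD={c.qd:.4g};FS={c.fs:.4g};MQRankSum={c.mq_rank_sum:.4g};"
            f"ReadPosRankSum={c.read_pos_rank_sum:.4g};MQ={c.mq:.4g};"
            f"SOR={c.sor:.4g};MBQ={c.site_base_quality:.4g}"
        )
        fmt_fields = []
        for s in samples:
            dp = int(c.total_depth.get(s, 0))
            ad = int(c.alt_depth.get(s, 0))
            fmt_fields.append(f"{dp - ad},{ad}:{dp}")
        lines.append(
            f"{c.contig}\t{c.pos}\t.\t{c.ref_base}\t{','.join(c.alt_bases)}\t.\t.\t{info}\tAD:DP\t"
            + "\t".join(fmt_fields)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> List[VariantCandidate]:
    """Read variant candidates with pysam; missing QC fields become NaN so
    the filter stage can attribute removals to a distinct reason."""
    out = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:

            def info_float(key: str) -> float:
                val = rec.info.get(key)
                if val is None:
                    return float("nan")
                if isinstance(val, tuple):
                    val = val[0]
                return float(val)

            total_depth, alt_depth = {}, {}
            for s in samples:
                sample = rec.samples[s]
                ad = sample.get("AD")
                dp = sample.get("DP")
                alt_depth[s] = int(ad[1]) if ad is not None and len(ad) > 1 else 0
                if dp is None:
                    dp = sum(int(x) for x in ad) if ad is not None else 0
                total_depth[s] = int(dp)
            out.append(
                VariantCandidate(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref_base=rec.ref,
                    alt_bases=tuple(rec.alts or ()),
                    qd=info_float("QD"),
                    fs=info_float("FS"),
                    mq_rank_sum=info_float("MQRankSum"),
                    read_pos_rank_sum=info_float("ReadPosRankSum"),
                    mq=info_float("MQ"),
                    sor=info_float("SOR"),
                    site_base_quality=info_float("MBQ"),
                    total_depth=total_depth,
                    alt_depth=alt_depth,
                )
            )
    return out


def vcf_samples(path: str) -> List[str]:
    with pysam.VariantFile(path) as vf:
        return list(vf.header.samples)


# ---------------------------------------------------------------------------
# TSV helpers


def write_tsv(df: pd.DataFrame, path: str, comment: Optional[str] = None, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_design(path: str) -> pd.Series:
    """sample_id -> group mapping."""
    df = read_tsv(path)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ValueError("design table must have columns sample_id, group")
    return df.set_index("sample_id")["group"]
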