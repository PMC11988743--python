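"""Editing-site annotation: mismatch class, genomic region, coding consequence.

Strand handling: the genomic ref->alt pair is complemented on minus-strand
genes before naming, so deamination events are recognised on either strand
(A->G on + and T->C under a - gene both collapse to A-to-I; C->T / G->A
collapse to C-to-U).  Sites without gene strand are named by the genomic
pair and collapsed under the same convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd
from Bio.Seq import Seq

from .models import COMPLEMENT, Gene
from .discovery import EditingSite

REGIONS = (
    "splicing",
    "exonic",
    "UTR5",
    "UTR3",
    "intronic",
    "ncRNA_exonic",
    "ncRNA_intronic",
    "upstream",
    "downstream",
    "intergenic",
)

CONSEQUENCES = ("synonymous", "nonsynonymous", "stopgain", "stoploss", "noncoding")


def classify_editing_type(ref_base: str, alt_base: str, gene_strand: str = "unknown") -> Tuple[str, str]:
    """Return ``(mismatch_type, collapsed_type)``.

    mismatch_type is the strand-adjusted pair, e.g. ``"A>G"``; collapsed
    classes are ``A-to-I`` (A>G), ``C-to-U`` (C>T) and the remaining pairs
    verbatim.  For unknown strand the genomic pair is reported and T>C /
    G>A additionally collapse to A-to-I / C-to-U.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    for b in (ref_base, alt_base):
        if b not in "ACGT":
            raise ValueError(f"non-ACGT base {b!r}")
    if ref_base == alt_base:
        raise ValueError("ref and alt must differ")
    if gene_strand not in ("+", "-", "unknown"):
        raise ValueError(f"bad strand {gene_strand!r}")

    if gene_strand == "-":
        r, a = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    else:
        r, a = ref_base, alt_base
    mismatch = f"{r}>{a}"
    if (r, a) == ("A", "G"):
        collapsed = "A-to-I"
    elif (r, a) == ("C", "T"):
        collapsed = "C-to-U"
    elif gene_strand == "unknown" and (r, a) == ("T", "C"):
        collapsed = "A-to-I"
    elif gene_strand == "unknown" and (r, a) == ("G", "A"):
        collapsed = "C-to-U"
    else:
        collapsed = mismatch
    return mismatch, collapsed


def _gene_region(gene: Gene, pos: int, splice_window: int) -> Optional[str]:
    """Region label relative to one gene body, or None if outside it."""
    if not gene.contains(pos):
        return None
    in_exon = gene.in_exon(pos)
    if not in_exon:
        # splicing: within splice_window nt of an exon boundary, intron side
        for s, e in gene.exons:
            if 0 < s - pos <= splice_window or 0 < pos - e <= splice_window:
                return "splicing"
    if not gene.is_coding:
        return "ncRNA_exonic" if in_exon else "ncRNA_intronic"
    if not in_exon:
        return "intronic"
    if gene.in_cds(pos):
        return "exonic"
    cds_start, cds_end = gene.cds[0][0], gene.cds[-1][1]
    if pos < cds_start:
        return "UTR5" if gene.strand == "+" else "UTR3"
    if pos > cds_end:
        return "UTR3" if gene.strand == "+" else "UTR5"
    return "exonic"


def annotate_region(
    contig: str,
    pos: int,
    genes: List[Gene],
    upstream_window: int = 1000,
    downstream_window: int = 1000,
    splice_window: int = 2,
) -> Tuple[str, Optional[Gene]]:
    """Assign the single highest-precedence region label for a position.

    Precedence: splicing > exonic > UTR5/UTR3 > intronic > ncRNA_exonic >
    ncRNA_intronic > upstream > downstream > intergenic.  Returns the label
    and the gene that supplied it (None for intergenic).
    """
    labels: List[Tuple[int, Gene, str]] = []
    rank = {r: i for i, r in enumerate(REGIONS)}
    for g in genes:
        if g.contig != contig:
            continue
        lab = _gene_region(g, pos, splice_window)
        if lab is None:
            # flanks, relative to transcription direction
            if g.strand == "+":
                if 0 < g.start - pos <= upstream_window:
                    lab = "upstream"
                elif 0 < pos - g.end <= downstream_window:
                    lab = "downstream"
            else:
                if 0 < pos - g.end <= upstream_window:
                    lab = "upstream"
                elif 0 < g.start - pos <= downstream_window:
                    lab = "downstream"
        if lab is not None:
            labels.append((rank[lab], g, lab))
    if not labels:
        return "intergenic", None
    labels.sort(key=lambda t: (t[0], -t[1].cds_length, t[1].gene_id))
    return labels[0][2], labels[0][1]


def annotate_coding_consequence(
    cds_sequence: str, cds_position: int, alt_base_transcript: str
) -> str:
    """Consequence of substituting ``alt_base_transcript`` at 0-based
    ``cds_position`` of the spliced CDS (both in transcript orientation)."""
    n = len(cds_sequence)
    if n % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not 0 <= cds_position < n:
        raise ValueError(f"cds_position {cds_position} outside CDS of length {n}")
    codon_start = 3 * (cds_position // 3)
    codon = cds_sequence[codon_start : codon_start + 3].upper()
    offset = cds_position - codon_start
    edited = codon[:offset] + alt_base_transcript.upper() + codon[offset + 1 :]
    aa_before = str(Seq(codon).translate())
    aa_after = str(Seq(edited).translate())
    if aa_before == aa_after:
        return "synonymous"
    if aa_after == "*":
        return "stopgain"
    if aa_before == "*":
        return "stoploss"
    return "nonsynonymous"


@dataclass
class AnnotatedSite:
    site: EditingSite
    gene_id: Optional[str]
    gene_strand: str
    mismatch_type: str
    collapsed_type: str
    region: str
    consequence: str


def annotate_sites(
    sites: List[EditingSite],
    genes: List[Gene],
    sequences: Dict[str, str],
    upstream_window: int = 1000,
    downstream_window: int = 1000,
    splice_window: int = 2,
) -> List[AnnotatedSite]:
    """Full annotation of each site: editing class, region and (for CDS
    hits) coding consequence.  Overlapping genes resolve to the longest
    CDS, ties broken by gene id."""
    out = []
    for s in sites:
        region, gene = annotate_region(
            s.contig, s.pos, genes, upstream_window, downstream_window, splice_window
        )
        strand = gene.strand if gene is not None else "unknown"
        mismatch, collapsed = classify_editing_type(s.ref_base, s.alt_base, strand)
        consequence = "noncoding"
        if gene is not None and region == "exonic" and gene.is_coding:
            off = gene.cds_offset(s.pos)
            if off is not None:
                cds_seq = gene.spliced_cds(sequences[s.contig])
                alt_t = (
                    COMPLEMENT[s.alt_base] if gene.strand == "-" else s.alt_base
                )
                consequence = annotate_coding_consequence(cds_seq, off, alt_t)
        out.append(
            AnnotatedSite(
                site=s,
                gene_id=gene.gene_id if gene is not None else None,
                gene_strand=strand,
                mismatch_type=mismatch,
                collapsed_type=collapsed,
                region=region,
                consequence=consequence,
            )
        )
    return out


def summarize_landscape(annotated: List[AnnotatedSite], fold_utr: bool = True) -> Dict[str, pd.Series]:
    """Proportions by collapsed editing class and region, counts by coding
    consequence.  ``fold_utr`` folds UTR5/UTR3 into "exonic" to match the
    headline category list; internal labels stay distinct."""
    if not annotated:
        empty = pd.Series(dtype=float)
        return {"by_type": empty, "by_region": empty, "by_consequence": pd.Series(dtype=int)}
    types = Counter(a.collapsed_type for a in annotated)
    regions = Counter(
        ("exonic" if fold_utr and a.region in ("UTR5", "UTR3") else a.region)
        for a in annotated
    )
    consequences = Counter(a.consequence for a in annotated)
    n = len(annotated)
    by_type = pd.Series({k: v / n for k, v in sorted(types.items())}, name="proportion")
    by_region = pd.Series({k: v / n for k, v in sorted(regions.items())}, name="proportion")
    by_consequence = pd.Series(dict(sorted(consequences.items())), name="count")
    return {"by_type": by_type, "by_region": by_region, "by_consequence": by_consequence}


def annotated_to_frame(annotated: List[AnnotatedSite], samples: List[str]) -> pd.DataFrame:
    """Annotated sites as a flat table (site columns + annotation columns)."""
    from .discovery import sites_to_frame

    base = sites_to_frame([a.site for a in annotated], samples)
    base["gene_id"] = [a.gene_id or "" for a in annotated]
    base["gene_strand"] = [a.gene_strand for a in annotated]
    base["mismatch_type"] = [a.mismatch_type for a in annotated]
    base["collapsed_type"] = [a.collapsed_type for a in annotated]
    base["region"] = [a.region for a in annotated]
    base["consequence"] = [a.consequence for a in annotated]
    return base
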