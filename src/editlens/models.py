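"""Core domain types shared across the pipeline.

Coordinate convention: 1-based inclusive intervals externally (VCF/GFF3);
helper accessors convert to 0-based half-open where noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class Gene:
    """A single-transcript gene model.

    ``exons`` and ``cds`` are tuples of (start, end) 1-based inclusive
    intervals sorted by genomic coordinate.  A gene with an empty ``cds``
    is treated as non-coding.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: tuple = ()
    cds: tuple = ()

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def cds_offset(self, pos: int) -> Optional[int]:
        """0-based offset of genomic ``pos`` within the spliced CDS,
        reading in transcript (strand) orientation; None if outside CDS."""
        if not self.in_cds(pos):
            return None
        off = 0
        if self.strand == "+":
            for s, e in self.cds:
                if pos > e:
                    off += e - s + 1
                else:
                    return off + (pos - s)
        else:
            for s, e in reversed(self.cds):
                if pos < s:
                    off += e - s + 1
                else:
                    return off + (e - pos)
        return None

    def spliced_cds(self, contig_seq: str) -> str:
        """Spliced CDS sequence in transcript orientation.

        ``contig_seq`` is the full contig sequence (0-based string).
        """
        parts = [contig_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq.upper()


@dataclass
class VariantCandidate:
    """One variant site with QC annotations and per-sample depths."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    alt_bases: tuple
    qd: float
    fs: float
    mq_rank_sum: float
    read_pos_rank_sum: float
    mq: float
    sor: float
    site_base_quality: float
    total_depth: dict = field(default_factory=dict)  # sample -> reads
    alt_depth: dict = field(default_factory=dict)  # sample -> reads

    @property
    def key(self):
        return (self.contig, self.pos, self.ref_base, self.alt_bases)

    def mean_depth(self) -> float:
        if not self.total_depth:
            return 0.0
        vals = list(self.total_depth.values())
        return sum(vals) / len(vals)


@dataclass
class EditingSite:
    """A filtered biallelic site with per-sample editing frequencies.

    ``frequency[s]`` is None where the sample's measurement is invalid
    (depth/alt-depth/window rules), otherwise alt/total.
    """

    contig: str
    pos: int
    ref_base: str
    alt_base: str
    total_depth: dict
    alt_depth: dict
    frequency: dict
    gene_id: Optional[str] = None

    @property
    def key(self):
        return (self.contig, self.pos, self.ref_base, self.alt_base)

    def valid_samples(self):
        return [s for s, f in self.frequency.items() if f is not None]
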