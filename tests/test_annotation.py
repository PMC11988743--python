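import itertools

import numpy as np
import pytest

from editlens.annotation import (
    AnnotatedSite,
    annotate_coding_consequence,
    annotate_region,
    annotate_sites,
    classify_editing_type,
    summarize_landscape,
)
from editlens.discovery import EditingSite, discover_sites
from editlens.models import COMPLEMENT, Gene
from editlens.simulate import SimulationConfig, simulate_study

BASES = "ACGT"

# independent genetic code oracle (hand-written standard table)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class TestClassifyEditingType:
    def test_a_to_g_plus_strand_is_a_to_i(self):
        assert classify_editing_type("A", "G", "+")[1] == "A-to-I"

    def test_c_to_t_plus_strand_is_c_to_u(self):
        assert classify_editing_type("C", "T", "+")[1] == "C-to-U"

    def test_minus_strand_complement_pairs(self):
        assert classify_editing_type("T", "C", "-")[1] == "A-to-I"
        assert classify_editing_type("G", "A", "-")[1] == "C-to-U"

    def test_all_24_cases_match_revcomp_oracle(self):
        for r, a in itertools.permutations(BASES, 2):
            plus = classify_editing_type(r, a, "+")
            minus = classify_editing_type(COMPLEMENT[r], COMPLEMENT[a], "-")
            assert plus == minus

    def test_unknown_strand_collapses_both_orientations(self):
        assert classify_editing_type("A", "G", "unknown")[1] == "A-to-I"
        assert classify_editing_type("T", "C", "unknown")[1] == "A-to-I"
        assert classify_editing_type("C", "T", "unknown")[1] == "C-to-U"
        assert classify_editing_type("G", "A", "unknown")[1] == "C-to-U"

    def test_errors(self):
        with pytest.raises(ValueError):
            classify_editing_type("N", "G", "+")
        with pytest.raises(ValueError):
            classify_editing_type("A", "A", "+")


@pytest.fixture
def two_exon_gene():
    # exons [101,200] and [301,400]; CDS [151,200]+[301,340] on +
    return Gene(
        gene_id="g1", contig="c", start=101, end=400, strand="+",
        exons=((101, 200), (301, 400)),
        cds=((151, 200), (301, 340)),
    )


class TestAnnotateRegion:
    def test_cds_exon_interior_is_exonic(self, two_exon_gene):
        region, gene = annotate_region("c", 180, [two_exon_gene], splice_window=2)
        assert region == "exonic" and gene.gene_id == "g1"

    def test_one_nt_into_intron_is_splicing(self, two_exon_gene):
        assert annotate_region("c", 201, [two_exon_gene], splice_window=2)[0] == "splicing"
        assert annotate_region("c", 300, [two_exon_gene], splice_window=2)[0] == "splicing"
        assert annotate_region("c", 250, [two_exon_gene], splice_window=2)[0] == "intronic"

    def test_upstream_window_boundary(self, two_exon_gene):
        region, _ = annotate_region("c", 101 - 999, [two_exon_gene], upstream_window=1000)
        assert region == "upstream"
        assert annotate_region("c", 101 - 1001, [two_exon_gene], upstream_window=1000)[0] == "intergenic"

    def test_utrs(self, two_exon_gene):
        assert annotate_region("c", 120, [two_exon_gene])[0] == "UTR5"
        assert annotate_region("c", 350, [two_exon_gene])[0] == "UTR3"

    def test_minus_strand_flanks_and_utrs_swap(self):
        g = Gene(
            gene_id="g2", contig="c", start=101, end=400, strand="-",
            exons=((101, 200), (301, 400)),
            cds=((151, 200), (301, 340)),
        )
        assert annotate_region("c", 420, [g])[0] == "upstream"
        assert annotate_region("c", 80, [g])[0] == "downstream"
        assert annotate_region("c", 120, [g])[0] == "UTR3"
        assert annotate_region("c", 370, [g])[0] == "UTR5"

    def test_ncrna_gene(self):
        g = Gene(gene_id="nc", contig="c", start=100, end=400, strand="+",
                 exons=((100, 200), (300, 400)), cds=())
        assert annotate_region("c", 150, [g])[0] == "ncRNA_exonic"
        assert annotate_region("c", 250, [g])[0] == "ncRNA_intronic"

    def test_unknown_contig_is_intergenic(self, two_exon_gene):
        region, gene = annotate_region("other", 150, [two_exon_gene])
        assert region == "intergenic" and gene is None

    def test_every_site_gets_exactly_one_label(self, two_exon_gene):
        for pos in range(1, 1500):
            region, _ = annotate_region("c", pos, [two_exon_gene])
            assert isinstance(region, str)


class TestCodingConsequence:
    def test_synonymous_example(self):
        # AAA -> AAG is Lys -> Lys
        assert annotate_coding_consequence("AAA", 2, "G") == "synonymous"

    def test_stopgain_example(self):
        # CAA -> TAA is Gln -> stop
        assert annotate_coding_consequence("CAA", 0, "T") == "stopgain"

    def test_stoploss_example(self):
        # TGA -> CGA is stop -> Arg
        assert annotate_coding_consequence("TGA", 0, "C") == "stoploss"

    def test_errors(self):
        with pytest.raises(ValueError):
            annotate_coding_consequence("AAAA", 0, "G")
        with pytest.raises(ValueError):
            annotate_coding_consequence("AAA", 3, "G")

    def test_exhaustive_codon_substitution_oracle(self):
        # all 64 codons x 9 single-base substitutions
        for codon in CODON_TABLE:
            for pos in range(3):
                for alt in BASES:
                    if alt == codon[pos]:
                        continue
                    edited = codon[:pos] + alt + codon[pos + 1:]
                    before, after = CODON_TABLE[codon], CODON_TABLE[edited]
                    if before == after:
                        expect = "synonymous"
                    elif after == "*":
                        expect = "stopgain"
                    elif before == "*":
                        expect = "stoploss"
                    else:
                        expect = "nonsynonymous"
                    assert annotate_coding_consequence(codon, pos, alt) == expect


def _site(pos, ref, alt, freq=0.5):
    return EditingSite(
        contig="c", pos=pos, ref_base=ref, alt_base=alt,
        total_depth={"s": 100}, alt_depth={"s": 50}, frequency={"s": freq},
    )


def _annotated(collapsed, region="exonic", consequence="noncoding"):
    return AnnotatedSite(
        site=_site(1, "A", "G"), gene_id=None, gene_strand="+",
        mismatch_type="A>G", collapsed_type=collapsed,
        region=region, consequence=consequence,
    )


class TestSummarizeLandscape:
    def test_small_proportions(self):
        ann = [_annotated("A-to-I"), _annotated("A-to-I"),
               _annotated("C-to-U"), _annotated("G>C")]
        out = summarize_landscape(ann)
        assert out["by_type"]["A-to-I"] == pytest.approx(0.50)
        assert out["by_type"]["C-to-U"] == pytest.approx(0.25)
        assert out["by_type"]["G>C"] == pytest.approx(0.25)
        assert out["by_type"].sum() == pytest.approx(1.0)

    def test_order_invariance(self):
        ann = [_annotated("A-to-I"), _annotated("C-to-U"), _annotated("G>C")]
        a = summarize_landscape(ann)
        b = summarize_landscape(ann[::-1])
        for key in a:
            assert a[key].equals(b[key])

    def test_empty_input_empty_summary(self):
        out = summarize_landscape([])
        assert out["by_type"].empty and out["by_region"].empty

    def test_utr_folding(self):
        ann = [_annotated("A-to-I", region="UTR5"), _annotated("A-to-I", region="UTR3")]
        assert summarize_landscape(ann, fold_utr=True)["by_region"]["exonic"] == 1.0
        assert "UTR5" in summarize_landscape(ann, fold_utr=False)["by_region"]

    def test_configured_type_proportions_recovered(self):
        cfg = SimulationConfig(
            n_genes=700, editing_sites_per_gene=4.0, seed=19,
            frac_germline_snps=0.0, frac_noise_sites=0.0,
            editing_type_probs={"A-to-I": 0.6, "C-to-U": 0.2, "other": 0.2},
            qc_corruption_rates={},
            frac_triallelic=0.0,
        )
        st = simulate_study(cfg)
        sites, _ = discover_sites(st.candidates)
        ann = annotate_sites(sites, st.genes, st.sequences)
        assert len(ann) > 2000
        out = summarize_landscape(ann)["by_type"]
        assert out["A-to-I"] == pytest.approx(0.60, abs=0.03)
        assert out["C-to-U"] == pytest.approx(0.20, abs=0.03)


class TestAnnotateSitesIntegration:
    def test_simulated_editing_sites_collapse_to_configured_class(self, small_study):
        sites, _ = discover_sites(small_study.candidates)
        ann = annotate_sites(sites, small_study.genes, small_study.sequences)
        truth = small_study.truth_sites.set_index("pos")
        by_gene = {g.gene_id: g for g in small_study.genes}
        for a in ann:
            assert a.region in (
                "splicing", "exonic", "UTR5", "UTR3", "intronic", "ncRNA_exonic",
                "ncRNA_intronic", "upstream", "downstream", "intergenic",
            )
            row = truth.loc[a.site.pos]
            if a.gene_id and row["gene_id"] == a.gene_id:
                gene = by_gene[a.gene_id]
                # mismatch pair was drawn strand-adjusted at generation time
                exp_ref = COMPLEMENT[row["ref"]] if gene.strand == "-" else row["ref"]
                exp_alt = COMPLEMENT[row["alt"]] if gene.strand == "-" else row["alt"]
                assert a.mismatch_type == f"{exp_ref}>{exp_alt}"

    def test_consequence_only_in_cds(self, small_study):
        sites, _ = discover_sites(small_study.candidates)
        ann = annotate_sites(sites, small_study.genes, small_study.sequences)
        for a in ann:
            if a.consequence != "noncoding":
                assert a.region == "exonic"
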