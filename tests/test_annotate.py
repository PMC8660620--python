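"""Location classification, impact rules and the candidate-table location grammar."""

import pytest

from svcohort.annotate import (
    GeneModel,
    Transcript,
    annotate_all,
    classify_location,
    location_summary,
    percent,
    predict_impact,
    read_gff3,
    write_gff3,
)
from svcohort.sv_io import MergedSV


def _sv(chrom="1", start=100, end=200, svtype="DEL", length=None, id="sv_x"):
    if length is None:
        length = 100 if svtype == "INS" else end - start
    return MergedSV(chrom=chrom, start=start, end=end, svtype=svtype, length=length,
                    carriers=frozenset({"a", "b"}), id=id)


@pytest.fixture
def toy_gene():
    """Plus-strand gene: exon1 100-200, intron1 201-300, exon2 301-400."""
    t = Transcript("t1", ((100, 200), (301, 400)))
    return GeneModel("G1", "G1", "protein_coding", "1", 1, (t,))


class TestClassifyLocation:
    def test_fully_exonic(self, toy_gene):
        ann = classify_location(_sv(start=150, end=180), [toy_gene])
        assert ann.location == "exon"
        assert ann.location_string == "EXON=1/2,STRAND=1"

    def test_spanning_exon_intron_boundary(self, toy_gene):
        ann = classify_location(_sv(start=190, end=250), [toy_gene])
        assert ann.location == "exon_intron"
        assert ann.location_string == "EXON=1/2,INTRON=1/1,STRAND=1"

    def test_purely_intronic(self, toy_gene):
        ann = classify_location(_sv(start=210, end=280), [toy_gene])
        assert ann.location == "intron"
        assert ann.location_string == "INTRON=1/1,STRAND=1"

    def test_beyond_flank_is_intergenic(self, toy_gene):
        ann = classify_location(_sv(start=9000, end=9100), [toy_gene], flank=5000)
        assert ann.location == "intergenic" and ann.genes == ()

    def test_within_flank_is_upstream_downstream_with_distance(self, toy_gene):
        ann = classify_location(_sv(start=1500, end=1600), [toy_gene], flank=5000)
        assert ann.location == "upstream_downstream"
        # gene span ends at 400; nearest affected base is 1501
        assert ann.distance == 1101
        assert ann.location_string == "DISTANCE=1101,STRAND=1"

    def test_utr_when_fully_inside_utr(self):
        t = Transcript("t1", ((1000, 2000),), cds=((1100, 1900),),
                       utr5=((1000, 1099),), utr3=((1901, 2000),))
        gene = GeneModel("G1", "G1", "protein_coding", "1", 1, (t,))
        ann = classify_location(_sv(start=1920, end=1980), [gene])
        assert ann.location == "utr"

    def test_insertion_point_classification(self, toy_gene):
        ann = classify_location(_sv(start=150, end=150, svtype="INS", length=70), [toy_gene])
        assert ann.location == "exon"
        ann = classify_location(_sv(start=250, end=250, svtype="INS", length=70), [toy_gene])
        assert ann.location == "intron"

    def test_absent_chromosome_warns_and_returns_intergenic(self, toy_gene, caplog):
        with caplog.at_level("WARNING", logger="svcohort.annotate"):
            ann = classify_location(_sv(chrom="99", start=100, end=200), [toy_gene])
        assert ann.location == "intergenic"
        assert any("absent from gene model" in r.message for r in caplog.records)

    def test_strand_flip_maps_ordinals(self, gene_factory):
        fwd = gene_factory(n_exons=5, strand=1, origin=10_000)
        rev = gene_factory(n_exons=5, strand=-1, origin=10_000)
        # SV inside genomic exon 2 (origin + 1000 .. +1299)
        sv = _sv(start=11_050, end=11_150)
        assert classify_location(sv, [fwd]).location_string == "EXON=2/5,STRAND=1"
        assert classify_location(sv, [rev]).location_string == "EXON=4/5,STRAND=-1"
        assert classify_location(sv, [fwd]).location == classify_location(sv, [rev]).location


class TestPublishedLocationStrings:
    """Gene layouts implied by published candidate rows reproduce their
    Location strings (strand-aware exon/intron ordinals, distance grammar)."""

    @pytest.mark.parametrize(
        "sv,n_exons,strand,origin,exon_len,intron_len,expected",
        [
            # 239 bp DEL inside the last exon of a 37-exon plus-strand gene
            (_sv(chrom="12", start=53161161, end=53161400), 37, 1,
             53161100 - 36 * 1000, 400, 600, "EXON=37/37,STRAND=1"),
            # 153 bp DUP across intron 26 / exon 26 of a 44-exon minus-strand gene
            (_sv(chrom="7", start=24102759, end=24102912, svtype="DUP"), 44, -1,
             24084800, 300, 700, "EXON=26/44,INTRON=26/43,STRAND=-1"),
            # 89 bp DEL across exon 7 / intron 6 of a 16-exon minus-strand gene
            (_sv(chrom="6", start=57942591, end=57942680), 16, -1,
             57933341, 300, 700, "EXON=7/16,INTRON=6/15,STRAND=-1"),
            # 58 bp DEL in intron 1 of a 5-exon minus-strand gene
            (_sv(chrom="12", start=17659189, end=17659247), 5, -1,
             17655690, 300, 700, "INTRON=1/4,STRAND=-1"),
        ],
    )
    def test_reproduces_location_string(self, gene_factory, sv, n_exons, strand, origin,
                                        exon_len, intron_len, expected):
        gene = gene_factory(chrom=sv.chrom, origin=origin, n_exons=n_exons, strand=strand,
                            exon_len=exon_len, intron_len=intron_len)
        ann = classify_location(sv, [gene])
        assert ann.location_string == expected

    def test_reproduces_distance_string(self, gene_factory):
        # 309 bp DEL 1644 bp away from a plus-strand gene
        sv = _sv(chrom="12", start=39646645, end=39646954)
        gene = gene_factory(chrom="12", origin=39646954 + 1644, n_exons=3, strand=1)
        ann = classify_location(sv, [gene])
        assert ann.location_string == "DISTANCE=1644,STRAND=1"


class TestPredictImpact:
    @pytest.fixture
    def coding_gene(self):
        t = Transcript("t1", ((1000, 2000),), cds=((1100, 1900),),
                       utr5=((1000, 1099),), utr3=((1901, 2000),))
        return GeneModel("G1", "G1", "protein_coding", "1", 1, (t,))

    @pytest.fixture
    def two_exon_gene(self):
        t = Transcript("t1", ((1000, 1200), (1500, 1700)),
                       cds=((1000, 1200), (1500, 1700)))
        return GeneModel("G2", "G2", "protein_coding", "1", 1, (t,))

    def _impact(self, sv, genes):
        ann = classify_location(sv, genes)
        return predict_impact(sv, ann, genes)

    def test_cds_deletion_not_multiple_of_three_is_frameshift(self, coding_gene):
        # 89 bp deletion fully inside the CDS; 89 mod 3 == 2
        ann = self._impact(_sv(start=1200, end=1289), [coding_gene])
        assert "frameshift" in ann.consequences and ann.impact == "high"

    def test_inframe_cds_deletion_is_not_frameshift(self, coding_gene):
        ann = self._impact(_sv(start=1200, end=1290), [coding_gene])  # 90 bp
        assert "frameshift" not in ann.consequences

    def test_deletion_over_stop_codon_is_stop_lost(self, coding_gene):
        # covers the last CDS codon (1898-1900) and runs into the 3' UTR
        ann = self._impact(_sv(start=1890, end=1950), [coding_gene])
        assert "stop_lost" in ann.consequences and ann.impact == "high"

    def test_utr_insertion_is_modifier(self, coding_gene):
        ann = self._impact(_sv(start=1950, end=1950, svtype="INS", length=88), [coding_gene])
        assert ann.consequences == {"utr_change"} and ann.impact == "modifier"

    def test_boundary_spanning_deletion_is_splice_region(self, two_exon_gene):
        ann = self._impact(_sv(start=1150, end=1250), [two_exon_gene])
        assert "splice_region" in ann.consequences and ann.impact == "modifier"

    def test_intronic_deletion_near_splice_site(self, two_exon_gene):
        ann = self._impact(_sv(start=1201, end=1260), [two_exon_gene])
        assert "splice_region" in ann.consequences

    def test_deep_intronic_deletion_is_intron_variant(self, two_exon_gene):
        # 60 bp deletion > 8 bp from both splice sites
        ann = self._impact(_sv(start=1220, end=1280), [two_exon_gene])
        assert ann.consequences == {"intron_variant"} and ann.impact == "modifier"

    def test_flank_variant_is_regulatory(self, coding_gene):
        ann = self._impact(_sv(start=4000, end=4300), [coding_gene])
        assert ann.consequences == {"regulatory_region"} and ann.impact == "modifier"

    def test_intergenic_has_no_impact(self, coding_gene):
        ann = self._impact(_sv(start=500_000, end=500_300), [coding_gene])
        assert ann.consequences == {"intergenic_variant"} and ann.impact == "none"


class TestSummaries:
    def test_published_percentages_round_half_up(self):
        assert percent(378, 965) == 39.17
        assert percent(106, 965) == 10.98
        assert percent(8, 965) == 0.83
        assert percent(882, 965, ndigits=1) == 91.4
        assert percent(83, 965, ndigits=1) == 8.6

    def test_single_class_is_100_percent(self, toy_gene):
        svs = [_sv(start=210 + 100 * i, end=240 + 100 * i, id=f"sv_{i}") for i in range(1)]
        anns = annotate_all(svs, [toy_gene])
        table = location_summary(anns)
        assert table.loc["intron", "percent"] == 100.00
        assert table["count"].sum() == len(anns)

    def test_counts_sum_and_empty(self, toy_gene):
        svs = [
            _sv(start=150, end=180, id="a"),
            _sv(start=210, end=280, id="b"),
            _sv(start=9000, end=9100, id="c"),
        ]
        table = location_summary(annotate_all(svs, [toy_gene]))
        assert table["count"].sum() == 3
        assert location_summary([]).empty


class TestGff3RoundTrip:
    def test_write_then_read_preserves_structure(self, tmp_path, gene_factory):
        genes = [
            gene_factory(chrom="1", origin=10_000, n_exons=3, strand=1, gene_id="G0001"),
            gene_factory(chrom="2", origin=50_000, n_exons=4, strand=-1, gene_id="G0002"),
        ]
        # give the first gene a CDS + UTRs so all feature types appear
        t = genes[0].transcripts[0]
        t2 = Transcript(t.transcript_id, t.exons, cds=((10_100, 10_299),),
                        utr5=((10_000, 10_099),), utr3=())
        genes[0] = GeneModel("G0001", "G0001", "protein_coding", "1", 1, (t2,))
        path = tmp_path / "genes.gff3"
        write_gff3(genes, path)
        back = read_gff3(path)
        assert [(g.gene_id, g.chrom, g.strand, g.biotype) for g in back] == [
            (g.gene_id, g.chrom, g.strand, g.biotype) for g in genes
        ]
        for got, want in zip(back, genes):
            assert got.transcripts[0].exons == want.transcripts[0].exons
            assert got.transcripts[0].cds == want.transcripts[0].cds
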