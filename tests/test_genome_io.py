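"""Format ingest/round-trip behaviour and quality filters."""

import gzip

import pytest

from irtopo import genome_io
from irtopo.genome_io import (
    FormatError,
    GeneRecord,
    GenomeSequence,
    SnvSite,
    read_bed,
    read_fasta,
    read_gff3,
    read_lineage_tsv,
    read_vcf_filtered,
    write_ir_bed,
)
from irtopo.ir_detection import InvertedRepeat


class TestFasta:
    def test_case_normalization(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nacgtn\n")
        (rec,) = read_fasta(p)
        assert rec.residues == "ACGTN"

    def test_iupac_mapped_to_n(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACRT\n")
        (rec,) = read_fasta(p)
        assert rec.residues == "ACNT"

    def test_two_records_in_order(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">one\nACGT\n>two\nGGCC\n")
        recs = read_fasta(p)
        assert [r.seq_id for r in recs] == ["one", "two"]

    def test_gzip_supported(self, tmp_path):
        p = tmp_path / "a.fa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">a\nACGT\n")
        assert read_fasta(p)[0].residues == "ACGT"

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_malformed_header_raises(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n")
        with pytest.raises(FormatError, match="line 1"):
            read_fasta(p)

    def test_round_trip(self, tmp_path):
        seqs = [GenomeSequence("a", "ACGTN" * 30), GenomeSequence("b", "GGCC")]
        p = tmp_path / "rt.fa"
        genome_io.write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(s.seq_id, s.residues) for s in back] == [
            (s.seq_id, s.residues) for s in seqs
        ]


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\nx\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        (g,) = read_gff3(p)
        assert (g.start, g.end) == (100, 200)
        assert g.end - g.start == 200 - 101 + 1

    def test_missing_exons_filled_in(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("x\t.\tgene\t11\t100\t.\t-\t.\tID=g1\n")
        (g,) = read_gff3(p)
        assert g.exons == [(10, 100)]

    def test_cds_outside_exon_extends_union(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "x\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "x\t.\texon\t1\t50\t.\t+\t.\tParent=g1\n"
            "x\t.\tCDS\t61\t90\t.\t+\t0\tParent=g1\n"
        )
        (g,) = read_gff3(p)
        assert (60, 90) in g.cds
        assert any(s <= 60 and 90 <= e for s, e in g.exons)

    def test_unknown_parent_skipped(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "x\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "x\t.\texon\t1\t50\t.\t+\t.\tParent=nope\n"
        )
        (g,) = read_gff3(p)
        assert g.exons == [(0, 100)]  # fill-in kicks in, orphan dropped

    def test_end_before_start_raises(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("x\t.\tgene\t200\t100\t.\t+\t.\tID=g1\n")
        with pytest.raises(FormatError):
            read_gff3(p)

    def test_write_read_idempotent(self, tmp_path):
        genes = [
            GeneRecord("g1", "x", 100, 400, "+", "protein_coding",
                       exons=[(100, 200), (250, 400)], cds=[(150, 200), (250, 350)]),
            GeneRecord("g2", "x", 500, 650, "-", "non_coding", exons=[(500, 650)]),
        ]
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        genome_io.write_gff3(genes, p1)
        back = read_gff3(p1)
        genome_io.write_gff3(back, p2)
        assert read_gff3(p2) == back
        assert [(g.gene_id, g.start, g.end, g.exons, g.cds) for g in back] == [
            (g.gene_id, g.start, g.end, g.exons, g.cds) for g in genes
        ]


class TestVcfFilter:
    def _write(self, tmp_path, body):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="MQ">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + body
        )
        return p

    def test_mq_boundary_exclusive_below(self, tmp_path):
        p = self._write(tmp_path, "chr1\t10\t.\tA\tG\t99\t.\tMQ=49\n")
        assert read_vcf_filtered(p) == []

    def test_boundary_inclusive(self, tmp_path):
        p = self._write(tmp_path, "chr1\t10\t.\tA\tG\t60\t.\tMQ=50\n")
        (s,) = read_vcf_filtered(p)
        assert (s.pos, s.ref_base, s.alt_base) == (9, "A", "G")

    def test_low_qual_excluded(self, tmp_path):
        p = self._write(tmp_path, "chr1\t10\t.\tA\tG\t59\t.\tMQ=60\n")
        assert read_vcf_filtered(p) == []

    def test_indels_excluded(self, tmp_path):
        p = self._write(
            tmp_path,
            "chr1\t10\t.\tAT\tA\t99\t.\tMQ=60\n"
            "chr1\t20\t.\tA\tAGG\t99\t.\tMQ=60\n",
        )
        assert read_vcf_filtered(p) == []

    def test_multiallelic_split_per_alt(self, tmp_path):
        p = self._write(tmp_path, "chr1\t10\t.\tA\tG,T\t99\t.\tMQ=60\n")
        sites = read_vcf_filtered(p)
        assert sorted(s.alt_base for s in sites) == ["G", "T"]
        assert {s.pos for s in sites} == {9}

    def test_missing_mq_dropped(self, tmp_path):
        p = self._write(tmp_path, "chr1\t10\t.\tA\tG\t99\t.\t.\n")
        assert read_vcf_filtered(p) == []

    def test_write_round_trip(self, tmp_path):
        sites = [
            SnvSite("chr1", 9, "A", "G", 60.0, 100.0),
            SnvSite("chr1", 42, "C", "T", 55.0, 80.0),
        ]
        p = tmp_path / "rt.vcf"
        genome_io.write_vcf(sites, p, contigs={"chr1": 1000})
        assert read_vcf_filtered(p) == sites


class TestBed:
    def test_ir_bed_line_format(self, tmp_path):
        ir = InvertedRepeat("chr1", 100, 124, 10, 4, "ACCTGAGCGA", "TTTT", "TCGCTCAGGT")
        p = tmp_path / "irs.bed"
        write_ir_bed([ir], p)
        assert p.read_text() == "chr1\t100\t124\tIR:arm=10;spacer=4\t10\t.\n"

    def test_round_trip(self, tmp_path):
        irs = [
            InvertedRepeat("c", 0, 24, 10, 4, "ACCTGAGCGA", "TTTT", "TCGCTCAGGT"),
            InvertedRepeat("c", 50, 70, 10, 0, "ACCTGAGCGA", "", "TCGCTCAGGT"),
            InvertedRepeat("d", 5, 33, 10, 8, "ACCTGAGCGA", "AAAAAAAA", "TCGCTCAGGT"),
        ]
        p = tmp_path / "irs.bed"
        write_ir_bed(irs, p)
        rows = read_bed(p)
        assert [(r[0], r[1], r[2]) for r in rows] == [(i.seq_id, i.start, i.end) for i in irs]
        assert rows[0][3] == "IR:arm=10;spacer=4"

    def test_empty_set_empty_file(self, tmp_path):
        p = tmp_path / "irs.bed"
        write_ir_bed([], p)
        assert p.read_text() == ""
        assert read_bed(p) == []

    def test_malformed_line_raises(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(FormatError):
            read_bed(p)


class TestLineage:
    HEADER = "assembly_id\tspecies\tfamily\tphylum\tkingdom\tdomain\n"

    def test_two_rows(self, tmp_path):
        p = tmp_path / "lin.tsv"
        p.write_text(
            self.HEADER
            + "GCF_1\tEscherichia coli\tEnterobacteriaceae\tPseudomonadota\t\tBacteria\n"
            + "GCF_2\tBacillus subtilis\tBacillaceae\tBacillota\t\tBacteria\n"
        )
        recs = read_lineage_tsv(p)
        assert len(recs) == 2
        assert recs[0].kingdom == ""
        assert recs[1].phylum == "Bacillota"

    def test_duplicate_assembly_raises(self, tmp_path):
        p = tmp_path / "lin.tsv"
        p.write_text(self.HEADER + "GCF_1\ta\t\t\t\t\nGCF_1\tb\t\t\t\t\n")
        with pytest.raises(FormatError):
            read_lineage_tsv(p)
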