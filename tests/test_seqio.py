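"""Format I/O: FASTQ dialect handling, quality conversion, csfasta pairing,
BED/SAM/VCF round trips."""
import io

import pytest
from Bio.SeqIO import QualityIO
from hypothesis import given, settings
from hypothesis import strategies as st

from exopipe import seqio
from exopipe.model import GenomicInterval, SequenceRead, VariantRecord

from .conftest import make_aln, make_read
from .oracles import solexa_to_phred_via_probability


class TestDialectDetection:
    @pytest.mark.parametrize(
        "lines,expected",
        [
            (["II!I"], "sanger"),          # '!' (33) only valid in Phred+33
            ([";>=<"], "solexa"),          # ';' (59) below the Illumina floor
            (["hhhgf"], "illumina13"),     # ambiguous range -> default
        ],
    )
    def test_examples(self, lines, expected):
        assert seqio.detect_fastq_dialect(lines, default="illumina13") == expected

    def test_ambiguous_range_returns_supplied_default(self):
        line = "".join(chr(c) for c in range(66, 105))
        assert seqio.detect_fastq_dialect([line], default="sanger") == "sanger"
        assert seqio.detect_fastq_dialect([line], default="solexa") == "solexa"

    def test_out_of_range_character_names_code_point(self):
        with pytest.raises(seqio.FormatError, match="31"):
            seqio.detect_fastq_dialect(["II\x1f"])

    def test_empty_sample_rejected(self):
        with pytest.raises(seqio.FormatError):
            seqio.detect_fastq_dialect([""])


class TestQualityConversion:
    def test_sanger_identity(self):
        assert seqio.convert_quality(40, "sanger", "sanger") == 40

    def test_solexa_zero_maps_to_phred_three(self):
        # 10*log10(10^0 + 1) = 3.0103 -> 3
        assert seqio.convert_quality(0, "solexa", "sanger") == 3

    def test_illumina13_offset_arithmetic(self):
        # char 'h' (104) in Phred+64 is q40; Sanger q40 is 'I' (73)
        q = 104 - 64
        assert seqio.convert_quality(q, "illumina13", "sanger") == 40
        assert chr(40 + 33) == "I"

    def test_solexa_range_matches_probability_oracle(self):
        for q in range(-5, 63):
            assert seqio.convert_quality(q, "solexa", "sanger") == \
                solexa_to_phred_via_probability(q)

    def test_matches_biopython_table(self):
        # independent published conversion (round-half-up on both sides)
        for q in range(-5, 63):
            expected = round(QualityIO.phred_quality_from_solexa(q))
            assert seqio.convert_quality(q, "solexa", "sanger") == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            seqio.convert_quality(-6, "solexa", "sanger")
        with pytest.raises(ValueError):
            seqio.convert_quality(94, "sanger", "illumina13")

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(-5, 61), st.sampled_from(["sanger", "illumina13"]))
    def test_monotone_non_decreasing(self, q, target):
        assert seqio.convert_quality(q, "solexa", target) <= \
            seqio.convert_quality(q + 1, "solexa", target)

    def test_converges_to_identity_above_q10(self):
        for q in range(10, 63):
            assert abs(seqio.convert_quality(q, "solexa", "sanger") - q) <= 1


class TestFastq:
    def test_round_trip_sanger_byte_identical(self):
        text = "@r1 lane1\nACGTN\n+\nIIII!\n@r2\nGGCC\n+\n!!II\n"
        reads = list(seqio.read_fastq(io.StringIO(text)))
        out = io.StringIO()
        assert seqio.write_fastq(reads, out) == 2
        assert out.getvalue() == text

    def test_read_converts_nothing_writes_sanger(self):
        # Illumina 1.3+ 'h' = q40 must come out as Sanger 'I'
        text = "@r1\nACGT\n+\nhhhh\n"
        reads = list(seqio.read_fastq(io.StringIO(text), "illumina13"))
        assert reads[0].quals == [40, 40, 40, 40]
        out = io.StringIO()
        seqio.write_fastq(reads, out)
        assert "IIII" in out.getvalue()

    @pytest.mark.parametrize(
        "name,expected",
        [("sample_R1.fastq", "R1"), ("sample_R2.fq.gz", "R2"),
         ("sample.fastq", "none")],
    )
    def test_mate_inference_from_filename(self, name, expected):
        assert seqio.infer_mate(name) == expected


class TestCsfastaQual:
    def test_positional_pairing(self):
        cs = io.StringIO("# solid run\n>r1\nT0123\n>r2\nG3210\n")
        ql = io.StringIO(">r1\n20 21 22 23\n>r2\n9 8 7 6\n")
        reads = list(seqio.read_csfasta_qual(cs, ql))
        assert len(reads) == 2
        assert reads[0].bases == "T0123"
        assert reads[0].quals == [20, 21, 22, 23]
        assert reads[0].encoding == "solid"
        assert len(reads[0]) == 4  # adapter base carries no quality

    def test_count_mismatch_names_divergent_record(self):
        cs = io.StringIO(">r1\nT0123\n>r2\nG3210\n")
        ql = io.StringIO(">r1\n20 21 22 23\n")
        with pytest.raises(seqio.PairingError, match="r2"):
            list(seqio.read_csfasta_qual(cs, ql))

    def test_id_mismatch(self):
        cs = io.StringIO(">r1\nT0123\n")
        ql = io.StringIO(">rX\n20 21 22 23\n")
        with pytest.raises(seqio.PairingError, match="rX"):
            list(seqio.read_csfasta_qual(cs, ql))

    def test_empty_files_yield_nothing(self):
        assert list(seqio.read_csfasta_qual(io.StringIO(""), io.StringIO(""))) == []


class TestBed:
    def test_parse_and_normalize(self):
        text = "track name=x\nchr1\t10\t20\tA\nchr1\t15\t30\tB\nchr2\t0\t5\n"
        ivs = seqio.read_bed(io.StringIO(text))
        assert ivs[0] == GenomicInterval("chr1", 10, 20, "A")
        merged = seqio.normalize_targets(ivs)
        assert [(i.chrom, i.start, i.end) for i in merged] == [
            ("chr1", 10, 30), ("chr2", 0, 5)
        ]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            seqio.read_bed(io.StringIO("chr1\t20\t10\n"))


class TestSamVcf:
    def test_sam_round_trip(self, tmp_path):
        records = [
            make_aln("a", pos=100, cigar="5S45M", quals=[30] * 50),
            make_aln("b", flag=4, rname=None, pos=0, cigar=""),
        ]
        path = tmp_path / "x.sam"
        assert seqio.write_sam(records, path, {"chr1": 10_000}) == 2
        back = list(seqio.read_sam(path))
        assert back[0].qname == "a" and back[0].pos == 100
        assert back[0].cigar == [("S", 5), ("M", 45)]
        assert back[1].is_unmapped and back[1].rname is None
        assert seqio.read_sam_header(path) == {"chr1": 10_000}

    def test_vcf_round_trip_with_genotypes(self, tmp_path):
        v = VariantRecord("chr1", 50, "rs1", "A", "G", qual=99.0,
                          genotype=(0, 1), depth=30, alt_depth=14,
                          annotations={"RefSeq": "NM_1", "Func": "exonic"})
        path = tmp_path / "x.vcf"
        seqio.write_vcf([v], path, {"chr1": 10_000})
        back = list(seqio.read_vcf(path))
        assert len(back) == 1
        b = back[0]
        assert (b.chrom, b.pos, b.vid, b.ref, b.alt) == ("chr1", 50, "rs1", "A", "G")
        assert b.genotype == (0, 1) and b.depth == 30 and b.alt_depth == 14
        assert b.annotations["RefSeq"] == "NM_1"

    def test_multiallelic_split_keeps_het_visible(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts\n"
            "chr1\t10\t.\tA\tG,T\t50\t.\t.\tGT\t1/2\n"
        )
        rows = list(seqio.read_vcf(path))
        assert len(rows) == 2
        assert all(r.genotype[0] != r.genotype[1] for r in rows)
        assert [r.alt for r in rows] == ["G", "T"]
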