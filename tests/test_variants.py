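"""Variant classification, zygosity splitting, Ti/Tv, association rates and
annotation merging."""
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exopipe import synthdata, variants as vr
from exopipe.model import VariantRecord


def snp(ref="A", alt="G", gt=(0, 1), vid=".", ann=None, depth=40, alt_depth=20):
    return VariantRecord("chr1", 100, vid, ref, alt, genotype=gt, depth=depth,
                         alt_depth=alt_depth, annotations=ann or {})


def dip(ref="A", alt="ACT", depth=10, alt_depth=5, ann=None):
    return VariantRecord("chr1", 200, ".", ref, alt, genotype=(0, 1),
                         depth=depth, alt_depth=alt_depth,
                         annotations=ann or {})


class TestClassification:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "G", "SNP"), ("A", "ACT", "insertion"), ("ACT", "A", "deletion")],
    )
    def test_by_allele_length(self, ref, alt, expected):
        assert vr.classify_variant(ref, alt) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            vr.classify_variant("A", "A")


class TestSnpZygosity:
    @pytest.mark.parametrize("gt,expected", [((1, 1), "hom"), ((0, 1), "het"),
                                             ((2, 2), "hom"), ((1, 2), "het")])
    def test_genotype_rules(self, gt, expected):
        assert vr.split_zygosity_snp(snp(gt=gt)) == expected

    def test_missing_genotype_is_unclassifiable(self):
        split = vr.split_zygosity([snp(gt=None)])
        assert len(split.unclassifiable) == 1


class TestDipZygosity:
    @pytest.mark.parametrize(
        "alt_depth,dsP,expected",
        [(8, 80, "hom"),   # boundary inclusive: 80% >= 80
         (7, 80, "het"),
         (0, 0, "hom")],   # dsP 0: everything homozygous
    )
    def test_boundary_rules(self, alt_depth, dsP, expected):
        assert vr.split_zygosity_dip(dip(depth=10, alt_depth=alt_depth), dsP) \
            == expected

    def test_zero_depth_routed_to_unclassifiable(self):
        v = dip(depth=0, alt_depth=0)
        split = vr.split_zygosity([v], 80)
        assert split.unclassifiable == [v]

    def test_ref_alt_denominator_switch(self):
        v = VariantRecord("chr1", 5, ".", "A", "AT", genotype=(0, 1),
                          depth=20, alt_depth=8, ref_depth=2)
        assert vr.split_zygosity_dip(v, 80) == "het"           # 8/20 = 40%
        assert vr.split_zygosity_dip(v, 80, use_ref_alt_depth=True) == "hom"

    def test_partition_exhaustive_and_monotone_in_dsP(self):
        _, dips = synthdata.gen_vcf(synthdata.FixturePlan(seed=13, n_snps=0,
                                                          n_dips=150))
        previous = None
        for dsP in range(0, 101, 5):
            split = vr.split_zygosity(dips, dsP)
            assert len(split.homozygous) + len(split.heterozygous) == len(dips)
            if previous is not None:
                assert len(split.homozygous) <= previous
            previous = len(split.homozygous)


class TestTiTv:
    def test_mixed_set(self):
        snps = [snp("A", "G"), snp("C", "T"), snp("A", "C")]
        assert vr.titv_ratio(snps) == pytest.approx(2.0)

    def test_zero_transversions_is_na(self):
        assert vr.titv_ratio([snp("A", "G")]) is None

    def test_planted_ratio_exact(self):
        snps, _ = synthdata.gen_vcf(synthdata.FixturePlan(seed=4, n_snps=3000,
                                                          titv=2.0, n_dips=0))
        assert vr.titv_ratio(snps) == pytest.approx(2.0, abs=0)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.sampled_from([("A", "G"), ("C", "T"), ("A", "C"),
                                     ("G", "T"), ("T", "A")]),
                    min_size=1, max_size=30))
    def test_invariant_under_strand_complement(self, pairs):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        fwd = [snp(r, a) for r, a in pairs]
        rev = [snp(comp[r], comp[a]) for r, a in pairs]
        assert vr.titv_counts(fwd) == vr.titv_counts(rev)


class TestAssociationRates:
    def test_db_fractions(self):
        records = [snp(vid="rs1"), snp(vid="rs2"), snp(vid="rs3"), snp(vid=".")]
        dbsnp, refseq = vr.association_rates(records)
        assert dbsnp == pytest.approx(0.75)
        assert refseq == 0.0

    def test_empty_and_fully_annotated(self):
        assert vr.association_rates([]) == (0.0, 0.0)
        records = [snp(vid="rs1", ann={"RefSeq": "NM_1"})]
        assert vr.association_rates(records) == (1.0, 1.0)


class TestMergeAnnotationTables:
    def _tables(self):
        key = {"chrom": ["chr1", "chr1"], "pos": [10, 20],
               "ref": ["A", "C"], "alt": ["G", "T"]}
        gatk = pd.DataFrame({**key, "Gene": ["X", "Y"], "GO": ["a", "b"]})
        annovar = pd.DataFrame({**key, "Gene": ["X2", "Y2"], "SIFT": [0.1, 0.9]})
        return gatk, annovar

    def test_outer_join_prefixes_collisions(self):
        gatk, annovar = self._tables()
        merged = vr.merge_annotation_tables(gatk, annovar)
        assert len(merged) == 2
        assert {"gatk.Gene", "annovar.Gene", "GO", "SIFT"} <= set(merged.columns)

    def test_key_only_in_secondary_retained(self):
        gatk, annovar = self._tables()
        extra = pd.DataFrame({"chrom": ["chr2"], "pos": [5], "ref": ["G"],
                              "alt": ["C"], "Gene": ["Z"], "SIFT": [0.5]})
        merged = vr.merge_annotation_tables(gatk, pd.concat([annovar, extra]))
        row = merged[merged.chrom == "chr2"].iloc[0]
        assert row["annovar.Gene"] == "Z" and pd.isna(row["gatk.Gene"])

    def test_sorted_by_position(self):
        gatk, annovar = self._tables()
        merged = vr.merge_annotation_tables(gatk.iloc[::-1], annovar)
        assert list(merged.pos) == [10, 20]

    def test_duplicate_keys_rejected(self):
        gatk, annovar = self._tables()
        bad = pd.concat([gatk, gatk.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            vr.merge_annotation_tables(bad, annovar)

    def test_role_swap_permutes_prefixes_only(self):
        gatk, annovar = self._tables()
        ab = vr.merge_annotation_tables(gatk, annovar)
        ba = vr.merge_annotation_tables(annovar, gatk)
        rename = {"gatk.Gene": "annovar.Gene", "annovar.Gene": "gatk.Gene"}
        assert sorted(ab.columns) == sorted(ba.rename(columns=rename).columns)
        pd.testing.assert_frame_equal(
            ab.sort_index(axis=1),
            ba.rename(columns=rename).sort_index(axis=1),
            check_like=True,
        )


class TestSummaries:
    def test_planted_fractions_recovered(self):
        plan = synthdata.FixturePlan(seed=21, n_snps=400, titv=3.0,
                                     snp_hom_fraction=0.25,
                                     snp_dbsnp_fraction=0.8, n_dips=120,
                                     dip_hom_fraction=0.4,
                                     dip_refseq_fraction=0.95,
                                     dip_coding_fraction=0.5)
        snps, dips = synthdata.gen_vcf(plan)
        summary = vr.variant_summaries(snps, dips, dsP=80)
        assert summary.n_snps == 400 and summary.n_dips == 120
        assert summary.n_deletions + summary.n_insertions == 120
        assert summary.dbsnp_fraction == pytest.approx(0.8)
        assert summary.titv == pytest.approx(3.0)
        assert summary.n_hom_snp == 100
        assert summary.n_hom_dip == 48
        assert summary.dip_refseq_fraction == pytest.approx(0.95)
        assert summary.n_dip_coding == 60
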