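"""Alignment filters: mapping, proper-pair, duplicate marking (vs O(N^2)
oracle) and exome overlap (vs per-base oracle)."""
import numpy as np
import pytest

from exopipe import alnfilter as af
from exopipe.model import (
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_SECONDARY,
    FLAG_UNMAPPED,
    GenomicInterval,
)

from .conftest import make_aln, random_alignment, random_intervals, random_pair
from .oracles import brute_force_duplicates, on_target_oracle


class TestMappingAndProperPair:
    def test_unmapped_and_secondary_removed(self):
        records = [make_aln("a"), make_aln("b"), make_aln("c"),
                   make_aln("d", flag=FLAG_UNMAPPED, rname=None, pos=0, cigar=""),
                   make_aln("e", flag=FLAG_UNMAPPED, rname=None, pos=0, cigar="")]
        kept, acc = af.filter_unmapped(records)
        assert (acc.input_count, acc.passed_count, acc.removed_count) == (5, 3, 2)
        kept2, _ = af.filter_unmapped([make_aln("s", flag=FLAG_SECONDARY)])
        assert kept2 == []

    def test_proper_pair_filter(self):
        proper = make_aln("p", flag=FLAG_PAIRED | FLAG_PROPER_PAIR)
        improper = make_aln("q", flag=FLAG_PAIRED)
        kept, acc = af.filter_proper_pair([proper, improper])
        assert [r.qname for r in kept] == ["p"]
        assert acc.removed_count == 1

    def test_proper_pair_noop_for_single_end(self):
        records = [make_aln("a"), make_aln("b")]
        kept, acc = af.filter_proper_pair(records)
        assert len(kept) == 2 and acc.removed_count == 0


class TestDuplicateMarking:
    def test_same_position_same_strand_flags_one(self):
        a = make_aln("a", pos=100, quals=[30] * 50)
        b = make_aln("b", pos=100, quals=[20] * 50)
        marked, acc = af.mark_duplicates([a, b])
        assert [r.is_duplicate for r in marked] == [False, True]
        assert acc.removed_count == 1

    def test_opposite_strands_not_duplicates(self):
        a = make_aln("a", pos=100)
        b = make_aln("b", pos=100, flag=0x10)
        marked, _ = af.mark_duplicates([a, b])
        assert not any(r.is_duplicate for r in marked)

    def test_soft_clip_unclipped_start_equality(self):
        # forward 5S95M at pos 100 has unclipped start 95, same as 100M at 95
        a = make_aln("a", pos=100, cigar="5S95M", quals=[20] * 100)
        b = make_aln("b", pos=95, cigar="100M", quals=[30] * 100)
        assert af.duplicate_key(a) == af.duplicate_key(b)
        marked, acc = af.mark_duplicates([a, b])
        assert [r.is_duplicate for r in marked] == [True, False]  # b higher qual

    def test_tie_breaks_on_smallest_qname(self):
        a = make_aln("zzz", pos=10, quals=[30] * 50)
        b = make_aln("aaa", pos=10, quals=[30] * 50)
        marked, _ = af.mark_duplicates([a, b])
        flagged = {r.qname for r in marked if r.is_duplicate}
        assert flagged == {"zzz"}

    def test_pe_pairs_flagged_as_units(self, rng):
        a1, a2 = random_pair(rng, "fragA")
        b1, b2 = random_pair(rng, "fragB")
        # make fragB a coordinate copy of fragA with lower qualities
        for src, dst in ((a1, b1), (a2, b2)):
            dst.pos, dst.cigar, dst.flag = src.pos, list(src.cigar), src.flag
            dst.quals = [5] * len(src.quals)
        b1.flag, b2.flag = a1.flag, a2.flag
        b1.qname = b2.qname = "fragB"
        marked, acc = af.mark_duplicates([a1, a2, b1, b2])
        assert {r.qname for r in marked if r.is_duplicate} == {"fragB"}
        assert acc.removed_count == 2

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        records = []
        n = int(rng.integers(20, 120))
        for i in range(n):
            if rng.random() < 0.3:
                records.extend(random_pair(rng, f"p{i}", genome_length=2_000))
            else:
                records.append(random_alignment(rng, f"s{i}", genome_length=2_000))
        marked, _ = af.mark_duplicates(records)
        flagged = {i for i, r in enumerate(marked) if r.is_duplicate}
        oracle_flagged, oracle_kept = brute_force_duplicates(records)
        assert flagged == oracle_flagged
        assert sorted(set(range(len(records))) - flagged) == oracle_kept

    def test_order_independent(self, rng):
        records = [random_alignment(rng, f"r{i}", genome_length=500)
                   for i in range(60)]
        marked, _ = af.mark_duplicates(records)
        truth = {r.qname: r.is_duplicate for r in marked}
        perm = list(rng.permutation(len(records)))
        shuffled, _ = af.mark_duplicates([records[i] for i in perm])
        assert {r.qname: r.is_duplicate for r in shuffled} == truth

    def test_exactly_one_kept_per_group(self, rng):
        records = [random_alignment(rng, f"r{i}", genome_length=300)
                   for i in range(80)]
        marked, _ = af.mark_duplicates(records)
        groups = {}
        for r in marked:
            groups.setdefault(af.duplicate_key(r), []).append(r)
        for group in groups.values():
            assert sum(not r.is_duplicate for r in group) == 1


class TestOnTarget:
    targets = [GenomicInterval("chr1", 140, 200)]

    def test_overlap_kept_half_open_removed(self):
        inside = make_aln("a", pos=101, cigar="50M")   # [100,150): 10 bases in
        outside = make_aln("b", pos=101, cigar="40M")  # [100,140): zero overlap
        kept, acc = af.filter_on_target([inside, outside], self.targets)
        assert [r.qname for r in kept] == ["a"]
        assert acc.removed_count == 1

    def test_deletion_consumes_reference_inside_target(self):
        # footprint [100,240) via 20M100D20M starting at pos 101;
        # target sits wholly inside the deletion gap
        rec = make_aln("d", pos=101, cigar="20M100D20M")
        kept, _ = af.filter_on_target([rec], [GenomicInterval("chr1", 150, 190)])
        assert kept == [rec]

    def test_min_overlap_threshold(self):
        rec = make_aln("a", pos=101, cigar="50M")  # 10 bases on target
        kept, _ = af.filter_on_target([rec], self.targets, min_overlap=10)
        assert kept == [rec]
        kept, _ = af.filter_on_target([rec], self.targets, min_overlap=11)
        assert kept == []

    def test_unknown_chromosome_counts_off_target(self):
        rec = make_aln("a", rname="chrUn", pos=150, cigar="50M")
        kept, acc = af.filter_on_target([rec], self.targets)
        assert kept == [] and acc.removed_count == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_per_base_oracle(self, trial):
        rng = np.random.default_rng(2000 + trial)
        intervals = random_intervals(rng)
        records = [random_alignment(rng, f"r{i}") for i in range(100)]
        for min_overlap in (1, 5):
            kept, _ = af.filter_on_target(records, intervals, min_overlap)
            expected = [r for r in records
                        if on_target_oracle(r, intervals, min_overlap)]
            assert [r.qname for r in kept] == [r.qname for r in expected]


class TestFilterChain:
    def test_stage_order_and_composition(self, rng):
        from exopipe import synthdata
        plan = synthdata.FixturePlan(seed=11, n_reads=300, n_duplicates=20,
                                     n_unmapped=15)
        fx = synthdata.generate(plan)
        kept, accounting = af.run_alnfilter(fx.alignments, fx.targets)
        names = [a.stage_name for a in accounting]
        assert names == ["mapping-filter", "proper-pair-filter",
                         "duplicate-filter", "exome-filter"]
        assert accounting[0].removed_count == 15
        assert accounting[2].removed_count == 20
        for prev, nxt in zip(accounting[:-1], accounting[1:]):
            assert prev.passed_count == nxt.input_count
        assert len(kept) == accounting[-1].passed_count
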