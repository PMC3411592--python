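"""Seeded synthetic-data generator with planted, recoverable ground truth.

Every generator draws from a single ``numpy.random.default_rng`` (PCG64 —
the algorithm is pinned so fixtures are byte-stable across platforms) seeded
from the plan, so a plan fully determines its output.

What is planted, and how it is recovered downstream:

* reads whose length, N content or low-quality content make them fail
  exactly one preprocessing stage at the default thresholds — per-stage
  accounting recovers the planted counts exactly;
* alignments with an on-target placement probability, extra copies sharing
  a duplicate key (flagged count equals the number of extra copies when
  base fragments occupy unique start sites), unmapped records, and
  improperly paired mates;
* variants with exact transition/transversion counts, homozygous fractions
  (genotypes for SNPs, boundary-avoiding allele fractions for DIPs),
  dbSNP membership and RefSeq/coding annotations.

Counts asserted exactly by tests are planted exactly by construction;
fractions asserted against confidence intervals are sampled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .model import (
    FLAG_FIRST_IN_PAIR,
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_REVERSE,
    FLAG_SECOND_IN_PAIR,
    FLAG_UNMAPPED,
    AlignmentRecord,
    GenomicInterval,
    SequenceRead,
)
from . import seqio

_BASES = np.array(list("ACGT"))
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = [
    ("A", "C"), ("A", "T"), ("C", "A"), ("C", "G"),
    ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G"),
]


@dataclass
class FixturePlan:
    """Everything a fixture run needs; defaults give a desk-scale exome:
    a 100 kb genome with 50 exons of 200 bp (10% capture target), 75 bp
    reads, and variant counts small enough for sub-second tests."""

    seed: int = 1
    # reference
    chrom: str = "chr1"
    genome_length: int = 100_000
    n_targets: int = 50
    target_length: int = 200
    # reads (preprocessing fixtures)
    n_good_reads: int = 1_000
    read_length: int = 75
    paired: bool = False
    fail_length: int = 0  # reads shorter than the 25 bp minimum
    fail_nmax: int = 0    # reads with >5% interior Ns
    fail_quality: int = 0  # reads with >5% positions below Phred 20
    # alignments
    n_reads: int = 2_000
    on_target_fraction: float = 0.4
    n_duplicates: int = 0   # extra copies sharing a duplicate key
    n_unmapped: int = 0
    n_improper_pairs: int = 0  # PE only
    insert_mean: float = 200.0
    insert_sd: float = 20.0
    unique_start_sites: bool = True  # avoid chance duplicate collisions
    # variants
    n_snps: int = 3_000
    titv: float = 2.0
    snp_hom_fraction: float = 0.3
    snp_dbsnp_fraction: float = 0.85
    n_dips: int = 200
    dip_hom_fraction: float = 0.3
    dsP: float = 80.0
    dip_refseq_fraction: float = 0.99
    dip_coding_fraction: float = 0.5

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def start_sites(self) -> int:
        """Distinct (strand, position) fragment starts available to
        :func:`gen_alignments` on-target placement: both strands times the
        positions where a read fits inside a target."""
        per_target = self.target_length - self.read_length + 1
        return 2 * self.n_targets * max(per_target, 0)


# --------------------------------------------------------------------------
# Reference + targets
# --------------------------------------------------------------------------


def gen_reference(
    plan: FixturePlan, rng: Optional[np.random.Generator] = None
) -> tuple[str, list[GenomicInterval]]:
    """Random genome plus evenly spaced, non-overlapping target intervals."""
    rng = rng or plan.rng()
    if plan.n_targets * plan.target_length > plan.genome_length:
        raise ValueError("targets do not fit into the genome")
    genome = "".join(rng.choice(_BASES, size=plan.genome_length))
    slot = plan.genome_length // plan.n_targets
    targets = []
    for i in range(plan.n_targets):
        wiggle = slot - plan.target_length
        offset = int(rng.integers(0, max(wiggle, 1)))
        start = i * slot + offset
        targets.append(
            GenomicInterval(plan.chrom, start, start + plan.target_length,
                            f"exon{i + 1:04d}")
        )
    return genome, targets


# --------------------------------------------------------------------------
# Reads
# --------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _good_read(rng: np.random.Generator, rid: str, length: int, mate: str
               ) -> SequenceRead:
    quals = [int(q) for q in rng.integers(30, 41, size=length)]
    return SequenceRead(rid, _random_bases(rng, length), quals, "sanger", mate)


def _length_fail(rng, rid, mate):
    return _good_read(rng, rid, 20, mate)  # < 25 bp minimum


def _nmax_fail(rng, rid, length, mate):
    read = _good_read(rng, rid, length, mate)
    n_ns = math.ceil(0.10 * length)  # 10% > the 5% ceiling
    # interior positions only, so end-trimming cannot rescue the read
    pos = rng.choice(np.arange(1, length - 1), size=n_ns, replace=False)
    bases = list(read.bases)
    for p in pos:
        bases[int(p)] = "N"
    read.bases = "".join(bases)
    return read


def _quality_fail(rng, rid, length, mate):
    read = _good_read(rng, rid, length, mate)
    n_low = math.ceil(0.10 * length)
    pos = rng.choice(np.arange(1, length - 1), size=n_low, replace=False)
    for p in pos:
        read.quals[int(p)] = 10  # < 20, but not the RSQCI value 2
    return read


def gen_reads(
    plan: FixturePlan, rng: Optional[np.random.Generator] = None
) -> tuple[list[SequenceRead], Optional[list[SequenceRead]]]:
    """Reads whose preprocessing fate is planted per stage.

    Each failing read passes every stage before the one it is planted to
    fail.  For paired data the failure is planted on the R2 mate, so each
    planted failure removes a pair (two reads) at its stage.
    """
    rng = rng or plan.rng()
    L = plan.read_length
    makers = (
        [("good", None)] * plan.n_good_reads
        + [("length", _length_fail)] * plan.fail_length
        + [("nmax", lambda r, i, m: _nmax_fail(r, i, L, m))] * plan.fail_nmax
        + [("quality", lambda r, i, m: _quality_fail(r, i, L, m))] * plan.fail_quality
    )
    order = rng.permutation(len(makers))
    r1: list[SequenceRead] = []
    r2: Optional[list[SequenceRead]] = [] if plan.paired else None
    for serial, idx in enumerate(order):
        kind, maker = makers[int(idx)]
        rid = f"read{serial:06d}"
        if plan.paired:
            r1.append(_good_read(rng, rid, L, "R1"))
            if kind == "good":
                r2.append(_good_read(rng, rid, L, "R2"))
            elif kind == "length":
                r2.append(_length_fail(rng, rid, "R2"))
            else:
                r2.append(maker(rng, rid, "R2"))
        else:
            if kind == "good":
                r1.append(_good_read(rng, rid, L, "none"))
            elif kind == "length":
                r1.append(_length_fail(rng, rid, "none"))
            else:
                r1.append(maker(rng, rid, "none"))
    return r1, r2


# --------------------------------------------------------------------------
# Alignments
# --------------------------------------------------------------------------


def _target_positions(targets: list[GenomicInterval], read_length: int
                      ) -> list[tuple[int, int]]:
    """(target index, 0-based start) pairs where a read fits on target."""
    out = []
    for i, iv in enumerate(targets):
        for pos in range(iv.start, iv.end - read_length + 1):
            out.append((i, pos))
    return out


def _off_target_position(
    rng: np.random.Generator,
    targets: list[GenomicInterval],
    genome_length: int,
    read_length: int,
) -> int:
    """Rejection-sample a start whose footprint misses every target."""
    while True:
        pos = int(rng.integers(0, genome_length - read_length + 1))
        end = pos + read_length
        if all(end <= iv.start or pos >= iv.end for iv in targets):
            return pos


def gen_alignments(
    plan: FixturePlan,
    genome: str,
    targets: list[GenomicInterval],
    rng: Optional[np.random.Generator] = None,
) -> list[AlignmentRecord]:
    """SAM records with planted on-target fraction, duplicates, unmapped
    reads and (for PE plans) improper pairs.

    With ``unique_start_sites`` (default) base fragments never collide by
    chance, so duplicate marking flags exactly ``n_duplicates`` records
    (SE) or ``2 * n_duplicates`` (PE); with it off, placement is uniform
    over the discrete on-target site grid (``plan.start_sites`` sites) and
    chance collisions follow the uniform-occupancy model.
    """
    rng = rng or plan.rng()
    L = plan.read_length
    on_sites = _target_positions(targets, L)
    used: set[tuple[bool, int]] = set()
    records: list[AlignmentRecord] = []

    def make(rid: str, pos0: int, reverse: bool, qual_lo: int = 30,
             flag_extra: int = 0) -> AlignmentRecord:
        flag = (FLAG_REVERSE if reverse else 0) | flag_extra
        quals = [int(q) for q in rng.integers(qual_lo, qual_lo + 11, size=L)]
        return AlignmentRecord(
            qname=rid, flag=flag, rname=plan.chrom, pos=pos0 + 1, mapq=60,
            cigar=[("M", L)], tlen=0, seq=genome[pos0:pos0 + L], quals=quals,
        )

    def draw_position(on_target: bool) -> tuple[int, bool]:
        while True:
            reverse = bool(rng.integers(0, 2))
            if on_target:
                _, pos0 = on_sites[int(rng.integers(0, len(on_sites)))]
            else:
                pos0 = _off_target_position(rng, targets, plan.genome_length, L)
            if not plan.unique_start_sites or (reverse, pos0) not in used:
                used.add((reverse, pos0))
                return pos0, reverse

    if plan.paired:
        n_pairs = plan.n_reads // 2
        for i in range(n_pairs):
            rid = f"frag{i:06d}"
            on_target = rng.random() < plan.on_target_fraction
            insert = max(int(round(rng.normal(plan.insert_mean, plan.insert_sd))), L)
            pos0, _ = draw_position(on_target)
            pos2 = min(pos0 + insert - L, plan.genome_length - L)
            insert = pos2 + L - pos0
            proper = i >= plan.n_improper_pairs
            base = FLAG_PAIRED | (FLAG_PROPER_PAIR if proper else 0)
            a = make(rid, pos0, False,
                     flag_extra=base | FLAG_FIRST_IN_PAIR | FLAG_MATE_REVERSE)
            b = make(rid, pos2, True, flag_extra=base | FLAG_SECOND_IN_PAIR)
            a.tlen, b.tlen = insert, -insert
            a.rnext = b.rnext = plan.chrom
            a.pnext, b.pnext = b.pos, a.pos
            records.extend([a, b])
        # duplicate only proper pairs so the copies survive to the
        # duplicate-marking stage
        dup_sources = [
            (records[2 * i], records[2 * i + 1])
            for i in rng.choice(np.arange(plan.n_improper_pairs, n_pairs),
                                size=plan.n_duplicates, replace=False)
        ] if plan.n_duplicates else []
        for j, (a, b) in enumerate(dup_sources):
            for mate in (a, b):
                dup = make(f"dup{j:06d}", mate.pos - 1, mate.is_reverse,
                           qual_lo=15, flag_extra=mate.flag & ~FLAG_REVERSE
                           | (FLAG_REVERSE if mate.is_reverse else 0))
                dup.tlen, dup.rnext, dup.pnext = mate.tlen, mate.rnext, mate.pnext
                records.append(dup)
    else:
        for i in range(plan.n_reads):
            on_target = rng.random() < plan.on_target_fraction
            pos0, reverse = draw_position(on_target)
            records.append(make(f"read{i:06d}", pos0, reverse))
        if plan.n_duplicates:
            sources = rng.choice(np.arange(plan.n_reads),
                                 size=plan.n_duplicates, replace=False)
            for j, src in enumerate(sources):
                orig = records[int(src)]
                records.append(
                    make(f"dup{j:06d}", orig.pos - 1, orig.is_reverse,
                         qual_lo=15,
                         flag_extra=FLAG_REVERSE if orig.is_reverse else 0)
                )

    for i in range(plan.n_unmapped):
        quals = [int(q) for q in rng.integers(30, 41, size=L)]
        records.append(
            AlignmentRecord(
                qname=f"unm{i:06d}", flag=FLAG_UNMAPPED | FLAG_MATE_UNMAPPED
                if plan.paired else FLAG_UNMAPPED,
                rname=None, pos=0, mapq=0, cigar=[], tlen=0,
                seq=_random_bases(rng, L), quals=quals,
            )
        )
    return records


# --------------------------------------------------------------------------
# Variants
# --------------------------------------------------------------------------


def gen_vcf(
    plan: FixturePlan,
    targets: Optional[list[GenomicInterval]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list, list]:
    """(snps, dips) with exact planted Ti/Tv counts, hom fractions and
    annotation rates.

    Ti/Tv is planted by count: n_tv = round(n/(1+titv)), n_ti = n - n_tv, so
    plans where n_snps divides evenly recover the ratio exactly.  DIP allele
    fractions sit at 0.9 (hom) and 0.5 (het), well away from the default
    dsP = 80 boundary.
    """
    from .model import VariantRecord

    rng = rng or plan.rng()
    span_hi = plan.genome_length - 10
    n_sites = plan.n_snps + plan.n_dips
    positions = np.sort(
        rng.choice(np.arange(100, span_hi), size=n_sites, replace=False)
    )
    snp_pos = positions[: plan.n_snps]
    dip_pos = positions[plan.n_snps:]

    snps: list[VariantRecord] = []
    n_tv = int(round(plan.n_snps / (1.0 + plan.titv))) if plan.n_snps else 0
    n_ti = plan.n_snps - n_tv
    is_ti = np.zeros(plan.n_snps, dtype=bool)
    is_ti[:n_ti] = True
    rng.shuffle(is_ti)
    n_hom = int(round(plan.snp_hom_fraction * plan.n_snps))
    is_hom = np.zeros(plan.n_snps, dtype=bool)
    is_hom[:n_hom] = True
    rng.shuffle(is_hom)
    n_db = int(round(plan.snp_dbsnp_fraction * plan.n_snps))
    in_db = np.zeros(plan.n_snps, dtype=bool)
    in_db[:n_db] = True
    rng.shuffle(in_db)
    for i, pos in enumerate(snp_pos):
        ref = str(rng.choice(_BASES))
        if is_ti[i]:
            alt = _TRANSITION_PARTNER[ref]
        else:
            pair = _TRANSVERSIONS[int(rng.integers(0, len(_TRANSVERSIONS)))]
            ref, alt = pair
        depth = int(rng.integers(20, 101))
        if is_hom[i]:
            gt, alt_d = (1, 1), depth - int(rng.integers(0, 3))
        else:
            gt, alt_d = (0, 1), int(round(depth * 0.5))
        snps.append(
            VariantRecord(
                chrom=plan.chrom, pos=int(pos) + 1,
                vid=f"rs{1_000_000 + i}" if in_db[i] else ".",
                ref=ref, alt=alt, qual=float(rng.integers(50, 1000)),
                genotype=gt, depth=depth, alt_depth=max(min(alt_d, depth), 0),
                annotations={"RefSeq": f"NM_{i:06d}"},
            )
        )

    dips: list[VariantRecord] = []
    n_hom_dip = int(round(plan.dip_hom_fraction * plan.n_dips))
    hom_dip = np.zeros(plan.n_dips, dtype=bool)
    hom_dip[:n_hom_dip] = True
    rng.shuffle(hom_dip)
    n_ref = int(round(plan.dip_refseq_fraction * plan.n_dips))
    has_ref = np.zeros(plan.n_dips, dtype=bool)
    has_ref[:n_ref] = True
    rng.shuffle(has_ref)
    n_cod = int(round(plan.dip_coding_fraction * plan.n_dips))
    coding = np.zeros(plan.n_dips, dtype=bool)
    coding[:n_cod] = True
    rng.shuffle(coding)
    for i, pos in enumerate(dip_pos):
        anchor = str(rng.choice(_BASES))
        indel = _random_bases(rng, int(rng.integers(1, 4)))
        if rng.random() < 0.5:
            ref, alt = anchor, anchor + indel  # insertion
        else:
            ref, alt = anchor + indel, anchor  # deletion
        depth = int(rng.integers(20, 101))
        frac = 0.9 if hom_dip[i] else 0.5  # off the dsP=80 boundary
        alt_d = int(round(frac * depth))
        # rounding must not cross the boundary either way
        while hom_dip[i] and 100.0 * alt_d / depth < plan.dsP:
            alt_d += 1
        while not hom_dip[i] and 100.0 * alt_d / depth >= plan.dsP:
            alt_d -= 1
        annotations = {"Func": "exonic" if coding[i] else "intronic"}
        if has_ref[i]:
            annotations["RefSeq"] = f"NM_{9000 + i:06d}"
        dips.append(
            VariantRecord(
                chrom=plan.chrom, pos=int(pos) + 1, vid=".",
                ref=ref, alt=alt, qual=float(rng.integers(50, 1000)),
                genotype=(1, 1) if hom_dip[i] else (0, 1),
                depth=depth, alt_depth=alt_d,
                annotations=annotations,
            )
        )
    return snps, dips


# --------------------------------------------------------------------------
# Whole-fixture writer
# --------------------------------------------------------------------------


@dataclass
class Fixture:
    plan: FixturePlan
    genome: str
    targets: list[GenomicInterval]
    reads_r1: list[SequenceRead]
    reads_r2: Optional[list[SequenceRead]]
    alignments: list[AlignmentRecord]
    snps: list
    dips: list
    paths: dict[str, Path] = field(default_factory=dict)


def generate(plan: FixturePlan) -> Fixture:
    """Run every generator off one seeded stream (deterministic per plan)."""
    rng = plan.rng()
    genome, targets = gen_reference(plan, rng)
    r1, r2 = gen_reads(plan, rng)
    alignments = gen_alignments(plan, genome, targets, rng)
    snps, dips = gen_vcf(plan, targets, rng)
    return Fixture(plan, genome, targets, r1, r2, alignments, snps, dips)


def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA/BED/FASTQ/SAM/VCF plus a ground-truth manifest TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plan = fixture.plan
    paths = {
        "reference": out / "reference.fasta",
        "targets": out / "targets.bed",
        "reads_r1": out / "reads_R1.fastq",
        "alignments": out / "alignments.sam",
        "snps": out / "snps.vcf",
        "dips": out / "dips.vcf",
        "manifest": out / "manifest.tsv",
    }
    with open(paths["reference"], "w") as fh:
        fh.write(f">{plan.chrom}\n")
        for i in range(0, len(fixture.genome), 80):
            fh.write(fixture.genome[i:i + 80] + "\n")
    seqio.write_bed(fixture.targets, paths["targets"])
    seqio.write_fastq(fixture.reads_r1, paths["reads_r1"])
    if fixture.reads_r2 is not None:
        paths["reads_r2"] = out / "reads_R2.fastq"
        seqio.write_fastq(fixture.reads_r2, paths["reads_r2"])
    seqio.write_sam(
        fixture.alignments, paths["alignments"],
        {plan.chrom: plan.genome_length},
    )
    contigs = {plan.chrom: plan.genome_length}
    seqio.write_vcf(fixture.snps, paths["snps"], contigs)
    seqio.write_vcf(fixture.dips, paths["dips"], contigs)
    manifest = {
        "seed": plan.seed,
        "genome_length": plan.genome_length,
        "target_bases": sum(len(t) for t in fixture.targets),
        "n_good_reads": plan.n_good_reads,
        "fail_length": plan.fail_length,
        "fail_nmax": plan.fail_nmax,
        "fail_quality": plan.fail_quality,
        "n_reads": plan.n_reads,
        "on_target_fraction": plan.on_target_fraction,
        "n_duplicates": plan.n_duplicates,
        "n_unmapped": plan.n_unmapped,
        "n_snps": plan.n_snps,
        "titv": plan.titv,
        "snp_hom_fraction": plan.snp_hom_fraction,
        "n_dips": plan.n_dips,
        "dip_hom_fraction": plan.dip_hom_fraction,
        "dsP": plan.dsP,
    }
    with open(paths["manifest"], "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in manifest.items():
            fh.write(f"{key}\t{value}\n")
    fixture.paths = paths
    return paths
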