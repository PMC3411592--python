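import numpy as np
import pytest

from exopipe.model import (
    FLAG_FIRST_IN_PAIR,
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_REVERSE,
    FLAG_SECOND_IN_PAIR,
    AlignmentRecord,
    GenomicInterval,
    SequenceRead,
)


def make_read(bases="ACGTACGTACGT", quals=None, rid="r1", encoding="sanger",
              mate="none"):
    if quals is None:
        quals = [35] * len(bases)
    elif isinstance(quals, int):
        quals = [quals] * len(bases)
    return SequenceRead(rid, bases, list(quals), encoding, mate)


def make_aln(qname="a", flag=0, rname="chr1", pos=100, mapq=60, cigar="50M",
             tlen=0, seq=None, quals=None):
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    qlen = sum(n for op, n in ops if op in "MIS=X")
    if seq is None:
        seq = "A" * qlen
    if quals is None:
        quals = [30] * qlen
    return AlignmentRecord(qname, flag, rname, pos, mapq, ops, tlen, seq,
                           list(quals))


def random_alignment(rng, qname, chrom="chr1", genome_length=20_000,
                     softclip=True):
    """A mapped SE record with a random CIGAR drawing on S/I/D ops."""
    parts = []
    if softclip and rng.random() < 0.3:
        parts.append(("S", int(rng.integers(1, 8))))
    parts.append(("M", int(rng.integers(20, 60))))
    if rng.random() < 0.3:
        parts.append(("I", int(rng.integers(1, 5))))
        parts.append(("M", int(rng.integers(5, 20))))
    if rng.random() < 0.3:
        parts.append(("D", int(rng.integers(1, 60))))
        parts.append(("M", int(rng.integers(5, 20))))
    if softclip and rng.random() < 0.3:
        parts.append(("S", int(rng.integers(1, 8))))
    ref_len = sum(n for op, n in parts if op in "MD")
    qlen = sum(n for op, n in parts if op in "MIS")
    pos = int(rng.integers(1, genome_length - ref_len))
    flag = FLAG_REVERSE if rng.random() < 0.5 else 0
    quals = [int(q) for q in rng.integers(10, 41, size=qlen)]
    bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=qlen)])
    return AlignmentRecord(qname, flag, chrom, pos, 60, parts, 0, bases, quals)


def random_pair(rng, qname, chrom="chr1", genome_length=20_000):
    """A proper PE fragment; mates may carry soft clips."""
    a = random_alignment(rng, qname, chrom, genome_length)
    b = random_alignment(rng, qname, chrom, genome_length)
    a.flag = (a.flag & FLAG_REVERSE) | FLAG_PAIRED | FLAG_PROPER_PAIR | FLAG_FIRST_IN_PAIR
    b.flag = (b.flag & FLAG_REVERSE) | FLAG_PAIRED | FLAG_PROPER_PAIR | FLAG_SECOND_IN_PAIR
    return a, b


def random_intervals(rng, chrom="chr1", genome_length=20_000, n=8):
    starts = np.sort(rng.choice(np.arange(0, genome_length - 400, 400),
                                size=n, replace=False))
    return [
        GenomicInterval(chrom, int(s), int(s) + int(rng.integers(50, 350)),
                        f"t{i}")
        for i, s in enumerate(starts)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
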