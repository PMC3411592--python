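"""Alignment, insert-size and exome-coverage statistics.

Fold coverage of a region is defined as aligned bases attributed to the
region divided by region length; the exome-wide figure is total on-target
aligned bases over total target length (a length-weighted mean, not a mean
of per-exon folds).  Capture specificity is the fraction of mapped,
deduplicated reads that overlap the capture targets.

``expected_duplicates_by_chance`` models coordinate-duplicate collisions
among non-duplicated molecules: with n fragments placed uniformly over P
equally likely start sites (by default both strands of the target space,
P = 2 x target length), the expected number of occupied sites is
P*(1 - (1 - 1/P)^n), and every read beyond the first at a site is flagged,
so the expectation of flagged reads is n - P*(1 - (1 - 1/P)^n).
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .alnfilter import TargetIndex
from .model import AlignmentRecord, GenomicInterval

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# BAM-level totals
# --------------------------------------------------------------------------


@dataclass
class BamStats:
    total_reads: int
    mapped: int
    unmapped: int
    aligned_bases: int
    genome_fold_coverage: Optional[float]


def bam_stats(
    records: Iterable[AlignmentRecord], genome_length: Optional[int] = None
) -> BamStats:
    """Totals over an alignment stream: read counts and genome fold coverage
    (aligned bases / genome length)."""
    total = mapped = bases = 0
    for r in records:
        total += 1
        if not r.is_unmapped:
            mapped += 1
            bases += r.aligned_query_bases()
    fold = bases / genome_length if genome_length else None
    return BamStats(total, mapped, total - mapped, bases, fold)


# --------------------------------------------------------------------------
# Alignment summary metrics
# --------------------------------------------------------------------------


@dataclass
class AlignmentSummary:
    mapped_reads: int
    median_read_length: Optional[float]
    insertion_rate: Optional[float]  # fraction of mapped reads with >=1 I op
    deletion_rate: Optional[float]
    high_quality_aligned_bases: int


def alignment_summary_metrics(
    records: Iterable[AlignmentRecord], mapq_threshold: int = 20
) -> AlignmentSummary:
    """High-level alignment metrics over mapped records.

    High-quality aligned bases are the M/=/X-consumed query bases of records
    at or above ``mapq_threshold``.
    """
    lengths: list[int] = []
    with_i = with_d = hq_bases = 0
    for r in records:
        if r.is_unmapped:
            continue
        lengths.append(len(r.seq) or r.query_length())
        ops = {op for op, _ in r.cigar}
        with_i += "I" in ops
        with_d += "D" in ops
        if r.mapq >= mapq_threshold:
            hq_bases += r.aligned_query_bases()
    n = len(lengths)
    if n == 0:
        return AlignmentSummary(0, None, None, None, 0)
    return AlignmentSummary(
        mapped_reads=n,
        median_read_length=float(np.median(lengths)),
        insertion_rate=with_i / n,
        deletion_rate=with_d / n,
        high_quality_aligned_bases=hq_bases,
    )


# --------------------------------------------------------------------------
# Insert sizes
# --------------------------------------------------------------------------


@dataclass
class InsertSizeMetrics:
    count: int
    mean: Optional[float]
    median: Optional[float]
    sd: Optional[float]
    histogram: Counter = field(default_factory=Counter)


def insert_size_metrics(
    records: Iterable[AlignmentRecord], exclude_outliers: bool = True
) -> InsertSizeMetrics:
    """Insert-size distribution of paired-end data.

    One observation per fragment: only the mate carrying the positive TLEN
    is counted.  With ``exclude_outliers`` (default), fragments longer than
    10x the median are left out of mean/sd — chimeric pairs otherwise
    dominate both — but stay in the histogram.
    """
    sizes = [
        abs(r.tlen)
        for r in records
        if r.is_paired and r.is_proper_pair and not r.is_unmapped and r.tlen > 0
    ]
    if not sizes:
        logger.info("no proper pairs with positive TLEN; insert metrics empty")
        return InsertSizeMetrics(0, None, None, None)
    histogram = Counter(sizes)
    median = float(np.median(sizes))
    core = (
        [s for s in sizes if s <= 10 * median] if exclude_outliers else list(sizes)
    )
    arr = np.asarray(core, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return InsertSizeMetrics(len(sizes), float(arr.mean()), median, sd, histogram)


# --------------------------------------------------------------------------
# Exome coverage
# --------------------------------------------------------------------------


@dataclass
class IntervalCoverage:
    interval: GenomicInterval
    read_count: int
    aligned_bases: int
    covered_bases: int

    @property
    def fold_coverage(self) -> float:
        return self.aligned_bases / len(self.interval)


@dataclass
class CoverageProfile:
    per_interval: list[IntervalCoverage]
    total_target_length: int

    @property
    def total_on_target_bases(self) -> int:
        return sum(c.aligned_bases for c in self.per_interval)

    @property
    def exome_fold_coverage(self) -> float:
        """Total on-target aligned bases over total target length."""
        if self.total_target_length == 0:
            return 0.0
        return self.total_on_target_bases / self.total_target_length

    def fraction_intervals_below(self, threshold: float) -> float:
        if not self.per_interval:
            return 0.0
        n = sum(1 for c in self.per_interval if c.fold_coverage < threshold)
        return n / len(self.per_interval)

    def fraction_intervals_at_or_above(self, threshold: float) -> float:
        if not self.per_interval:
            return 0.0
        n = sum(1 for c in self.per_interval if c.fold_coverage >= threshold)
        return n / len(self.per_interval)


def exon_coverage(
    records: Iterable[AlignmentRecord],
    targets: TargetIndex | Iterable[GenomicInterval],
    min_overlap: int = 1,
) -> CoverageProfile:
    """Per-target read counts, aligned bases and fold coverage.

    A read counts toward every target its footprint overlaps by at least
    ``min_overlap`` bases; its aligned-base contribution to a target is the
    intersection of footprint and target.  Covered bases are target
    positions touched by at least one read footprint.
    """
    if not isinstance(targets, TargetIndex):
        targets = TargetIndex(targets)
    read_counts = Counter()
    base_counts = Counter()
    covered: dict[int, np.ndarray] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        footprint = rec.footprint()
        hits = targets.overlap_by_target(rec, 1)
        for idx, bases in hits.items():
            base_counts[idx] += bases
            if bases >= min_overlap:
                read_counts[idx] += 1
            iv = targets.intervals[idx]
            mask = covered.setdefault(idx, np.zeros(len(iv), dtype=bool))
            for span_start, span_end in footprint:
                lo = max(span_start, iv.start) - iv.start
                hi = min(span_end, iv.end) - iv.start
                if hi > lo:
                    mask[lo:hi] = True
    per_interval = [
        IntervalCoverage(
            interval=iv,
            read_count=read_counts.get(idx, 0),
            aligned_bases=base_counts.get(idx, 0),
            covered_bases=int(covered[idx].sum()) if idx in covered else 0,
        )
        for idx, iv in enumerate(targets.intervals)
    ]
    return CoverageProfile(per_interval, targets.total_length)


# --------------------------------------------------------------------------
# Capture specificity & duplicate-collision model
# --------------------------------------------------------------------------


def capture_specificity(
    records: Iterable[AlignmentRecord],
    targets: TargetIndex | Iterable[GenomicInterval],
    min_overlap: int = 1,
    per_base: bool = False,
) -> Optional[float]:
    """Fraction of mapped, non-duplicate reads on target, in [0, 1].

    Pass records *after* duplicate removal (or with duplicates flagged; the
    flag is honoured here).  ``per_base=True`` switches the unit from reads
    to aligned bases.  Returns None (NA) when nothing is mapped.
    """
    if not isinstance(targets, TargetIndex):
        targets = TargetIndex(targets)
    denom = numer = 0
    for r in records:
        if r.is_unmapped or r.is_duplicate or r.is_secondary or r.is_supplementary:
            continue
        if per_base:
            denom += r.aligned_query_bases()
            numer += sum(targets.overlap_by_target(r, 1).values())
        else:
            denom += 1
            numer += bool(targets.overlaps(r, min_overlap))
    if denom == 0:
        logger.info("capture specificity undefined: no mapped reads")
        return None
    return numer / denom


def expected_duplicates_by_chance(n_reads: int, n_start_sites: int) -> float:
    """Expected reads flagged as coordinate duplicates by pure chance.

    Uniform placement of ``n_reads`` fragments over ``n_start_sites``
    equally likely sites: E[flagged] = n - P*(1 - (1 - 1/P)^n).  Use
    ``n_start_sites = 2 * target_length`` (both strands) for an exome run.
    """
    if n_start_sites <= 0:
        raise ValueError("n_start_sites must be positive")
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if n_start_sites == 1:  # single site: every read beyond the first collides
        return float(max(n_reads - 1, 0))
    p = float(n_start_sites)
    # expm1/log1p formulation keeps precision for huge P
    expected_occupied = -p * math.expm1(n_reads * math.log1p(-1.0 / p))
    return n_reads - expected_occupied
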