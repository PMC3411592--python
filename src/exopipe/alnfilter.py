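"""Alignment filtering: unmapped/secondary removal, proper-pair filtering,
coordinate-based PCR-duplicate marking, and exome (on-target) filtering.

Stages run in the fixed order mapping → proper-pair → duplicates → exome,
each emitting :class:`~exopipe.model.FilterAccounting` for the summary
report.

Duplicate detection is coordinate-based: reads are grouped by reference,
strand and *unclipped* 5' fragment start (soft/hard clips undone), paired
fragments by both mates' triples, so duplicates survive differential
clipping.  Within a group the record (or pair) with the highest base-quality
sum is kept; ties break on the lexicographically smallest query name, which
makes the choice deterministic and independent of input order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .model import FLAG_DUPLICATE, AlignmentRecord, FilterAccounting, GenomicInterval
from .seqio import normalize_targets

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Target index
# --------------------------------------------------------------------------


class TargetIndex:
    """Normalized target intervals with fast per-chromosome overlap lookup."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals = normalize_targets(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for idx, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
        self._warned_chroms: set[str] = set()

    @property
    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, record: AlignmentRecord, min_overlap: int = 1) -> bool:
        """True iff the record's reference footprint overlaps any single
        target by at least ``min_overlap`` bases."""
        return bool(self.overlap_by_target(record, min_overlap))

    def overlap_by_target(
        self, record: AlignmentRecord, min_overlap: int = 1
    ) -> dict[int, int]:
        """Target index → overlap bases, for targets meeting ``min_overlap``."""
        if record.rname is None:
            return {}
        tree = self._trees.get(record.rname)
        if tree is None:
            if record.rname not in self._warned_chroms:
                logger.warning(
                    "reference %s absent from target set; reads there count "
                    "off-target",
                    record.rname,
                )
                self._warned_chroms.add(record.rname)
            return {}
        overlap: dict[int, int] = {}
        for span_start, span_end in record.footprint():
            for hit in tree.overlap(span_start, span_end):
                bases = min(span_end, hit.end) - max(span_start, hit.begin)
                overlap[hit.data] = overlap.get(hit.data, 0) + bases
        return {idx: b for idx, b in overlap.items() if b >= min_overlap}


# --------------------------------------------------------------------------
# Individual filters
# --------------------------------------------------------------------------


def filter_unmapped(
    records: Iterable[AlignmentRecord],
) -> tuple[list[AlignmentRecord], FilterAccounting]:
    """Drop unmapped records plus secondary/supplementary alignments (which
    would double-count downstream coverage)."""
    records = list(records)
    kept = [
        r
        for r in records
        if not (r.is_unmapped or r.is_secondary or r.is_supplementary)
    ]
    return kept, FilterAccounting(
        "mapping-filter", len(records), len(kept), len(records) - len(kept)
    )


def filter_proper_pair(
    records: Iterable[AlignmentRecord],
) -> tuple[list[AlignmentRecord], FilterAccounting]:
    """Drop paired records lacking the proper-pair flag; a no-op (with a
    logged notice) on single-end data."""
    records = list(records)
    if not any(r.is_paired for r in records):
        logger.info("proper-pair filter skipped: no paired records")
        return records, FilterAccounting("proper-pair-filter", len(records),
                                         len(records), 0)
    kept = [r for r in records if not r.is_paired or r.is_proper_pair]
    return kept, FilterAccounting(
        "proper-pair-filter", len(records), len(kept), len(records) - len(kept)
    )


def duplicate_key(record: AlignmentRecord):
    """Single-end duplicate key: (reference, strand, unclipped 5' start)."""
    return (record.rname, record.is_reverse, record.unclipped_start())


def _fragment_key(records: Sequence[AlignmentRecord]):
    """Order-independent key over one or two mates' single-end keys."""
    return tuple(sorted(duplicate_key(r) for r in records))


def mark_duplicates(
    records: Iterable[AlignmentRecord],
) -> tuple[list[AlignmentRecord], FilterAccounting]:
    """Flag coordinate-duplicate records, keeping the best per group.

    Paired fragments (both mates present and mapped) are keyed by both
    mates' (reference, strand, unclipped start) triples and flagged as a
    unit; everything else is keyed as single-end.  Output preserves input
    order; only the duplicate flag changes.
    """
    records = list(records)
    # unit = one fragment: a [record] or a [mate1, mate2] list of indices
    by_qname: dict[str, list[int]] = {}
    units: list[list[int]] = []
    for i, rec in enumerate(records):
        if rec.is_paired and not rec.is_mate_unmapped and not rec.is_unmapped:
            by_qname.setdefault(rec.qname, []).append(i)
        else:
            units.append([i])
    for qname, idxs in by_qname.items():
        if len(idxs) == 2:
            units.append(idxs)
        else:  # mate not in stream; fall back to single-end keys
            units.extend([i] for i in idxs)

    groups: dict[tuple, list[list[int]]] = {}
    for unit in units:
        key = _fragment_key([records[i] for i in unit])
        groups.setdefault(key, []).append(unit)

    flagged: set[int] = set()
    for unit_list in groups.values():
        if len(unit_list) == 1:
            continue
        best = min(
            unit_list,
            key=lambda u: (
                -sum(records[i].quality_sum() for i in u),
                records[u[0]].qname,
            ),
        )
        for unit in unit_list:
            if unit is not best:
                flagged.update(unit)

    out = [
        replace(r, flag=r.flag | FLAG_DUPLICATE) if i in flagged else r
        for i, r in enumerate(records)
    ]
    return out, FilterAccounting(
        "duplicate-filter", len(records), len(records) - len(flagged), len(flagged)
    )


def filter_on_target(
    records: Iterable[AlignmentRecord],
    targets: TargetIndex | Iterable[GenomicInterval],
    min_overlap: int = 1,
) -> tuple[list[AlignmentRecord], FilterAccounting]:
    """Keep records whose reference footprint (M/D/=/X span) overlaps a
    target by at least ``min_overlap`` bases."""
    if not isinstance(targets, TargetIndex):
        targets = TargetIndex(targets)
    records = list(records)
    kept = [r for r in records if targets.overlaps(r, min_overlap)]
    return kept, FilterAccounting(
        "exome-filter", len(records), len(kept), len(records) - len(kept)
    )


# --------------------------------------------------------------------------
# Filter chain
# --------------------------------------------------------------------------


@dataclass
class AlnFilterConfig:
    drop_duplicates: bool = True  # False: flag only, keep records
    min_overlap: int = 1


def run_alnfilter(
    records: Iterable[AlignmentRecord],
    targets: TargetIndex | Iterable[GenomicInterval],
    config: Optional[AlnFilterConfig] = None,
) -> tuple[list[AlignmentRecord], list[FilterAccounting]]:
    """Mapping → proper-pair → duplicate → exome filters, in that order,
    returning survivors and per-stage accounting."""
    config = config or AlnFilterConfig()
    if not isinstance(targets, TargetIndex):
        targets = TargetIndex(targets)
    accounting: list[FilterAccounting] = []

    kept, acc = filter_unmapped(records)
    accounting.append(acc)
    kept, acc = filter_proper_pair(kept)
    accounting.append(acc)
    marked, acc = mark_duplicates(kept)
    accounting.append(acc)
    kept = [r for r in marked if not r.is_duplicate] if config.drop_duplicates else marked
    kept, acc = filter_on_target(kept, targets, config.min_overlap)
    accounting.append(acc)
    return kept, accounting
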