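"""Shared domain types for the exome pipeline.

Coordinate conventions: BED-style :class:`GenomicInterval` objects are 0-based
half-open; SAM (:class:`AlignmentRecord.pos`) and VCF (:class:`VariantRecord.pos`)
positions are 1-based, per their format standards.  Any arithmetic crossing
formats converts explicitly at the point of use.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

#: Recognised quality-score encodings.
ENCODINGS = ("sanger", "solexa", "illumina13", "solid")

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_IN_PAIR = 0x40
FLAG_SECOND_IN_PAIR = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

# CIGAR operations that consume query / reference sequence
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_FOOTPRINT_OPS = frozenset("MD=X")  # contiguous reference footprint (N splits it)
_ALIGNED_OPS = frozenset("M=X")


@dataclass
class SequenceRead:
    """One sequencing read in nucleotide or color space.

    In color space ``bases`` holds the leading adapter base followed by color
    digits (e.g. ``"T0123"``); the adapter base carries no quality, so
    ``len(quals) == len(bases) - 1`` there, while nucleotide-space reads have
    one quality per base.
    """

    read_id: str
    bases: str
    quals: list[int]
    encoding: str = "sanger"
    mate: str = "none"  # none | R1 | R2

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        expected = len(self.bases) - (1 if self.is_color_space else 0)
        if len(self.quals) != expected:
            raise ValueError(
                f"read {self.read_id!r}: {len(self.quals)} qualities for "
                f"{len(self.bases)} symbols ({self.encoding})"
            )

    @property
    def is_color_space(self) -> bool:
        return self.encoding == "solid"

    def __len__(self) -> int:
        """Number of sequenced positions (colors for SOLiD reads)."""
        return len(self.quals)

    def slice(self, start: int, stop: int) -> "SequenceRead":
        """Sub-read over quality positions [start, stop), keeping the adapter
        base of a color-space read."""
        if self.is_color_space:
            bases = self.bases[0] + self.bases[1 + start : 1 + stop]
        else:
            bases = self.bases[start:stop]
        return replace(self, bases=bases, quals=self.quals[start:stop])


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A target (exon) region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentRecord:
    """One SAM-style alignment.

    ``cigar`` is a list of ``(op, length)`` with ``op`` a SAM operation
    character; empty for unmapped records.  ``pos`` is the 1-based leftmost
    mapped position (0 when unmapped, mirroring SAM's convention of meaningless
    coordinates on unmapped records).
    """

    qname: str
    flag: int
    rname: Optional[str]
    pos: int
    mapq: int
    cigar: list[tuple[str, int]]
    tlen: int
    seq: str
    quals: list[int]
    rnext: Optional[str] = None
    pnext: int = 0

    # -- flag helpers ------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER_PAIR)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    # -- CIGAR arithmetic --------------------------------------------
    def query_length(self) -> int:
        """Query bases consumed by the CIGAR (M/I/S/=/X)."""
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)

    def reference_length(self) -> int:
        """Reference bases consumed by the CIGAR (M/D/N/=/X)."""
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    def aligned_query_bases(self) -> int:
        """Query bases aligned to the reference (M/=/X only)."""
        return sum(n for op, n in self.cigar if op in _ALIGNED_OPS)

    def reference_end(self) -> int:
        """1-based inclusive rightmost reference position."""
        return self.pos + self.reference_length() - 1

    def footprint(self) -> list[tuple[int, int]]:
        """Reference footprint as 0-based half-open spans of M/D/=/X runs.

        N (skipped region) advances the reference cursor but splits the
        footprint; insertions and clips do not touch the reference.
        """
        spans: list[tuple[int, int]] = []
        ref = self.pos - 1
        run_start: Optional[int] = None
        for op, n in self.cigar:
            if op in _FOOTPRINT_OPS:
                if run_start is None:
                    run_start = ref
                ref += n
            elif op == "N":
                if run_start is not None:
                    spans.append((run_start, ref))
                    run_start = None
                ref += n
            # I/S/H/P consume no reference
        if run_start is not None:
            spans.append((run_start, ref))
        return spans

    def unclipped_start(self) -> int:
        """1-based 5' fragment start after undoing soft/hard clips.

        For a forward read this is ``pos`` minus leading clips; for a reverse
        read the biological 5' end is the clip-extended reference end.
        """
        if self.is_reverse:
            tail = 0
            for op, n in reversed(self.cigar):
                if op in "SH":
                    tail += n
                else:
                    break
            return self.reference_end() + tail
        lead = 0
        for op, n in self.cigar:
            if op in "SH":
                lead += n
            else:
                break
        return self.pos - lead

    def quality_sum(self) -> int:
        return sum(self.quals)


@dataclass
class VariantRecord:
    """One VCF-style variant (already split to a single alt allele)."""

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str
    qual: Optional[float] = None
    genotype: Optional[tuple[int, int]] = None
    depth: Optional[int] = None
    alt_depth: Optional[int] = None
    ref_depth: Optional[int] = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref == alt ({self.ref})")
        if (
            self.depth is not None
            and self.alt_depth is not None
            and self.alt_depth > self.depth
        ):
            raise ValueError(f"{self.chrom}:{self.pos} alt_depth > depth")

    @property
    def variant_class(self) -> str:
        """SNP / insertion / deletion, decided purely by allele lengths."""
        if len(self.alt) > len(self.ref):
            return "insertion"
        if len(self.alt) < len(self.ref):
            return "deletion"
        return "SNP"

    @property
    def in_dbsnp(self) -> bool:
        return self.vid not in (".", "", None)


@dataclass
class FilterAccounting:
    """Pass/fail bookkeeping for one filtering stage."""

    stage_name: str
    input_count: int
    passed_count: int
    removed_count: int

    def __post_init__(self) -> None:
        if self.input_count != self.passed_count + self.removed_count:
            raise ValueError(
                f"stage {self.stage_name}: {self.input_count} != "
                f"{self.passed_count} + {self.removed_count}"
            )

    @property
    def passed_percent(self) -> float:
        """Percentage passed; an empty stage counts as 100% (nothing removed)."""
        if self.input_count == 0:
            return 100.0
        return 100.0 * self.passed_count / self.input_count


def fmt_na(value: Optional[float], digits: int = 4) -> str:
    """Render a possibly-undefined statistic, using ``NA`` for None/NaN."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.{digits}f}"
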