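"""Independent brute-force oracles used to validate the library.

Everything here deliberately re-derives results by the most literal method
available — per-base arrays, all-pairs comparison, probability arithmetic —
sharing no code path with the implementations it checks.
"""
from __future__ import annotations

import math
from collections import defaultdict

from exopipe.model import AlignmentRecord, GenomicInterval


def solexa_to_phred_via_probability(q_solexa: int) -> int:
    """Solexa score -> error odds -> error probability -> Phred,
    rounded half-up."""
    odds = 10.0 ** (-q_solexa / 10.0)
    p_err = odds / (1.0 + odds)
    phred = -10.0 * math.log10(p_err)
    return max(0, min(93, math.floor(phred + 0.5)))


# --------------------------------------------------------------------------
# Per-base coverage / on-target oracle
# --------------------------------------------------------------------------


def footprint_positions(rec: AlignmentRecord) -> set[int]:
    """0-based reference positions covered by M/D/=/X, by walking the CIGAR
    one operation at a time."""
    out: set[int] = set()
    ref = rec.pos - 1
    for op, n in rec.cigar:
        if op in "MD=X":
            out.update(range(ref, ref + n))
            ref += n
        elif op == "N":
            ref += n
        # I, S, H, P: no reference consumption
    return out


def per_base_coverage(
    records: list[AlignmentRecord], intervals: list[GenomicInterval]
):
    """(read_counts, aligned_bases, covered_bases) per interval via explicit
    per-base set intersection."""
    read_counts = [0] * len(intervals)
    aligned = [0] * len(intervals)
    covered = [set() for _ in intervals]
    for rec in records:
        if rec.is_unmapped:
            continue
        positions = footprint_positions(rec)
        for i, iv in enumerate(intervals):
            if rec.rname != iv.chrom:
                continue
            inside = {p for p in positions if iv.start <= p < iv.end}
            if inside:
                read_counts[i] += 1
                aligned[i] += len(inside)
                covered[i] |= inside
    return read_counts, aligned, [len(c) for c in covered]


def on_target_oracle(
    rec: AlignmentRecord, intervals: list[GenomicInterval], min_overlap: int = 1
) -> bool:
    positions = footprint_positions(rec)
    for iv in intervals:
        if rec.rname != iv.chrom:
            continue
        if sum(1 for p in positions if iv.start <= p < iv.end) >= min_overlap:
            return True
    return False


# --------------------------------------------------------------------------
# O(N^2) duplicate-marking oracle
# --------------------------------------------------------------------------


def _unclipped_start(rec: AlignmentRecord) -> int:
    ref_len = sum(n for op, n in rec.cigar if op in "MDN=X")
    if rec.is_reverse:
        end = rec.pos + ref_len - 1
        for op, n in reversed(rec.cigar):
            if op not in "SH":
                break
            end += n
        return end
    start = rec.pos
    for op, n in rec.cigar:
        if op not in "SH":
            break
        start -= n
    return start


def _se_key(rec: AlignmentRecord):
    return (rec.rname, rec.is_reverse, _unclipped_start(rec))


def brute_force_duplicates(records: list[AlignmentRecord]):
    """All-pairs duplicate detection.

    Returns (flagged indices, kept index per group) computed by grouping
    fragments via pairwise key comparison and picking the best by quality
    sum then smallest qname.
    """
    paired: dict[str, list[int]] = defaultdict(list)
    units: list[list[int]] = []
    for i, rec in enumerate(records):
        if rec.is_paired and not rec.is_unmapped and not rec.is_mate_unmapped:
            paired[rec.qname].append(i)
        else:
            units.append([i])
    for qname, idxs in paired.items():
        if len(idxs) == 2:
            units.append(sorted(idxs))
        else:
            units.extend([i] for i in idxs)

    def unit_key(unit):
        return tuple(sorted(_se_key(records[i]) for i in unit))

    # pairwise grouping (no hashing of a shared key object)
    groups: list[list[list[int]]] = []
    for unit in units:
        placed = False
        for group in groups:
            if unit_key(group[0]) == unit_key(unit):
                group.append(unit)
                placed = True
                break
        if not placed:
            groups.append([unit])

    flagged: set[int] = set()
    kept: list[int] = []
    for group in groups:
        def score(unit):
            total = sum(sum(records[i].quals) for i in unit)
            return (-total, records[unit[0]].qname)
        best = sorted(group, key=score)[0]
        kept.extend(best)
        for unit in group:
            if unit is not best:
                flagged.update(unit)
    return flagged, sorted(kept)
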