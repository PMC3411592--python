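"""Read quality control and preprocessing.

Trimmers shorten reads (N-tails, Illumina Read Segment Quality Control
Indicator tails, low-quality tails, hard length caps); filters then drop
whole reads that are too short, too N-rich, or too unreliable.  Every stage
reports pass/fail accounting, and QC statistics are computed on the raw and
the surviving reads so the effect of preprocessing is visible.

For paired-end data the two mates are processed in lockstep: when either
mate fails a filter the whole pair is dropped (both reads counted as removed
at that stage), which keeps the surviving R1/R2 files aligner-ready.

Color-space (SOLiD) reads pass through the quality-based stages unchanged in
semantics — qualities are per color — but the nucleotide-identity N-trimmer
does not apply to colors and is skipped with a logged notice.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import FilterAccounting, SequenceRead
from .seqio import PairingError

logger = logging.getLogger(__name__)

#: Phred value of the Illumina Read Segment Quality Control Indicator
#: ('B' in Phred+64 encodings): a trailing run at this value flags an
#: unreliable read segment rather than a real quality estimate.
RSQCI_QUALITY = 2


# --------------------------------------------------------------------------
# Trimmers (read -> read; never drop records)
# --------------------------------------------------------------------------


def trim_nucleotide(read: SequenceRead, base: str = "N") -> SequenceRead:
    """Strip maximal leading and trailing runs of ``base`` (5' and 3' ends);
    interior occurrences are untouched.  Qualities are trimmed in lockstep."""
    if read.is_color_space:
        logger.info("nucleotide trimming skipped for color-space read %s", read.read_id)
        return read
    start, stop = 0, len(read.bases)
    while start < stop and read.bases[start] == base:
        start += 1
    while stop > start and read.bases[stop - 1] == base:
        stop -= 1
    if start == 0 and stop == len(read.bases):
        return read
    return read.slice(start, stop)


def trim_rsqci(read: SequenceRead) -> SequenceRead:
    """Remove the trailing run of positions flagged by the Read Segment
    Quality Control Indicator (Phred == 2)."""
    stop = len(read.quals)
    while stop > 0 and read.quals[stop - 1] == RSQCI_QUALITY:
        stop -= 1
    return read if stop == len(read.quals) else read.slice(0, stop)


def trim_quality(read: SequenceRead, q_threshold: int) -> SequenceRead:
    """Remove trailing positions with quality below ``q_threshold``."""
    stop = len(read.quals)
    while stop > 0 and read.quals[stop - 1] < q_threshold:
        stop -= 1
    return read if stop == len(read.quals) else read.slice(0, stop)


def trim_to_length(read: SequenceRead, max_len: int) -> SequenceRead:
    """Truncate the read at the 3' end to at most ``max_len`` positions."""
    if max_len < 0:
        raise ValueError("max_len must be non-negative")
    return read if len(read) <= max_len else read.slice(0, max_len)


# --------------------------------------------------------------------------
# Filters (read -> bool; True = keep)
# --------------------------------------------------------------------------


def filter_length(read: SequenceRead, min_len: int = 25) -> bool:
    """Fail reads shorter than ``min_len``; exactly ``min_len`` passes."""
    return len(read) >= min_len


def filter_nmax(read: SequenceRead, max_frac: float = 0.05) -> bool:
    """Fail reads whose fraction of unidentified calls (N, or '.' in color
    space) strictly exceeds ``max_frac``."""
    if len(read) == 0:
        return True  # nothing to judge; the length filter handles empties
    symbols = read.bases[1:] if read.is_color_space else read.bases
    n_count = symbols.count(".") if read.is_color_space else symbols.count("N")
    return n_count / len(read) <= max_frac


def filter_quality(
    read: SequenceRead, q_unreliable: int = 20, max_frac: float = 0.05
) -> bool:
    """Fail reads with more than ``max_frac`` of positions below
    ``q_unreliable`` (strict inequality on the fraction)."""
    if len(read) == 0:
        return True
    low = sum(1 for q in read.quals if q < q_unreliable)
    return low / len(read) <= max_frac


# --------------------------------------------------------------------------
# QC statistics
# --------------------------------------------------------------------------


@dataclass
class ReadQCStats:
    """Aggregate read characteristics: lengths, base composition, quality by
    cycle, and unidentified-call statistics."""

    read_count: int = 0
    length_histogram: Counter = field(default_factory=Counter)
    per_position_base_counts: list[Counter] = field(default_factory=list)
    per_position_quality_sum: list[int] = field(default_factory=list)
    per_position_count: list[int] = field(default_factory=list)
    reads_with_n: int = 0
    n_fraction_histogram: Counter = field(default_factory=Counter)

    def per_position_mean_quality(self) -> list[float]:
        return [
            s / c if c else float("nan")
            for s, c in zip(self.per_position_quality_sum, self.per_position_count)
        ]


def compute_qc_stats(reads: Iterable[SequenceRead]) -> ReadQCStats:
    """One pass over reads accumulating :class:`ReadQCStats`.

    N-fraction histogram bins are the fraction rounded to 2 decimals.
    """
    stats = ReadQCStats()
    for read in reads:
        n = len(read)
        stats.read_count += 1
        stats.length_histogram[n] += 1
        symbols = read.bases[1:] if read.is_color_space else read.bases
        unknown = "." if read.is_color_space else "N"
        while len(stats.per_position_base_counts) < n:
            stats.per_position_base_counts.append(Counter())
            stats.per_position_quality_sum.append(0)
            stats.per_position_count.append(0)
        for i in range(n):
            stats.per_position_base_counts[i][symbols[i]] += 1
            stats.per_position_quality_sum[i] += read.quals[i]
            stats.per_position_count[i] += 1
        n_count = symbols.count(unknown)
        if n_count:
            stats.reads_with_n += 1
        stats.n_fraction_histogram[round(n_count / n, 2) if n else 0.0] += 1
    return stats


# --------------------------------------------------------------------------
# Staged runner
# --------------------------------------------------------------------------


@dataclass
class PreprocessConfig:
    """Stage toggles and thresholds for :func:`run_preprocess`.

    Defaults follow the pipeline's standard exome settings: N-tail and RSQCI
    trimming on; drop reads shorter than 25, with more than 5% Ns, or with
    more than 5% positions below Phred 20.
    """

    trim_n: bool = True
    trim_rsqci_tails: bool = True
    trim_quality_threshold: Optional[int] = None
    trim_max_length: Optional[int] = None
    min_length: int = 25
    max_n_frac: float = 0.05
    lowq_threshold: int = 20
    max_lowq_frac: float = 0.05


@dataclass
class PreprocessResult:
    reads_r1: list[SequenceRead]
    reads_r2: Optional[list[SequenceRead]]
    accounting: list[FilterAccounting]
    qc_before: ReadQCStats
    qc_after: ReadQCStats


def _stages(config: PreprocessConfig):
    """(name, kind, fn) triples in the default stage order: trimmers first,
    then filters (length must be judged on the post-trim read)."""
    stages = []
    if config.trim_n:
        stages.append(("trim-n", "trim", lambda r: trim_nucleotide(r, "N")))
    if config.trim_rsqci_tails:
        stages.append(("trim-rsqci", "trim", trim_rsqci))
    if config.trim_quality_threshold is not None:
        q = config.trim_quality_threshold
        stages.append(("trim-quality", "trim", lambda r: trim_quality(r, q)))
    if config.trim_max_length is not None:
        m = config.trim_max_length
        stages.append(("trim-length", "trim", lambda r: trim_to_length(r, m)))
    stages.append(
        ("min-length-filter", "filter", lambda r: filter_length(r, config.min_length))
    )
    stages.append(
        ("n-max-filter", "filter", lambda r: filter_nmax(r, config.max_n_frac))
    )
    stages.append(
        (
            "quality-filter",
            "filter",
            lambda r: filter_quality(r, config.lowq_threshold, config.max_lowq_frac),
        )
    )
    return stages


def _strip_mate_suffix(read_id: str) -> str:
    head = read_id.split()[0] if read_id else read_id
    return head[:-2] if head.endswith(("/1", "/2")) else head


def run_preprocess(
    reads_r1: Iterable[SequenceRead],
    reads_r2: Optional[Iterable[SequenceRead]] = None,
    config: Optional[PreprocessConfig] = None,
) -> PreprocessResult:
    """Apply trimmers then filters stage by stage, with per-stage accounting.

    Single-end: pass ``reads_r2=None``.  Paired-end: both iterables must
    yield mates in matching order; a pair is removed whenever either mate
    fails a filter and both mates count as removed at that stage.
    """
    config = config or PreprocessConfig()
    r1 = list(reads_r1)
    r2 = list(reads_r2) if reads_r2 is not None else None
    paired = r2 is not None

    if paired:
        if len(r1) != len(r2):
            raise PairingError(f"R1 has {len(r1)} reads but R2 has {len(r2)}")
        for a, b in zip(r1, r2):
            if _strip_mate_suffix(a.read_id) != _strip_mate_suffix(b.read_id):
                raise PairingError(
                    f"mate identifiers diverge: {a.read_id!r} vs {b.read_id!r}"
                )
        qc_before = compute_qc_stats(r1 + r2)
    else:
        qc_before = compute_qc_stats(r1)

    accounting: list[FilterAccounting] = []
    for name, kind, fn in _stages(config):
        n_in = len(r1) * (2 if paired else 1)
        if kind == "trim":
            r1 = [fn(r) for r in r1]
            if paired:
                r2 = [fn(r) for r in r2]
            accounting.append(FilterAccounting(name, n_in, n_in, 0))
            continue
        if paired:
            keep = [fn(a) and fn(b) for a, b in zip(r1, r2)]
            r1 = [r for r, k in zip(r1, keep) if k]
            r2 = [r for r, k in zip(r2, keep) if k]
            n_out = 2 * len(r1)
        else:
            r1 = [r for r in r1 if fn(r)]
            n_out = len(r1)
        accounting.append(FilterAccounting(name, n_in, n_out, n_in - n_out))

    qc_after = compute_qc_stats(r1 + r2 if paired else r1)
    return PreprocessResult(r1, r2, accounting, qc_before, qc_after)


# --------------------------------------------------------------------------
# TSV export
# --------------------------------------------------------------------------


def accounting_table(accountings: Sequence[FilterAccounting]):
    """Per-stage accounting as a DataFrame (stage, input, passed, removed,
    passed_percent)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "stage": [a.stage_name for a in accountings],
            "input": [a.input_count for a in accountings],
            "passed": [a.passed_count for a in accountings],
            "removed": [a.removed_count for a in accountings],
            "passed_percent": [round(a.passed_percent, 1) for a in accountings],
        }
    )


def qc_stats_tables(stats: ReadQCStats):
    """QC statistics as DataFrames: (length histogram, per-position table,
    N-fraction histogram)."""
    import pandas as pd

    lengths = pd.DataFrame(
        sorted(stats.length_histogram.items()), columns=["length", "count"]
    )
    mean_q = stats.per_position_mean_quality()
    per_pos = pd.DataFrame(
        {
            "position": np.arange(1, len(stats.per_position_base_counts) + 1),
            **{
                b: [c.get(b, 0) for c in stats.per_position_base_counts]
                for b in "ACGTN"
            },
            "mean_quality": [round(q, 3) for q in mean_q],
        }
    )
    n_hist = pd.DataFrame(
        sorted(stats.n_fraction_histogram.items()), columns=["n_fraction", "count"]
    )
    return lengths, per_pos, n_hist
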