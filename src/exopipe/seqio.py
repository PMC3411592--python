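"""Readers, writers and quality-encoding conversion for the standard formats
the pipeline touches: FASTQ (Sanger / Solexa / Illumina 1.3+ dialects), ABI
SOLiD csfasta + qual pairs, BED, SAM and VCF.

FASTQ dialects differ in their ASCII offset and quality scale: Sanger is
Phred+33 (q in [0, 93]), Illumina 1.3+ is Phred+64 (q in [0, 62]) and Solexa
is odds-based with offset 64 (q in [-5, 62]).  Solexa scores q_s relate to
error probability p by q_s = 10*log10(p/(1-p)), so conversion to Phred goes
through probability space rather than a constant offset.

SAM and VCF I/O are delegated to pysam; FASTQ/FASTA parsing to Biopython.
Output VCFs carry a minimal but standards-valid header so they re-parse.
"""
from __future__ import annotations

import math
import re
from itertools import zip_longest
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

import pysam
from Bio import SeqIO

from .model import AlignmentRecord, GenomicInterval, SequenceRead, VariantRecord

Source = Union[str, Path, IO[str]]


class FormatError(ValueError):
    """Malformed input in one of the supported text formats."""


class PairingError(ValueError):
    """Two files that must describe the same records disagree."""


# --------------------------------------------------------------------------
# FASTQ dialect detection and quality conversion
# --------------------------------------------------------------------------

#: (ascii_offset, min_quality, max_quality) per encoding; solid qualities are
#: numeric (qual file), listed for range checks only.
_ENC_RANGES = {
    "sanger": (33, 0, 93),
    "solexa": (64, -5, 62),
    "illumina13": (64, 0, 62),
    "solid": (33, -1, 93),
}

_BIO_FORMAT = {
    "sanger": "fastq-sanger",
    "solexa": "fastq-solexa",
    "illumina13": "fastq-illumina",
}


def detect_fastq_dialect(quality_lines: Iterable[str], default: str = "sanger") -> str:
    """Guess the FASTQ dialect from a sample of quality lines.

    The three dialects occupy overlapping ASCII windows (Sanger 33-126,
    Solexa 59-126, Illumina 1.3+ 64-126), so only a character below the next
    window's floor is diagnostic; a sample living entirely in the shared
    range resolves to *default*.
    """
    min_code: Optional[int] = None
    seen = False
    for line in quality_lines:
        for ch in line.rstrip("\n"):
            seen = True
            code = ord(ch)
            if code < 33 or code > 126:
                raise FormatError(
                    f"quality character code {code} outside all FASTQ dialect ranges"
                )
            if min_code is None or code < min_code:
                min_code = code
    if not seen:
        raise FormatError("no quality characters to detect a dialect from")
    assert min_code is not None
    if min_code < 59:
        return "sanger"
    if min_code < 64:
        return "solexa"
    return default


def _to_phred(q: float, enc: str) -> float:
    if enc == "solexa":
        return 10.0 * math.log10(10.0 ** (q / 10.0) + 1.0)
    return float(q)


def _from_phred(p: float, enc: str) -> float:
    if enc == "solexa":
        if p <= 0:
            return -5.0
        ratio = 10.0 ** (p / 10.0) - 1.0
        if ratio <= 10.0 ** (-0.5):  # below the Solexa floor of -5
            return -5.0
        return 10.0 * math.log10(ratio)
    return float(p)


def convert_quality(q: int, from_enc: str, to_enc: str) -> int:
    """Convert one quality value between encodings.

    Sanger and Illumina 1.3+ share the Phred scale (offset arithmetic only);
    Solexa conversions go through probability space.  Rounding is
    half-up; the result is clamped to the target encoding's range.
    """
    for enc in (from_enc, to_enc):
        if enc not in _ENC_RANGES or enc == "solid":
            raise ValueError(f"unsupported quality encoding {enc!r}")
    lo, hi = _ENC_RANGES[from_enc][1], _ENC_RANGES[from_enc][2]
    if not lo <= q <= hi:
        raise ValueError(f"quality {q} outside {from_enc} range [{lo}, {hi}]")
    if from_enc == to_enc:
        return q
    value = _from_phred(_to_phred(q, from_enc), to_enc)
    rounded = math.floor(value + 0.5)
    lo, hi = _ENC_RANGES[to_enc][1], _ENC_RANGES[to_enc][2]
    return max(lo, min(hi, rounded))


def convert_read(read: SequenceRead, to_enc: str = "sanger") -> SequenceRead:
    """Re-encode a nucleotide-space read's qualities."""
    if read.encoding == to_enc:
        return read
    if read.is_color_space:
        raise ValueError("color-space reads keep SOLiD numeric qualities")
    quals = [convert_quality(q, read.encoding, to_enc) for q in read.quals]
    return SequenceRead(read.read_id, read.bases, quals, to_enc, read.mate)


def infer_mate(filename: Union[str, Path]) -> str:
    """Paired-end role from the file name: stems ending _R1 / _R2."""
    stem = Path(filename).name
    stem = re.sub(r"\.(fastq|fq|csfasta|qual)(\.gz)?$", "", stem)
    if stem.endswith("_R1"):
        return "R1"
    if stem.endswith("_R2"):
        return "R2"
    return "none"


# --------------------------------------------------------------------------
# FASTQ / csfasta
# --------------------------------------------------------------------------


def _open(source: Source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_fastq(
    source: Source, encoding: str = "sanger", mate: str = "none"
) -> Iterator[SequenceRead]:
    """Parse a FASTQ file in the given dialect into :class:`SequenceRead`s.

    Qualities are kept on the dialect's native scale; use
    :func:`convert_read` to normalise to Sanger.
    """
    if encoding not in _BIO_FORMAT:
        raise ValueError(f"not a FASTQ encoding: {encoding!r}")
    handle, owned = _open(source)
    qual_key = "solexa_quality" if encoding == "solexa" else "phred_quality"
    try:
        for rec in SeqIO.parse(handle, _BIO_FORMAT[encoding]):
            yield SequenceRead(
                read_id=rec.description or rec.id,
                bases=str(rec.seq),
                quals=list(rec.letter_annotations[qual_key]),
                encoding=encoding,
                mate=mate,
            )
    finally:
        if owned:
            handle.close()


def write_fastq(reads: Iterable[SequenceRead], dest: Source) -> int:
    """Write reads as Sanger FASTQ (converting other dialects), returning the
    record count."""
    handle, owned = _open(dest, "w")
    n = 0
    try:
        for read in reads:
            sanger = convert_read(read, "sanger")
            qual = "".join(chr(q + 33) for q in sanger.quals)
            handle.write(f"@{sanger.read_id}\n{sanger.bases}\n+\n{qual}\n")
            n += 1
    finally:
        if owned:
            handle.close()
    return n


def _strip_comments(handle: IO[str]) -> IO[str]:
    """csfasta/qual files may start with '#' comment lines Biopython's FASTA
    parser does not expect; return a filtered file-like object."""
    import io as _io

    return _io.StringIO(
        "".join(line for line in handle if not line.startswith("#"))
    )


def read_csfasta_qual(
    csfasta: Source, qual: Source, mate: str = "none"
) -> Iterator[SequenceRead]:
    """Pair an ABI SOLiD csfasta file with its qual file positionally.

    Both are FASTA-layout; the csfasta sequence is an adapter base followed by
    color digits, the qual file lists one integer per color.  Identifiers must
    match record-for-record.
    """
    cs_handle, cs_owned = _open(csfasta)
    q_handle, q_owned = _open(qual)
    try:
        cs_iter = SeqIO.parse(_strip_comments(cs_handle), "fasta")
        q_iter = SeqIO.parse(_strip_comments(q_handle), "qual")
        for i, (cs, qr) in enumerate(zip_longest(cs_iter, q_iter)):
            if cs is None or qr is None:
                short = "qual" if cs is not None else "csfasta"
                present = cs if cs is not None else qr
                raise PairingError(
                    f"{short} file ran out at record {i + 1} "
                    f"(unmatched {present.id!r})"
                )
            if cs.id != qr.id:
                raise PairingError(
                    f"record {i + 1}: csfasta id {cs.id!r} != qual id {qr.id!r}"
                )
            yield SequenceRead(
                read_id=cs.id,
                bases=str(cs.seq),
                quals=list(qr.letter_annotations["phred_quality"]),
                encoding="solid",
                mate=mate,
            )
    finally:
        if cs_owned:
            cs_handle.close()
        if q_owned:
            q_handle.close()


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------


def read_bed(source: Source) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open, per the BED standard)."""
    handle, owned = _open(source)
    intervals = []
    try:
        for ln, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line {ln}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            intervals.append(GenomicInterval(chrom, start, end, name))
    finally:
        if owned:
            handle.close()
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], dest: Source) -> int:
    handle, owned = _open(dest, "w")
    n = 0
    try:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            n += 1
    finally:
        if owned:
            handle.close()
    return n


def normalize_targets(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort intervals and merge overlapping/adjacent ones per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged.pop()
            merged.append(
                GenomicInterval(last.chrom, last.start, max(last.end, iv.end), last.name)
            )
        else:
            merged.append(iv)
    return merged


# --------------------------------------------------------------------------
# SAM (via pysam)
# --------------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=XB"


def _from_pysam(a: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = [(_CIGAR_OPS[op], n) for op, n in (a.cigartuples or [])]
    return AlignmentRecord(
        qname=a.query_name or "",
        flag=a.flag,
        rname=a.reference_name,
        pos=0 if a.is_unmapped else a.reference_start + 1,
        mapq=a.mapping_quality,
        cigar=cigar,
        tlen=a.template_length,
        seq=a.query_sequence or "",
        quals=list(a.query_qualities or []),
        rnext=a.next_reference_name,
        pnext=0 if a.next_reference_id < 0 else a.next_reference_start + 1,
    )


def read_sam(path: Union[str, Path]) -> Iterator[AlignmentRecord]:
    """Iterate alignments of a SAM/BAM file as :class:`AlignmentRecord`s."""
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for a in sam:
            yield _from_pysam(a)


def read_sam_header(path: Union[str, Path]) -> dict[str, int]:
    """Reference name → length mapping from the @SQ header lines."""
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        return dict(zip(sam.references, sam.lengths))


def write_sam(
    records: Iterable[AlignmentRecord],
    path: Union[str, Path],
    references: dict[str, int],
) -> int:
    """Write records as headered SAM; returns the record count."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
        }
    )
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header=header)
            a.query_name = rec.qname
            a.flag = rec.flag
            if rec.rname is not None and not rec.is_unmapped:
                a.reference_name = rec.rname
                a.reference_start = rec.pos - 1
                a.cigarstring = "".join(f"{ln}{op}" for op, ln in rec.cigar) or None
            a.mapping_quality = rec.mapq
            if rec.rnext is not None:
                a.next_reference_name = rec.rnext
                a.next_reference_start = rec.pnext - 1
            a.template_length = rec.tlen
            a.query_sequence = rec.seq or None
            if rec.quals:
                a.query_qualities = rec.quals
            out.write(a)
            n += 1
    return n


# --------------------------------------------------------------------------
# VCF (read via pysam, minimal writer)
# --------------------------------------------------------------------------


def _split_alleles(rec) -> Iterator[VariantRecord]:
    """Yield one VariantRecord per alternate allele of a pysam variant.

    Genotype allele indices are re-expressed relative to the row's alt: the
    row's own alt becomes 1, reference stays 0, any *other* alt becomes 2 so
    mixed-alt heterozygotes remain visibly heterozygous after the split.
    """
    def lookup(mapping, key):
        # pysam raises rather than returning None for keys absent from the
        # header definition
        try:
            return mapping.get(key)
        except (KeyError, ValueError):
            return None

    sample = rec.samples[0] if rec.samples else None
    gt = tuple(sample["GT"]) if sample is not None and "GT" in sample else None
    depth = None
    if sample is not None and lookup(sample, "DP") is not None:
        depth = int(sample["DP"])
    elif lookup(rec.info, "DP") is not None:
        depth = int(rec.info["DP"])
    ad = None
    if sample is not None and lookup(sample, "AD"):
        ad = tuple(sample["AD"])
    annotations = {}
    for key, value in rec.info.items():
        if key == "DP":
            continue
        if isinstance(value, (tuple, list)):
            annotations[key] = ",".join(str(v) for v in value)
        elif value is True:
            annotations[key] = key
        else:
            annotations[key] = str(value)
    for i, alt in enumerate(rec.alts or (), start=1):
        genotype = None
        if gt is not None and None not in gt:
            mapped = tuple(0 if g == 0 else (1 if g == i else 2) for g in gt)
            genotype = (min(mapped), max(mapped))
        alt_depth = None
        if ad is not None and len(ad) > i and ad[i] is not None:
            alt_depth = int(ad[i])
        ref_depth = int(ad[0]) if ad is not None and ad[0] is not None else None
        yield VariantRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            vid=rec.id or ".",
            ref=rec.ref,
            alt=alt,
            qual=rec.qual,
            genotype=genotype,
            depth=depth,
            alt_depth=alt_depth,
            ref_depth=ref_depth,
            annotations=annotations,
        )


def read_vcf(path: Union[str, Path]) -> Iterator[VariantRecord]:
    """Iterate a VCF, splitting multi-allelic records into per-alt rows."""
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            yield from _split_alleles(rec)


def write_vcf(
    variants: Iterable[VariantRecord],
    path: Union[str, Path],
    contigs: Optional[dict[str, int]] = None,
    info_keys: Optional[Iterable[str]] = None,
) -> int:
    """Write variants as a single-sample VCF v4.2 with a minimal valid header.

    INFO keys are declared as ``Number=1,Type=String``; genotype data goes out
    as GT:DP:AD.  The output re-parses through :func:`read_vcf`.
    """
    variants = list(variants)
    if info_keys is None:
        keys: list[str] = []
        for v in variants:
            for k in v.annotations:
                if k not in keys:
                    keys.append(k)
        info_keys = keys
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            out.write(f"##contig=<ID={name},length={length}>\n")
        for key in info_keys:
            out.write(
                f'##INFO=<ID={key},Number=1,Type=String,Description="{key}">\n'
            )
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        n = 0
        for v in variants:
            info = ";".join(
                f"{k}={v.annotations[k]}" for k in info_keys if k in v.annotations
            ) or "."
            qual = "." if v.qual is None else f"{v.qual:g}"
            gt = "./." if v.genotype is None else f"{v.genotype[0]}/{v.genotype[1]}"
            dp = "." if v.depth is None else str(v.depth)
            if v.alt_depth is None:
                ad = "."
            else:
                ref_d = v.ref_depth
                if ref_d is None and v.depth is not None:
                    ref_d = v.depth - v.alt_depth
                ad = f"{ref_d if ref_d is not None else '.'},{v.alt_depth}"
            out.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t{qual}\t.\t{info}"
                f"\tGT:DP:AD\t{gt}:{dp}:{ad}\n"
            )
            n += 1
    return n
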