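"""Multi-section summary report and the end-to-end pipeline driver.

The report mirrors the pipeline's four-section summary document:

1. alignment key figures — exome size, genome and exome fold coverage,
   capture specificity, expected chance duplicates, coverage-bin fractions;
2. filter performance — one row per preprocessing / alignment filter stage
   with counts and the percentage passed;
3. DIP summary — deletion/insertion counts, RefSeq association, coding
   calls, zygosity counts;
4. SNP summary — counts, dbSNP fraction, Ti/Tv, zygosity counts.

The on-disk form is a sectioned TSV (one ``## section`` block per section,
blank-line separated); raw values are written losslessly (``repr`` for
floats) next to a one-decimal display column, so parsing the file
reconstructs every numeric field exactly.  Sections that were not run are
rendered as explicit ``not run`` markers, never dropped.

``run_all`` chains preprocessing, alignment filtering, statistics, variant
post-processing and report generation over files on disk.  It is resumable:
a stage whose outputs all exist and are newer than its inputs is skipped,
so re-running a finished pipeline rewrites nothing and the report stays
byte-identical.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import alnfilter, alnstats, preprocess, seqio, variants as variants_mod
from .model import FilterAccounting
from .variants import VariantSummary

logger = logging.getLogger(__name__)

NOT_RUN = "not run"


# --------------------------------------------------------------------------
# Report model
# --------------------------------------------------------------------------


@dataclass
class SummaryReport:
    key_figures: Optional[dict[str, Optional[float]]] = None
    filter_rows: list[FilterAccounting] = field(default_factory=list)
    dip_summary: Optional[dict[str, Optional[float]]] = None
    snp_summary: Optional[dict[str, Optional[float]]] = None


def build_report(
    accountings: Sequence[FilterAccounting],
    key_figures: Optional[dict[str, Optional[float]]] = None,
    variant_summary: Optional[VariantSummary] = None,
) -> SummaryReport:
    """Assemble the four report sections; pass None for anything not run."""
    dip = snp = None
    if variant_summary is not None:
        s = variant_summary
        dip = {
            "n_dips": s.n_dips,
            "n_deletions": s.n_deletions,
            "n_insertions": s.n_insertions,
            "n_refseq_associated": s.n_dip_refseq_associated,
            "refseq_fraction": s.dip_refseq_fraction,
            "n_coding": s.n_dip_coding,
            "n_hom": s.n_hom_dip,
            "n_het": s.n_het_dip,
        }
        snp = {
            "n_snps": s.n_snps,
            "n_dbsnp": s.n_dbsnp,
            "dbsnp_fraction": s.dbsnp_fraction,
            "titv_ratio": s.titv,
            "n_hom": s.n_hom_snp,
            "n_het": s.n_het_snp,
        }
    return SummaryReport(
        key_figures=dict(key_figures) if key_figures is not None else None,
        filter_rows=list(accountings),
        dip_summary=dip,
        snp_summary=snp,
    )


def _fmt_raw(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _fmt_display(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, float):
        return f"{value:.1f}"
    return str(value)


def _write_kv_section(fh, title: str, data: Optional[dict], sep: str) -> None:
    fh.write(f"## {title}\n")
    if data is None:
        fh.write(f"{NOT_RUN}\n\n")
        return
    fh.write(sep.join(("key", "value", "display")) + "\n")
    for key, value in data.items():
        fh.write(sep.join((key, _fmt_raw(value), _fmt_display(value))) + "\n")
    fh.write("\n")


def write_report(
    report: SummaryReport, out_path: Union[str, Path], format: str = "tsv"
) -> Path:
    """Write the sectioned report; ``format`` is ``tsv`` or ``csv``."""
    sep = {"tsv": "\t", "csv": ","}[format]
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        _write_kv_section(fh, "alignment key figures", report.key_figures, sep)
        fh.write("## filter performance\n")
        fh.write(sep.join(("stage", "input", "passed", "removed",
                           "passed_percent")) + "\n")
        for row in report.filter_rows:
            fh.write(sep.join((
                row.stage_name, str(row.input_count), str(row.passed_count),
                str(row.removed_count), f"{row.passed_percent:.1f}",
            )) + "\n")
        fh.write("\n")
        _write_kv_section(fh, "DIP summary", report.dip_summary, sep)
        _write_kv_section(fh, "SNP summary", report.snp_summary, sep)
    return out_path


def _parse_number(text: str):
    if text == "NA":
        return None
    try:
        return int(text)
    except ValueError:
        return float(text)


def read_report(path: Union[str, Path], format: str = "tsv") -> SummaryReport:
    """Parse a written report back; numeric fields reconstruct exactly
    (percentages are recomputed from the exact counts)."""
    sep = {"tsv": "\t", "csv": ","}[format]
    sections: dict[str, list[list[str]]] = {}
    current: Optional[str] = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("## "):
            current = line[3:]
            sections[current] = []
        elif line and current is not None:
            sections[current].append(line.split(sep))
    report = SummaryReport()

    def parse_kv(name: str) -> Optional[dict]:
        rows = sections.get(name, [])
        if rows and rows[0][0] == NOT_RUN:
            return None
        return {row[0]: _parse_number(row[1]) for row in rows[1:]}

    report.key_figures = parse_kv("alignment key figures")
    for row in sections.get("filter performance", [])[1:]:
        report.filter_rows.append(
            FilterAccounting(row[0], int(row[1]), int(row[2]), int(row[3]))
        )
    report.dip_summary = parse_kv("DIP summary")
    report.snp_summary = parse_kv("SNP summary")
    return report


# --------------------------------------------------------------------------
# Pipeline driver
# --------------------------------------------------------------------------


@dataclass
class PipelineInputs:
    """File inputs for :func:`run_all`.

    Alignment itself is external (BWA-class tools): the driver consumes the
    raw reads for preprocessing/QC accounting and an already-aligned SAM for
    everything downstream, plus the capture-target BED and (optionally)
    caller-produced SNP/DIP VCFs.
    """

    fastq_r1: Union[str, Path]
    sam: Union[str, Path]
    targets_bed: Union[str, Path]
    fastq_r2: Optional[Union[str, Path]] = None
    encoding: str = "sanger"
    snp_vcf: Optional[Union[str, Path]] = None
    dip_vcf: Optional[Union[str, Path]] = None
    dsP: float = 80.0
    preprocess_config: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig
    )
    alnfilter_config: alnfilter.AlnFilterConfig = field(
        default_factory=alnfilter.AlnFilterConfig
    )


def _fresh(outputs: Sequence[Path], inputs: Sequence[Path]) -> bool:
    """True when every output exists and is at least as new as every input."""
    if not all(p.exists() for p in outputs):
        return False
    newest_in = max((p.stat().st_mtime for p in inputs), default=0.0)
    return all(p.stat().st_mtime >= newest_in for p in outputs)


def _write_kv(path: Path, data: dict) -> None:
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in data.items():
            fh.write(f"{key}\t{_fmt_raw(value)}\n")


def _read_kv(path: Path) -> dict:
    out = {}
    for line in path.read_text().splitlines()[1:]:
        key, value = line.split("\t")
        out[key] = _parse_number(value)
    return out


def _read_accounting(path: Path) -> list[FilterAccounting]:
    df = pd.read_csv(path, sep="\t")
    return [
        FilterAccounting(r.stage, int(r.input), int(r.passed), int(r.removed))
        for r in df.itertuples()
    ]


def run_all(
    inputs: PipelineInputs, out_dir: Union[str, Path], force: bool = False
) -> Path:
    """Run preprocess → alignment filter → statistics → variants → report
    over files, skipping any stage whose outputs are already up to date.

    Returns the path of the final report TSV.
    """
    out = Path(out_dir)
    for sub in ("preprocess", "alnfilter", "stats", "variants"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    paired = inputs.fastq_r2 is not None

    # -- stage 1: preprocessing ------------------------------------
    pre_out = out / "preprocess"
    pre_files = [pre_out / "accounting.tsv", pre_out / "filtered_R1.fastq"]
    if paired:
        pre_files.append(pre_out / "filtered_R2.fastq")
    pre_inputs = [Path(inputs.fastq_r1)] + ([Path(inputs.fastq_r2)] if paired else [])
    if force or not _fresh(pre_files, pre_inputs):
        logger.info("stage preprocess: running")
        r1 = seqio.read_fastq(inputs.fastq_r1, inputs.encoding, mate="R1" if paired else "none")
        r2 = seqio.read_fastq(inputs.fastq_r2, inputs.encoding, mate="R2") if paired else None
        result = preprocess.run_preprocess(r1, r2, inputs.preprocess_config)
        seqio.write_fastq(result.reads_r1, pre_out / "filtered_R1.fastq")
        if paired:
            seqio.write_fastq(result.reads_r2, pre_out / "filtered_R2.fastq")
        preprocess.accounting_table(result.accounting).to_csv(
            pre_out / "accounting.tsv", sep="\t", index=False
        )
        for tag, stats in (("before", result.qc_before), ("after", result.qc_after)):
            lengths, per_pos, n_hist = preprocess.qc_stats_tables(stats)
            lengths.to_csv(pre_out / f"qc_{tag}_lengths.tsv", sep="\t", index=False)
            per_pos.to_csv(pre_out / f"qc_{tag}_per_position.tsv", sep="\t", index=False)
            n_hist.to_csv(pre_out / f"qc_{tag}_n_fractions.tsv", sep="\t", index=False)
    else:
        logger.info("stage preprocess: up to date, skipped")

    # -- stage 2: alignment filtering ------------------------------
    aln_out = out / "alnfilter"
    aln_files = [aln_out / "filtered.sam", aln_out / "accounting.tsv"]
    aln_inputs = [Path(inputs.sam), Path(inputs.targets_bed)]
    targets = None
    if force or not _fresh(aln_files, aln_inputs):
        logger.info("stage alnfilter: running")
        targets = alnfilter.TargetIndex(seqio.read_bed(inputs.targets_bed))
        records = list(seqio.read_sam(inputs.sam))
        kept, accountings = alnfilter.run_alnfilter(
            records, targets, inputs.alnfilter_config
        )
        seqio.write_sam(kept, aln_out / "filtered.sam",
                        seqio.read_sam_header(inputs.sam))
        preprocess.accounting_table(accountings).to_csv(
            aln_out / "accounting.tsv", sep="\t", index=False
        )
    else:
        logger.info("stage alnfilter: up to date, skipped")

    # -- stage 3: statistics ---------------------------------------
    stats_out = out / "stats"
    stats_files = [stats_out / "key_figures.tsv", stats_out / "exon_coverage.tsv"]
    stats_inputs = [aln_out / "filtered.sam", aln_out / "accounting.tsv",
                    Path(inputs.targets_bed), Path(inputs.sam)]
    if force or not _fresh(stats_files, stats_inputs):
        logger.info("stage stats: running")
        if targets is None:
            targets = alnfilter.TargetIndex(seqio.read_bed(inputs.targets_bed))
        header = seqio.read_sam_header(inputs.sam)
        genome_length = sum(header.values())
        raw = list(seqio.read_sam(inputs.sam))
        filtered = list(seqio.read_sam(aln_out / "filtered.sam"))
        aln_acc = _read_accounting(aln_out / "accounting.tsv")
        bam = alnstats.bam_stats(raw, genome_length)
        summary = alnstats.alignment_summary_metrics(filtered)
        coverage = alnstats.exon_coverage(filtered, targets)
        # capture specificity: exome-filter survivors over its mapped,
        # deduplicated input reads (the stage-4 accounting row)
        exome_row = aln_acc[-1]
        capture = (
            exome_row.passed_count / exome_row.input_count
            if exome_row.input_count else None
        )
        dup_row = aln_acc[2]
        expected_dup = alnstats.expected_duplicates_by_chance(
            dup_row.input_count, 2 * targets.total_length
        ) if targets.total_length else None
        figures = {
            "exome_size_bases": targets.total_length,
            "exome_interval_count": len(targets),
            "total_reads": bam.total_reads,
            "mapped_reads": bam.mapped,
            "unmapped_reads": bam.unmapped,
            "genome_fold_coverage": bam.genome_fold_coverage,
            "exome_fold_coverage": coverage.exome_fold_coverage,
            "capture_specificity_percent":
                100.0 * capture if capture is not None else None,
            "expected_duplicates_by_chance": expected_dup,
            "fraction_targets_below_1x": coverage.fraction_intervals_below(1.0),
            "fraction_targets_at_or_above_20x":
                coverage.fraction_intervals_at_or_above(20.0),
            "median_read_length": summary.median_read_length,
            "high_quality_aligned_bases": summary.high_quality_aligned_bases,
            "insertion_rate": summary.insertion_rate,
            "deletion_rate": summary.deletion_rate,
        }
        insert = alnstats.insert_size_metrics(filtered)
        if insert.count:
            figures["insert_size_mean"] = insert.mean
            figures["insert_size_median"] = insert.median
            figures["insert_size_sd"] = insert.sd
            pd.DataFrame(
                sorted(insert.histogram.items()), columns=["insert_size", "count"]
            ).to_csv(stats_out / "insert_size_histogram.tsv", sep="\t", index=False)
        _write_kv(stats_out / "key_figures.tsv", figures)
        pd.DataFrame(
            {
                "name": [c.interval.name for c in coverage.per_interval],
                "chrom": [c.interval.chrom for c in coverage.per_interval],
                "start": [c.interval.start for c in coverage.per_interval],
                "end": [c.interval.end for c in coverage.per_interval],
                "read_count": [c.read_count for c in coverage.per_interval],
                "covered_bases": [c.covered_bases for c in coverage.per_interval],
                "fold_coverage": [round(c.fold_coverage, 4)
                                  for c in coverage.per_interval],
            }
        ).to_csv(stats_out / "exon_coverage.tsv", sep="\t", index=False)
    else:
        logger.info("stage stats: up to date, skipped")

    # -- stage 4: variants (optional) ------------------------------
    var_out = out / "variants"
    have_variants = inputs.snp_vcf is not None and inputs.dip_vcf is not None
    if have_variants:
        var_files = [var_out / "summary.tsv"]
        var_inputs = [Path(inputs.snp_vcf), Path(inputs.dip_vcf)]
        if force or not _fresh(var_files, var_inputs):
            logger.info("stage variants: running")
            snps = list(seqio.read_vcf(inputs.snp_vcf))
            dips = list(seqio.read_vcf(inputs.dip_vcf))
            summary = variants_mod.variant_summaries(snps, dips, inputs.dsP)
            for name, records in (("snp", snps), ("dip", dips)):
                split = variants_mod.split_zygosity(records, inputs.dsP)
                seqio.write_vcf(split.homozygous, var_out / f"{name}s_hom.vcf")
                seqio.write_vcf(split.heterozygous, var_out / f"{name}s_het.vcf")
            _write_kv(var_out / "summary.tsv", vars(summary))
        else:
            logger.info("stage variants: up to date, skipped")

    # -- stage 5: report -------------------------------------------
    report_path = out / "report.tsv"
    report_inputs = [pre_out / "accounting.tsv", aln_out / "accounting.tsv",
                     stats_out / "key_figures.tsv"]
    if have_variants:
        report_inputs.append(var_out / "summary.tsv")
    if force or not _fresh([report_path], report_inputs):
        logger.info("stage report: running")
        accountings = _read_accounting(pre_out / "accounting.tsv") + _read_accounting(
            aln_out / "accounting.tsv"
        )
        figures = _read_kv(stats_out / "key_figures.tsv")
        variant_summary = None
        if have_variants:
            raw = _read_kv(var_out / "summary.tsv")
            variant_summary = VariantSummary(**raw)
        report = build_report(accountings, figures, variant_summary)
        write_report(report, report_path)
    else:
        logger.info("stage report: up to date, skipped")
    return report_path
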