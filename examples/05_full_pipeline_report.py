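"""End-to-end run: fixture files in, four-section summary report out.

Writes a complete synthetic fixture (FASTQ, SAM, BED, VCFs) to a temporary
directory, runs the resumable pipeline driver over the files, and prints
the final report.  Running the driver a second time skips every stage.
"""
import tempfile
from pathlib import Path

from exopipe import report, synthdata

plan = synthdata.FixturePlan(seed=5, n_good_reads=400, fail_length=9,
                             fail_nmax=6, fail_quality=5, n_reads=1_000,
                             n_duplicates=40, n_unmapped=30, n_snps=600,
                             n_dips=80)
with tempfile.TemporaryDirectory() as tmp:
    paths = synthdata.write_fixture(synthdata.generate(plan),
                                    Path(tmp) / "fixture")
    inputs = report.PipelineInputs(
        fastq_r1=paths["reads_r1"], sam=paths["alignments"],
        targets_bed=paths["targets"], snp_vcf=paths["snps"],
        dip_vcf=paths["dips"],
    )
    report_path = report.run_all(inputs, Path(tmp) / "run")
    print(report_path.read_text())

print("Sections: alignment key figures, filter performance (every stage's")
print("counts), DIP summary, SNP summary.  Each display percentage sits")
print("next to the exact value it was computed from.")
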