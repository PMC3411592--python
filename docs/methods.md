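# Methods

This note documents the models and procedures `exopipe` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Quality encodings and conversion

Three FASTQ dialects are supported. Sanger is Phred+33 with quality range
[0, 93]; Illumina 1.3+ is Phred+64 with range [0, 62]; Solexa uses offset 64
but an odds-based scale in [−5, 62], where Q_solexa = −10·log₁₀(p/(1−p)) for
error probability p. Illumina 1.3+ → Sanger is therefore pure offset
arithmetic, while Solexa → Sanger goes through probability space:

    Q_phred = 10·log₁₀(10^(Q_solexa/10) + 1)

rounded half-up (`floor(x + 0.5)`), matching the published conversion
tables, and clamped to the target range. The mapping converges to the
identity: for Q ≥ 10 the difference is at most 1. Tests verify the full
range against an independent odds → p → Phred brute force and against
Biopython's converter.

Dialect auto-detection is a heuristic over observed character codes: any
code below 59 proves Sanger, codes in [59, 64) prove Solexa, and a sample
confined to the shared window [64, 126] is genuinely ambiguous and resolves
to a caller-supplied default. Every entry point also accepts an explicit
encoding that bypasses detection, because overlapping ranges make any
heuristic fallible.

Color-space (ABI SOLiD) reads arrive as csfasta + qual pairs, carried as an
adapter base plus color digits with one quality per color. They pass
through length/quality logic unchanged (quality semantics carry over);
base-identity operations such as N-trimming do not apply to colors and are
skipped with a logged notice. Conversion to aligner-ready double encoding
is out of scope since alignment is external.

## Read preprocessing

Stage order: trimmers first, then filters, because read length must be
judged on the post-trim read. Defaults:

| stage | rule | default |
|---|---|---|
| trim-n | strip 5′/3′ runs of N (interior Ns untouched) | on |
| trim-rsqci | strip trailing run at Phred = 2, the Illumina Read Segment Quality Control Indicator | on |
| trim-quality | strip trailing bases below Q | off |
| trim-length | 3′ hard truncation | off |
| min-length-filter | fail if length < 25 (25 passes) | 25 bp |
| n-max-filter | fail if N fraction strictly exceeds 5% | 0.05 |
| quality-filter | fail if the fraction of positions below Phred 20 strictly exceeds 5% | 0.05, Q20 |

The 25 bp / 5% / 5% thresholds are the pipeline's standard exome settings;
the Phred 20 definition of an "unreliable" call is a conventional
high-confidence cutoff and is exposed as a parameter. Filters always see
post-trim reads. For paired-end data a pair is dropped when either mate
fails a filter, with both mates counted as removed at that stage: emitting
singletons would break aligner-ready pairing, and the symmetric contract is
the simplest correct one. Every stage emits accounting with the invariant
input = passed + removed (an empty stage reports 100% passed).

## Alignment filtering

Fixed order: mapping → proper-pair → duplicates → exome. The mapping
filter also drops secondary and supplementary alignments so downstream
coverage never double-counts a read. The proper-pair filter is an identity
(with a logged notice) on single-end data.

Duplicate detection is coordinate-based. A single-end key is (reference,
strand, unclipped 5′ start), where the unclipped start undoes leading
(forward) or trailing (reverse) soft/hard clips so that differentially
clipped copies of one fragment still collide. Paired fragments are keyed by
both mates' triples, order-normalised, and flagged as a unit — the physical
PCR event duplicates fragments, not single ends. Within a group the record
(or pair) with the highest base-quality sum is kept, ties broken by
lexicographically smallest query name; this is the de-facto convention of
coordinate duplicate-marking tools and makes the choice deterministic and
order-independent. Both marking (flag) and removal (drop) modes exist.

The exome filter keeps a record when its reference footprint — the
contiguous span consumed by M/D/=/X operations; N splits it, insertions and
clips don't touch it — overlaps any single target by at least `min_overlap`
bases (default 1, the weakest reading of "overlaps"; configurable for
padded designs). Reads on chromosomes absent from the target set count as
off-target with a warning. Whether the original design used the full
footprint or just the start position is unknowable from its description;
the footprint is the more faithful notion of overlap and is what the
per-base oracle validates.

## Alignment statistics

- Genome fold coverage: aligned (M/=/X) query bases of mapped reads over
  genome length.
- Per-exon coverage: a read counts toward every target its footprint
  overlaps; its base contribution is |footprint ∩ target|. Exome fold
  coverage is total on-target bases over total target length — a
  length-weighted figure, deliberately not the mean of per-exon folds.
  Narrative coverage bins are <1× ("not covered") and ≥20× ("highly
  covered"), with configurable edges.
- Capture specificity: on-target / mapped reads, computed after duplicate
  removal. The read unit is the default (a base-level variant exists
  behind a flag); undefined (NA) with zero mapped reads.
- Insert sizes: one observation per fragment (the mate with positive
  TLEN), statistics over |TLEN|. Fragments beyond 10× the median are
  excluded from mean/sd — chimeric pairs otherwise dominate both — but
  stay in the histogram. Sample sd (ddof 1).
- Expected chance duplicates: with n fragments uniform over P sites,
  E[occupied] = P·(1 − (1 − 1/P)^n), so E[flagged] = n − E[occupied].
  P defaults to 2 × target length (both strands). The formula is an
  in-package model validated only against its own Monte-Carlo oracle
  (within 3 standard errors at 10,000 reps), never against external data.
  The expm1/log1p formulation keeps precision for large P; P = 1 is
  handled exactly (n − 1).

## Variant post-processing

Variant class is decided purely by allele length (equal → SNP, longer alt →
insertion, shorter → deletion); multi-allelic records are split into
per-alt rows on input, with genotype indices re-expressed so a mixed-alt
heterozygote stays visibly heterozygous. SNP zygosity comes from the
genotype (two identical non-reference alleles → homozygous). DIP zygosity
uses the alt-read percentage against `dsP` (default 80): homozygous iff
100·AD/DP ≥ dsP. The boundary is inclusive so dsP = 100 still classifies
pure-alt sites; the denominator is total depth, switchable to ref+alt
depth. Zero-depth or genotype-less variants go to an explicit
"unclassifiable" bucket rather than silently into either class.

Ti/Tv counts A↔G and C↔T as transitions and the remaining eight
substitutions as transversions; zero transversions yields NA, not infinity.
dbSNP membership is a non-'.' VCF ID; RefSeq association is a non-empty
annotation under any RefSeq-named key. Coding status of a DIP is read from
an ANNOVAR-style function column ("exonic"/"splicing" labels) — gene models
are never recomputed. Annotation merging is a full outer join on
(chrom, pos, ref, alt) with colliding columns source-prefixed
(`gatk.Gene` / `annovar.Gene`), rows sorted by position, and duplicate keys
within one table rejected loudly.

## Report and pipeline driver

The report has four sections: alignment key figures, the complete filter
table (preprocessing + alignment stages in execution order), DIP summary,
SNP summary. Sections that did not run are written as explicit "not run"
markers. Percentages are displayed with one decimal but always next to the
exact counts or repr-precision values they derive from, so parsing the file
reconstructs every numeric field exactly.

`run_all` chains the stages over files. Sequence alignment and variant
calling are external tools by design, so the driver consumes raw FASTQ (for
preprocessing and its accounting), an aligned SAM, the target BED, and
optionally caller-produced VCFs. Each stage is skipped when its outputs all
exist and are no older than its inputs (mtime comparison), which makes a
finished run re-entrant and byte-stable; `force=True` overrides.

## Synthetic data

The generator's purpose is planted, exactly recoverable structure, not
realism. A single PCG64 stream (pinned algorithm, seeded per plan)
determines every byte of output. Defaults describe a desk-scale exome:
100 kb genome, 50 targets of 200 bp (10% capture), 75 bp reads, insert
200 ± 20 bp, and variant sets small enough for sub-second tests.

Counts that downstream tests assert exactly are planted by construction:
failing reads are built to fail exactly one preprocessing stage (short
reads of 20 bp; 10% interior Ns so end-trimming cannot rescue them; 10% of
positions at Phred 10, which is below the Q20 cutoff but distinct from the
RSQCI value 2); duplicate fragments are extra copies with strictly lower
qualities at occupied start sites, with base fragments kept on unique
sites so chance collisions are zero; Ti/Tv is planted as substitution
counts (n_tv = round(n/(1+τ)), exact whenever n divides evenly); DIP allele
fractions sit at 0.9/0.5, well off the dsP = 80 boundary, with
rounding-safe adjustment. Fractions asserted against confidence intervals
(the on-target rate) are sampled per read instead. A uniform-placement
mode (`unique_start_sites=False`) drops the uniqueness constraint so
chance collisions follow the occupancy model.

Not emulated: realistic error profiles, quality covariation along the
read, GC or capture bias, indel sequencing artifacts, adapter
contamination, multi-chromosome references. Passing tests therefore
demonstrate the correctness of the bookkeeping, interval arithmetic and
classification logic — not robustness to the noise structure of real
instrument data.

## Problem sizes and numerical choices

Oracle-equivalence tests run 100 seeded instances against per-base
depth-array and O(N²) pairwise comparators at sizes (≤20 kb genomes, a few
hundred reads or ≤200 SAM records) where the brute force is fast yet
exercises clipped/inserted/deleted CIGARs and paired fragments; the
acceptance script uses 5,000 alignments, 3,000 SNPs and a 10,000-rep
Monte-Carlo run. Floats are compared exactly where construction guarantees
exactness and at 3 Monte-Carlo standard errors where sampling is involved.
Division-by-zero cases are defined throughout: empty filter stages report
100% passed, capture specificity and Ti/Tv report NA, zero-length target
sets report zero coverage.

## Known limitations

- BAM is readable through pysam, but outputs are plain SAM/TSV/VCF text;
  no indexing, CRAM or bgzip beyond transparent decompression.
- Duplicate marking has no optical-duplicate distinction and assumes
  qname-grouped mates are present in the stream; a lone mate falls back to
  a single-end key.
- The insert-size outlier rule (10× median) is a blunt instrument; it is
  flag-controlled.
- QC output is TSV tables (plus optional plots); spreadsheet/PDF rendering
  is content-equivalent TSV by design.
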