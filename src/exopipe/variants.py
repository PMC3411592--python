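"""Variant post-processing: classification, zygosity splitting, Ti/Tv,
database-association rates, summaries, and annotation-table merging.

Zygosity is decided differently for the two variant classes, mirroring how
exome callers report them.  SNPs carry a genotype: two identical non-
reference alleles mean homozygous, anything mixed heterozygous.  Small
indels (DIPs — deletion/insertion polymorphisms) are split on the alt-allele
read fraction instead: a DIP is called homozygous when
100 * alt_depth / depth >= dsP, where dsP is a percentage threshold in
[0, 100] (boundary inclusive, so dsP=100 still classifies pure-alt sites).

The transition/transversion ratio (Ti/Tv) counts A<->G and C<->T
substitutions as transitions and the remaining eight as transversions; a
call set with zero transversions reports NA rather than infinity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import VariantRecord

logger = logging.getLogger(__name__)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: ANNOVAR-style variant-function labels counted as coding.
CODING_LABELS = frozenset({"exonic", "splicing", "exonic;splicing"})


def classify_variant(ref: str, alt: str) -> str:
    """SNP / insertion / deletion purely from allele lengths."""
    return VariantRecord("chr", 1, ".", ref, alt).variant_class


# --------------------------------------------------------------------------
# Zygosity
# --------------------------------------------------------------------------


def split_zygosity_snp(variant: VariantRecord) -> str:
    """'hom' when both genotype alleles are the same non-reference allele,
    else 'het' (mixed-alt genotypes are logged as multi-allelic)."""
    if variant.genotype is None:
        raise ValueError(f"{variant.chrom}:{variant.pos} has no genotype")
    a, b = variant.genotype
    if a == b and a != 0:
        return "hom"
    if 0 not in (a, b) and a != b:
        logger.info(
            "multi-allelic genotype %s at %s:%s treated as heterozygous",
            variant.genotype, variant.chrom, variant.pos,
        )
    return "het"


def split_zygosity_dip(
    variant: VariantRecord, dsP: float, use_ref_alt_depth: bool = False
) -> str:
    """'hom' iff the alt-supporting read percentage is >= dsP.

    The denominator is total depth by default; ``use_ref_alt_depth``
    switches it to ref_depth + alt_depth.
    """
    if variant.alt_depth is None:
        raise ValueError(f"{variant.chrom}:{variant.pos} has no alt depth")
    if use_ref_alt_depth:
        if variant.ref_depth is None:
            raise ValueError(f"{variant.chrom}:{variant.pos} has no ref depth")
        depth = variant.ref_depth + variant.alt_depth
    else:
        depth = variant.depth
    if not depth:
        raise ValueError(f"{variant.chrom}:{variant.pos} has zero depth")
    return "hom" if 100.0 * variant.alt_depth / depth >= dsP else "het"


@dataclass
class ZygositySplit:
    homozygous: list[VariantRecord] = field(default_factory=list)
    heterozygous: list[VariantRecord] = field(default_factory=list)
    unclassifiable: list[VariantRecord] = field(default_factory=list)
    dsP: Optional[float] = None


def split_zygosity(
    variants: Iterable[VariantRecord],
    dsP: float = 80.0,
    use_ref_alt_depth: bool = False,
) -> ZygositySplit:
    """Partition a variant list into homozygous/heterozygous calls.

    SNPs split on genotype; DIPs on alt fraction versus ``dsP``.  Variants
    that cannot be judged (no genotype / zero depth) land in
    ``unclassifiable`` rather than silently in either class.
    """
    split = ZygositySplit(dsP=dsP)
    for v in variants:
        try:
            if v.variant_class == "SNP":
                side = split_zygosity_snp(v)
            else:
                side = split_zygosity_dip(v, dsP, use_ref_alt_depth)
        except ValueError as exc:
            logger.warning("unclassifiable variant: %s", exc)
            split.unclassifiable.append(v)
            continue
        (split.homozygous if side == "hom" else split.heterozygous).append(v)
    return split


# --------------------------------------------------------------------------
# Ti/Tv and association rates
# --------------------------------------------------------------------------


def titv_counts(snps: Iterable[VariantRecord]) -> tuple[int, int]:
    ti = tv = 0
    for v in snps:
        if v.variant_class != "SNP" or len(v.ref) != 1:
            continue
        if (v.ref.upper(), v.alt.upper()) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    return ti, tv


def titv_ratio(snps: Iterable[VariantRecord]) -> Optional[float]:
    """Transitions over transversions; None (NA) with zero transversions."""
    ti, tv = titv_counts(snps)
    if tv == 0:
        return None
    return ti / tv


def has_refseq_annotation(variant: VariantRecord) -> bool:
    """A non-empty annotation under any key naming RefSeq."""
    return any(
        "refseq" in key.lower() and value not in ("", ".")
        for key, value in variant.annotations.items()
    )


def association_rates(
    variants: Sequence[VariantRecord],
) -> tuple[float, float]:
    """(dbSNP fraction, RefSeq fraction) over the input set.

    dbSNP membership means a non-'.' VCF ID; RefSeq association means a
    non-empty RefSeq annotation value.  Empty input yields (0, 0).
    """
    if not variants:
        return 0.0, 0.0
    n = len(variants)
    dbsnp = sum(v.in_dbsnp for v in variants) / n
    refseq = sum(has_refseq_annotation(v) for v in variants) / n
    return dbsnp, refseq


# --------------------------------------------------------------------------
# Annotation-table merge
# --------------------------------------------------------------------------

DEFAULT_KEY = ("chrom", "pos", "ref", "alt")


def merge_annotation_tables(
    primary: pd.DataFrame,
    secondary: pd.DataFrame,
    key: Sequence[str] = DEFAULT_KEY,
    prefixes: tuple[str, str] = ("gatk", "annovar"),
) -> pd.DataFrame:
    """Full outer join of two per-variant annotation tables on the variant
    key, with colliding non-key columns prefixed by source.

    Rows are ordered by (chrom, pos).  Duplicate keys within either table
    are an error (the merge would multiply rows silently).
    """
    key = list(key)
    for name, table in zip(prefixes, (primary, secondary)):
        missing = [k for k in key if k not in table.columns]
        if missing:
            raise ValueError(f"{name} table lacks key columns {missing}")
        dup = table.loc[table.duplicated(subset=key), key]
        if not dup.empty:
            offenders = [tuple(row) for row in dup.itertuples(index=False)]
            raise ValueError(f"duplicate keys in {name} table: {offenders}")
    collisions = (set(primary.columns) & set(secondary.columns)) - set(key)
    left = primary.rename(
        columns={c: f"{prefixes[0]}.{c}" for c in collisions}
    )
    right = secondary.rename(
        columns={c: f"{prefixes[1]}.{c}" for c in collisions}
    )
    merged = left.merge(right, on=key, how="outer")
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    return merged


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------


@dataclass
class VariantSummary:
    # DIP section
    n_dips: int = 0
    n_deletions: int = 0
    n_insertions: int = 0
    n_dip_refseq_associated: int = 0
    n_dip_coding: int = 0
    dip_refseq_fraction: float = 0.0
    # SNP section
    n_snps: int = 0
    n_dbsnp: int = 0
    dbsnp_fraction: float = 0.0
    titv: Optional[float] = None
    n_hom_snp: int = 0
    n_het_snp: int = 0
    n_hom_dip: int = 0
    n_het_dip: int = 0


def variant_summaries(
    snps: Sequence[VariantRecord],
    dips: Sequence[VariantRecord],
    dsP: float = 80.0,
    coding_key: str = "Func",
    coding_labels: frozenset[str] = CODING_LABELS,
) -> VariantSummary:
    """Aggregate the report's DIP and SNP sections.

    Coding status of a DIP is read from the ``coding_key`` annotation column
    (ANNOVAR-style labels); gene models are never recomputed here.
    """
    s = VariantSummary()
    s.n_dips = len(dips)
    s.n_deletions = sum(v.variant_class == "deletion" for v in dips)
    s.n_insertions = sum(v.variant_class == "insertion" for v in dips)
    s.n_dip_refseq_associated = sum(has_refseq_annotation(v) for v in dips)
    s.dip_refseq_fraction = s.n_dip_refseq_associated / s.n_dips if s.n_dips else 0.0
    s.n_dip_coding = sum(
        v.annotations.get(coding_key, "") in coding_labels for v in dips
    )
    dip_split = split_zygosity(dips, dsP)
    s.n_hom_dip = len(dip_split.homozygous)
    s.n_het_dip = len(dip_split.heterozygous)

    s.n_snps = len(snps)
    s.n_dbsnp = sum(v.in_dbsnp for v in snps)
    s.dbsnp_fraction = s.n_dbsnp / s.n_snps if s.n_snps else 0.0
    s.titv = titv_ratio(snps)
    snp_split = split_zygosity(snps, dsP)
    s.n_hom_snp = len(snp_split.homozygous)
    s.n_het_snp = len(snp_split.heterozygous)
    return s
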