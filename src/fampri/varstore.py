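"""Multi-sample VCF + annotation-table ingestion and cohort statistics.

VCF records are read through cyvcf2, decomposed to biallelic
:class:`AnnotatedVariant` records, and joined against a side annotation
table (TSV keyed by CHROM, POS, REF, ALT) carrying the gene symbol, the
functional consequence, the gnomAD maximum allele frequency and the CADD
phred score.  Coordinates are 1-based inclusive throughout, per VCF
convention.

Genotypes are stored as alt-allele dosages: 0 (hom-ref), 1 (het),
2 (hom-alt), or ``None`` (missing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .errors import DataError

log = logging.getLogger(__name__)

HOMREF, HET, HOMALT = 0, 1, 2
MISSING = None

CONSEQUENCES = ("missense", "frameshift", "nonsense", "splice", "other")

# VEP-style terms mapped onto the controlled vocabulary.
_CONSEQUENCE_MAP = {
    "missense": "missense", "missense_variant": "missense",
    "frameshift": "frameshift", "frameshift_variant": "frameshift",
    "nonsense": "nonsense", "stop_gained": "nonsense", "stop_lost": "nonsense",
    "start_lost": "nonsense",
    "splice": "splice", "splice_donor_variant": "splice",
    "splice_acceptor_variant": "splice", "splice_region_variant": "splice",
    "splice_donor_region_variant": "splice",
}


def normalize_consequence(term: str | None) -> str:
    """Map an annotation consequence term to the controlled vocabulary."""
    if term is None:
        return "other"
    return _CONSEQUENCE_MAP.get(str(term).strip().lower(), "other")


@dataclass
class AnnotatedVariant:
    """One biallelic VCF record joined with its functional annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    consequence: str = "other"
    gene: str | None = None
    gnomad_max_af: float | None = None
    cadd_phred: float | None = None
    genotypes: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> list[str]:
        return [iid for iid, g in self.genotypes.items() if g in (HET, HOMALT)]


@dataclass(frozen=True)
class CohortStats:
    alt_allele_count: int
    called_allele_count: int
    cohort_af: float          # NaN when no genotype is called
    genotyping_rate: float


def cohort_stats(variant: AnnotatedVariant) -> CohortStats:
    """Alt-allele frequency and genotyping rate within the multi-sample VCF.

    Missing genotypes are excluded from both the numerator and denominator;
    a fully missing site gets ``cohort_af = NaN`` (and fails any frequency
    filter) rather than raising, so batch runs never abort on one bad site.
    """
    if not variant.genotypes:
        raise DataError(f"{variant.chrom}:{variant.pos}: variant has no samples")
    called = [g for g in variant.genotypes.values() if g is not None]
    alt = sum(called)
    denom = 2 * len(called)
    af = alt / denom if denom else math.nan
    return CohortStats(
        alt_allele_count=alt,
        called_allele_count=denom,
        cohort_af=af,
        genotyping_rate=len(called) / len(variant.genotypes),
    )


def _read_annotation_table(path: str | Path) -> dict[tuple[str, int, str, str], dict]:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    required = {"CHROM", "POS", "REF", "ALT"}
    if not required.issubset(df.columns):
        raise DataError(f"annotation table {path} lacks columns {sorted(required - set(df.columns))}")
    table = {}
    for row in df.itertuples(index=False):
        rec = row._asdict()
        table[(str(rec["CHROM"]), int(rec["POS"]), rec["REF"], rec["ALT"])] = rec
    return table


def read_annotated_vcf(
    vcf_path: str | Path, annotation_path: str | Path | None = None
) -> list[AnnotatedVariant]:
    """Read a multi-sample VCF into biallelic :class:`AnnotatedVariant` records.

    Multi-allelic sites are decomposed into one record per alternate allele
    (a sample's dosage at each record counts only that allele, so a 1/2
    genotype contributes one het to each split record).  When an annotation
    table is given, records are joined on (CHROM, POS, REF, ALT); variants
    missing from the table are kept with empty annotation fields and a
    warning.
    """
    annotation = _read_annotation_table(annotation_path) if annotation_path else {}
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    out: list[AnnotatedVariant] = []
    for record in vcf:
        filter_status = record.FILTER or "PASS"   # cyvcf2 reports PASS as None
        for alt_index, alt in enumerate(record.ALT, start=1):
            genotypes: dict[str, int | None] = {}
            for iid, alleles in zip(samples, record.genotypes):
                a = alleles[:-1]                  # last entry is the phased flag
                if any(x < 0 for x in a):
                    genotypes[iid] = MISSING
                else:
                    genotypes[iid] = sum(1 for x in a if x == alt_index)
            key = (str(record.CHROM), int(record.POS), record.REF, alt)
            ann = annotation.get(key)
            if annotation and ann is None:
                log.warning("no annotation for %s:%d %s>%s", *key)
            out.append(AnnotatedVariant(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                filter_status=filter_status,
                consequence=normalize_consequence(ann.get("CONSEQUENCE")) if ann else "other",
                gene=(str(ann["GENE"]) if ann and not pd.isna(ann.get("GENE")) else None),
                gnomad_max_af=_opt_float(ann, "GNOMAD_MAX_AF"),
                cadd_phred=_opt_float(ann, "CADD_PHRED"),
                genotypes=genotypes,
            ))
    return out


def _opt_float(ann: dict | None, column: str) -> float | None:
    if ann is None or column not in ann or pd.isna(ann[column]):
        return None
    return float(ann[column])


_GT_STRINGS = {HOMREF: "0/0", HET: "0/1", HOMALT: "1/1", MISSING: "./."}


def write_vcf(
    variants: Sequence[AnnotatedVariant],
    samples: Sequence[str],
    path: str | Path,
    contigs: Iterable[tuple[str, int]] = (),
) -> None:
    """Write biallelic variants as a minimal VCF 4.2 with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=LowQual,Description="Failed upstream recalibration">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            gts = "\t".join(_GT_STRINGS[v.genotypes.get(s, MISSING)] for s in samples)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t"
                     f"{v.filter_status}\t.\tGT\t{gts}\n")


def write_annotation_table(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write the side annotation TSV consumed by :func:`read_annotated_vcf`."""
    rows = [{
        "CHROM": v.chrom, "POS": v.pos, "REF": v.ref, "ALT": v.alt,
        "GENE": v.gene, "CONSEQUENCE": v.consequence,
        "GNOMAD_MAX_AF": v.gnomad_max_af, "CADD_PHRED": v.cadd_phred,
    } for v in sorted(variants, key=lambda v: v.key)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def marker_qc_filter(
    variants: Iterable[AnnotatedVariant],
    min_rate: float = 0.9,
    min_carriers: int = 2,
) -> list[AnnotatedVariant]:
    """Marker-level QC used before IBD detection.

    Keeps variants genotyped in strictly more than ``min_rate`` of samples
    (''more than 90%'') and carried (het or hom-alt) by at least
    ``min_carriers`` individuals.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise DataError(f"min_rate must be in [0,1], got {min_rate}")
    kept = []
    for v in variants:
        st = cohort_stats(v)
        if st.genotyping_rate > min_rate and len(v.carriers()) >= min_carriers:
            kept.append(v)
    return kept
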