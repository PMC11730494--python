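"""Co-segregation filtering and the five-step rare-variant cascade.

The segregation rule retains variants whose genotypes track the affection
status of the named individuals: under the dominant (het) pattern every
affected must be heterozygous and every unaffected hom-ref; under the
recessive (hom) pattern every affected must be hom-alt and every unaffected
at most a carrier.  A variant with any missing genotype among the named
individuals is excluded from both — the conservative reading of "shared".

Surviving variants then pass, in order: (1) FILTER == PASS with a
protein-level consequence, (2) rarity in both gnomAD and the cohort VCF,
(3) CADD phred at or above threshold, (4) membership in the IBD regions
shared by the affected individuals.  The per-step survivor counts (with
het/hom splits) are collected in a :class:`FilterLedger`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .ibdshare import SharedRegion, overlaps
from .varstore import HET, HOMALT, HOMREF, AnnotatedVariant, cohort_stats

STEPS = ("segregation", "pass_consequence", "rare", "cadd", "ibd")


@dataclass(frozen=True)
class SegregationPattern:
    """Which individuals define the co-segregation requirement."""

    affected_ids: tuple[str, ...]
    unaffected_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.affected_ids or not self.unaffected_ids:
            raise ConfigurationError("both affected and unaffected ids are required")
        if set(self.affected_ids) & set(self.unaffected_ids):
            raise ConfigurationError("affected and unaffected ids overlap")


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the filter cascade; all bounds are inclusive as printed."""

    gnomad_max_af_threshold: float = 0.001
    cohort_af_threshold: float = 0.02
    cadd_min: float = 15.0
    consequences_kept: frozenset[str] = frozenset({"missense", "frameshift", "nonsense", "splice"})
    require_pass: bool = True
    ibd_mode: str = "gene"

    def __post_init__(self) -> None:
        if self.gnomad_max_af_threshold < 0 or self.cohort_af_threshold < 0:
            raise ConfigurationError("frequency thresholds must be non-negative")


@dataclass
class FilterLedger:
    """Per-step survivor counts of the cascade, with het/hom splits."""

    n_input: int = 0
    n_input_het: int = 0
    n_input_hom: int = 0
    n_pass_consequence: int = 0
    n_pass_consequence_het: int = 0
    n_pass_consequence_hom: int = 0
    n_rare: int = 0
    n_rare_het: int = 0
    n_rare_hom: int = 0
    n_cadd: int = 0
    n_cadd_het: int = 0
    n_cadd_hom: int = 0
    n_ibd: int = 0
    n_ibd_het: int = 0
    n_ibd_hom: int = 0
    survivors: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)
    modes: dict[tuple[str, int, str, str], str] = field(default_factory=dict)

    def check(self) -> None:
        counts = [self.n_input, self.n_pass_consequence, self.n_rare, self.n_cadd, self.n_ibd]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise AssertionError(f"ledger counts are not monotone: {counts}")
        for step in STEPS:
            het = getattr(self, f"n_{_abbr(step)}_het") if step != "segregation" else self.n_input_het
            hom = getattr(self, f"n_{_abbr(step)}_hom") if step != "segregation" else self.n_input_hom
            tot = getattr(self, f"n_{_abbr(step)}") if step != "segregation" else self.n_input
            if het + hom != tot:
                raise AssertionError(f"step {step}: het {het} + hom {hom} != {tot}")

    def final_survivors(self) -> list[AnnotatedVariant]:
        return self.survivors.get("ibd", [])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for step in STEPS:
            key = _abbr(step) if step != "segregation" else "input"
            rows.append({
                "step": step,
                "n": getattr(self, f"n_{key}"),
                "n_het": getattr(self, f"n_{key}_het"),
                "n_hom": getattr(self, f"n_{key}_hom"),
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _abbr(step: str) -> str:
    return {"pass_consequence": "pass_consequence", "rare": "rare",
            "cadd": "cadd", "ibd": "ibd"}[step]


def segregation_filter(
    variants: Iterable[AnnotatedVariant],
    pattern: SegregationPattern,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Split variants into dominant (het) and recessive (hom) candidates.

    het candidates: every affected het, every unaffected hom-ref.
    hom candidates: every affected hom-alt, every unaffected het or hom-ref.
    Any missing genotype among the pattern individuals disqualifies the
    variant from both lists.
    """
    het_candidates, hom_candidates = [], []
    for v in variants:
        missing_ids = [i for i in (*pattern.affected_ids, *pattern.unaffected_ids)
                       if i not in v.genotypes]
        if missing_ids:
            raise ConfigurationError(
                f"sample(s) {missing_ids} absent from genotype map at {v.chrom}:{v.pos}")
        aff = [v.genotypes[i] for i in pattern.affected_ids]
        un = [v.genotypes[i] for i in pattern.unaffected_ids]
        if any(g is None for g in aff + un):
            continue
        if all(g == HET for g in aff) and all(g == HOMREF for g in un):
            het_candidates.append(v)
        elif all(g == HOMALT for g in aff) and all(g in (HOMREF, HET) for g in un):
            hom_candidates.append(v)
    return het_candidates, hom_candidates


def _sorted(variants: Iterable[AnnotatedVariant]) -> list[AnnotatedVariant]:
    return sorted(variants, key=lambda v: v.key)


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    pattern: SegregationPattern,
    cfg: CascadeConfig,
    ibd_regions: Sequence[SharedRegion],
    gene_spans: Mapping[str, tuple[str, int, int]] | None = None,
) -> FilterLedger:
    """Run segregation plus the four annotation filters, recording a ledger.

    Steps apply in the printed order; the gnomAD and cohort allele-frequency
    conditions form a single "rare" step.  A missing gnomAD frequency counts
    as 0 (absent from gnomAD means rare); a missing CADD score fails the
    CADD step; an all-missing-genotype site has undefined cohort frequency
    and fails the rare step.
    """
    ledger = FilterLedger()
    het, hom = segregation_filter(variants, pattern)
    het_keys = {v.key for v in het}
    current = _sorted(het + hom)
    ledger.modes = {v.key: ("het" if v.key in het_keys else "hom") for v in current}
    _record(ledger, "input", current)
    ledger.survivors["segregation"] = current

    current = [v for v in current
               if (not cfg.require_pass or v.filter_status == "PASS")
               and v.consequence in cfg.consequences_kept]
    _record(ledger, "pass_consequence", current)
    ledger.survivors["pass_consequence"] = current

    def is_rare(v: AnnotatedVariant) -> bool:
        gaf = 0.0 if v.gnomad_max_af is None else v.gnomad_max_af
        caf = cohort_stats(v).cohort_af
        return gaf <= cfg.gnomad_max_af_threshold and \
            not math.isnan(caf) and caf <= cfg.cohort_af_threshold

    current = [v for v in current if is_rare(v)]
    _record(ledger, "rare", current)
    ledger.survivors["rare"] = current

    current = [v for v in current
               if v.cadd_phred is not None and v.cadd_phred >= cfg.cadd_min]
    _record(ledger, "cadd", current)
    ledger.survivors["cadd"] = current

    current = [v for v in current
               if overlaps(ibd_regions, v, gene_spans=gene_spans, mode=cfg.ibd_mode)]
    _record(ledger, "ibd", current)
    ledger.survivors["ibd"] = current

    ledger.check()
    return ledger


def _record(ledger: FilterLedger, key: str, survivors: list[AnnotatedVariant]) -> None:
    het = sum(1 for v in survivors if ledger.modes.get(v.key) == "het")
    setattr(ledger, f"n_{key}", len(survivors))
    setattr(ledger, f"n_{key}_het", het)
    setattr(ledger, f"n_{key}_hom", len(survivors) - het)


def rank_survivors(
    ledger: FilterLedger, seed_genes: Sequence[str] | None = None
) -> list[str]:
    """Order candidate genes for follow-up.

    Genes carrying final survivors are sorted by membership in the optional
    seed list (a phenotype-derived gene set) first, then by the maximum CADD
    score of their surviving variants, then alphabetically.  A transparent,
    deterministic stand-in for network-based gene prioritizers.
    """
    seeds = set(seed_genes or ())
    by_gene: dict[str, float] = {}
    for v in ledger.final_survivors():
        if v.gene is None:
            continue
        score = v.cadd_phred if v.cadd_phred is not None else float("-inf")
        by_gene[v.gene] = max(by_gene.get(v.gene, float("-inf")), score)
    return sorted(by_gene, key=lambda g: (-(g in seeds), -by_gene[g], g))
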