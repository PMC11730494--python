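"""Coding-position arithmetic, substitution translation, and APOE calling.

This is deliberately transcript-light: it maps a CDS position to its codon
and within-codon offset, translates a single-base substitution with the
standard genetic code, and reconstructs APOE epsilon genotypes from the two
defining SNPs rs429358 (T>C) and rs7412 (C>T).  Full transcript-aware
annotation (projection from genomic coordinates, splice effects) belongs
upstream, in the variant-effect predictor that feeds the annotation table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import FampriError

_BASES = frozenset("ACGT")

# Standard genetic code, one-letter amino acids, '*' for stop.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# Epsilon allele from the (rs429358, rs7412) haplotype.
_EPSILON = {("T", "T"): "e2", ("T", "C"): "e3", ("C", "C"): "e4", ("C", "T"): "e1"}


@dataclass(frozen=True)
class CodingChange:
    """A single-base substitution at a 1-based CDS position (c. notation)."""

    cds_pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise FampriError(f"CDS position must be >= 1, got {self.cds_pos}")
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise FampriError(f"bases must be in ACGT: {self.ref_base}>{self.alt_base}")
        if self.ref_base == self.alt_base:
            raise FampriError("ref and alt base are identical")

    @classmethod
    def parse(cls, text: str) -> "CodingChange":
        """Parse ``c.3215C>T`` (also accepts ``c.3215C-T`` / ``3215C>T``)."""
        m = re.fullmatch(r"(?:c\.)?(\d+)([ACGT])[>-]([ACGT])", text.strip())
        if not m:
            raise FampriError(f"cannot parse coding change {text!r}")
        return cls(int(m.group(1)), m.group(2), m.group(3))


@dataclass(frozen=True)
class ProteinChange:
    codon_index: int
    within_codon_pos: int
    aa_ref: str
    aa_alt: str

    @property
    def label(self) -> str:
        return f"p.{self.aa_ref}{self.codon_index}{self.aa_alt}"


@dataclass(frozen=True)
class ApoeCall:
    """APOE genotype reconstructed from rs429358 and rs7412.

    ``ambiguous`` is set for the rs429358/rs7412 double heterozygote, whose
    two phasings are e2/e4 and e1/e3; the e2/e4 resolution is reported,
    following the universal convention that e1 is vanishingly rare.
    """

    rs429358: tuple[str, str]
    rs7412: tuple[str, str]
    epsilon_pair: tuple[str, str]
    ambiguous: bool = False

    @property
    def label(self) -> str:
        return "/".join(self.epsilon_pair)


def cds_to_codon(cds_pos: int) -> tuple[int, int]:
    """Map a 1-based CDS position to (codon_index, within_codon_pos).

    ``codon_index`` is 1-based, ``within_codon_pos`` in 1..3, so that
    ``3*(codon_index-1) + within_codon_pos == cds_pos``.
    """
    if cds_pos < 1:
        raise FampriError(f"CDS position must be >= 1, got {cds_pos}")
    codon_index = (cds_pos + 2) // 3
    return codon_index, cds_pos - 3 * (codon_index - 1)


def translate_substitution(
    ref_codon: str, within_codon_pos: int, alt_base: str
) -> tuple[str, str]:
    """Translate a codon and its single-base substitution (standard code).

    Stop codons are returned as ``'*'``.  The reference base at the given
    offset must differ from ``alt_base``.
    """
    ref_codon = ref_codon.upper()
    if len(ref_codon) != 3 or any(b not in _BASES for b in ref_codon):
        raise FampriError(f"invalid codon {ref_codon!r}")
    if within_codon_pos not in (1, 2, 3):
        raise FampriError(f"within_codon_pos must be 1..3, got {within_codon_pos}")
    if alt_base not in _BASES:
        raise FampriError(f"invalid alternate base {alt_base!r}")
    if ref_codon[within_codon_pos - 1] == alt_base:
        raise FampriError(
            f"substitution is silent at the DNA level: codon {ref_codon}, "
            f"position {within_codon_pos} already {alt_base}")
    alt_codon = ref_codon[: within_codon_pos - 1] + alt_base + ref_codon[within_codon_pos:]
    return _CODON_TABLE[ref_codon], _CODON_TABLE[alt_codon]


def protein_change(change: CodingChange, ref_codon: str) -> ProteinChange:
    """Full coding-to-protein description of a substitution."""
    codon_index, offset = cds_to_codon(change.cds_pos)
    if ref_codon.upper()[offset - 1] != change.ref_base:
        raise FampriError(
            f"reference codon {ref_codon!r} does not carry {change.ref_base} "
            f"at offset {offset}")
    aa_ref, aa_alt = translate_substitution(ref_codon, offset, change.alt_base)
    return ProteinChange(codon_index, offset, aa_ref, aa_alt)


def _norm_genotype(gt: str | tuple[str, str], alleles: frozenset[str], rsid: str) -> tuple[str, str]:
    if isinstance(gt, str):
        parts = tuple(gt.replace("|", "/").split("/"))
    else:
        parts = tuple(gt)
    if len(parts) != 2 or any(a not in alleles for a in parts):
        raise FampriError(f"invalid {rsid} genotype {gt!r}; alleles must be in {sorted(alleles)}")
    return parts  # order preserved; calling is order-independent


def call_apoe(rs429358_gt: str | tuple[str, str], rs7412_gt: str | tuple[str, str]) -> ApoeCall:
    """Reconstruct the APOE epsilon genotype from its two defining SNPs.

    rs429358 segregates T>C and rs7412 C>T; the epsilon alleles are the
    haplotypes e2=(T,T), e3=(T,C), e4=(C,C).  All genotype combinations
    phase uniquely except the double heterozygote, which is returned as
    e2/e4 with ``ambiguous=True`` (the e1/e3 phasing is suppressed because
    e1 is essentially never observed).
    """
    g1 = _norm_genotype(rs429358_gt, frozenset("TC"), "rs429358")
    g2 = _norm_genotype(rs7412_gt, frozenset("CT"), "rs7412")
    het1 = g1[0] != g1[1]
    het2 = g2[0] != g2[1]
    if het1 and het2:
        return ApoeCall(g1, g2, ("e2", "e4"), ambiguous=True)
    if not het1:
        haps = [(g1[0], g2[0]), (g1[0], g2[1])]
    else:
        haps = [(g1[0], g2[0]), (g1[1], g2[0])]
    pair = tuple(sorted(_EPSILON[h] for h in haps))
    return ApoeCall(g1, g2, pair, ambiguous=False)
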