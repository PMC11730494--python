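"""Synthetic family data by gene dropping.

Stands in for an undeposited familial exome dataset: builds a pedigree,
drops founder haplotypes through it with recombination on a uniform genetic
map, plants a causal variant, draws phenotypes from the disease model's
penetrances, attaches background variants with annotation fields straddling
every cascade threshold, and records the full truth (carriers, phenotypes,
pairwise IBD tracts) so downstream modules can be validated against known
answers.

The emitted multi-sample VCF contains the sequenced family members plus a
set of unrelated cohort exomes (genotyped at Hardy–Weinberg proportions),
mirroring the joint-genotyped family-plus-in-house-collection VCF such
studies filter on; without the cohort a private familial variant could
never satisfy a within-VCF allele-frequency threshold.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np

from .errors import ConfigurationError
from .ibdshare import IBDSegment, write_ibd
from .linkstats import DiseaseModel
from .pedio import Individual, Pedigree, Phenotype, Sex, write_ped
from .varstore import AnnotatedVariant, write_annotation_table, write_vcf

# A haplotype mosaic is a piecewise-constant map position -> founder
# haplotype id: arrays (breakpoints, ids) with breakpoints[0] == 1.
Mosaic = tuple[np.ndarray, np.ndarray]


@dataclass
class SimConfig:
    """Study conditions of a simulated family dataset.

    Defaults emulate the sequenced-family design this package targets: a
    four-generation pedigree, a dominant model with 1% prevalence and 0.90
    penetrance for carriers, one planted ultra-rare causal variant among
    ~200 protein-altering candidates, a marker density of 500 per 5 Mb
    (100/Mb) on a uniform 1 cM/Mb map, and an unrelated in-house cohort
    joint-genotyped with the family.
    """

    n_generations: int = 4
    offspring_range: tuple[int, int] = (2, 3)
    marry_prob: float = 0.7
    causal_af: float | None = None          # None: plant one founder copy
    model: DiseaseModel = field(
        default_factory=lambda: DiseaseModel(0.01, (0.0, 0.9, 0.9)))
    n_background_variants: int = 199
    n_cohort_extras: int = 185
    missing_rate: float = 0.0
    chrom: str = "17"
    chrom_length_bp: int = 80_000_000
    n_markers_per_mb: float = 100.0
    cm_per_mb: float = 1.0
    gene_size_bp: int = 200_000
    causal_pos: int = 74_842_922
    causal_gnomad_af: float = 2.64e-5
    causal_cadd: float = 23.0
    pass_rate: float = 0.85
    consequence_mix: dict[str, float] = field(default_factory=lambda: {
        "missense": 0.55, "frameshift": 0.05, "nonsense": 0.05,
        "splice": 0.10, "other": 0.25})
    fixed_structure: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.consequence_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("consequence_mix probabilities must sum to 1")
        if self.n_markers_per_mb < 0:
            raise ConfigurationError("marker density must be non-negative")
        if not 1 <= self.offspring_range[0] <= self.offspring_range[1]:
            raise ConfigurationError(f"bad offspring_range {self.offspring_range}")


@dataclass
class SimTruth:
    """Everything the simulator knows that an analyst would not."""

    causal_key: tuple[str, int, str, str]
    causal_gene: str
    carriers: list[str]                      # family members with >= 1 causal copy
    phenotypes: dict[str, str]
    affected_ids: tuple[str, ...]            # the sequenced affected (pattern)
    unaffected_ids: tuple[str, ...]          # the sequenced healthy (pattern)
    genotyped: list[str]
    ibd_tracts: dict[tuple[str, str], list[tuple[str, int, int]]]


@dataclass
class SimResult:
    pedigree: Pedigree
    truth: SimTruth
    variants: list[AnnotatedVariant]         # causal + background, all samples
    marker_positions: np.ndarray
    marker_genotypes: dict[str, np.ndarray]  # family members only
    gene_spans: dict[str, tuple[str, int, int]]
    config: SimConfig

    @property
    def causal_variant(self) -> AnnotatedVariant:
        for v in self.variants:
            if v.key == self.truth.causal_key:
                return v
        raise AssertionError("causal variant missing from variant list")


# -- fixed study-emulation pedigree ---------------------------------------
# (iid, father, mother, sex, genotyped?, designated carrier?) — a
# four-generation family with 15 genotyped members: 6 affected carriers and
# 9 unaffected non-carriers, the design the causal variant segregates in.
_FIXED_STRUCTURE = [
    ("GP1", None, None, "M", False, True),
    ("GP2", None, None, "F", False, False),
    ("C1", "GP1", "GP2", "M", True, True),
    ("C2", "GP1", "GP2", "F", True, True),
    ("C3", "GP1", "GP2", "M", True, False),
    ("S1", None, None, "F", True, False),
    ("S2", None, None, "M", True, False),
    ("D1", "C1", "S1", "M", True, True),
    ("D2", "C1", "S1", "F", True, False),
    ("D3", "C1", "S1", "M", True, False),
    ("D4", "S2", "C2", "F", True, True),
    ("D5", "S2", "C2", "M", True, False),
    ("S3", None, None, "F", True, False),
    ("S4", None, None, "M", True, False),
    ("E1", "D1", "S3", "M", True, True),
    ("E2", "D1", "S3", "F", True, False),
    ("E3", "S4", "D4", "F", True, True),
]
_FIXED_AFFECTED = ("C1", "D4", "E1")        # sequenced affected, 3 generations
_FIXED_UNAFFECTED = ("C3", "D2")            # sequenced healthy relatives


def study_emulation_preset(seed: int = 0) -> SimConfig:
    """The default study conditions: fixed 4-generation family, planted
    ultra-rare causal het variant, 199 background variants."""
    return SimConfig(fixed_structure=True, seed=seed)


# -- pedigree construction ------------------------------------------------

_SEX = {"M": Sex.MALE, "F": Sex.FEMALE, "U": Sex.UNKNOWN}


def random_pedigree(n_members: int, rng: np.random.Generator, name: str = "SIM") -> Pedigree:
    """A random loop-free pedigree with exactly ``n_members`` individuals.

    Grown from a founder couple by alternately marrying in new founder
    spouses and adding children; spouses are always new founders, so the
    structure is loop-free by construction.
    """
    if n_members < 1:
        raise ConfigurationError("pedigree needs at least one member")
    rows: list[tuple[str, str | None, str | None, Sex]] = []
    counter = itertools.count(1)

    def new_iid() -> str:
        return f"I{next(counter):03d}"

    rows.append((new_iid(), None, None, Sex.MALE))
    couples: list[tuple[str, str]] = []
    unmarried: list[tuple[str, Sex]] = [(rows[0][0], Sex.MALE)]
    while len(rows) < n_members:
        if couples and (not unmarried or rng.random() < 0.6):
            f, m = couples[int(rng.integers(len(couples)))]
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            child = new_iid()
            rows.append((child, f, m, sex))
            unmarried.append((child, sex))
        else:
            iid, sex = unmarried.pop(int(rng.integers(len(unmarried))))
            spouse = new_iid()
            spouse_sex = Sex.FEMALE if sex is Sex.MALE else Sex.MALE
            rows.append((spouse, None, None, spouse_sex))
            if sex is Sex.MALE:
                couples.append((iid, spouse))
            else:
                couples.append((spouse, iid))
    individuals = [Individual(iid=i, fid=name, father=f, mother=m, sex=s)
                   for i, f, m, s in rows]
    return Pedigree(individuals, name=name)


def drop_marker(
    pedigree: Pedigree, af: float, rng: np.random.Generator
) -> dict[str, int]:
    """Gene-drop a single unlinked biallelic marker; returns alt dosages."""
    alleles: dict[str, tuple[int, int]] = {}
    for ind in _topo_order(pedigree):
        if ind.is_founder:
            alleles[ind.iid] = (int(rng.random() < af), int(rng.random() < af))
        else:
            pa = alleles[ind.father][int(rng.integers(2))]
            ma = alleles[ind.mother][int(rng.integers(2))]
            alleles[ind.iid] = (pa, ma)
    return {iid: a + b for iid, (a, b) in alleles.items()}


def _topo_order(pedigree: Pedigree) -> list[Individual]:
    done: set[str] = set()
    order: list[Individual] = []
    pending = list(pedigree)
    while pending:
        rest = []
        for ind in pending:
            if ind.is_founder or (ind.father in done and ind.mother in done):
                order.append(ind)
                done.add(ind.iid)
            else:
                rest.append(ind)
        if len(rest) == len(pending):
            raise ConfigurationError("pedigree is not topologically orderable")
        pending = rest
    return order


def _build_random_structure(cfg: SimConfig, rng: np.random.Generator):
    rows: list[tuple[str, str | None, str | None, str, bool, bool]] = []
    counter = itertools.count(1)

    def new_iid() -> str:
        return f"I{next(counter):03d}"

    f0, m0 = new_iid(), new_iid()
    rows.append((f0, None, None, "M", True, False))
    rows.append((m0, None, None, "F", True, False))
    couples = [(f0, m0)]
    for gen in range(2, cfg.n_generations + 1):
        next_couples = []
        for f, m in couples:
            k = int(rng.integers(cfg.offspring_range[0], cfg.offspring_range[1] + 1))
            for _ in range(k):
                sex = "M" if rng.random() < 0.5 else "F"
                child = new_iid()
                rows.append((child, f, m, sex, True, False))
                if gen < cfg.n_generations and rng.random() < cfg.marry_prob:
                    spouse = new_iid()
                    s_sex = "F" if sex == "M" else "M"
                    rows.append((spouse, None, None, s_sex, True, False))
                    next_couples.append((child, spouse) if sex == "M" else (spouse, child))
        couples = next_couples
        if not couples and gen < cfg.n_generations:
            break
    return rows


# -- meiosis and mosaics --------------------------------------------------

def _meiosis(
    pat: Mosaic, mat: Mosaic, length_bp: int, morgans: float, rng: np.random.Generator
) -> Mosaic:
    """One gamete: crossovers Poisson on a uniform map, random start phase."""
    n_cross = rng.poisson(morgans)
    cuts = np.sort(rng.integers(2, length_bp, size=n_cross)) if n_cross else np.array([], dtype=int)
    sources = [pat, mat]
    cur = int(rng.integers(2))
    boundaries = [1, *cuts.tolist(), length_bp + 1]
    out_b: list[int] = []
    out_i: list[int] = []
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        if start == stop:
            cur ^= 1
            continue
        bks, hids = sources[cur]
        lo = int(np.searchsorted(bks, start, side="right")) - 1
        hi = int(np.searchsorted(bks, stop - 1, side="right")) - 1
        for k in range(lo, hi + 1):
            seg_start = max(start, int(bks[k]))
            if out_i and out_i[-1] == int(hids[k]):
                pass
            else:
                out_b.append(seg_start)
                out_i.append(int(hids[k]))
        cur ^= 1
    return np.asarray(out_b), np.asarray(out_i)


def _mosaic_at(mosaic: Mosaic, pos: int) -> int:
    bks, ids = mosaic
    return int(ids[int(np.searchsorted(bks, pos, side="right")) - 1])


def _mosaic_ids_at(mosaics: tuple[Mosaic, Mosaic], pos: int) -> set[int]:
    return {_mosaic_at(mosaics[0], pos), _mosaic_at(mosaics[1], pos)}


def _pair_shared_tracts(
    a: tuple[Mosaic, Mosaic], b: tuple[Mosaic, Mosaic], length_bp: int
) -> list[tuple[int, int]]:
    """Intervals where two individuals carry at least one common founder haplotype."""
    cuts = np.unique(np.concatenate(
        [a[0][0], a[1][0], b[0][0], b[1][0], [1, length_bp + 1]]))
    out: list[tuple[int, int]] = []
    for start, stop in zip(cuts[:-1], cuts[1:]):
        shared = bool(_mosaic_ids_at(a, int(start)) & _mosaic_ids_at(b, int(start)))
        if shared:
            if out and out[-1][1] == start - 1:
                out[-1] = (out[-1][0], int(stop) - 1)
            else:
                out.append((int(start), int(stop) - 1))
    return out


# -- main entry -----------------------------------------------------------

def simulate_family(cfg: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Simulate one family dataset; optionally write all files to ``out_dir``.

    Reproducible: a fixed config (including seed) yields byte-identical
    outputs.  Returns the in-memory :class:`SimResult`; when ``out_dir`` is
    given, also writes family.vcf, family.ped, annotations.tsv,
    gene_spans.tsv, truth.ibd and truth.json.
    """
    rng = np.random.default_rng(cfg.seed)
    structure = _FIXED_STRUCTURE if cfg.fixed_structure else _build_random_structure(cfg, rng)
    individuals = []
    genotyped = [r[0] for r in structure if r[4]]
    designated = {r[0]: r[5] for r in structure}
    for iid, father, mother, sex, _gt, _carrier in structure:
        individuals.append(Individual(
            iid=iid, fid="SIMFAM", father=father, mother=mother, sex=_SEX[sex]))
    pedigree = Pedigree(individuals, name="SIMFAM")
    if not pedigree.founders:
        raise ConfigurationError("simulated pedigree has no founders")
    order = _topo_order(pedigree)
    length = cfg.chrom_length_bp
    morgans = length / 1e6 * cfg.cm_per_mb / 100.0

    # founder haplotypes get globally unique integer ids
    hap_counter = itertools.count()
    mosaics: dict[str, tuple[Mosaic, Mosaic]] = {}
    founder_hap_ids: list[int] = []
    for ind in order:
        if not ind.is_founder:
            continue
        h1, h2 = next(hap_counter), next(hap_counter)
        founder_hap_ids.extend([h1, h2])
        mosaics[ind.iid] = (
            (np.array([1]), np.array([h1])), (np.array([1]), np.array([h2])))

    # causal allele lives on specific founder haplotypes
    if cfg.causal_af is None:
        causal_haps = {founder_hap_ids[0]}     # one copy in the first founder
    else:
        causal_haps = {h for h in founder_hap_ids if rng.random() < cfg.causal_af}

    def is_carrier_hapset(hapset: set[int]) -> bool:
        return bool(hapset & causal_haps)

    # gene dropping; in fixed mode the transmission at the causal position
    # is conditioned (by resampling the meiosis) on the designated carriers,
    # reproducing the realized descent of the study variant
    for ind in order:
        if ind.is_founder:
            continue
        for attempt in range(10_000):
            pat = _meiosis(*mosaics[ind.father], length, morgans, rng)
            mat = _meiosis(*mosaics[ind.mother], length, morgans, rng)
            if not cfg.fixed_structure:
                break
            got = is_carrier_hapset(_mosaic_ids_at((pat, mat), cfg.causal_pos))
            if got == designated[ind.iid]:
                break
        else:
            raise ConfigurationError(
                f"could not realize designated carrier state for {ind.iid}")
        mosaics[ind.iid] = (pat, mat)

    def causal_dosage(iid: str) -> int:
        return sum(1 for m in mosaics[iid]
                   if _mosaic_at(m, cfg.causal_pos) in causal_haps)

    carriers = [ind.iid for ind in order if causal_dosage(ind.iid) >= 1]

    # phenotypes: in fixed mode the realized family is reproduced (carrier
    # <-> affected among genotyped members); otherwise drawn from penetrance
    f = cfg.model.penetrances
    phenotypes: dict[str, str] = {}
    for ind in order:
        if cfg.fixed_structure:
            if ind.iid in genotyped:
                phenotypes[ind.iid] = "affected" if designated[ind.iid] else "unaffected"
            else:
                phenotypes[ind.iid] = "unknown"
        else:
            phenotypes[ind.iid] = (
                "affected" if rng.random() < f[causal_dosage(ind.iid)] else "unaffected")
    individuals = [Individual(
        iid=i.iid, fid=i.fid, father=i.father, mother=i.mother, sex=i.sex,
        phenotype=Phenotype(phenotypes[i.iid]))
        for i in pedigree]
    pedigree = Pedigree(individuals, name="SIMFAM")

    # gene map: contiguous tiles
    n_genes = -(-length // cfg.gene_size_bp)
    gene_spans = {
        f"GENE{i + 1:04d}": (cfg.chrom, i * cfg.gene_size_bp + 1,
                             min((i + 1) * cfg.gene_size_bp, length))
        for i in range(n_genes)}

    def gene_at(pos: int) -> str:
        return f"GENE{(pos - 1) // cfg.gene_size_bp + 1:04d}"

    # variant table: planted causal + annotated background
    extras = [f"X{j + 1:03d}" for j in range(cfg.n_cohort_extras)]
    variants: list[AnnotatedVariant] = []

    def genotype_map(dosages_family: dict[str, int], pop_af: float) -> dict[str, int | None]:
        g: dict[str, int | None] = dict(dosages_family)
        for x in extras:
            g[x] = int(rng.random() < pop_af) + int(rng.random() < pop_af)
        if cfg.missing_rate > 0:
            for k in list(g):
                if rng.random() < cfg.missing_rate:
                    g[k] = None
        return g

    causal_fam = {iid: causal_dosage(iid) for iid in genotyped}
    variants.append(AnnotatedVariant(
        chrom=cfg.chrom, pos=cfg.causal_pos, ref="C", alt="T",
        filter_status="PASS", consequence="missense", gene=gene_at(cfg.causal_pos),
        gnomad_max_af=cfg.causal_gnomad_af, cadd_phred=cfg.causal_cadd,
        genotypes=genotype_map(causal_fam, cfg.causal_gnomad_af)))

    consequences = list(cfg.consequence_mix)
    cons_p = np.array([cfg.consequence_mix[c] for c in consequences])
    taken = {cfg.causal_pos}
    bases = ["A", "C", "G", "T"]
    for _ in range(cfg.n_background_variants):
        while True:
            pos = int(rng.integers(1, length + 1))
            if pos not in taken:
                taken.add(pos)
                break
        pop_af = float(10.0 ** rng.uniform(np.log10(5e-3), np.log10(0.5)))
        gnomad_af = (float(10.0 ** rng.uniform(-6.5, -3.0))
                     if rng.random() < 0.35 else pop_af * float(np.exp(rng.normal(0, 0.3))))
        hap_alleles = {h: int(rng.random() < pop_af) for h in founder_hap_ids}
        if not any(hap_alleles.values()):
            hap_alleles[founder_hap_ids[int(rng.integers(len(founder_hap_ids)))]] = 1
        fam = {iid: sum(hap_alleles[_mosaic_at(m, pos)] for m in mosaics[iid])
               for iid in genotyped}
        ref = bases[int(rng.integers(4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        variants.append(AnnotatedVariant(
            chrom=cfg.chrom, pos=pos, ref=ref, alt=alt,
            filter_status="PASS" if rng.random() < cfg.pass_rate else "LowQual",
            consequence=consequences[int(rng.choice(len(consequences), p=cons_p))],
            gene=gene_at(pos),
            gnomad_max_af=min(gnomad_af, 1.0),
            cadd_phred=float(rng.uniform(0, 15) if rng.random() < 0.5
                             else rng.uniform(15, 40)),
            genotypes=genotype_map(fam, pop_af)))
    variants.sort(key=lambda v: v.key)

    # dense marker panel (family members only), for the exclusion IBD scan
    n_markers = int(round(length / 1e6 * cfg.n_markers_per_mb))
    marker_positions = _draw_positions(rng, length, n_markers)
    marker_genotypes: dict[str, np.ndarray] = {}
    if n_markers:
        marker_afs = rng.uniform(0.1, 0.5, size=n_markers)
        # founder haplotype ids are consecutive ints, so a matrix indexes them
        hap_matrix = (rng.random((len(founder_hap_ids), n_markers))
                      < marker_afs[None, :]).astype(np.int8)
        cols = np.arange(n_markers)
        for iid in genotyped:
            gts = np.zeros(n_markers, dtype=np.int8)
            for m in mosaics[iid]:
                gts += hap_matrix[_ids_along(m, marker_positions), cols]
            marker_genotypes[iid] = gts

    # truth IBD tracts among the sequenced pattern samples
    if cfg.fixed_structure:
        affected_ids, unaffected_ids = _FIXED_AFFECTED, _FIXED_UNAFFECTED
    else:
        aff = [i for i in genotyped if phenotypes[i] == "affected"]
        un = [i for i in genotyped if phenotypes[i] == "unaffected"]
        affected_ids, unaffected_ids = tuple(aff[:3]), tuple(un[:2])
    tract_samples = sorted(set(affected_ids) | set(unaffected_ids))
    ibd_tracts = {}
    for s1, s2 in itertools.combinations(tract_samples, 2):
        tracts = _pair_shared_tracts(mosaics[s1], mosaics[s2], length)
        ibd_tracts[(s1, s2)] = [(cfg.chrom, a, b) for a, b in tracts]

    truth = SimTruth(
        causal_key=(cfg.chrom, cfg.causal_pos, "C", "T"),
        causal_gene=gene_at(cfg.causal_pos),
        carriers=carriers,
        phenotypes=phenotypes,
        affected_ids=affected_ids,
        unaffected_ids=unaffected_ids,
        genotyped=list(genotyped),
        ibd_tracts=ibd_tracts,
    )
    result = SimResult(
        pedigree=pedigree, truth=truth, variants=variants,
        marker_positions=marker_positions, marker_genotypes=marker_genotypes,
        gene_spans=gene_spans, config=cfg)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted positions in [1, length] without materializing the range."""
    if n == 0:
        return np.array([], dtype=int)
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 16))
    while len(pos) < n:
        pos = np.unique(np.concatenate(
            [pos, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.permutation(pos)[:n])


def _ids_along(mosaic: Mosaic, positions: np.ndarray) -> np.ndarray:
    bks, ids = mosaic
    return ids[np.searchsorted(bks, positions, side="right") - 1]


def write_outputs(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, PED, annotation TSV, truth IBD and truth JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    samples = result.truth.genotyped + [
        f"X{j + 1:03d}" for j in range(cfg.n_cohort_extras)]
    paths = {
        "vcf": out / "family.vcf",
        "ped": out / "family.ped",
        "annotations": out / "annotations.tsv",
        "gene_spans": out / "gene_spans.tsv",
        "ibd": out / "truth.ibd",
        "truth": out / "truth.json",
    }
    write_vcf(result.variants, samples, paths["vcf"],
              contigs=[(cfg.chrom, cfg.chrom_length_bp)])
    write_ped(result.pedigree, paths["ped"])
    write_annotation_table(result.variants, paths["annotations"])
    with open(paths["gene_spans"], "w") as fh:
        fh.write("GENE\tCHROM\tSTART\tEND\n")
        for gene, (chrom, s, e) in result.gene_spans.items():
            fh.write(f"{gene}\t{chrom}\t{s}\t{e}\n")
    segments = [IBDSegment(s1, s2, chrom, a, b, score=10.0)
                for (s1, s2), tr in result.truth.ibd_tracts.items()
                for chrom, a, b in tr]
    write_ibd(segments, paths["ibd"])
    truth_dict = asdict(result.truth)
    truth_dict["causal_key"] = list(truth_dict["causal_key"])
    truth_dict["ibd_tracts"] = {
        f"{k[0]},{k[1]}": v for k, v in truth_dict["ibd_tracts"].items()}
    with open(paths["truth"], "w") as fh:
        json.dump(truth_dict, fh, indent=1, default=str)
    return paths
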