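"""Parametric single-point linkage under a configurable disease model.

The likelihood of a pedigree is evaluated jointly over a biallelic disease
locus and a biallelic marker locus.  Each haplotype carries one allele from
each locus; founders are weighted by Hardy–Weinberg and linkage-equilibrium
priors, transmissions by Mendelian haplotype probabilities with
recombination fraction ``theta``, and each individual contributes a
penetrance factor (``f_g`` if affected, ``1 - f_g`` if unaffected, 1 if
unknown) and an indicator matching the observed marker genotype.  The sum
over joint diplotypes is computed exactly by Elston–Stewart peeling over
the nuclear-family order from :func:`fampri.pedio.peeling_order`.

The LOD score is the log10 likelihood ratio at ``theta = 0`` versus free
recombination (``theta = 0.5``), and the tail conversions printed alongside
it (half-chi-square for the LOD, Student t for group comparisons) are
provided as small wrappers over scipy's survival functions.

A brute-force reference, :func:`enumerate_loglik`, sums the same likelihood
over every joint diplotype assignment; it is exponential in pedigree size
and exists for validation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DiseaseModelError, FampriError, PedigreeLoopError
from .pedio import Pedigree, Phenotype, peeling_order

LN10 = math.log(10.0)

# Haplotype index h = 2*d + m with d in {0,1} (1 = disease allele) and
# m in {0,1} (1 = marker alt allele).  Ordered diplotype state
# s = 4*h_paternal + h_maternal, 16 states per individual.
_HAP_D = np.array([0, 0, 1, 1])
_HAP_M = np.array([0, 1, 0, 1])
_S_PAT, _S_MAT = np.divmod(np.arange(16), 4)
_N_DISEASE = _HAP_D[_S_PAT] + _HAP_D[_S_MAT]     # disease-allele dosage per state
_N_MARKER = _HAP_M[_S_PAT] + _HAP_M[_S_MAT]      # marker alt dosage per state


@dataclass(frozen=True)
class DiseaseModel:
    """Penetrance model of a monogenic trait.

    Parameters
    ----------
    prevalence
        Population prevalence K of the trait.
    penetrances
        (f0, f1, f2) = P(affected | 0, 1, 2 disease alleles); f0 is the
        phenocopy rate.
    disease_allele_freq
        Frequency of the disease allele among founder haplotypes.  When not
        supplied it is derived from the prevalence under Hardy–Weinberg.
    """

    prevalence: float
    penetrances: tuple[float, float, float]
    disease_allele_freq: float | None = None
    inheritance_label: str = "autosomal dominant"

    def __post_init__(self) -> None:
        f0, f1, f2 = self.penetrances
        if not (0.0 <= f0 <= f1 <= f2 <= 1.0):
            raise DiseaseModelError(
                f"penetrances must satisfy 0 <= f0 <= f1 <= f2 <= 1, got {self.penetrances}")
        if self.disease_allele_freq is None:
            object.__setattr__(
                self, "disease_allele_freq",
                derive_disease_allele_freq(self.prevalence, self.penetrances))
        else:
            implied = _prevalence_from(self.disease_allele_freq, self.penetrances)
            if abs(implied - self.prevalence) > 1e-6:
                raise DiseaseModelError(
                    f"supplied disease_allele_freq {self.disease_allele_freq} implies "
                    f"prevalence {implied:.6g}, not {self.prevalence:.6g}")


@dataclass(frozen=True)
class LinkageResult:
    """Single-point LOD at theta=0 against theta=0.5, with its p-value."""

    lod: float
    theta: float
    p_value: float
    loglik_linked: float
    loglik_unlinked: float


def _prevalence_from(p: float, penetrances: tuple[float, float, float]) -> float:
    f0, f1, f2 = penetrances
    q = 1.0 - p
    return f2 * p * p + f1 * 2.0 * p * q + f0 * q * q


def derive_disease_allele_freq(
    prevalence: float, penetrances: tuple[float, float, float]
) -> float:
    """Disease-allele frequency p solving the Hardy–Weinberg prevalence equation.

    Solves ``f2 p^2 + 2 f1 p(1-p) + f0 (1-p)^2 = K`` for the smaller root in
    (0, 1), i.e. the rarest allele frequency consistent with the stated
    prevalence and penetrances.
    """
    f0, f1, f2 = penetrances
    K = prevalence
    a = f2 - 2.0 * f1 + f0
    b = 2.0 * (f1 - f0)
    c = f0 - K
    roots: list[float]
    if abs(a) < 1e-14:
        roots = [] if abs(b) < 1e-14 else [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    valid = sorted(p for p in roots if 0.0 < p < 1.0)
    if not valid:
        raise DiseaseModelError(
            f"no disease-allele frequency in (0,1) yields prevalence {K} "
            f"under penetrances {penetrances}")
    return valid[0]


# -- factor construction --------------------------------------------------

def _founder_prior(p_disease: float, q_marker: float) -> np.ndarray:
    hap = np.where(_HAP_D, p_disease, 1.0 - p_disease) * \
        np.where(_HAP_M, q_marker, 1.0 - q_marker)
    return hap[_S_PAT] * hap[_S_MAT]


def _gamete_probs(theta: float) -> np.ndarray:
    """(16, 4) array: P(transmitted haplotype | parental diplotype)."""
    T = np.zeros((16, 4))
    for s in range(16):
        hp, hm = divmod(s, 4)
        T[s, hp] += (1.0 - theta) / 2.0
        T[s, hm] += (1.0 - theta) / 2.0
        rec1 = 2 * _HAP_D[hp] + _HAP_M[hm]   # disease from paternal, marker from maternal
        rec2 = 2 * _HAP_D[hm] + _HAP_M[hp]
        T[s, rec1] += theta / 2.0
        T[s, rec2] += theta / 2.0
    return T


def _transmission_tensor(theta: float) -> np.ndarray:
    """(16, 16, 16): P(child state | father state, mother state)."""
    T = _gamete_probs(theta)
    # child's paternal haplotype comes from the father, maternal from the mother
    return T[:, _S_PAT][:, None, :] * T[:, _S_MAT][None, :, :]


def _penetrance_vector(phenotype: Phenotype, model: DiseaseModel) -> np.ndarray:
    f = np.asarray(model.penetrances)[_N_DISEASE]
    if phenotype is Phenotype.AFFECTED:
        return f
    if phenotype is Phenotype.UNAFFECTED:
        return 1.0 - f
    return np.ones(16)


def _marker_vector(genotype: int | None) -> np.ndarray:
    if genotype is None:
        return np.ones(16)
    return (_N_MARKER == genotype).astype(float)


def _unary_factors(
    pedigree: Pedigree,
    marker_genotypes: dict[str, int | None],
    model: DiseaseModel,
    marker_af: float,
) -> dict[str, np.ndarray]:
    prior = _founder_prior(model.disease_allele_freq, marker_af)
    unary = {}
    for ind in pedigree:
        u = _penetrance_vector(ind.phenotype, model) * \
            _marker_vector(marker_genotypes.get(ind.iid))
        if ind.is_founder:
            u = u * prior
        unary[ind.iid] = u
    return unary


# -- Elston–Stewart peeling -----------------------------------------------

def pedigree_loglik(
    pedigree: Pedigree,
    marker_genotypes: dict[str, int | None],
    model: DiseaseModel,
    marker_af: float,
    theta: float,
) -> float:
    """Exact natural-log pedigree likelihood at recombination fraction theta.

    ``marker_genotypes`` maps iid to the observed marker alt-allele dosage
    (0, 1, 2) or ``None`` for missing; individuals absent from the map are
    treated as missing.  Likelihoods are accumulated with per-message
    rescaling so deep pedigrees do not underflow.
    """
    if not 0.0 <= theta <= 0.5:
        raise FampriError(f"theta must lie in [0, 0.5], got {theta}")
    if pedigree.has_loops:
        raise PedigreeLoopError(
            f"pedigree {pedigree.name!r} has loops; likelihood peeling unsupported")
    unary = _unary_factors(pedigree, marker_genotypes, model, marker_af)
    trans = _transmission_tensor(theta)
    messages: dict[str, list[np.ndarray]] = {iid: [] for iid in unary}
    consumed: set[str] = set()
    log_scale = 0.0
    log_total = 0.0

    def weight(iid: str) -> np.ndarray:
        w = unary[iid].copy()
        for msg in messages[iid]:
            w *= msg
        return w

    for fam in peeling_order(pedigree):
        wf = weight(fam.father)
        wm = weight(fam.mother)
        pair = np.ones((16, 16))                      # (father state, mother state)
        for child in fam.children:
            if child == fam.pivot:
                continue                              # keep the pivot child's axis
            pair = pair * (trans @ weight(child))     # sum over child states
        if fam.pivot is None:
            msg = None
            total = float((pair * wf[:, None] * wm[None, :]).sum())
            if total <= 0.0:
                return -math.inf
            log_total += math.log(total)
        elif fam.pivot in fam.children:               # peel down onto a child
            msg = np.einsum("fm,fmc->c", pair * wf[:, None] * wm[None, :], trans)
        elif fam.pivot == fam.father:                 # peel up onto a parent
            msg = (pair * wm[None, :]).sum(axis=1)
        else:
            msg = (pair * wf[:, None]).sum(axis=0)
        consumed.update(m for m in fam.members if m != fam.pivot)
        if msg is not None:
            scale = msg.max()
            if scale <= 0.0:
                return -math.inf
            messages[fam.pivot].append(msg / scale)
            log_scale += math.log(scale)

    for ind in pedigree:                              # childless, unmarried members
        if ind.iid not in consumed:
            total = float(weight(ind.iid).sum())
            if total <= 0.0:
                return -math.inf
            log_total += math.log(total)
    return log_total + log_scale


def enumerate_loglik(
    pedigree: Pedigree,
    marker_genotypes: dict[str, int | None],
    model: DiseaseModel,
    marker_af: float,
    theta: float,
    max_states: int = 100_000_000,
) -> float:
    """Brute-force log likelihood by summation over all joint diplotypes.

    States incompatible with an individual's observed marker genotype are
    pruned before enumeration, so pedigrees of up to ~8 fully genotyped
    members are feasible; the joint state space is capped at ``max_states``.
    Exists as an independent validation of :func:`pedigree_loglik`.
    """
    if not 0.0 <= theta <= 0.5:
        raise FampriError(f"theta must lie in [0, 0.5], got {theta}")
    unary = _unary_factors(pedigree, marker_genotypes, model, marker_af)
    trans = _transmission_tensor(theta)
    iids = [ind.iid for ind in pedigree]
    axis = {iid: k for k, iid in enumerate(iids)}
    states = {iid: np.flatnonzero(_marker_vector(marker_genotypes.get(iid)) > 0)
              for iid in iids}
    n_joint = math.prod(len(states[iid]) for iid in iids)
    if n_joint > max_states:
        raise FampriError(
            f"joint state space {n_joint} exceeds max_states={max_states}")
    shape = [len(states[iid]) for iid in iids]

    def expand(arr: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
        full = [1] * len(iids)
        for a, s in zip(axes, arr.shape):
            full[a] = s
        return arr.reshape(full)

    joint = np.ones(shape)
    for iid in iids:
        joint *= expand(unary[iid][states[iid]], (axis[iid],))
    for ind in pedigree.nonfounders:
        sub = trans[np.ix_(states[ind.father], states[ind.mother], states[ind.iid])]
        af, am, ac = axis[ind.father], axis[ind.mother], axis[ind.iid]
        order = np.argsort([af, am, ac])
        joint *= expand(sub.transpose(order), tuple(sorted((af, am, ac))))
    total = float(joint.sum())
    return math.log(total) if total > 0.0 else -math.inf


# -- LOD and tail statistics ----------------------------------------------

def single_point_lod(
    pedigree: Pedigree,
    marker_genotypes: dict[str, int | None],
    model: DiseaseModel,
    marker_af: float = 0.001,
    theta: float = 0.0,
) -> LinkageResult:
    """Single-point parametric LOD at ``theta`` against free recombination."""
    ll_linked = pedigree_loglik(pedigree, marker_genotypes, model, marker_af, theta)
    ll_free = pedigree_loglik(pedigree, marker_genotypes, model, marker_af, 0.5)
    lod = (ll_linked - ll_free) / LN10
    p = lod_to_pvalue(lod) if lod >= 0.0 else float("nan")
    return LinkageResult(lod=lod, theta=theta, p_value=p,
                         loglik_linked=ll_linked, loglik_unlinked=ll_free)


def lod_grid(
    pedigree: Pedigree,
    marker_genotypes: dict[str, int | None],
    model: DiseaseModel,
    marker_af: float = 0.001,
    thetas: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> list[tuple[float, float]]:
    """Diagnostic LOD curve over a grid of recombination fractions."""
    ll_free = pedigree_loglik(pedigree, marker_genotypes, model, marker_af, 0.5)
    out = []
    for theta in thetas:
        if theta == 0.5:
            out.append((theta, 0.0))
            continue
        ll = pedigree_loglik(pedigree, marker_genotypes, model, marker_af, theta)
        out.append((theta, (ll - ll_free) / LN10))
    return out


def lod_to_pvalue(lod: float) -> float:
    """Half upper tail of a 1-df chi-square at ``2 ln(10) * lod``.

    The one-sided p-value of a LOD score under the usual boundary
    asymptotics: ``pchisq(lod * 2*log(10), df=1, lower.tail=FALSE) / 2``.
    """
    if lod < 0.0:
        raise FampriError(f"lod must be non-negative, got {lod}")
    return float(stats.chi2.sf(lod * 2.0 * LN10, df=1) / 2.0)


def t_two_tailed(t: float, df: float) -> float:
    """Two-tailed p-value of a Student t statistic."""
    if df < 1:
        raise FampriError(f"degrees of freedom must be >= 1, got {df}")
    return float(2.0 * stats.t.sf(abs(t), df))
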