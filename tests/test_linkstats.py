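import math

import numpy as np
import pytest

from fampri.errors import DiseaseModelError, FampriError, PedigreeLoopError
from fampri.linkstats import (
    DiseaseModel, derive_disease_allele_freq, enumerate_loglik, lod_grid,
    lod_to_pvalue, pedigree_loglik, single_point_lod, t_two_tailed,
)
from fampri.pedio import Individual, Pedigree, Phenotype, Sex
from fampri.simfam import drop_marker, random_pedigree

A, U, UNK = Phenotype.AFFECTED, Phenotype.UNAFFECTED, Phenotype.UNKNOWN


def random_phenotyped(n, rng):
    ped = random_pedigree(n, rng)
    inds = [Individual(iid=x.iid, fid=x.fid, father=x.father, mother=x.mother,
                       sex=x.sex, phenotype=[A, U, UNK][int(rng.integers(3))])
            for x in ped]
    return Pedigree(inds, name=ped.name)


# -- disease model ---------------------------------------------------------

def test_derive_freq_dominant_090():
    p = derive_disease_allele_freq(0.01, (0.0, 0.9, 0.9))
    assert p == pytest.approx(1 - math.sqrt(1 - 1 / 90), abs=1e-12)
    assert p == pytest.approx(0.005571, abs=5e-7)


def test_derive_freq_fully_penetrant():
    p = derive_disease_allele_freq(0.01, (0.0, 1.0, 1.0))
    assert p == pytest.approx(1 - math.sqrt(0.99), abs=1e-12)
    assert p == pytest.approx(0.005013, abs=5e-7)


def test_derive_freq_small_prevalence_limit():
    assert derive_disease_allele_freq(1e-8, (0.0, 0.9, 0.9)) < 1e-7


@pytest.mark.parametrize("K,f", [
    (0.01, (0.0, 0.9, 0.9)), (0.001, (0.0, 1.0, 1.0)),
    (0.05, (0.01, 0.8, 0.9)), (0.01, (0.005, 0.5, 1.0)),
])
def test_derive_freq_round_trips(K, f):
    p = derive_disease_allele_freq(K, f)
    f0, f1, f2 = f
    q = 1 - p
    assert f2 * p * p + 2 * f1 * p * q + f0 * q * q == pytest.approx(K, abs=1e-9)


def test_derive_freq_no_root():
    with pytest.raises(DiseaseModelError):
        derive_disease_allele_freq(0.5, (0.0, 0.0, 0.1))


def test_model_rejects_inconsistent_supplied_freq():
    with pytest.raises(DiseaseModelError):
        DiseaseModel(0.01, (0.0, 0.9, 0.9), disease_allele_freq=0.2)


# -- pedigree likelihood ---------------------------------------------------

def test_single_founder_het_closed_form(dominant_model):
    ped = Pedigree([Individual("X")])
    for q in (0.001, 0.1, 0.43):
        ll = pedigree_loglik(ped, {"X": 1}, dominant_model, q, 0.0)
        assert ll == pytest.approx(math.log(2 * q * (1 - q)), abs=1e-12)


def test_theta_domain_error(dominant_model):
    ped = Pedigree([Individual("X")])
    with pytest.raises(FampriError):
        pedigree_loglik(ped, {"X": 1}, dominant_model, 0.1, 0.7)


def test_looped_pedigree_rejected(dominant_model):
    ped = Pedigree([
        Individual("GF", sex=Sex.MALE), Individual("GM", sex=Sex.FEMALE),
        Individual("A", father="GF", mother="GM", sex=Sex.MALE),
        Individual("B", father="GF", mother="GM", sex=Sex.FEMALE),
        Individual("X", father="A", mother="B"),
    ])
    with pytest.raises(PedigreeLoopError):
        pedigree_loglik(ped, {}, dominant_model, 0.1, 0.0)


def test_theta_half_factorizes(dominant_model, rng):
    """At theta=0.5 the joint likelihood equals the product of the
    disease-only and marker-only likelihoods (independence)."""
    for _ in range(10):
        ped = random_phenotyped(int(rng.integers(3, 9)), rng)
        gts = drop_marker(ped, 0.3, rng)
        joint = pedigree_loglik(ped, gts, dominant_model, 0.3, 0.5)
        disease_only = pedigree_loglik(ped, {}, dominant_model, 0.3, 0.5)
        unphenotyped = Pedigree([
            Individual(iid=x.iid, fid=x.fid, father=x.father, mother=x.mother, sex=x.sex)
            for x in ped], name=ped.name)
        marker_only = pedigree_loglik(unphenotyped, gts, dominant_model, 0.3, 0.5)
        assert joint == pytest.approx(disease_only + marker_only, abs=1e-9)


def test_peeling_equals_enumeration_small(dominant_model, rng):
    for _ in range(25):
        ped = random_phenotyped(int(rng.integers(2, 8)), rng)
        gts = drop_marker(ped, float(rng.uniform(0.05, 0.5)), rng)
        theta = float(rng.uniform(0, 0.5))
        af = float(rng.uniform(0.01, 0.5))
        a = pedigree_loglik(ped, gts, dominant_model, af, theta)
        b = enumerate_loglik(ped, gts, dominant_model, af, theta)
        assert a == pytest.approx(b, abs=1e-9)


def test_loglik_with_missing_marker_data(dominant_model, rng):
    ped = random_phenotyped(6, rng)
    gts = drop_marker(ped, 0.2, rng)
    some_missing = dict(gts)
    some_missing[ped.individuals[0].iid] = None
    a = pedigree_loglik(ped, some_missing, dominant_model, 0.2, 0.1)
    b = enumerate_loglik(ped, some_missing, dominant_model, 0.2, 0.1)
    assert a == pytest.approx(b, abs=1e-9)
    # dropping an observation cannot decrease the likelihood
    assert a >= pedigree_loglik(ped, gts, dominant_model, 0.2, 0.1) - 1e-12


def test_impossible_genotypes_give_minus_inf(dominant_model):
    ped = Pedigree([
        Individual("F", sex=Sex.MALE), Individual("M", sex=Sex.FEMALE),
        Individual("C", father="F", mother="M")])
    ll = pedigree_loglik(ped, {"F": 0, "M": 0, "C": 2}, dominant_model, 0.1, 0.0)
    assert ll == -math.inf


# -- LOD -------------------------------------------------------------------

def closed_form_family():
    """Fully penetrant dominant family whose single-point LOD is exactly
    4*log10(2): phase fixed through an affected marker-het grandparent,
    four informative non-recombinant children."""
    model = DiseaseModel(prevalence=0.01, penetrances=(0.0, 1.0, 1.0))
    ped = Pedigree([
        Individual("GF", sex=Sex.MALE, phenotype=A),
        Individual("GM", sex=Sex.FEMALE, phenotype=U),
        Individual("P", father="GF", mother="GM", sex=Sex.MALE, phenotype=A),
        Individual("S", sex=Sex.FEMALE, phenotype=U),
        *[Individual(f"K{i}", father="P", mother="S", phenotype=A)
          for i in range(1, 5)],
    ])
    gts = {"GF": 1, "GM": 0, "P": 1, "S": 0, "K1": 1, "K2": 1, "K3": 1, "K4": 1}
    return ped, gts, model


def test_four_child_dominant_family_lod():
    ped, gts, model = closed_form_family()
    res = single_point_lod(ped, gts, model, marker_af=0.001)
    assert res.lod == pytest.approx(4 * math.log10(2), abs=1e-9)
    assert res.lod == pytest.approx((res.loglik_linked - res.loglik_unlinked) / math.log(10))


def test_no_children_no_lod():
    model = DiseaseModel(prevalence=0.01, penetrances=(0.0, 1.0, 1.0))
    ped = Pedigree([Individual("P", sex=Sex.MALE, phenotype=A),
                    Individual("S", sex=Sex.FEMALE, phenotype=U)])
    res = single_point_lod(ped, {"P": 1, "S": 0}, model, marker_af=0.001)
    assert res.lod == pytest.approx(0.0, abs=1e-12)


def test_lod_zero_at_theta_half(dominant_model, rng):
    for _ in range(5):
        ped = random_phenotyped(7, rng)
        gts = drop_marker(ped, 0.2, rng)
        res = single_point_lod(ped, gts, dominant_model, marker_af=0.2, theta=0.5)
        assert res.lod == 0.0
        grid = dict(lod_grid(ped, gts, dominant_model, marker_af=0.2))
        assert grid[0.5] == 0.0


def test_preset_family_lod_positive(preset_sim, dominant_model):
    cv = preset_sim.causal_variant
    gts = {i: g for i, g in cv.genotypes.items() if i in preset_sim.pedigree}
    res = single_point_lod(preset_sim.pedigree, gts, dominant_model)
    assert res.lod > 0
    assert 0 < res.p_value < 0.5


# -- tail conversions ------------------------------------------------------

def test_lod_to_pvalue_printed_value():
    assert round(lod_to_pvalue(2.070), 3) == 0.001


def test_lod_to_pvalue_boundaries():
    assert lod_to_pvalue(0.0) == pytest.approx(0.5)
    with pytest.raises(FampriError):
        lod_to_pvalue(-0.1)


def test_lod_to_pvalue_normal_tail_identity():
    """p = 1 - Phi(sqrt(chi2)), an independent route to the same tail."""
    from scipy.stats import norm
    for lod in (0.5, 1.0, 2.070, 3.0):
        chi2 = lod * 2 * math.log(10)
        assert lod_to_pvalue(lod) == pytest.approx(norm.sf(math.sqrt(chi2)), rel=1e-12)
    assert lod_to_pvalue(3.0) == pytest.approx(1.0e-4, rel=0.05)


def test_lod_to_pvalue_strictly_decreasing():
    lods = np.linspace(0, 5, 40)
    ps = [lod_to_pvalue(x) for x in lods]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_t_two_tailed_printed_values():
    assert round(t_two_tailed(2.693, 53), 4) == 0.0095
    assert t_two_tailed(4.411, 44) < 1e-4
    assert t_two_tailed(0.0, 10) == pytest.approx(1.0)
    assert t_two_tailed(-2.693, 53) == t_two_tailed(2.693, 53)
    with pytest.raises(FampriError):
        t_two_tailed(1.0, 0.5)
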