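import itertools

import pytest

from fampri.errors import ConfigurationError
from fampri.ibdshare import IBDSegment, shared_regions
from fampri.segfilter import (
    CascadeConfig, SegregationPattern, rank_survivors, run_cascade, segregation_filter,
)
from fampri.varstore import HET, HOMALT, HOMREF, AnnotatedVariant

AFFECTED = ("A1", "A2", "A3")
UNAFFECTED = ("U1", "U2")
PATTERN = SegregationPattern(AFFECTED, UNAFFECTED)


def variant(aff, un, pos=100, **kw):
    gts = dict(zip(AFFECTED, aff)) | dict(zip(UNAFFECTED, un))
    base = dict(chrom="1", pos=pos, ref="A", alt="G", genotypes=gts)
    base.update(kw)
    return AnnotatedVariant(**base)


def test_het_candidate_pattern():
    het, hom = segregation_filter([variant([HET] * 3, [HOMREF] * 2)], PATTERN)
    assert len(het) == 1 and hom == []


def test_sharing_violation_excluded():
    het, hom = segregation_filter([variant([HET, HET, HOMREF], [HOMREF] * 2)], PATTERN)
    assert het == [] and hom == []


def test_hom_candidate_allows_carrier_unaffected():
    het, hom = segregation_filter([variant([HOMALT] * 3, [HET, HOMREF])], PATTERN)
    assert het == [] and len(hom) == 1


def test_missing_genotype_disqualifies():
    het, hom = segregation_filter([variant([HET, HET, None], [HOMREF] * 2)], PATTERN)
    assert het == [] and hom == []


def test_unknown_sample_id_is_config_error():
    v = AnnotatedVariant(chrom="1", pos=1, ref="A", alt="G", genotypes={"A1": HET})
    with pytest.raises(ConfigurationError):
        segregation_filter([v], PATTERN)


def test_het_pattern_unique_by_enumeration():
    """Brute force over all 2^5 {homref,het} assignments: exactly one is a
    het candidate, and the filter agrees with direct pattern matching."""
    n_het = 0
    for gts in itertools.product([HOMREF, HET], repeat=5):
        v = variant(gts[:3], gts[3:])
        het, hom = segregation_filter([v], PATTERN)
        expected_het = all(g == HET for g in gts[:3]) and all(g == HOMREF for g in gts[3:])
        assert (len(het) == 1) == expected_het
        assert hom == []              # no homalt present anywhere
        n_het += len(het)
    assert n_het == 1


def test_segregation_matches_exhaustive_oracle(preset_sim):
    """Per-variant boolean recomputation over the simulated dataset."""
    pattern = SegregationPattern(preset_sim.truth.affected_ids,
                                 preset_sim.truth.unaffected_ids)
    het, hom = segregation_filter(preset_sim.variants, pattern)
    het_keys = {v.key for v in het}
    hom_keys = {v.key for v in hom}
    for v in preset_sim.variants:
        gts = [v.genotypes[i] for i in pattern.affected_ids + pattern.unaffected_ids]
        a, u = gts[:3], gts[3:]
        want_het = None not in gts and all(g == HET for g in a) and all(g == HOMREF for g in u)
        want_hom = None not in gts and all(g == HOMALT for g in a) and all(g in (HOMREF, HET) for g in u)
        assert (v.key in het_keys) == want_het
        assert (v.key in hom_keys) == want_hom


def cascade_inputs(preset_sim):
    t = preset_sim.truth
    segs = [IBDSegment(p[0], p[1], c, a, b)
            for p, tr in t.ibd_tracts.items() for c, a, b in tr]
    regions = shared_regions(segs, set(t.affected_ids))
    pattern = SegregationPattern(t.affected_ids, t.unaffected_ids)
    return pattern, regions


def test_cascade_monotone_and_planted_survives(preset_sim):
    pattern, regions = cascade_inputs(preset_sim)
    ledger = run_cascade(preset_sim.variants, pattern, CascadeConfig(), regions,
                         gene_spans=preset_sim.gene_spans)
    counts = [ledger.n_input, ledger.n_pass_consequence, ledger.n_rare,
              ledger.n_cadd, ledger.n_ibd]
    assert counts == sorted(counts, reverse=True)
    assert any(v.key == preset_sim.truth.causal_key for v in ledger.final_survivors())
    # survivor sets nest step by step
    keys = [set(v.key for v in ledger.survivors[s])
            for s in ("segregation", "pass_consequence", "rare", "cadd", "ibd")]
    for outer, inner in zip(keys, keys[1:]):
        assert inner <= outer


def test_cascade_idempotent(preset_sim):
    pattern, regions = cascade_inputs(preset_sim)
    ledger = run_cascade(preset_sim.variants, pattern, CascadeConfig(), regions,
                         gene_spans=preset_sim.gene_spans)
    again = run_cascade(ledger.final_survivors(), pattern, CascadeConfig(), regions,
                        gene_spans=preset_sim.gene_spans)
    assert [v.key for v in again.final_survivors()] == \
        [v.key for v in ledger.final_survivors()]


def test_cascade_empty_input():
    ledger = run_cascade([], PATTERN, CascadeConfig(), [])
    assert ledger.n_input == ledger.n_ibd == 0


def test_cascade_annihilating_cadd(preset_sim):
    pattern, regions = cascade_inputs(preset_sim)
    cfg = CascadeConfig(cadd_min=float("inf"))
    ledger = run_cascade(preset_sim.variants, pattern, cfg, regions,
                         gene_spans=preset_sim.gene_spans)
    assert ledger.n_cadd == 0 and ledger.n_ibd == 0


def test_cascade_thresholds_inclusive():
    v = variant([HET] * 3, [HOMREF] * 2, consequence="missense",
                gnomad_max_af=0.001, cadd_phred=15.0)
    # cohort AF is 3/10 here, so relax the cohort threshold to isolate the
    # gnomAD and CADD boundaries
    cfg = CascadeConfig(cohort_af_threshold=0.5, ibd_mode="position")
    regions = shared_regions([IBDSegment("A1", "A2", "1", 1, 1000),
                              IBDSegment("A1", "A3", "1", 1, 1000),
                              IBDSegment("A2", "A3", "1", 1, 1000)], set(AFFECTED))
    ledger = run_cascade([v], PATTERN, cfg, regions)
    assert ledger.n_cadd == 1 and ledger.n_ibd == 1


def test_rank_survivors_ordering():
    vs = [
        variant([HET] * 3, [HOMREF] * 2, pos=1, gene="AAA", cadd_phred=20.0),
        variant([HET] * 3, [HOMREF] * 2, pos=2, gene="BBB", cadd_phred=30.0),
        variant([HET] * 3, [HOMREF] * 2, pos=3, gene="CCC", cadd_phred=30.0),
    ]
    from fampri.segfilter import FilterLedger
    ledger = FilterLedger(survivors={"ibd": vs})
    assert rank_survivors(ledger) == ["BBB", "CCC", "AAA"]       # CADD, then name
    assert rank_survivors(ledger, seed_genes=["AAA"]) == ["AAA", "BBB", "CCC"]
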