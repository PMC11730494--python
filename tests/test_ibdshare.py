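import itertools

import numpy as np
import pytest

from fampri.errors import DataError
from fampri.ibdshare import (
    IBDSegment, naive_ibd_scan, overlaps, read_ibd, shared_regions,
    write_bed, write_ibd,
)
from fampri.varstore import AnnotatedVariant


def seg(s1, s2, start, end, chrom="17"):
    return IBDSegment(s1, s2, chrom, start, end)


def test_read_one_line(tmp_path):
    p = tmp_path / "a.ibd"
    p.write_text("A\t1\tB\t1\t17\t100\t200\t3.0\n")
    [s] = read_ibd(p)
    assert s.pair == ("A", "B") and (s.chrom, s.start, s.end) == ("17", 100, 200)
    assert s.score == 3.0


def test_pair_normalization(tmp_path):
    p = tmp_path / "a.ibd"
    p.write_text("B\t1\tA\t1\t17\t100\t200\t3.0\nA\t2\tB\t1\t17\t150\t250\t2.0\n")
    segs = read_ibd(p)
    assert {s.pair for s in segs} == {("A", "B")}


def test_reversed_coordinates_error(tmp_path):
    p = tmp_path / "a.ibd"
    p.write_text("A\t1\tB\t1\t17\t300\t200\t3.0\n")
    with pytest.raises(DataError, match=":1"):
        read_ibd(p)


def test_ibd_round_trip(tmp_path, preset_sim):
    segs = [IBDSegment(p[0], p[1], c, a, b, score=10.0)
            for p, tr in preset_sim.truth.ibd_tracts.items() for c, a, b in tr]
    path = tmp_path / "t.ibd"
    write_ibd(segs, path)
    assert read_ibd(path) == segs


def brute_force_shared(segments, required, max_pos=500):
    """Per-position membership oracle."""
    pairs = list(itertools.combinations(sorted(required), 2))
    chroms = {s.chrom for s in segments}
    out = []
    for chrom in sorted(chroms):
        covered = []
        for pos in range(1, max_pos + 1):
            ok = all(any(s.chrom == chrom and s.pair == p and s.start <= pos <= s.end
                         for s in segments) for p in pairs)
            covered.append(ok)
        start = None
        for pos, ok in enumerate(covered, 1):
            if ok and start is None:
                start = pos
            elif not ok and start is not None:
                out.append((chrom, start, pos - 1))
                start = None
        if start is not None:
            out.append((chrom, start, max_pos))
    return out


def test_shared_regions_three_pair_example():
    segs = [seg("A", "B", 100, 300), seg("A", "C", 200, 400), seg("B", "C", 250, 350)]
    regions = shared_regions(segs, {"A", "B", "C"})
    assert [(r.chrom, r.start, r.end) for r in regions] == [("17", 250, 300)]
    assert regions == [r for r in regions if len(r.supporting_pairs) == 3]
    assert brute_force_shared(segs, {"A", "B", "C"}) == [("17", 250, 300)]


def test_shared_regions_missing_pair_gives_nothing():
    segs = [seg("A", "B", 100, 300), seg("A", "C", 200, 400)]
    assert shared_regions(segs, {"A", "B", "C"}) == []


def test_shared_regions_pair_identity():
    segs = [seg("A", "B", 100, 200)]
    [r] = shared_regions(segs, {"A", "B"})
    assert (r.start, r.end) == (100, 200)


def test_shared_regions_merges_own_overlaps():
    segs = [seg("A", "B", 100, 200), seg("A", "B", 150, 260)]
    [r] = shared_regions(segs, {"A", "B"})
    assert (r.start, r.end) == (100, 260)


def test_min_pairs_relaxation():
    segs = [seg("A", "B", 100, 300), seg("A", "C", 200, 400)]
    regions = shared_regions(segs, {"A", "B", "C"}, min_pairs=1)
    assert [(r.start, r.end) for r in regions] == [(100, 400)]
    regions2 = shared_regions(segs, {"A", "B", "C"}, min_pairs=2)
    assert [(r.start, r.end) for r in regions2] == [(200, 300)]


@pytest.mark.parametrize("seed", range(20))
def test_shared_regions_matches_per_base_oracle(seed):
    """Randomized instances with coordinates <= 1e4, checked exhaustively."""
    rng = np.random.default_rng(seed)
    samples = ["A", "B", "C", "D"][: int(rng.integers(2, 5))]
    segs = []
    for _ in range(int(rng.integers(1, 15))):
        i, j = rng.choice(len(samples), size=2, replace=False)
        chrom = str(rng.integers(1, 3))
        a = int(rng.integers(1, 9_000))
        b = a + int(rng.integers(0, 1_000))
        segs.append(IBDSegment(samples[i], samples[j], chrom, a, b))
    got = [(r.chrom, r.start, r.end) for r in shared_regions(segs, set(samples))]
    assert got == brute_force_shared(segs, set(samples), max_pos=10_000)
    # output intervals disjoint and sorted
    for (c1, s1, e1), (c2, s2, e2) in zip(got, got[1:]):
        assert (c1, e1) < (c2, s2) or (c1 < c2)


def test_overlaps_position_and_gene_modes():
    regions = shared_regions([seg("A", "B", 250, 300)], {"A", "B"})
    v = AnnotatedVariant(chrom="17", pos=275, ref="A", alt="G", gene="G1")
    assert overlaps(regions, v, mode="position")
    v_out = AnnotatedVariant(chrom="17", pos=301, ref="A", alt="G", gene="G1")
    assert not overlaps(regions, v_out, mode="position")    # inclusive end boundary
    spans = {"G1": ("17", 240, 260)}
    assert overlaps(regions, v_out, gene_spans=spans, mode="gene")  # partial overlap
    assert not overlaps(regions, v_out, gene_spans={}, mode="gene")  # unknown gene


def test_bed_writer_half_open(tmp_path):
    regions = shared_regions([seg("A", "B", 100, 200)], {"A", "B"})
    out = tmp_path / "r.bed"
    write_bed(regions, out)
    assert out.read_text() == "17\t99\t200\t1\n"


def test_naive_scan_all_missing_empty():
    assert naive_ibd_scan([1, 2, 3], [None] * 3, [None] * 3, "17", "A", "B") == []


def test_naive_scan_recovers_simulated_tracts():
    """Across simulated families, the exclusion scan recovers >= 80% of
    nearly every truth tract longer than 5 Mb between relative pairs."""
    from fampri.simfam import simulate_family, study_emulation_preset
    total = recovered = 0
    for seed in range(5):
        sim = simulate_family(study_emulation_preset(seed=seed))
        pos = sim.marker_positions
        for pair, tracts in sim.truth.ibd_tracts.items():
            long_tracts = [(a, b) for _, a, b in tracts if b - a >= 5_000_000]
            if not long_tracts:
                continue
            segs = naive_ibd_scan(pos, sim.marker_genotypes[pair[0]],
                                  sim.marker_genotypes[pair[1]],
                                  "17", *pair, window=100, max_opposite_homozygotes=2)
            for a, b in long_tracts:
                cover = sum(max(0, min(b, s.end) - max(a, s.start) + 1) for s in segs)
                total += 1
                recovered += cover >= 0.8 * (b - a + 1)
    assert total >= 20
    assert recovered / total >= 0.9


def test_naive_scan_unrelated_pair_short_runs(rng):
    """Unrelated genotypes at common markers: no window of 200 markers with
    <= 1 opposite homozygote is expected."""
    n = 2000
    af = rng.uniform(0.2, 0.5, size=n)
    g1 = rng.binomial(2, af)
    g2 = rng.binomial(2, af)
    segs = naive_ibd_scan(np.arange(1, n + 1) * 1000, g1, g2, "1", "A", "B",
                          window=200, max_opposite_homozygotes=1)
    assert segs == []
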