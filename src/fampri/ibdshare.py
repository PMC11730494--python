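"""Identity-by-descent segment handling and intersection.

Reads Beagle-style pairwise ``.ibd`` segment files, computes the regions
shared by every pair of a required sample set (the multi-way intersection
used as the final filter of the variant cascade), and tests variants or
gene spans for overlap.  A naive exclusion-based scan over a genotype pair
is included so synthetic data can be pushed through the full pipeline
without an external IBD caller; it is emphatically not an HMM and models
nothing beyond opposite-homozygote exclusion.

All public coordinates are 1-based inclusive; interval arithmetic is done
half-open internally and converted at the boundary (BED output is 0-based
half-open, per the format).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError
from .varstore import AnnotatedVariant

Pair = tuple[str, str]


@dataclass(frozen=True)
class IBDSegment:
    """A pairwise IBD interval; samples are stored in lexicographic order."""

    sample1: str
    sample2: str
    chrom: str
    start: int        # 1-based inclusive
    end: int          # 1-based inclusive
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"IBD segment {self.chrom}:{self.start}-{self.end}: start > end")
        if self.sample1 == self.sample2:
            raise DataError(f"IBD segment pairs {self.sample1} with itself")
        if self.sample1 > self.sample2:
            s1, s2 = self.sample2, self.sample1
            object.__setattr__(self, "sample1", s1)
            object.__setattr__(self, "sample2", s2)

    @property
    def pair(self) -> Pair:
        return (self.sample1, self.sample2)


@dataclass(frozen=True)
class SharedRegion:
    """A maximal interval IBD-shared by every required pair."""

    chrom: str
    start: int
    end: int
    supporting_pairs: frozenset[Pair]


def read_ibd(path: str | Path) -> list[IBDSegment]:
    """Read a Beagle-dialect IBD file.

    Columns: sample1 hap1 sample2 hap2 chrom start end LOD, tab- or
    whitespace-delimited; haplotype columns are ignored and pairs are
    normalized to lexicographic order.
    """
    path = Path(path)
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 7:
                raise DataError(f"{path}:{lineno}: expected >= 7 columns, got {len(fields)}")
            s1, _h1, s2, _h2, chrom, start, end = fields[:7]
            score = float(fields[7]) if len(fields) > 7 else None
            try:
                segments.append(IBDSegment(s1, s2, chrom, int(start), int(end), score))
            except DataError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    return segments


def _merge_halfopen(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def shared_regions(
    segments: Iterable[IBDSegment],
    required_samples: set[str] | Sequence[str],
    min_pairs: int | None = None,
) -> list[SharedRegion]:
    """Maximal intervals IBD-covered for every pair of the required samples.

    For each chromosome, each required pair's segments are merged into a
    union of intervals, and the intersection across pairs is returned.  The
    default is pairwise-complete sharing (all k(k-1)/2 pairs); ``min_pairs``
    relaxes this to intervals covered by at least that many pairs.  Output
    regions are disjoint, sorted, 1-based inclusive.
    """
    required = sorted(set(required_samples))
    if len(required) < 2:
        raise DataError("shared_regions needs at least two required samples")
    pairs = set(itertools.combinations(required, 2))
    need = len(pairs) if min_pairs is None else min(min_pairs, len(pairs))
    # per chromosome, per pair: merged half-open interval unions
    by_chrom: dict[str, dict[Pair, list[tuple[int, int]]]] = {}
    for seg in segments:
        if seg.pair not in pairs:
            continue
        by_chrom.setdefault(seg.chrom, {}).setdefault(seg.pair, []).append(
            (seg.start, seg.end + 1))
    out: list[SharedRegion] = []
    for chrom in sorted(by_chrom):
        pair_intervals = {p: _merge_halfopen(iv) for p, iv in by_chrom[chrom].items()}
        if len(pair_intervals) < need:
            continue
        # sweep over breakpoints, counting covering pairs per atomic interval
        events: list[tuple[int, int, Pair]] = []
        for p, ivs in pair_intervals.items():
            for s, e in ivs:
                events.append((s, +1, p))
                events.append((e, -1, p))
        cuts = sorted({pos for pos, _, _ in events})
        active: set[Pair] = set()
        ev_sorted = sorted(events, key=lambda t: (t[0], t[1]))
        idx = 0
        current: tuple[int, int, frozenset[Pair]] | None = None
        for a, b in zip(cuts, cuts[1:] + [None]):
            while idx < len(ev_sorted) and ev_sorted[idx][0] == a:
                _, delta, p = ev_sorted[idx]
                (active.discard if delta < 0 else active.add)(p)
                idx += 1
            if b is None:
                break
            if len(active) >= need:
                if current is not None and current[1] == a:
                    current = (current[0], b, current[2] | frozenset(active))
                else:
                    if current is not None:
                        out.append(SharedRegion(chrom, current[0], current[1] - 1, current[2]))
                    current = (a, b, frozenset(active))
            else:
                if current is not None:
                    out.append(SharedRegion(chrom, current[0], current[1] - 1, current[2]))
                    current = None
        if current is not None:
            out.append(SharedRegion(chrom, current[0], current[1] - 1, current[2]))
    return out


def overlaps(
    regions: Iterable[SharedRegion],
    variant: AnnotatedVariant,
    gene_spans: Mapping[str, tuple[str, int, int]] | None = None,
    mode: str = "gene",
) -> bool:
    """Does a variant fall within the shared IBD regions?

    ``mode="position"`` tests the variant position itself; ``mode="gene"``
    (the default, matching 'variants in genes within IBD segments') tests
    whether the variant's gene span intersects any region.  A variant whose
    gene is absent from ``gene_spans`` is treated as non-overlapping.
    """
    if mode not in ("position", "gene"):
        raise DataError(f"unknown overlap mode {mode!r}")
    if mode == "position":
        return any(r.chrom == variant.chrom and r.start <= variant.pos <= r.end
                   for r in regions)
    if not gene_spans or variant.gene not in gene_spans:
        return False
    chrom, gstart, gend = gene_spans[variant.gene]
    return any(r.chrom == chrom and r.start <= gend and gstart <= r.end
               for r in regions)


def write_bed(regions: Iterable[SharedRegion], path: str | Path) -> None:
    """Write shared regions as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{len(r.supporting_pairs)}\n")


def write_ibd(segments: Iterable[IBDSegment], path: str | Path) -> None:
    """Write segments in the Beagle dialect read by :func:`read_ibd`."""
    with open(path, "w") as fh:
        for s in segments:
            score = "" if s.score is None else f"\t{s.score:g}"
            fh.write(f"{s.sample1}\t1\t{s.sample2}\t1\t{s.chrom}\t{s.start}\t{s.end}{score}\n")


def read_gene_spans(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Read a gene-span TSV (GENE CHROM START END, 1-based inclusive)."""
    spans = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header[:4] != ["GENE", "CHROM", "START", "END"]:
            raise DataError(f"{path}: expected header GENE CHROM START END")
        for line in fh:
            if not line.strip():
                continue
            gene, chrom, start, end = line.split()[:4]
            spans[gene] = (chrom, int(start), int(end))
    return spans


def naive_ibd_scan(
    positions: Sequence[int],
    genotypes1: Sequence[int | None],
    genotypes2: Sequence[int | None],
    chrom: str,
    sample1: str,
    sample2: str,
    window: int = 50,
    max_opposite_homozygotes: int = 1,
) -> list[IBDSegment]:
    """Exclusion-based IBD scan over one genotype pair.

    Emits maximal runs of at least ``window`` position-sorted markers
    containing at most ``max_opposite_homozygotes`` opposite-homozygote
    sites (one sample hom-ref, the other hom-alt).  Sites missing in either
    sample are dropped before scanning.  This is a deliberately simple
    stand-in for a model-based IBD caller, adequate for exercising the
    pipeline on synthetic data where truth tracts are long.
    """
    pos = np.asarray(positions)
    if np.any(np.diff(pos) < 0):
        raise DataError("marker positions must be sorted")
    g1 = np.array([-1 if g is None else g for g in genotypes1])
    g2 = np.array([-1 if g is None else g for g in genotypes2])
    keep = (g1 >= 0) & (g2 >= 0)
    pos, g1, g2 = pos[keep], g1[keep], g2[keep]
    n = len(pos)
    if n == 0:
        return []
    opposite = ((g1 == 0) & (g2 == 2)) | ((g1 == 2) & (g2 == 0))
    # two-pointer sweep: for each right end, the smallest feasible left end
    left = 0
    count = 0
    best_left = np.empty(n, dtype=int)
    for right in range(n):
        count += opposite[right]
        while count > max_opposite_homozygotes:
            count -= opposite[left]
            left += 1
        best_left[right] = left
    segments = []
    for right in range(n):
        is_maximal = right == n - 1 or best_left[right + 1] > best_left[right]
        if is_maximal and right - best_left[right] + 1 >= window:
            segments.append(IBDSegment(
                sample1, sample2, chrom,
                int(pos[best_left[right]]), int(pos[right])))
    return segments
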