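"""Four-gamete compatible intervals and the minimal full covering.

Two biallelic markers show no evidence of historical recombination when at
most three of the four possible two-site haplotypes (gametes 00, 01, 10, 11)
occur among the strains — the classical four-gamete test.  A *compatible
interval* is a contiguous run of markers that are pairwise compatible; such
an interval admits a single perfect phylogeny over its SDPs and is the unit
over which haplotype groups, IBD and local trees are computed.

All-pairs compatibility is hereditary (any sub-run of a compatible run is
compatible), so the maximal right extent r(i) of a compatible run starting
at marker i is non-decreasing in i and can be computed with a two-pointer
sweep.  The chromosome is then covered by a minimal set of maximal
intervals chosen greedily left to right; this construction guarantees that
no marker is covered by more than two intervals, which is why the covering
can always be displayed on two alternating ("even"/"odd") parity rows.

Heterozygous and missing calls are excluded per strain from gamete
counting; a marker pair with fewer than two doubly-informative strains is
compatible by convention, and monomorphic columns are compatible with
everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_model import (
    GenomicInterval,
    GenotypeMatrix,
    Marker,
    SDP,
    require_single_chromosome,
)


@dataclass(frozen=True)
class CompatibleInterval:
    """A maximal run of pairwise four-gamete-compatible markers."""

    bounds: GenomicInterval
    ordinal: int

    @property
    def parity(self) -> str:
        """Display row: alternates with ordinal."""
        return "even" if self.ordinal % 2 == 0 else "odd"


def pair_compatible(a: SDP | np.ndarray, b: SDP | np.ndarray) -> bool:
    """Four-gamete test on two SDPs.

    True iff at most 3 distinct ordered gamete pairs occur among strains
    whose codes at both markers are homozygous calls (0 or 1).
    """
    pa = a.pattern if isinstance(a, SDP) else np.asarray(a)
    pb = b.pattern if isinstance(b, SDP) else np.asarray(b)
    if pa.shape != pb.shape:
        raise ValueError(f"SDP length mismatch: {pa.shape} vs {pb.shape}")
    informative = ((pa == 0) | (pa == 1)) & ((pb == 0) | (pb == 1))
    gametes = 2 * pa[informative] + pb[informative]
    return len(np.unique(gametes)) <= 3


class _BitColumns:
    """Per-column bitmask representation for fast pairwise 4-gamete tests.

    Column j is summarized by two Python integers whose bit i is set when
    strain i carries allele 0 (resp. 1).  Gamete (x, y) occurs for a column
    pair iff the AND of the matching masks is non-zero, so a pair check is
    four integer ANDs.
    """

    def __init__(self, calls: np.ndarray) -> None:
        self.m = calls.shape[1]
        self.is0: list[int] = []
        self.is1: list[int] = []
        for j in range(self.m):
            col = calls[:, j]
            b0 = b1 = 0
            for i, c in enumerate(col):
                if c == 0:
                    b0 |= 1 << i
                elif c == 1:
                    b1 |= 1 << i
            self.is0.append(b0)
            self.is1.append(b1)

    def compatible(self, j: int, k: int) -> bool:
        a0, a1 = self.is0[j], self.is1[j]
        b0, b1 = self.is0[k], self.is1[k]
        n = ((a0 & b0 != 0) + (a0 & b1 != 0)
             + (a1 & b0 != 0) + (a1 & b1 != 0))
        return n <= 3


def max_right_extent(matrix: GenotypeMatrix) -> np.ndarray:
    """For each marker i, the largest j with markers i..j pairwise compatible.

    Two-pointer sweep: the right frontier only advances, checking the new
    column against every column currently in the window.  r is
    non-decreasing and r[i] >= i.
    """
    require_single_chromosome(matrix)
    m = matrix.n_markers
    if m == 0:
        raise ValueError("empty matrix: no markers")
    bits = _BitColumns(matrix.calls)
    r = np.empty(m, dtype=np.int64)
    j = 0
    for i in range(m):
        if j < i:
            j = i
        while j + 1 < m and all(bits.compatible(j + 1, k)
                                for k in range(i, j + 1)):
            j += 1
        r[i] = j
    return r


def maximal_covering(matrix: GenotypeMatrix) -> list[CompatibleInterval]:
    """Minimal full covering of the chromosome by maximal compatible intervals.

    Among maximal intervals (those not contained in a longer compatible
    interval), start with the one covering marker 0 that reaches furthest
    right; then repeatedly take the maximal interval covering the first
    uncovered marker with the largest right end.  Overlap depth never
    exceeds 2.
    """
    chrom = require_single_chromosome(matrix)
    r = max_right_extent(matrix)
    m = matrix.n_markers
    positions = matrix.positions()

    # leftmost start index achieving each right extent: the maximal interval
    # ending at r[i] is [first_i_with_that_r, r[i]]
    first_start_for_extent: dict[int, int] = {}
    for i in range(m):
        ri = int(r[i])
        if ri not in first_start_for_extent:
            first_start_for_extent[ri] = i

    intervals: list[CompatibleInterval] = []
    covered_to = -1
    ordinal = 0
    while covered_to < m - 1:
        u = covered_to + 1
        end = int(r[u])  # r non-decreasing: largest extent over starts <= u
        start = first_start_for_extent[end]
        intervals.append(CompatibleInterval(
            bounds=GenomicInterval(
                chrom=chrom,
                start_pos=int(positions[start]), end_pos=int(positions[end]),
                start_idx=start, end_idx=end),
            ordinal=ordinal))
        ordinal += 1
        covered_to = end
    return intervals


def covering_depth(intervals: list[CompatibleInterval], n_markers: int) -> np.ndarray:
    """Per-marker count of covering intervals (diagnostic for the <=2 bound)."""
    depth = np.zeros(n_markers, dtype=np.int64)
    for iv in intervals:
        depth[iv.bounds.start_idx:iv.bounds.end_idx + 1] += 1
    return depth


def interval_density_histogram(items, view: GenomicInterval,
                               bins: int) -> np.ndarray:
    """Counts of item start positions in uniform base-pair windows of ``view``.

    ``items`` may be :class:`GenomicInterval` or :class:`Marker` objects (or
    anything with a ``start_pos`` or ``pos`` attribute).  The view is split
    into ``bins`` windows of equal width; the last window absorbs the
    remainder.  Each item counts once, in the window containing its start.
    """
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    if view.start_pos > view.end_pos:
        raise ValueError("empty view: start > end")
    span = view.end_pos - view.start_pos + 1
    width = max(1, span // bins)
    counts = np.zeros(bins, dtype=np.int64)
    for item in items:
        pos = _start_of(item)
        if not view.contains_pos(pos):
            continue
        b = min((pos - view.start_pos) // width, bins - 1)
        counts[b] += 1
    return counts


def _start_of(item) -> int:
    if isinstance(item, CompatibleInterval):
        return item.bounds.start_pos
    if isinstance(item, GenomicInterval):
        return item.start_pos
    if isinstance(item, Marker):
        return item.pos
    if hasattr(item, "start_pos"):
        return item.start_pos
    if hasattr(item, "pos"):
        return item.pos
    raise TypeError(f"cannot locate start position of {item!r}")
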