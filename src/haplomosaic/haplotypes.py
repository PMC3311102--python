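"""Haplotype identity groups and dynamic identity-by-descent.

Within each compatible interval, strains are partitioned into *haplotype
groups*: equivalence classes of (substantially) identical sequence.  Two
strains are linked when the fraction of informative markers at which they
differ is at most ``mismatch_tol``; heterozygous and missing calls act as
wildcards (they make a marker uninformative for that pair).  Groups are the
single-linkage closure of that relation, which at the default tolerance of
0 with complete data reduces to exact row-equality classes.

A region is identical by descent (IBD) for a selected strain subset when
all selected strains fall in the same haplotype group there; maximal runs
of consecutive IBD-positive compatible intervals are merged into blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .compatible_intervals import CompatibleInterval
from .genotype_model import GenomicInterval, GenotypeMatrix


@dataclass
class HaplotypeAssignment:
    """Partition of the strain panel within one compatible interval.

    ``groups[i]`` is the dense 0-based group id of strain i (ids ordered by
    each group's smallest strain index); ``group_members`` maps id to the
    member strain names.
    """

    interval: CompatibleInterval
    strains: list[str]
    groups: np.ndarray
    group_members: dict[int, list[str]]

    @property
    def n_groups(self) -> int:
        return len(self.group_members)

    def group_of(self, strain: str) -> int:
        try:
            i = self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain name: {strain!r}") from None
        return int(self.groups[i])


@dataclass(frozen=True)
class IBDInterval:
    """A maximal merged run of IBD-positive compatible intervals."""

    bounds: GenomicInterval
    n_intervals_merged: int


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def assign_haplotype_groups(matrix: GenotypeMatrix,
                            interval: CompatibleInterval,
                            mismatch_tol: float = 0.0) -> HaplotypeAssignment:
    """Single-linkage haplotype grouping within one compatible interval.

    A strain pair links when (informative mismatches) / (informative
    markers compared) <= ``mismatch_tol``; a pair with zero informative
    markers links by convention (no evidence of difference).
    """
    if not 0.0 <= mismatch_tol <= 1.0:
        raise ValueError(f"mismatch_tol must be in [0,1], got {mismatch_tol}")
    b = interval.bounds
    if b.end_idx >= matrix.n_markers:
        raise IndexError("interval extends past the matrix")
    block = matrix.calls[:, b.start_idx:b.end_idx + 1]
    n = matrix.n_strains
    informative = (block == 0) | (block == 1)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = informative[i] & informative[j]
            n_inf = int(both.sum())
            if n_inf == 0:
                uf.union(i, j)
                continue
            mism = int((block[i, both] != block[j, both]).sum())
            if mism / n_inf <= mismatch_tol:
                uf.union(i, j)
    roots = [uf.find(i) for i in range(n)]
    # dense ids in order of each group's smallest strain index
    id_of_root: dict[int, int] = {}
    for root in roots:
        if root not in id_of_root:
            id_of_root[root] = len(id_of_root)
    groups = np.array([id_of_root[r] for r in roots], dtype=np.int64)
    members: dict[int, list[str]] = {g: [] for g in range(len(id_of_root))}
    for i, g in enumerate(groups):
        members[int(g)].append(matrix.strains[i])
    return HaplotypeAssignment(interval=interval, strains=list(matrix.strains),
                               groups=groups, group_members=members)


def assign_all_intervals(matrix: GenotypeMatrix,
                         intervals: Sequence[CompatibleInterval],
                         mismatch_tol: float = 0.0) -> list[HaplotypeAssignment]:
    """Haplotype grouping for every interval of a covering, in ordinal order."""
    return [assign_haplotype_groups(matrix, iv, mismatch_tol)
            for iv in sorted(intervals, key=lambda iv: iv.ordinal)]


def compute_ibd(assignments: Sequence[HaplotypeAssignment],
                selected: Sequence[str]) -> list[IBDInterval]:
    """Merged IBD blocks over the selected strain subset.

    A compatible interval is IBD-positive iff all selected strains share one
    haplotype group there; maximal runs of consecutive positive intervals
    merge into single blocks whose bounds are the genomic union of their
    constituents (marker-index bounds are authoritative where merged blocks
    share boundary base pairs with neighbors).
    """
    if not selected:
        raise ValueError("selected strain set must be non-empty")
    if not assignments:
        return []
    idx = [assignments[0].strains.index(s) if s in assignments[0].strains
           else _raise_unknown(s) for s in selected]
    positive = [len({int(a.groups[i]) for i in idx}) == 1 for a in assignments]
    blocks: list[IBDInterval] = []
    run_start: int | None = None
    for t in range(len(assignments) + 1):
        if t < len(assignments) and positive[t]:
            if run_start is None:
                run_start = t
            continue
        if run_start is not None:
            first = assignments[run_start].interval.bounds
            last = assignments[t - 1].interval.bounds
            blocks.append(IBDInterval(
                bounds=GenomicInterval(
                    chrom=first.chrom,
                    start_pos=first.start_pos, end_pos=last.end_pos,
                    start_idx=first.start_idx, end_idx=last.end_idx),
                n_intervals_merged=t - run_start))
            run_start = None
    return blocks


def _raise_unknown(name: str):
    raise KeyError(f"unknown strain name: {name!r}")
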