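"""Haplotype mosaic coloring and position-radiating strain sorting.

A chromosome's haplotype structure is displayed as a mosaic of colored
bars: within any one compatible interval two strains share a color exactly
when they share a haplotype group.  Color *identity across intervals* is
what makes the mosaic readable, and two schemes are provided:

``default_coloring``
    minimizes the total number of color transitions along the chromosome.
    Consecutive intervals are matched group-to-group by maximum-weight
    assignment on shared-strain counts; matched groups inherit their color,
    unmatched groups take the smallest palette index unused in the
    interval.  Because a boundary's transition count depends only on the
    matching at that boundary, per-boundary optimal matching attains the
    global minimum.

``order_recoloring``
    recolors a displayed subset top-down: the topmost strain is monochrome,
    and every other strain takes the color (display rank) of the
    earliest-ranked strain sharing its haplotype group in each interval.

``sort_strains_at``
    sorts strains by haplotype group at a selected position, breaking ties
    by groups at increasingly distant intervals radiating alternately
    right then left, bounded by the view; residual ties keep the initial
    order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotype_model import GenomicInterval
from .haplotypes import HaplotypeAssignment

#: ordered palette of distinguishable colors; the color *index* is the
#: semantic unit — these hex values only matter at render time.
PALETTE: tuple[str, ...] = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
    "#393b79", "#637939", "#8c6d31", "#843c39", "#7b4173",
)

#: fixed subspecies colors (blue/red/green convention)
SUBSPECIES_COLORS: dict[str, str] = {
    "domesticus": "#2040d0",
    "musculus": "#d02020",
    "castaneus": "#20a020",
}


@dataclass
class ColorMosaic:
    """Per (strain, interval ordinal) palette index.

    ``colors`` has shape (n_strains, n_intervals); within one interval two
    strains share a color iff they share a haplotype group.
    """

    strains: list[str]
    colors: np.ndarray

    @property
    def n_intervals(self) -> int:
        return self.colors.shape[1]

    def transitions(self) -> int:
        """Total count of (strain, boundary) color changes."""
        return int((self.colors[:, 1:] != self.colors[:, :-1]).sum())


def _check_chain(assignments: Sequence[HaplotypeAssignment]) -> list[str]:
    if not assignments:
        raise ValueError("no haplotype assignments given")
    strains = assignments[0].strains
    for a in assignments[1:]:
        if a.strains != strains:
            raise ValueError("assignments must share one strain panel")
    return strains


def default_coloring(assignments: Sequence[HaplotypeAssignment]) -> ColorMosaic:
    """Transition-minimizing mosaic coloring over the whole interval chain."""
    strains = _check_chain(assignments)
    n = len(strains)
    colors = np.zeros((n, len(assignments)), dtype=np.int64)
    colors[:, 0] = assignments[0].groups  # base case: color = group id
    for t in range(1, len(assignments)):
        prev_colors = colors[:, t - 1]
        groups = assignments[t].groups
        k = assignments[t].n_groups
        palette_prev = sorted(set(int(c) for c in prev_colors))
        # shared-strain counts: rows = current groups, cols = previous colors
        w = np.zeros((k, len(palette_prev)), dtype=np.int64)
        col_of = {c: j for j, c in enumerate(palette_prev)}
        for i in range(n):
            w[groups[i], col_of[int(prev_colors[i])]] += 1
        # exact maximum-weight matching; zero-weight pairs are not matches
        rows, cols = linear_sum_assignment(w, maximize=True)
        assigned: dict[int, int] = {}
        used: set[int] = set()
        for g, j in zip(rows, cols):
            if w[g, j] > 0:
                assigned[int(g)] = palette_prev[j]
                used.add(palette_prev[j])
        nxt = 0
        for g in range(k):
            if g not in assigned:
                while nxt in used:
                    nxt += 1
                assigned[g] = nxt
                used.add(nxt)
        colors[:, t] = [assigned[int(g)] for g in groups]
    return ColorMosaic(strains=list(strains), colors=colors)


def order_recoloring(assignments: Sequence[HaplotypeAssignment],
                     display_order: Sequence[str]) -> ColorMosaic:
    """Recolor a displayed subset by display rank.

    In each interval, a strain's color is the display rank of the
    earliest-ranked strain sharing its haplotype group, so the topmost
    strain is color 0 genome-wide and the coloring of the first k strains
    never depends on strains ranked below them.
    """
    if not display_order:
        raise ValueError("display_order must be non-empty")
    strains = _check_chain(assignments)
    idx = []
    for s in display_order:
        if s not in strains:
            raise KeyError(f"unknown strain name: {s!r}")
        idx.append(strains.index(s))
    n = len(display_order)
    colors = np.zeros((n, len(assignments)), dtype=np.int64)
    for t, a in enumerate(assignments):
        first_rank_of_group: dict[int, int] = {}
        for rank, i in enumerate(idx):
            g = int(a.groups[i])
            if g not in first_rank_of_group:
                first_rank_of_group[g] = rank
            colors[rank, t] = first_rank_of_group[g]
    return ColorMosaic(strains=list(display_order), colors=colors)


def _containing_interval(assignments: Sequence[HaplotypeAssignment],
                         position: int) -> int:
    """Index of the interval containing ``position``; inside an overlap the
    interval with the smaller start wins."""
    hits = [t for t, a in enumerate(assignments)
            if a.interval.bounds.contains_pos(position)]
    if hits:
        return min(hits, key=lambda t: assignments[t].interval.bounds.start_pos)
    # position between covered markers: nearest interval by genomic distance
    def dist(t: int) -> int:
        b = assignments[t].interval.bounds
        return min(abs(position - b.start_pos), abs(position - b.end_pos))
    return min(range(len(assignments)), key=dist)


def sort_strains_at(assignments: Sequence[HaplotypeAssignment],
                    position: int, view: GenomicInterval,
                    initial_order: Sequence[str]) -> list[str]:
    """Sort strains by haplotype at ``position``, radiating outward.

    Stable lexicographic sort on group ids at intervals ordered: the
    interval containing the position first, then alternately next-right and
    next-left, restricted to intervals intersecting the view.  Persisting
    ties keep ``initial_order``.
    """
    strains = _check_chain(assignments)
    if not view.contains_pos(position):
        raise ValueError(
            f"position {position} outside view "
            f"[{view.start_pos}, {view.end_pos}]")
    in_view = [t for t, a in enumerate(assignments)
               if a.interval.bounds.end_pos >= view.start_pos
               and a.interval.bounds.start_pos <= view.end_pos]
    if not in_view:
        return list(initial_order)
    center = _containing_interval([assignments[t] for t in in_view], position)
    order: list[int] = [in_view[center]]
    step = 1
    while True:
        right = center + step
        left = center - step
        advanced = False
        if right < len(in_view):
            order.append(in_view[right])
            advanced = True
        if left >= 0:
            order.append(in_view[left])
            advanced = True
        if not advanced:
            break
        step += 1

    def key(name: str) -> tuple[int, ...]:
        i = strains.index(name)
        return tuple(int(assignments[t].groups[i]) for t in order)

    return sorted(initial_order, key=key)
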