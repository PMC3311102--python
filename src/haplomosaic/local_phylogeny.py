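"""Local neighbor-joining phylogenies over haplotype groups.

Each compatible interval admits a perfect phylogeny over its SDPs; the
displayed tree is a neighbor-joining (Saitou & Nei 1987) tree over the
interval's haplotype groups.  Distances between groups are computed on
group *consensus* sequences: the per-marker majority allele among members
(heterozygous/missing excluded, ties undefined), with distance = fraction
of markers, among those where both consensuses are defined, at which they
differ.

Leaf annotations follow the viewer's conventions: each leaf lists its
member strains, a count of supporting SNPs (markers where all members
share a defined allele that separates the leaf from at least one other
leaf's consensus) and a confidence score (that count over the interval's
marker total).  Branch lengths that come out negative are clamped to zero
with the excess moved to the sister branch, preserving the pair's summed
length.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
import numpy as np

from .compatible_intervals import CompatibleInterval
from .genotype_model import GenotypeMatrix
from .haplotypes import HaplotypeAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupDistanceMatrix:
    """Symmetric pairwise distances between haplotype groups (in [0, 1])."""

    group_ids: tuple[int, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.matrix, dtype=float)
        k = len(self.group_ids)
        if d.shape != (k, k):
            raise ValueError("distance matrix shape does not match group count")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0.0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "matrix", d)


@dataclass
class TreeNode:
    """Node of the (unrooted, internally rooted) NJ tree."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """NJ tree over the haplotype groups of one interval.

    ``leaf_info`` maps group id to (member strains, supporting_snps,
    confidence); ``subspecies`` optionally maps strain name to its local
    subspecific origin, used to color strain names in the rendered view.
    """

    root: TreeNode
    group_ids: tuple[int, ...]
    leaf_info: dict[int, tuple[list[str], int, float]] = field(default_factory=dict)
    subspecies: dict[str, str] = field(default_factory=dict)

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Pairwise path lengths between leaves (symmetric, keyed both ways)."""
        # each leaf's root path as an ordered (node, edge length) list
        leaves: list[tuple[str, list[tuple[TreeNode, float]]]] = []

        def collect(node: TreeNode, acc: list[tuple[TreeNode, float]]) -> None:
            if node.is_leaf:
                assert node.name is not None
                leaves.append((node.name, acc))
            for child, length in node.children:
                collect(child, acc + [(child, length)])

        collect(self.root, [])
        out: dict[tuple[str, str], float] = {}
        for i, (na, pa) in enumerate(leaves):
            for nb, pb in leaves[i + 1:]:
                k = 0  # drop the shared root-path prefix
                while (k < len(pa) and k < len(pb)
                       and pa[k][0] is pb[k][0]):
                    k += 1
                dist = (sum(d for _, d in pa[k:])
                        + sum(d for _, d in pb[k:]))
                out[(na, nb)] = out[(nb, na)] = dist
        return out


def group_consensus(matrix: GenotypeMatrix, interval: CompatibleInterval,
                    assignment: HaplotypeAssignment) -> np.ndarray:
    """(n_groups, n_interval_markers) consensus codes; -1 where undefined.

    The consensus at a marker is the majority homozygous allele among the
    group's members; heterozygous/missing calls are excluded and an exact
    tie (or no informative member) leaves the consensus undefined.
    """
    b = interval.bounds
    block = matrix.calls[:, b.start_idx:b.end_idx + 1]
    k = assignment.n_groups
    cons = np.full((k, block.shape[1]), -1, dtype=np.int8)
    for g in range(k):
        rows = block[assignment.groups == g]
        n0 = (rows == 0).sum(axis=0)
        n1 = (rows == 1).sum(axis=0)
        cons[g, n0 > n1] = 0
        cons[g, n1 > n0] = 1
        cons[g, (n0 == 0) & (n1 == 0)] = -1
    return cons


def group_distance_matrix(matrix: GenotypeMatrix, interval: CompatibleInterval,
                          assignment: HaplotypeAssignment) -> GroupDistanceMatrix:
    """Pairwise consensus distances between the interval's haplotype groups."""
    k = assignment.n_groups
    if k < 2:
        raise ValueError("need >= 2 haplotype groups to build a tree")
    cons = group_consensus(matrix, interval, assignment)
    d = np.zeros((k, k))
    for a in range(k):
        for b_ in range(a + 1, k):
            defined = (cons[a] >= 0) & (cons[b_] >= 0)
            n = int(defined.sum())
            if n == 0:
                logger.warning(
                    "groups %d and %d share no comparable markers; distance 1.0",
                    a, b_)
                d[a, b_] = d[b_, a] = 1.0
            else:
                diff = int((cons[a, defined] != cons[b_, defined]).sum())
                d[a, b_] = d[b_, a] = diff / n
    return GroupDistanceMatrix(group_ids=tuple(range(k)), matrix=d)


def neighbor_joining(dm: GroupDistanceMatrix) -> PhyloTree:
    """Standard Saitou–Nei NJ with negative-branch clamping.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined (ties toward the smaller index pair); branch lengths use the
    closed form, and a negative length is clamped to 0 with the excess
    added to the sister branch so the pair's total is preserved.
    """
    ids = list(dm.group_ids)
    nodes: list[TreeNode] = [TreeNode(name=f"g{g}") for g in ids]
    d = dm.matrix.astype(float).copy()

    if len(ids) == 1:
        raise ValueError("need >= 2 leaves")
    if len(ids) == 2:
        # single edge of length d, represented as a midpoint root
        h = d[0, 1] / 2.0
        root = TreeNode(children=[(nodes[0], h), (nodes[1], h)])
        return PhyloTree(root=root, group_ids=dm.group_ids)

    active = list(range(len(ids)))
    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances to the new internal node
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k_ in active:
            if k_ in (i, j):
                continue
            d[u, k_] = d[k_, u] = (d[i, k_] + d[j, k_] - d[i, j]) / 2.0
        nodes.append(new)
        active = [k_ for k_ in active if k_ not in (i, j)] + [u]

    # final 3-node star: closed-form branch lengths
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root, group_ids=dm.group_ids)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += -li  # excess moved to the sister branch
        li = 0.0
    if lj < 0.0:
        li += -lj
        lj = 0.0
        li = max(li, 0.0)
    return li, lj


def leaf_support(matrix: GenotypeMatrix, interval: CompatibleInterval,
                 assignment: HaplotypeAssignment) -> dict[int, tuple[int, float]]:
    """Per-leaf (supporting_snps, confidence).

    A marker supports leaf L when every member of L carries the same
    defined allele and that allele differs from the consensus of at least
    one other leaf (where that consensus is defined).
    """
    b = interval.bounds
    block = matrix.calls[:, b.start_idx:b.end_idx + 1]
    m = block.shape[1]
    cons = group_consensus(matrix, interval, assignment)
    out: dict[int, tuple[int, float]] = {}
    for g in range(assignment.n_groups):
        rows = block[assignment.groups == g]
        support = 0
        for t in range(m):
            col = rows[:, t]
            if np.any((col != 0) & (col != 1)) or len(set(col.tolist())) != 1:
                continue
            allele = int(col[0])
            others = [h for h in range(assignment.n_groups) if h != g]
            if any(cons[h, t] >= 0 and cons[h, t] != allele for h in others):
                support += 1
        out[g] = (support, support / m if m else 0.0)
    return out


def build_local_tree(matrix: GenotypeMatrix, interval: CompatibleInterval,
                     assignment: HaplotypeAssignment,
                     subspecies: dict[str, str] | None = None) -> PhyloTree:
    """Distance matrix + NJ + leaf annotation for one interval."""
    dm = group_distance_matrix(matrix, interval, assignment)
    tree = neighbor_joining(dm)
    support = leaf_support(matrix, interval, assignment)
    tree.leaf_info = {
        g: (assignment.group_members[g], support[g][0], support[g][1])
        for g in range(assignment.n_groups)}
    if subspecies:
        tree.subspecies = dict(subspecies)
    return tree


# ---------------------------------------------------------------------------
# Newick output

def _newick_of(node: TreeNode) -> str:
    if node.is_leaf:
        return node.name or ""
    inner = ",".join(f"{_newick_of(child)}:{length:.10g}"
                     for child, length in node.children)
    return f"({inner})"


def newick_string(tree: PhyloTree) -> str:
    return _newick_of(tree.root) + ";"


def write_newick(tree: PhyloTree, path: str | os.PathLike) -> None:
    """Standard Newick with branch lengths; leaves named ``g<id>``."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def write_leaf_table(tree: PhyloTree, path: str | os.PathLike) -> None:
    """Sidecar table: leaf, confidence, supporting_snps, member strains."""
    with open(path, "w") as fh:
        fh.write("leaf\tconfidence\tsupporting_snps\tstrains\n")
        for g in tree.group_ids:
            strains, nsup, conf = tree.leaf_info.get(g, ([], 0, 0.0))
            names = ",".join(
                f"{s}({tree.subspecies[s]})" if s in tree.subspecies else s
                for s in strains)
            fh.write(f"g{g}\t{conf:.6g}\t{nsup}\t{names}\n")
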