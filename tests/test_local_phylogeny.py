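"""Group distances, neighbor joining, leaf support, Newick output."""

import numpy as np
import pytest

from haplomosaic.haplotypes import assign_haplotype_groups
from haplomosaic.local_phylogeny import (
    GroupDistanceMatrix,
    group_distance_matrix,
    leaf_support,
    neighbor_joining,
    newick_string,
    write_newick,
)

from conftest import make_matrix, make_interval


def dm(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return GroupDistanceMatrix(group_ids=tuple(range(len(matrix))),
                               matrix=matrix)


def random_additive_metric(rng, n_leaves):
    """Random binary tree with positive branch lengths -> leaf metric."""
    nodes = {f"g{i}": {f"g{i}": 0.0} for i in range(n_leaves)}
    # dict node -> {leaf: distance to leaf below}
    active = list(nodes)
    dists = {name: dict(d) for name, d in nodes.items()}
    leaf_dist = np.zeros((n_leaves, n_leaves))
    idx = {f"g{i}": i for i in range(n_leaves)}
    counter = 0
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[min(i, j)], active[max(i, j)]
        la = float(rng.uniform(0.05, 1.0))
        lb = float(rng.uniform(0.05, 1.0))
        for u, du in dists[a].items():
            for v, dv in dists[b].items():
                d = du + la + dv + lb
                leaf_dist[idx[u], idx[v]] = leaf_dist[idx[v], idx[u]] = d
        new = f"n{counter}"
        counter += 1
        dists[new] = {u: du + la for u, du in dists[a].items()}
        dists[new].update({v: dv + lb for v, dv in dists[b].items()})
        active = [x for x in active if x not in (a, b)] + [new]
    return leaf_dist


class TestGroupDistances:
    def test_identical_and_opposite_consensus(self, mk_matrix, mk_interval):
        m = mk_matrix([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 1]])
        a = assign_haplotype_groups(m, mk_interval(m, 0, 2))
        d = group_distance_matrix(m, mk_interval(m, 0, 2), a)
        assert d.matrix[0, 1] == 1.0
        m2 = mk_matrix([[0, 0], [0, 0], [0, 1], [0, 1]])
        a2 = assign_haplotype_groups(m2, mk_interval(m2, 0, 1))
        d2 = group_distance_matrix(m2, mk_interval(m2, 0, 1), a2)
        assert d2.matrix[0, 1] == 0.5

    def test_undefined_marker_excluded(self, mk_matrix, mk_interval):
        # 10 markers; group B's members tie (0 vs 1) at marker 9 -> undefined;
        # consensuses differ at 5 of the 9 defined markers -> 5/9
        row_a = [0] * 10
        row_b1 = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        row_b2 = [1, 1, 1, 1, 1, 0, 0, 0, 0, 1]
        m = mk_matrix([row_a, row_a, row_b1, row_b2])
        a = assign_haplotype_groups(m, mk_interval(m, 0, 9), 0.2)
        assert a.n_groups == 2
        d = group_distance_matrix(m, mk_interval(m, 0, 9), a)
        assert d.matrix[0, 1] == pytest.approx(5 / 9)

    def test_single_group_rejected(self, mk_matrix, mk_interval):
        m = mk_matrix([[0, 0], [0, 0]])
        a = assign_haplotype_groups(m, mk_interval(m, 0, 1))
        with pytest.raises(ValueError):
            group_distance_matrix(m, mk_interval(m, 0, 1), a)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            dm([[0.0, 0.3], [0.2, 0.0]])  # asymmetric
        with pytest.raises(ValueError):
            dm([[0.0, -0.1], [-0.1, 0.0]])  # negative


class TestNeighborJoining:
    def test_two_leaves_single_edge(self):
        tree = neighbor_joining(dm([[0.0, 0.3], [0.3, 0.0]]))
        assert tree.leaf_distances()[("g0", "g1")] == pytest.approx(0.3)
        assert newick_string(tree) == "(g0:0.15,g1:0.15);"

    def test_three_leaves_closed_form(self):
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        tree = neighbor_joining(dm([[0, d_ab, d_ac],
                                    [d_ab, 0, d_bc],
                                    [d_ac, d_bc, 0]]))
        lengths = {c.name: l for c, l in tree.root.children}
        assert lengths["g0"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["g1"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["g2"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_recovers_additive_metric_exactly(self, n_leaves):
        rng = np.random.default_rng(40 + n_leaves)
        metric = random_additive_metric(rng, n_leaves)
        tree = neighbor_joining(dm(metric))
        got = tree.leaf_distances()
        for i in range(n_leaves):
            for j in range(i + 1, n_leaves):
                assert got[(f"g{i}", f"g{j}")] == pytest.approx(
                    metric[i, j], abs=1e-9)

    def test_agrees_with_skbio_on_additive_metric(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(77)
        metric = random_additive_metric(rng, 6)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(
            metric, ids=[f"g{i}" for i in range(6)]))
        mine = neighbor_joining(dm(metric)).leaf_distances()
        for i in range(6):
            for j in range(i + 1, 6):
                sk_d = sk_tree.find(f"g{i}").distance(sk_tree.find(f"g{j}"))
                assert mine[(f"g{i}", f"g{j}")] == pytest.approx(sk_d, abs=1e-6)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(51)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            # noisy (generally non-additive) random metric
            base = rng.uniform(0.1, 1.0, size=(n, n))
            metric = (base + base.T) / 2
            np.fill_diagonal(metric, 0.0)
            tree = neighbor_joining(dm(metric))

            def walk(node):
                for child, length in node.children:
                    assert length >= 0.0
                    walk(child)

            walk(tree.root)


class TestLeafSupport:
    def test_private_allele_every_marker(self, mk_matrix, mk_interval):
        m = mk_matrix([[0, 0, 0], [1, 1, 1]])
        a = assign_haplotype_groups(m, mk_interval(m, 0, 2))
        sup = leaf_support(m, mk_interval(m, 0, 2), a)
        assert sup[0] == (3, 1.0)
        assert sup[1] == (3, 1.0)

    def test_indistinct_leaf_scores_zero(self, mk_matrix, mk_interval):
        # groups forced apart by tolerance choice won't happen at tol=0 with
        # identical rows, so craft distinction at one marker only
        m = mk_matrix([[0, 0], [0, 1]])
        a = assign_haplotype_groups(m, mk_interval(m, 0, 1))
        sup = leaf_support(m, mk_interval(m, 0, 1), a)
        assert sup[0] == (1, 0.5)  # marker 1 separates; marker 0 does not

    def test_toy_three_groups_hand_count(self, mk_matrix, mk_interval):
        # 3 groups x 6 markers; count supporting markers by hand:
        # g0 = 000000, g1 = 111000, g2 = 110110
        m = mk_matrix([[0, 0, 0, 0, 0, 0],
                       [1, 1, 1, 0, 0, 0],
                       [1, 1, 0, 1, 1, 0]])
        iv = mk_interval(m, 0, 5)
        a = assign_haplotype_groups(m, iv)
        sup = leaf_support(m, iv, a)
        # g0 differs from some other consensus at markers 0,1,2,3,4 -> 5
        # g1 differs at 0?no(g2 also 1.. g1 vs g0 yes) markers 0,1 both differ
        # from g0; marker 2 differs from both; 3,4 differ from g2 -> 5
        # g2: markers 0,1 differ from g0; 2 differs from g1? g2 has 0 there,
        # g1 has 1 -> yes; 3,4 differ from both; 5 nowhere -> 5
        assert sup[0] == (5, 5 / 6)
        assert sup[1] == (5, 5 / 6)
        assert sup[2] == (5, 5 / 6)


class TestNewick:
    def test_round_trip_with_dendropy(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(90)
        metric = random_additive_metric(rng, 5)
        tree = neighbor_joining(dm(metric))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i in range(5):
            for j in range(i + 1, 5):
                assert pdm.distance(taxa[f"g{i}"], taxa[f"g{j}"]) \
                    == pytest.approx(metric[i, j], abs=1e-9)


def tree_splits(tree):
    """Leaf bipartitions induced by every edge of the tree."""
    splits = set()

    def below(node):
        if node.is_leaf:
            return frozenset([node.name])
        got = frozenset()
        for child, _ in node.children:
            s = below(child)
            splits.add(s)
            got |= s
        return got

    total = below(tree.root)
    return {frozenset((s, total - s)) for s in splits}


def test_perfect_phylogeny_bipartitions_on_clean_data():
    """On complete error-free data, every SDP of a compatible interval
    splits the tol=0 haplotype groups along one edge of the NJ tree."""
    # rows built from a laminar family of mutation-carrier sets, so every
    # marker is an edge-induced bipartition (a perfect phylogeny by design)
    n_leaves = 6
    subsets = [{0, 1}, {0, 1, 2}, {3, 4}, {5}, {3, 4, 5}]
    calls = np.zeros((n_leaves, len(subsets)), dtype=np.int8)
    for j, sub in enumerate(subsets):
        for i in sub:
            calls[i, j] = 1
    m = make_matrix(calls)
    iv = make_interval(m, 0, len(subsets) - 1)
    a = assign_haplotype_groups(m, iv, 0.0)
    d = group_distance_matrix(m, iv, a)
    tree = neighbor_joining(d)
    splits = tree_splits(tree)
    leaves = frozenset(f"g{g}" for g in range(a.n_groups))
    for j in range(m.n_markers):
        ones = frozenset(f"g{int(a.groups[i])}" for i in range(n_leaves)
                         if calls[i, j] == 1)
        split = frozenset((ones, leaves - ones))
        trivial = not ones or ones == leaves or min(map(len, split)) == 1
        assert trivial or split in splits
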