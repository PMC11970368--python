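"""NJ, UPGMA, Newick serialisation, and majority-rule consensus."""

import numpy as np
import pytest

from pdistree import (
    DistanceMatrix,
    NewickError,
    TreeError,
    majority_consensus,
    neighbor_joining,
    parse_newick,
    random_binary_tree,
    random_ultrametric_tree,
    upgma,
    write_newick,
)


def _dm(names, entries):
    n = len(names)
    D = np.zeros((n, n))
    for (i, j), v in entries.items():
        D[i, j] = D[j, i] = v
    return DistanceMatrix(tuple(names), D)


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_recovers_known_additive_tree():
    """Additive distances from ((A:2,B:3):1,(C:4,D:5)) -- verified to satisfy
    the four-point condition -- must be reproduced exactly."""
    dm = _dm(
        "ABCD",
        {(0, 1): 5, (0, 2): 7, (0, 3): 8, (1, 2): 8, (1, 3): 9, (2, 3): 9},
    )
    # four-point condition: two of the three pair sums are equal and maximal
    sums = sorted([5 + 9, 7 + 9, 8 + 8])
    assert sums[1] == sums[2]
    tree = neighbor_joining(dm)
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    paths = tree.pairwise_path_lengths().reorder(dm.names)
    assert np.allclose(paths.values, dm.values, atol=1e-12)
    lengths = sorted(
        round(n.length, 9) for n in tree.iter_nodes() if n.length is not None
    )
    assert lengths == [1, 2, 3, 4, 5]


def test_nj_three_taxa_closed_form():
    dm = _dm("ABC", {(0, 1): 0.4, (0, 2): 0.6, (1, 2): 0.8})
    tree = neighbor_joining(dm)
    by_name = {n.name: n.length for n in tree.leaves()}
    assert by_name["A"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
    assert by_name["B"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
    assert by_name["C"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)
    assert len(tree.root.children) == 3


def test_nj_taxon_order_invariance(rng):
    tree = random_binary_tree(9, seed=31)
    dm = tree.pairwise_path_lengths()
    perm = rng.permutation(dm.n)
    names_p = tuple(dm.names[p] for p in perm)
    t1 = neighbor_joining(dm)
    t2 = neighbor_joining(dm.reorder(names_p))
    assert t1.bipartitions() == t2.bipartitions()


def test_nj_requires_three_defined_taxa():
    with pytest.raises(TreeError):
        neighbor_joining(_dm("AB", {(0, 1): 0.1}))
    D = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
    with pytest.raises(Exception, match="undefined"):
        neighbor_joining(DistanceMatrix(("A", "B", "C"), D))


def test_nj_negative_lengths_kept_unless_clamped():
    # A matrix violating additivity strongly enough to force a negative edge.
    dm = _dm("ABCDE", {(0, 1): 0.45, (0, 2): 0.74, (0, 3): 0.75, (0, 4): 0.37,
                       (1, 2): 0.53, (1, 3): 0.54, (1, 4): 0.62,
                       (2, 3): 0.14, (2, 4): 0.88, (3, 4): 0.38})
    raw = neighbor_joining(dm)
    lengths = [n.length for n in raw.iter_nodes() if n.length is not None]
    assert min(lengths) < 0
    clamped = neighbor_joining(dm, clamp_negative=True)
    assert min(n.length for n in clamped.iter_nodes() if n.length is not None) >= 0


def test_nj_consistency_on_random_additive_matrices():
    """On tree metrics from random binary trees with positive branch lengths,
    NJ must recover the unrooted topology and all path lengths."""
    for seed in range(25):
        n_taxa = 5 + seed % 12
        truth = random_binary_tree(n_taxa, seed=seed)
        dm = truth.pairwise_path_lengths()
        rec = neighbor_joining(dm)
        assert rec.bipartitions() == truth.bipartitions()
        paths = rec.pairwise_path_lengths().reorder(dm.names)
        assert np.max(np.abs(paths.values - dm.values)) <= 1e-9


def test_nj_matches_scikit_bio_on_arbitrary_matrix(rng):
    """Independent-oracle cross-check on a non-additive random matrix."""
    skbio = pytest.importorskip("skbio")
    n = 10
    M = rng.uniform(0.05, 0.95, (n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    names = tuple(f"s{i}" for i in range(n))
    mine = neighbor_joining(DistanceMatrix(names, M))
    ref = parse_newick(str(skbio.tree.nj(skbio.DistanceMatrix(M, ids=list(names)))).strip())
    assert mine.bipartitions() == ref.bipartitions()


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_three_taxon_textbook_case():
    dm = _dm("ABC", {(0, 1): 2, (0, 2): 4, (1, 2): 4})
    tree = upgma(dm)
    assert write_newick(tree, decimals=0) in (
        "((A:1,B:1):1,C:2);",
        "(C:2,(A:1,B:1):1);",
    )


def test_upgma_is_ultrametric(rng):
    n = 9
    M = rng.uniform(0.1, 1.0, (n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    tree = upgma(DistanceMatrix(tuple(f"s{i}" for i in range(n)), M))
    depths = list(tree.leaf_depths().values())
    assert max(depths) - min(depths) < 1e-9


def test_upgma_consistency_on_random_ultrametric_matrices():
    for seed in range(25):
        n_taxa = 4 + seed % 10
        truth = random_ultrametric_tree(n_taxa, seed=seed)
        dm = truth.pairwise_path_lengths()
        rec = upgma(dm)
        assert rec.bipartitions() == truth.bipartitions()
        paths = rec.pairwise_path_lengths().reorder(dm.names)
        assert np.max(np.abs(paths.values - dm.values)) <= 1e-9


def test_upgma_matches_scipy_average_linkage(rng):
    """Merge heights must agree with scipy's average-linkage dendrogram."""
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    n = 8
    M = rng.uniform(0.1, 1.0, (n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    tree = upgma(DistanceMatrix(tuple(f"s{i}" for i in range(n)), M))
    Z = average(squareform(M))
    # root height equals half the final average-linkage merge distance, and
    # every internal node height appears among scipy's merge heights
    assert max(tree.leaf_depths().values()) == pytest.approx(Z[-1, 2] / 2)


# ---------------------------------------------------------------------------
# Newick


def test_write_newick_trifurcation():
    from pdistree import Node, PhyloTree

    tree = PhyloTree(
        Node(children=[Node("A", 1.0), Node("B", 2.0), Node("C", 3.0)])
    )
    assert write_newick(tree) == "(A:1.000000,B:2.000000,C:3.000000);"


def test_newick_round_trip_preserves_topology_and_lengths():
    text = "((A:0.100000,B:0.200000)87:0.500000,C:0.300000);"
    tree = parse_newick(text)
    assert write_newick(tree) == text
    inner = [n for n in tree.iter_nodes() if n.support is not None]
    assert len(inner) == 1 and inner[0].support == 87


def test_newick_quoted_names_with_spaces():
    text = "('sample one':0.100000,'it''s':0.200000,C:0.300000);"
    tree = parse_newick(text)
    assert set(tree.leaf_names()) == {"sample one", "it's", "C"}
    assert write_newick(tree) == text


def test_newick_tolerates_missing_lengths():
    tree = parse_newick("((A,B),(C,D));")
    assert tree.bipartitions() == {frozenset({"C", "D"})}


@pytest.mark.parametrize("bad", ["(A,B),C;", "((A,B);", "(A,B)", "(A,'B);"])
def test_newick_malformed_is_fatal(bad):
    with pytest.raises(NewickError):
        parse_newick(bad)


def test_newick_round_trip_random_trees():
    for seed in range(5):
        tree = random_binary_tree(8, seed=seed)
        back = parse_newick(write_newick(tree))
        assert back.bipartitions() == tree.bipartitions()
        assert np.allclose(
            back.pairwise_path_lengths().reorder(tree.leaf_names()).values,
            tree.pairwise_path_lengths().values,
            atol=1e-6,
        )


# ---------------------------------------------------------------------------
# consensus


def test_consensus_of_identical_trees_is_unanimous():
    trees = [parse_newick("((A,B),((C,D),E));") for _ in range(10)]
    cons = majority_consensus(trees)
    assert cons.bipartitions() == trees[0].bipartitions()
    supports = [n.support for n in cons.iter_nodes() if n.support is not None]
    assert supports and all(s == 100 for s in supports)


def test_consensus_counts_majority_split():
    trees = [parse_newick("((A,B),(C,D));")] * 6 + [
        parse_newick("((A,C),(B,D));")
    ] * 4
    cons = majority_consensus(trees)
    assert cons.bipartitions() == {frozenset({"C", "D"})}
    [node] = [n for n in cons.iter_nodes() if n.support is not None]
    assert node.support == 60


def test_consensus_supports_above_threshold_and_compatible():
    trees = (
        [parse_newick("(((A,B),C),(D,E));")] * 7
        + [parse_newick("(((A,C),B),(D,E));")] * 3
    )
    cons = majority_consensus(trees, threshold=0.5)
    supports = [n.support for n in cons.iter_nodes() if n.support is not None]
    assert all(50 < s <= 100 for s in supports)
    splits = cons.bipartitions()
    assert frozenset({"D", "E"}) in splits
    for s in splits:
        for t in splits:
            assert s <= t or t <= s or not (s & t)


def test_consensus_mismatched_leaf_sets_fatal():
    t1 = parse_newick("((A,B),(C,D));")
    t2 = parse_newick("((A,B),(C,E));")
    with pytest.raises(TreeError, match="E"):
        majority_consensus([t1, t2])


def test_consensus_agrees_with_dendropy(rng):
    """Independent-oracle cross-check of majority-rule splits and supports."""
    dendropy = pytest.importorskip("dendropy")
    distinct = [write_newick(random_binary_tree(6, seed=s)) for s in (3, 4, 5)]
    newicks = [distinct[0]] * 7 + [distinct[1]] * 3 + [distinct[2]] * 2
    mine = majority_consensus([parse_newick(t) for t in newicks])
    assert mine.bipartitions()  # majority topology is non-trivial
    tl = dendropy.TreeList.get(data="\n".join(newicks), schema="newick")
    ref = tl.consensus(min_freq=0.5000001)
    ref_text = ref.as_string(schema="newick", suppress_rooting=True).strip()
    assert mine.bipartitions() == parse_newick(ref_text).bipartitions()
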