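"""Distance matrices, NJ recovery, bootstrap and congruence scoring."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from lipopeptidome import phylogenetics as ph
from lipopeptidome import synthetic_data as sd


def _edit_distance_oracle(a, b):
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def test_identical_sequences_give_zero_distances():
    dm = ph.distance_matrix({"a": "ACGT" * 20, "b": "ACGT" * 20, "c": "ACGT" * 20})
    assert np.all(dm.data == 0)


def test_substitution_distance_definition():
    base = "A" * 100
    ten_subs = "C" * 10 + "A" * 90
    dm = ph.distance_matrix({"x": base, "y": ten_subs, "z": "G" * 100})
    assert dm["x", "y"] == pytest.approx(0.10)


def test_distance_matrix_matches_dp_oracle():
    rng = np.random.default_rng(5)
    seqs = {
        f"t{i}": "".join(rng.choice(list("ACGT"), 60)) for i in range(10)
    }
    dm = ph.distance_matrix(seqs)
    for i in seqs:
        for j in seqs:
            if i < j:
                exp = _edit_distance_oracle(seqs[i], seqs[j]) / 60
                assert dm[i, j] == pytest.approx(exp)


def test_duplicate_labels_rejected():
    with pytest.raises(ph.TreeInputError):
        ph.distance_matrix([("a", "AC"), ("a", "AG"), ("b", "AT")])


def test_nj_recovers_additive_four_taxon_tree_exactly():
    """Hand-built additive matrix: topology and branch lengths recovered.

    Generating tree: (a:1, b:2)u, (c:1.5, d:2.5)v, u-v edge 3.
    """
    labels = ["a", "b", "c", "d"]
    mat = np.array(
        [
            [0.0, 3.0, 5.5, 6.5],
            [3.0, 0.0, 6.5, 7.5],
            [5.5, 6.5, 0.0, 4.0],
            [6.5, 7.5, 4.0, 0.0],
        ]
    )
    tree = ph.nj_tree(DistanceMatrix(mat, labels))
    assert ph.tree_splits(tree) == {
        frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})})
    }
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 1.5, "d": 2.5})
    tip_dm = tree.tip_tip_distances()
    assert tip_dm["a", "d"] == pytest.approx(6.5)


def test_nj_three_taxa_and_nonfinite_rejection():
    dm = DistanceMatrix(np.array([[0, 1, 2.0], [1, 0, 2], [2, 2, 0]]), list("abc"))
    tree = ph.nj_tree(dm)
    assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]
    bad = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
    with pytest.raises(ph.TreeInputError):
        ph.nj_tree(DistanceMatrix(bad, list("abc")))


def test_nj_invariant_under_label_permutation():
    cfg = sd.SimConfig(seed=21)
    gen = sd.make_random_tree([f"t{i}" for i in range(7)], cfg)
    dm = ph._with_lengths(gen).tip_tip_distances()
    perm = list(reversed(list(dm.ids)))
    t1 = ph.nj_tree(dm)
    t2 = ph.nj_tree(dm.filter(perm))
    assert ph.rf_distance(t1, t2) == 0


def test_negative_branch_lengths_clamped_with_warning():
    # a non-additive matrix whose NJ solution contains a negative branch
    mat = np.array(
        [
            [0.0, 0.45, 0.735, 0.745, 0.375],
            [0.45, 0.0, 0.535, 0.54, 0.625],
            [0.735, 0.535, 0.0, 0.135, 0.875],
            [0.745, 0.54, 0.135, 0.0, 0.385],
            [0.375, 0.625, 0.875, 0.385, 0.0],
        ]
    )
    with pytest.warns(UserWarning, match="negative branch"):
        tree = ph.nj_tree(DistanceMatrix(mat, list("abcde")))
    assert all(
        (n.length or 0) >= 0 for n in tree.traverse(include_self=False)
    )


def test_bootstrap_full_support_for_planted_clades():
    rng = np.random.default_rng(13)
    base1 = "".join(rng.choice(list("ACGT"), 300))
    base2 = "".join(rng.choice(list("ACGT"), 300))

    def _variant(base, positions):
        chars = list(base)
        for p in positions:
            chars[p] = "ACGT"[("ACGT".index(chars[p]) + 1) % 4]
        return "".join(chars)

    aligned = {
        "A1": _variant(base1, [0, 10]),
        "A2": _variant(base1, [20, 30]),
        "A3": _variant(base1, [40, 50]),
        "B1": _variant(base2, [5, 15]),
        "B2": _variant(base2, [25, 35]),
    }
    tree = ph.bootstrap_support(aligned, n_reps=100, seed=3)
    supports = {
        frozenset(t.name for t in node.tips()): node.support
        for node in tree.non_tips(include_self=False)
        if hasattr(node, "support")
    }
    planted = [s for side, s in supports.items() if side in (
        frozenset({"A1", "A2", "A3"}), frozenset({"B1", "B2"})
    )]
    assert planted and all(s == 1.0 for s in planted)

    single = ph.bootstrap_support(aligned, n_reps=1, seed=3)
    for node in single.non_tips(include_self=False):
        if hasattr(node, "support"):
            assert node.support in (0.0, 1.0)

    again = ph.bootstrap_support(aligned, n_reps=100, seed=3)
    assert {n.name for n in again.non_tips(include_self=False)} == {
        n.name for n in tree.non_tips(include_self=False)
    }


def test_self_congruence_is_perfect_for_random_trees():
    for seed in range(5):
        cfg = sd.SimConfig(seed=seed)
        tree = sd.make_random_tree([f"t{i}" for i in range(8)], cfg)
        rep = ph.congruence(tree, tree)
        assert rep.normalized_rf == 0.0
        assert rep.cophenetic_correlation == pytest.approx(1.0)
        assert rep.discordant_leaves == []


def test_four_leaf_alternative_topologies_are_maximally_distant():
    t1 = ph.read_newick(["((A:1,B:1):1,(C:1,D:1):1);"])
    t2 = ph.read_newick(["((A:1,C:1):1,(B:1,D:1):1);"])
    t3 = ph.read_newick(["((A:1,D:1):1,(B:1,C:1):1);"])
    for a, b in [(t1, t2), (t1, t3), (t2, t3)]:
        assert ph.normalized_rf(a, b) == 1.0


def test_congruence_requires_four_shared_leaves():
    t1 = ph.read_newick(["((A:1,B:1):1,(C:1,D:1):1);"])
    t2 = ph.read_newick(["((A:1,B:1):1,(C:1,E:1):1);"])
    with pytest.raises(ph.TreeInputError):
        ph.congruence(t1, t2)


def _regraft_leaf(tree, leaf_name, target_name):
    """Move one leaf next to a distant tip (planted HGT-like discordance)."""
    t = tree.copy()
    leaf = t.find(leaf_name)
    parent = leaf.parent
    parent.remove(leaf)
    if len(parent.children) == 1 and parent.parent is not None:
        child = parent.children[0]
        child.length = (child.length or 0) + (parent.length or 0)
        grand = parent.parent
        grand.remove(parent)
        grand.append(child)
    target = t.find(target_name)
    tparent = target.parent
    tparent.remove(target)
    joint = TreeNode(children=[target, leaf])
    joint.length = 0.05
    leaf.length = 0.05
    tparent.append(joint)
    return t


def test_planted_regraft_ranked_first_discordant():
    cfg = sd.SimConfig(seed=31)
    tree = sd.make_random_tree([f"t{i}" for i in range(10)], cfg)
    dm = ph._with_lengths(tree).tip_tip_distances()
    moved = "t1"
    target = max(
        (lab for lab in dm.ids if lab != moved), key=lambda lab: dm[moved, lab]
    )
    regrafted = _regraft_leaf(tree, moved, target)
    rep = ph.congruence(tree, regrafted)
    assert rep.normalized_rf > 0
    assert rep.discordant_leaves[0][0] == moved


def test_newick_and_distance_io(tmp_path):
    t = ph.read_newick(["((A:1,B:2):0.5,(C:1,D:1):1);"])
    out = tmp_path / "t.nwk"
    ph.write_newick(t, str(out))
    back = ph.read_newick(str(out))
    assert ph.rf_distance(t, back) == 0

    dm = ph.distance_matrix({"a": "AAAA", "b": "AAAC", "c": "CCCC"})
    tsv = tmp_path / "dm.tsv"
    with open(tsv, "w") as fh:
        fh.write("\t" + "\t".join(dm.ids) + "\n")
        for lab in dm.ids:
            fh.write(lab + "\t" + "\t".join(str(dm[lab, o]) for o in dm.ids) + "\n")
    back_dm = ph.read_distance_tsv(tsv)
    assert np.allclose(back_dm.data, dm.data)
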