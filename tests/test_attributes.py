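import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, strategies as st

from intronsim.attributes import (
    GAP,
    TOP,
    AttributeConfig,
    BranchForm,
    Msa,
    align,
    attribute_set,
    branch_form,
    infer_tree,
    k2p_distance_matrix,
    nj_tree,
    overall_stats,
    pair_stats,
    relative_location,
    sed_bootstrap,
    topology_score,
)
from intronsim.attributes import _k2p_from_counts
from intronsim.core import Sequence
from intronsim.tree import GuideTree, TreeNode, fixture_tree, ladderize


def _leaf(label):
    return TreeNode(label, 1.0)


def _pairwise_nw_score(a: str, b: str) -> int:
    """Independent exhaustive global-alignment oracle (match +1, mismatch -1,
    gap -2, linear)."""

    @lru_cache(maxsize=None)
    def score(i, j):
        if i == 0 and j == 0:
            return 0
        best = -(10**9)
        if i > 0 and j > 0:
            best = max(best, score(i - 1, j - 1) + (1 if a[i - 1] == b[j - 1] else -1))
        if i > 0:
            best = max(best, score(i - 1, j) - 2)
        if j > 0:
            best = max(best, score(i, j - 1) - 2)
        return best

    return score(len(a), len(b))


def _alignment_score(msa: Msa) -> int:
    assert msa.n_rows == 2
    s = 0
    for x, y in zip(msa.matrix[0], msa.matrix[1]):
        if x == GAP or y == GAP:
            s -= 2
        else:
            s += 1 if x == y else -1
    return s


class TestAlign:
    def test_identical_pair_has_no_gaps(self):
        seqs = [Sequence("GT" + "ACGT" * 74 + "AG", i) for i in ("a", "b")]
        msa = align(seqs)
        assert msa.n_cols == 300
        assert not (msa.matrix == GAP).any()

    def test_toy_pair_matches_exhaustive_oracle(self):
        a, b = "GTAAAG", "GTAG"
        msa = align([Sequence(a, "a"), Sequence(b, "b")])
        assert msa.n_cols == 6
        assert (msa.matrix == GAP).sum() == 2
        assert _alignment_score(msa) == _pairwise_nw_score(a, b)

    @given(st.text(alphabet="ACGT", min_size=4, max_size=25).filter(lambda s: len(s) >= 4),
           st.text(alphabet="ACGT", min_size=4, max_size=25))
    def test_pairwise_score_is_optimal(self, a, b):
        msa = align([Sequence(a, "a"), Sequence(b, "b")])
        assert _alignment_score(msa) == _pairwise_nw_score(a, b)

    def test_degapping_recovers_inputs(self, md23_leaves):
        msa = align(md23_leaves)
        for s in md23_leaves:
            assert msa.degapped(s.id) == s.bases
        assert msa.n_cols >= max(len(s) for s in md23_leaves)

    def test_input_order_invariance(self, md23_leaves):
        msa_a = align(md23_leaves)
        msa_b = align(list(reversed(md23_leaves)))
        assert msa_a.ids == msa_b.ids
        assert np.array_equal(msa_a.matrix, msa_b.matrix)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            align([])


class TestPairStats:
    def test_identical_rows(self):
        ps = pair_stats("GTACGT", "GTACGT")
        assert ps.P == 0 and ps.Q == 0 and ps.d == 0

    def test_closed_form_values(self):
        # P=0.1, Q=0.05: d = -1/2 ln(0.75 sqrt(0.9)), R = d_s/d_v
        ps = _k2p_from_counts(10, 5, 100)
        assert ps.d == pytest.approx(0.17018116514, abs=1e-9)
        assert ps.r_pair == pytest.approx(2.23045429453, abs=1e-9)
        expected_d = -0.5 * np.log((1 - 0.2 - 0.05) * np.sqrt(1 - 0.1))
        assert ps.d == pytest.approx(expected_d, abs=1e-12)

    def test_saturated_pair_is_undefined(self):
        assert not _k2p_from_counts(50, 10, 100).defined

    def test_gap_sites_excluded(self):
        ps = pair_stats("AC-GT", "ACAGT")
        assert ps.n_sites == 4 and ps.d == 0


class TestOverallStats:
    def test_matches_brute_force_on_synthetic_msa(self, rng):
        rows = rng.integers(0, 4, size=(4, 120)).astype(np.uint8)
        rows[:, :60] = rows[0, :60]  # shared conserved block keeps pairs defined
        msa = Msa(["a", "b", "c", "d"], rows)
        ov = overall_stats(msa)
        dists = [
            pair_stats(msa.matrix[i], msa.matrix[j]).d
            for i, j in itertools.combinations(range(4), 2)
        ]
        dists = [d for d in dists if np.isfinite(d)]
        assert ov.dbar == pytest.approx(np.mean(dists), abs=1e-12)

    def test_two_row_msa_equals_pair_distance(self):
        msa = align([Sequence("GT" + "AC" * 50 + "AG", "a"),
                     Sequence("GT" + "AC" * 48 + "GC" + "AC" + "AG", "b")])
        ov = overall_stats(msa)
        ps = pair_stats(msa.matrix[0], msa.matrix[1])
        assert ov.dbar == pytest.approx(ps.d)

    def test_identical_rows_zero(self):
        msa = Msa(["a", "b"], np.zeros((2, 50), dtype=np.uint8))
        assert overall_stats(msa).dbar == 0.0


class TestBootstrap:
    def _divergent_msa(self, rng, n=6, L=300):
        base = rng.integers(0, 4, L).astype(np.uint8)
        rows = []
        for _ in range(n):
            r = base.copy()
            idx = rng.choice(L, L // 5, replace=False)
            r[idx] = (r[idx] + rng.integers(1, 4, idx.size)) % 4
            rows.append(r)
        return Msa([f"s{i}" for i in range(n)], np.vstack(rows))

    def test_identical_rows_zero_se(self):
        msa = Msa(["a", "b", "c"], np.ones((3, 100), dtype=np.uint8))
        assert sed_bootstrap(msa, 100, np.random.default_rng(0)) == 0.0

    def test_deterministic_under_seed(self, rng):
        msa = self._divergent_msa(rng)
        a = sed_bootstrap(msa, 200, np.random.default_rng(7))
        b = sed_bootstrap(msa, 200, np.random.default_rng(7))
        assert a == b > 0

    def test_column_duplication_shrinks_se_by_sqrt2(self, rng):
        msa = self._divergent_msa(rng)
        doubled = Msa(msa.ids, np.repeat(msa.matrix, 2, axis=1))
        ratios = []
        for seed in range(20):
            a = sed_bootstrap(msa, 300, np.random.default_rng(seed))
            b = sed_bootstrap(doubled, 300, np.random.default_rng(1000 + seed))
            ratios.append(b / a)
        assert 0.64 < np.mean(ratios) < 0.78


def _splits(tree: GuideTree) -> set:
    all_leaves = frozenset(l.label for l in tree.root.leaves())
    out = set()
    for node in tree.root.preorder():
        for child in node.children:
            s = frozenset(l.label for l in child.leaves())
            if 1 < len(s) < len(all_leaves) - 1:
                out.add(frozenset([s, all_leaves - s]))
    return out


class TestTreeInference:
    def test_nj_recovers_additive_topology(self):
        root = TreeNode("AS_1", None, [
            TreeNode("X1", 1.0, [_leaf("A"), TreeNode("X2", 0.5, [_leaf("B"), _leaf("C")])]),
            TreeNode("X3", 1.5, [_leaf("D"), _leaf("E")]),
            _leaf("F"),
        ])
        true_tree = GuideTree(root, {l: 100 for l in "ABCDEF"})
        parents = {}

        def note(node):
            for c in node.children:
                parents[c.label] = (node.label, c.branch_length or 0.0)
                note(c)

        note(root)

        def to_root(lab):
            out, d, cur = {}, 0.0, lab
            while cur in parents:
                p, bl = parents[cur]
                d += bl
                out[p] = d
                cur = p
            return out

        leaves = list("ABCDEF")
        dm = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            pi, pj = to_root(leaves[i]), to_root(leaves[j])
            dm[i, j] = dm[j, i] = min(pi[k] + pj[k] for k in pi if k in pj)
        inferred = nj_tree(dm, leaves, outgroup="F")
        assert _splits(inferred) == _splits(true_tree)

    def test_inferred_tree_is_valid_rooted_display(self, md23_leaves):
        tree = infer_tree(md23_leaves)
        assert tree.n_leaves == 14
        assert len(tree.root.children) == 3
        assert sorted(tree.leaf_labels) == sorted(s.id for s in md23_leaves)

    def test_saturated_distances_are_imputed(self):
        rows = np.array([
            [0, 0, 0, 0] * 25,
            [1, 1, 1, 1] * 25,  # every site differs: saturated pair
            [0, 0, 0, 1] * 25,
            [0, 0, 1, 0] * 25,
        ], dtype=np.uint8)
        dm, n_imputed = k2p_distance_matrix(Msa(list("abcd"), rows))
        assert n_imputed >= 1
        assert np.isfinite(dm).all() and (dm >= 0).all()


class TestTopologyScore:
    def _caterpillar6(self):
        return GuideTree(TreeNode("AS1", None, [_leaf("A"), _leaf("B"),
            TreeNode("AS2", 1.0, [_leaf("C"), TreeNode("AS3", 1.0, [_leaf("D"),
            TreeNode("AS4", 1.0, [_leaf("E"), _leaf("F")])])])]),
            {l: 100 for l in "ABCDEF"})

    def _balanced6(self):
        return GuideTree(TreeNode("R", None, [
            TreeNode("X", 1.0, [_leaf("A"), _leaf("B")]),
            TreeNode("Y", 1.0, [_leaf("C"), _leaf("D")]),
            TreeNode("Z", 1.0, [_leaf("E"), _leaf("F")])]),
            {l: 100 for l in "ABCDEF"})

    def test_branch_forms_of_cherry_and_straight(self):
        layout = ladderize(self._balanced6())
        assert branch_form(layout, "A") is BranchForm.INV_L_SHAPE
        assert branch_form(layout, "B") is BranchForm.L_SHAPE
        # caterpillar leaf near the root row is a straight line
        cat = ladderize(self._caterpillar6())
        assert branch_form(cat, "A") is BranchForm.STRAIGHT

    def test_relative_location_is_row_bijection(self, tree14):
        layout = ladderize(tree14)
        locs = [relative_location(layout, leaf) for leaf in layout.leaf_order]
        assert locs[0] == TOP
        assert locs[1:] == layout.leaf_order[:-1]

    @given(st.integers(0, 40), st.integers(4, 20))
    def test_self_score_is_two_points_per_leaf(self, seed, n):
        tree = fixture_tree(seed, n_leaves=n)
        assert topology_score(tree, tree) == 2 * n

    def test_cross_score_from_per_leaf_tabulation(self):
        # hand tabulation: forms agree for B, D, E, F; locations for B, F
        assert topology_score(self._balanced6(), self._caterpillar6()) == 6

    def test_score_bounds(self):
        score = topology_score(self._balanced6(), self._caterpillar6())
        assert 0 <= score <= 12

    def test_non_bijective_match_rejected(self):
        tree = self._balanced6()
        bad = {l: "A" for l in "ABCDEF"}
        with pytest.raises(ValueError):
            topology_score(tree, tree, match=bad)


class TestAttributeSet:
    def test_reproducible_under_seed(self, md23_leaves, tree14):
        config = AttributeConfig(bootstrap_reps=100, seed=3)
        a = attribute_set(md23_leaves, tree14, config)
        b = attribute_set(md23_leaves, tree14, config)
        assert a == b
        assert a.L_MSA >= 1975 and 0 <= a.TS_ML <= 28 and a.SEDbar > 0

    def test_identical_sequences_degenerate(self, tree14):
        seqs = [Sequence("GT" + "ACGT" * 50 + "AG", lab) for lab in tree14.leaf_labels]
        aset = attribute_set(seqs, tree14, AttributeConfig(bootstrap_reps=50))
        assert aset.Dbar == 0.0 and aset.SEDbar == 0.0
        assert aset.L_MSA == 204
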