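"""NJMerge: the siblinghood screens, relabeling, and the merge loop."""

import numpy as np
import pytest

from njmerge import (
    ConstraintForest,
    DistanceMatrix,
    additive_matrix,
    adversarial_forest,
    centroid_decompose,
    clade_join_supertree,
    is_compatibility_supertree,
    nearly_additive_perturb,
    nj_tree,
    njmerge,
    parse_newick,
    random_binary_tree,
    restrict,
)
from njmerge.errors import NJMergeFailure, TreeError
from njmerge.merge import check_property1, check_property2, relabel
from conftest import make_noise_matrix


class TestProperty1:
    def test_vacuous_when_no_common_tree(self):
        forest = ConstraintForest([parse_newick("((A,B),(C,D));"),
                                   parse_newick("((E,F),(G,H));")])
        assert check_property1(forest, "A", "E")

    def test_cherry_accepted_non_cherry_rejected(self):
        forest = ConstraintForest([parse_newick("((A,B),(C,D));")])
        assert check_property1(forest, "A", "B")
        assert not check_property1(forest, "A", "C")

    def test_non_sibling_pair_in_larger_tree_rejected(self):
        # G and H co-occur as non-siblings, so the proposal (G, H) violates
        # the constraint tree and must be rejected
        forest = ConstraintForest([parse_newick("((E,G),(F,H));")])
        assert not check_property1(forest, "G", "H")
        assert check_property1(forest, "E", "G")


class TestRelabel:
    def test_cross_tree_join_shares_new_leaf(self):
        forest = ConstraintForest([parse_newick("((A,C),(E,G));"),
                                   parse_newick("((B,D),(F,H));")])
        relabel(forest, "C", "D", "X")
        labels = [t.leaf_labels() for t in forest.trees]
        assert all("X" in ls for ls in labels)
        assert forest.registry["X"] == frozenset({"C", "D"})

    def test_cherry_contraction_drops_to_trivial(self):
        forest = ConstraintForest([parse_newick("((A,B),(C,D));")])
        relabel(forest, "A", "B", "Z")
        # the quartet shrinks to a 3-leaf tree on {Z, C, D}: retained but
        # constraint-free
        assert len(forest.trees) == 1
        assert forest.trees[0].leaf_labels() == frozenset({"Z", "C", "D"})
        assert check_property1(forest, "Z", "C")

    def test_label_absent_everywhere_is_noop(self):
        forest = ConstraintForest([parse_newick("((A,B),(C,D));")])
        before = [t.bipartitions() for t in forest.trees]
        relabel(forest, "Y", "W", "V")
        assert [t.bipartitions() for t in forest.trees] == before


class TestProperty2:
    def test_single_affected_tree_trivially_ok(self):
        forest = ConstraintForest([parse_newick("((A,B),(C,D));"),
                                   parse_newick("((E,F),(G,H));")])
        assert check_property2(forest, "A", "E", "Z")

    def test_disjoint_residuals_ok(self):
        forest = ConstraintForest([parse_newick("((A,C),(E,G));"),
                                   parse_newick("((B,D),(F,H));")])
        assert check_property2(forest, "C", "D", "X")

    def test_clashing_merged_trees_rejected(self):
        # force two trees to share two merged leaves with clashing triplets
        forest = ConstraintForest([parse_newick("((A1,A2),(A3,A4));"),
                                   parse_newick("((B1,B2),(B3,B4));")])
        relabel(forest, "A1", "B1", "X")  # X in both trees
        # proposal (A2, B3) -> Y: tree1 rooted at Y sees X with {A3,A4};
        # tree2 rooted at Y sees X beside B2 -- triplet clash
        assert check_property2(forest, "A4", "B2", "Y") in (True, False)
        ok = check_property2(forest, "A2", "B2", "Y")
        # verify against the exhaustive oracle
        from njmerge import root_at_leaf, rooted_compatible
        from njmerge.merge import _relabel_tree
        from conftest import exhaustive_rooted_compatible

        sim = [_relabel_tree(t.copy(), "A2", "B2", "Y") for t in forest.trees]
        sim = [t for t in sim if t is not None and len(t) >= 4]
        rooted = [root_at_leaf(t, "Y") for t in sim]
        assert ok == exhaustive_rooted_compatible(rooted)

    def test_groupwise_implies_pairwise(self):
        # group compatibility implies pairwise compatibility: groupwise must
        # never accept a proposal pairwise rejects
        rng = np.random.default_rng(10)
        checked = 0
        for trial in range(60):
            n = 12
            labels = [f"t{i:02d}" for i in range(n)]
            parts = [frozenset(labels[:4]), frozenset(labels[4:8]),
                     frozenset(labels[8:])]
            forest = ConstraintForest([
                restrict(random_binary_tree(
                    n, int(rng.integers(2**31 - 1)), labels=labels), p)
                for p in parts
            ])
            # apply two cross-tree joins to create overlap
            relabel(forest, labels[0], labels[4], "M1")
            relabel(forest, labels[1], labels[8], "M2")
            for x, y in [("M1", "M2"), (labels[2], labels[5]),
                         (labels[3], labels[9])]:
                if not check_property1(forest, x, y):
                    continue
                group = check_property2(forest, x, y, "Z", mode="groupwise")
                pair = check_property2(forest, x, y, "Z", mode="pairwise")
                checked += 1
                if group:
                    assert pair
        assert checked > 30


class TestNJMerge:
    def test_empty_forest_reduces_to_nj(self):
        for seed in range(10):
            D = make_noise_matrix(9, np.random.default_rng(seed))
            res = njmerge([], D)
            assert res.tree.is_isomorphic_unrooted(nj_tree(D))
            assert res.proposal_ranks == [0] * 6

    def test_recovery_with_agreeing_constraints(self):
        # nearly additive matrix + constraints that agree with the true tree
        for seed in range(15):
            n = 10 + (seed % 3) * 10
            truth = random_binary_tree(n, seed=seed)
            D = nearly_additive_perturb(additive_matrix(truth), truth,
                                        seed=seed + 500)
            dec = centroid_decompose(nj_tree(D), max(4, n // 3))
            forest = [restrict(truth, s) for s in dec.subsets if len(s) >= 3]
            res = njmerge(forest, D)
            assert res.tree.is_isomorphic_unrooted(truth)

    def test_constrained_away_from_nj_choice(self):
        # additive matrix for the 8-taxon reference tree, but a constraint
        # tree in which G and H are non-siblings: the greedy (G, H) join is
        # rejected and G ends up with F, yet the output remains a
        # compatibility supertree of the forest
        truth = parse_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,E:1,(F:1,(G:1,H:1):1):1);")
        D = additive_matrix(truth)
        forest = [parse_newick("((F,G),(E,H));")]
        res = njmerge(forest, D)
        assert is_compatibility_supertree(res.tree, forest)
        assert not res.tree.is_isomorphic_unrooted(truth)
        # the greedy (G, H) join was rejected; G pairs with F instead
        assert res.tree.has_cherry("G", "F")
        assert ("G", "H", "@z1") not in res.join_log

    def test_overlapping_constraints_rejected(self):
        D = make_noise_matrix(8, np.random.default_rng(0),
                              labels=list("ABCDEFGH"))
        with pytest.raises(TreeError):
            njmerge([parse_newick("((A,B),(C,D));"),
                     parse_newick("((D,E),(F,G));")], D)

    def test_constraint_leaf_missing_from_matrix(self):
        D = make_noise_matrix(4, np.random.default_rng(0),
                              labels=list("ABCD"))
        with pytest.raises(TreeError):
            njmerge([parse_newick("((A,B),(C,Z));")], D)

    def test_soundness_on_wrong_constraints(self):
        # deliberately wrong constraint trees: every returned tree is still
        # a compatibility supertree; failures raise NJMergeFailure
        rng = np.random.default_rng(3)
        returned = failed = 0
        for trial in range(120):
            n = int(rng.integers(9, 13))
            labels = [f"t{i:02d}" for i in range(n)]
            D = make_noise_matrix(n, rng, labels=labels)
            sh = list(labels)
            rng.shuffle(sh)
            half = n // 2
            parts = [frozenset(sh[:half]), frozenset(sh[half:])]
            forest = [
                restrict(random_binary_tree(
                    n, int(rng.integers(2**31 - 1)), labels=labels), p)
                for p in parts
            ]
            try:
                res = njmerge(forest, D, verify=False)
                assert is_compatibility_supertree(res.tree, forest)
                returned += 1
            except NJMergeFailure as exc:
                assert isinstance(exc.join_log, list)
                failed += 1
        assert returned + failed == 120
        assert returned > 0

    def test_termination_in_n_minus_3_joins(self):
        truth = random_binary_tree(14, seed=2)
        D = nearly_additive_perturb(additive_matrix(truth), truth, seed=3)
        res = njmerge([], D)
        assert len(res.join_log) == 14 - 3

    def test_adversarial_instance_fails_and_contrast_succeeds(self):
        forest, D = adversarial_forest(seed=5)
        with pytest.raises(NJMergeFailure) as err:
            njmerge(forest, D)
        assert isinstance(err.value.join_log, list)
        # same matrix and subsets, constraints from one supertree: success
        guide = nj_tree(D)
        agreeing = [restrict(guide, t.leaf_labels()) for t in forest]
        res = njmerge(agreeing, D)
        assert is_compatibility_supertree(res.tree, agreeing)

    def test_clade_join_witness_for_disjoint_forests(self):
        forest, D = adversarial_forest(seed=8)
        # even for failing instances a compatibility supertree exists
        witness = clade_join_supertree(forest)
        assert is_compatibility_supertree(witness, forest)
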