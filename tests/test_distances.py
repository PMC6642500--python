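"""AGID, log-det, additive matrices, and PHYLIP matrix I/O."""

import math
from itertools import combinations

import numpy as np
import pytest

from njmerge import (
    Alignment,
    DistanceMatrix,
    additive_matrix,
    agid_matrix,
    jc_sequences,
    logdet_matrix,
    parse_newick,
    random_binary_tree,
    read_matrix,
    write_matrix,
)
from njmerge.errors import MatrixError, SaturationError, TreeError
from conftest import path_internode_count


class TestDistanceMatrix:
    def test_rejects_asymmetry(self):
        with pytest.raises(MatrixError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(MatrixError):
            DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))

    def test_submatrix_preserves_entries(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(1, 2, (5, 5))
        V = 0.5 * (V + V.T)
        np.fill_diagonal(V, 0)
        D = DistanceMatrix(list("abcde"), V)
        S = D.submatrix(["d", "b"])
        assert S.get("d", "b") == pytest.approx(D.get("b", "d"))


class TestAgid:
    def test_single_quartet(self):
        D = agid_matrix([parse_newick("((A,B),(C,D));")])
        assert D.get("A", "B") == 1
        assert D.get("A", "C") == 2
        assert D.get("C", "D") == 1

    def test_identical_copies_average_to_one(self):
        g = parse_newick("((A,B),(C,E));")
        one = agid_matrix([g])
        many = agid_matrix([g.copy() for _ in range(7)])
        assert np.allclose(one.values, many.values)

    def test_matches_path_walk_oracle(self):
        genes = [random_binary_tree(5, seed=s, labels=list("ABCDE"))
                 for s in (1, 2, 3)]
        D = agid_matrix(genes)
        for a, b in combinations("ABCDE", 2):
            expected = np.mean([path_internode_count(g, a, b) for g in genes])
            assert D.get(a, b) == pytest.approx(expected)

    def test_missing_taxa_averaged_over_cooccurring(self):
        genes = [
            parse_newick("((A,B),(C,D));"),
            parse_newick("((A,B),(C,E));"),
            parse_newick("((A,D),(B,E));"),
        ]
        D = agid_matrix(genes)
        for a, b in combinations("ABCDE", 2):
            present = [g for g in genes if {a, b} <= g.leaf_labels()]
            expected = np.mean([path_internode_count(g, a, b) for g in present])
            assert D.get(a, b) == pytest.approx(expected)

    def test_never_cooccurring_pair_rejected(self):
        with pytest.raises(MatrixError, match="co-occur"):
            agid_matrix([parse_newick("((A,B),(C,D));"),
                         parse_newick("((A,B),(C,E));")])

    def test_unit_edge_additive_relation(self):
        # AGID of copies of a species tree equals the unit-length additive
        # matrix minus one (node count = edge count - 1 on every path)
        sp = random_binary_tree(8, seed=13)
        for node in sp.iter_nodes():
            if node.parent is not None:
                node.length = 1.0
        D_agid = agid_matrix([sp.copy(), sp.copy()])
        D_add = additive_matrix(sp)
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(D_agid.values[off],
                           D_add.submatrix(D_agid.labels).values[off] - 1)


class TestLogDet:
    def test_identical_sequences_zero(self):
        aln = Alignment({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert logdet_matrix(aln).get("a", "b") == pytest.approx(0.0)

    def test_hand_coded_determinant_oracle(self):
        a = "ACGTACGTACGTACGTTTGG"
        b = "ACGTTCGAACGGACTTACGG"
        D = logdet_matrix(Alignment({"s1": a, "s2": b}))
        # frozen value from an independent cofactor-expansion oracle
        assert D.get("s1", "s2") == pytest.approx(0.5392527381949779, abs=1e-12)

    def test_oracle_agreement_random_pairs(self):
        NUC = {"A": 0, "C": 1, "G": 2, "T": 3}

        def det(m):
            if len(m) == 1:
                return m[0][0]
            return sum(
                ((-1) ** j) * m[0][j]
                * det([row[:j] + row[j + 1:] for row in m[1:]])
                for j in range(len(m))
            )

        rng = np.random.default_rng(5)
        for _ in range(5):
            pair = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(2)]
            aln = Alignment({"x": pair[0], "y": pair[1]})
            F = [[0.0] * 4 for _ in range(4)]
            for u, v in zip(*pair):
                F[NUC[u]][NUC[v]] += 1.0 / 200
            f = [sum(r) for r in F]
            g = [sum(F[i][j] for i in range(4)) for j in range(4)]
            try:
                expected = -0.25 * (
                    math.log(det(F))
                    - 0.5 * (sum(map(math.log, f)) + sum(map(math.log, g)))
                )
            except ValueError:
                with pytest.raises(SaturationError):
                    logdet_matrix(aln)
                continue
            assert logdet_matrix(aln).get("x", "y") == pytest.approx(
                max(expected, 0.0), abs=1e-9
            )

    def test_jc_consistency_at_point_three(self):
        # paralinear distance equals expected substitutions/site under JC
        t = parse_newick("(A:0.15,B:0.15);")
        reps = [
            logdet_matrix(jc_sequences(t, 20000, seed=s)).get("A", "B")
            for s in range(6)
        ]
        se = np.std(reps, ddof=1) / math.sqrt(len(reps))
        assert abs(np.mean(reps) - 0.3) < 3 * max(se, 1e-3)

    def test_non_acgt_sites_excluded_pairwise(self):
        aln = Alignment({"a": "ACGTNNNN", "b": "ACGTACGT"})
        assert logdet_matrix(aln).get("a", "b") == pytest.approx(0.0)

    def test_saturated_pair_raises(self):
        # sequences over a two-letter sub-alphabet give det F = 0
        aln = Alignment({"a": "ACACACAC", "b": "CACACACA"})
        with pytest.raises(SaturationError, match="a"):
            logdet_matrix(aln)


class TestAdditive:
    def test_quartet_path_sums(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        D = additive_matrix(t)
        assert D.get("A", "B") == 2
        assert D.get("A", "C") == 4 or D.get("A", "C") == 3

    def test_missing_length_rejected(self):
        with pytest.raises(TreeError):
            additive_matrix(parse_newick("((A:1,B),(C:1,D:1));"))

    def test_four_point_condition(self):
        t = random_binary_tree(12, seed=21)
        D = additive_matrix(t)
        for quad in combinations(sorted(t.leaf_labels()), 4):
            a, b, c, d = quad
            sums = sorted([
                D.get(a, b) + D.get(c, d),
                D.get(a, c) + D.get(b, d),
                D.get(a, d) + D.get(b, c),
            ])
            assert sums[1] == pytest.approx(sums[2])


class TestPhylipIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        V = rng.uniform(0, 5, (3, 3))
        V = 0.5 * (V + V.T)
        np.fill_diagonal(V, 0)
        D = DistanceMatrix(["alpha", "beta", "gamma"], V)
        path = tmp_path / "d.phy"
        write_matrix(D, path)
        again = read_matrix(path)
        assert again.labels == D.labels
        assert np.allclose(again.values, D.values, atol=1e-9)

    def test_round_trip_large(self, tmp_path):
        rng = np.random.default_rng(17)
        n = 100
        V = rng.uniform(0, 9, (n, n))
        V = 0.5 * (V + V.T)
        np.fill_diagonal(V, 0)
        D = DistanceMatrix([f"s{i}" for i in range(n)], V)
        path = tmp_path / "big.phy"
        write_matrix(D, path)
        again = read_matrix(path)
        assert np.allclose(again.values, D.values, atol=1e-8)

    def test_asymmetric_file_rejected(self, tmp_path):
        path = tmp_path / "bad.phy"
        path.write_text("2\na 0 1.0\nb 2.0 0\n")
        with pytest.raises(MatrixError):
            read_matrix(path)

    def test_wrong_row_count_rejected(self, tmp_path):
        path = tmp_path / "bad.phy"
        path.write_text("3\na 0 1 1\nb 1 0 1\n")
        with pytest.raises(MatrixError):
            read_matrix(path)
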