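"""Trees, substitution models and pruning likelihoods."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from jointfold.msa_io import MultipleAlignment
from jointfold.phylo import (
    DistanceError,
    PairSubstModel,
    PhyloTree,
    column_loglik,
    column_logliks,
    estimate_tree,
    expm_rate,
    jc_distance,
    paircol_loglik,
    reversible_rate_matrix,
)
from conftest import two_leaf_tree, three_leaf_tree


class TestTreeEstimation:
    def test_identical_rows_give_zero_branches(self):
        aln = MultipleAlignment(["a", "b"], ["ACGU", "ACGU"])
        t = estimate_tree(aln)
        assert np.allclose(t.blen[:2], 0.0)

    def test_saturated_distance_errors(self):
        aln = MultipleAlignment(["a", "b"], ["ACGU", "CAUG"])
        with pytest.raises(DistanceError, match="a.*b|saturat"):
            estimate_tree(aln)

    def test_nj_recovers_additive_distances(self, models):
        """On additive distances NJ reproduces every pairwise path length."""
        # quartet ((a,b),(c,d)) with internal edge 0.05 — build rows whose
        # JC distances approximate additivity is hard, so check the NJ step
        # directly through jc distances of constructed rows is skipped;
        # instead verify path-length reconstruction on the distance matrix.
        from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

        d = {
            ("a", "b"): 0.10, ("a", "c"): 0.25, ("a", "d"): 0.27,
            ("b", "c"): 0.29, ("b", "d"): 0.31, ("c", "d"): 0.12,
        }
        names = ["a", "b", "c", "d"]
        matrix = [
            [d[tuple(sorted((names[i], names[j])))] if j < i else 0.0 for j in range(i)] + [0.0]
            for i in range(4)
        ]
        tree = DistanceTreeConstructor().nj(DistanceMatrix(names, matrix))
        pt = PhyloTree.from_biopython(tree, names)
        # path lengths between leaves must match the additive input
        def path_len(t, i, j):
            # brute force: accumulate parent chains
            parent = {}
            for node, kids in enumerate(t.children):
                for k in kids:
                    parent[k] = node
            def chain(x):
                out = [x]
                while x in parent:
                    x = parent[x]
                    out.append(x)
                return out
            ci, cj = chain(i), chain(j)
            common = next(x for x in ci if x in cj)
            s = sum(t.blen[x] for x in ci[: ci.index(common)])
            s += sum(t.blen[x] for x in cj[: cj.index(common)])
            return s

        for (x, y), dist in d.items():
            i, j = names.index(x), names.index(y)
            assert path_len(pt, i, j) == pytest.approx(dist, abs=1e-9)

    def test_jc_distance_skips_gaps_pairwise(self):
        assert jc_distance("AC-U", "ACGU") == 0.0
        with pytest.raises(DistanceError):
            jc_distance("--A", "A--")


class TestColumnLikelihoods:
    def test_single_leaf_stationary(self, models):
        t = PhyloTree(["t0"], [[]], np.array([0.0]), 0)
        got = column_loglik(t, models.single_model, ["A"])
        assert got == pytest.approx(np.log(models.single_model.pi[0]))

    def test_zero_branches_force_identity(self, models):
        t = two_leaf_tree(0.0, 0.0)
        same = column_loglik(t, models.single_model, ["A", "A"])
        assert same == pytest.approx(np.log(models.single_model.pi[0]))
        diff = column_loglik(t, models.single_model, ["A", "C"])
        assert diff == -np.inf

    def test_two_leaf_matches_transition_matrix_sum(self, models):
        """Pruning equals the explicit sum over root states, with the
        transition matrices computed by scipy's scaling-and-squaring."""
        m = models.single_model
        t = two_leaf_tree(0.1, 0.1)
        P1 = expm(m.Q * 0.1)
        expected = sum(
            m.pi[x] * P1[x, 0] * P1[x, 1] for x in range(4)
        )
        got = column_loglik(t, m, ["A", "C"])
        assert got == pytest.approx(np.log(expected), abs=1e-10)

    def test_likelihoods_normalise_over_leaf_data(self, models):
        """Sum over all residue assignments of a column's likelihood is 1."""
        m = models.single_model
        t = two_leaf_tree(0.2, 0.35)
        total = 0.0
        for a in "ACGU":
            for b in "ACGU":
                total += np.exp(column_loglik(t, m, [a, b]))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invariant_under_leaf_reordering(self, models):
        t = PhyloTree(["x", "y"], [[], [], [0, 1]], np.array([0.3, 0.1, 0.0]), 2)
        t_sw = PhyloTree(["y", "x"], [[], [], [1, 0]], np.array([0.1, 0.3, 0.0]), 2)
        a = column_loglik(t, models.single_model, ["A", "G"])
        b = column_loglik(t_sw, models.single_model, ["G", "A"])
        assert a == pytest.approx(b, abs=1e-12)

    def test_gap_and_n_are_missing_data(self, models):
        t = two_leaf_tree()
        assert column_loglik(t, models.single_model, ["-", "-"]) == pytest.approx(0.0)
        partial = column_loglik(t, models.single_model, ["A", "-"])
        assert partial == pytest.approx(np.log(models.single_model.pi[0]))


class TestPairColumnLikelihoods:
    def test_single_leaf_pair_state(self, models):
        t = PhyloTree(["t0"], [[]], np.array([0.0]), 0)
        from jointfold.phylo import PAIR_STATES

        got = paircol_loglik(t, models.pair_model, ["G"], ["C"])
        assert got == pytest.approx(
            np.log(models.pair_model.pi[PAIR_STATES.index("GC")])
        )

    def test_all_gaps_is_log_one(self, models):
        t = two_leaf_tree()
        assert paircol_loglik(t, models.pair_model, ["-", "-"], ["-", "-"]) == 0.0

    def test_gap_in_one_column_missing_in_both(self, models):
        t = two_leaf_tree()
        half = paircol_loglik(t, models.pair_model, ["G", "-"], ["C", "A"])
        only = paircol_loglik(t, models.pair_model, ["G", "-"], ["C", "-"])
        assert half == pytest.approx(only, abs=1e-12)

    def test_three_taxon_matches_internal_state_enumeration(self, models):
        """Pruning equals the brute-force sum over both internal nodes'
        16-state assignments."""
        m = models.pair_model
        t = three_leaf_tree()
        P = {i: expm(m.Q * float(t.blen[i])) for i in range(4)}
        from jointfold.phylo import PAIR_STATES

        leaves = [PAIR_STATES.index(s) for s in ("GC", "GU", "AU")]
        expected = 0.0
        for root in range(16):
            for inner in range(16):
                expected += (
                    m.pi[root]
                    * P[3][root, inner] * P[0][inner, leaves[0]] * P[1][inner, leaves[1]]
                    * P[2][root, leaves[2]]
                )
        got = paircol_loglik(
            t, m, ["G", "G", "A"], ["C", "U", "U"]
        )
        assert got == pytest.approx(np.log(expected), abs=1e-10)

    def test_long_branches_approach_stationary_independence(self, models):
        m = models.pair_model
        t = two_leaf_tree(50.0, 50.0)
        from jointfold.phylo import PAIR_STATES

        got = paircol_loglik(t, m, ["G", "A"], ["C", "U"])
        expected = (
            m.pi[PAIR_STATES.index("GC")] * m.pi[PAIR_STATES.index("AU")]
        )
        assert np.exp(got) == pytest.approx(expected, abs=1e-6)


class TestModels:
    def test_expm_eigendecomposition_matches_pade(self, models):
        for Q in (models.single_model.Q, models.pair_model.Q):
            for t in (0.01, 0.3, 2.0):
                assert np.allclose(expm_rate(Q, t), expm(Q * t), atol=1e-10)

    def test_reversible_rate_matrix_properties(self, rng):
        pi = rng.dirichlet(np.ones(4))
        S = rng.random((4, 4))
        S = S + S.T
        Q = reversible_rate_matrix(pi, S)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(pi @ Q, 0.0, atol=1e-12)  # stationarity
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0)

    def test_pair_model_declares_canonical_concentration(self, models):
        with pytest.raises(ValueError, match="canonical"):
            PairSubstModel(np.ones(16) / 16, models.pair_model.Q * 0.0)
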