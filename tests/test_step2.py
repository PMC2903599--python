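"""Constrained Step-2 scoring: rescaling rules and consistency reduction."""

import numpy as np
import pytest

from jointfold.evoscfg import StructureConstraint, inside_outside
from jointfold.msa_io import AlignmentPair, MultipleAlignment, concatenate
from jointfold.params import Params
from jointfold.phylo import estimate_tree
from jointfold.step1 import PartialStructure
from jointfold.step2 import (
    combine_step2,
    direct_concat_scoring,
    empty_partial,
    evo_step2,
    run_step2,
    thermo_step2,
)
from jointfold.thermo import CofoldConstraint, EnergyModel, cofold_partition

from conftest import two_leaf_tree


def one_row_pair(s1="GGGAAACCC", s2="GGGUUUCCC"):
    a1 = MultipleAlignment(["s"], [s1])
    a2 = MultipleAlignment(["s"], [s2])
    return AlignmentPair(a1, a2, [("s", "s")])


def two_row_pair():
    a1 = MultipleAlignment(["t0", "t1"], ["GCGCAAAAGCGC", "GUGCAAAAGCAC"])
    a2 = MultipleAlignment(["t0", "t1"], ["GGCAAAAAGCC-", "GGCAAAAAGCCU"])
    return AlignmentPair(a1, a2, [("t0", "t0"), ("t1", "t1")])


def partial(pairs, part, ev, th, n1=None):
    return PartialStructure(
        frozenset(pairs), part, 0.9, ev, tuple(th),
        tuple(frozenset(pairs) for _ in th),
    )


class TestThermoRescaling:
    def test_empty_partials_equal_unconstrained_cofold(self, energy):
        pair = one_row_pair()
        params = Params(evo=False)
        out = thermo_step2(
            pair, (empty_partial(1, 1), empty_partial(2, 1)), energy, params
        )
        raw = cofold_partition("GGGAAACCC", "GGGUUUCCC", energy)
        assert out.scales[0] == (1.0, 1.0)
        assert np.abs(out.pair_rows[0] - raw.pair_prob).max() < 1e-15
        assert np.abs(out.ss_rows[0] - raw.unpaired_prob).max() < 1e-15

    def test_product_rescaling_of_free_pairs(self, energy):
        """Non-constrained pairs carry raw * q1 * q2 (0.8 * 0.5 * 0.5 = 0.2
        style arithmetic, checked against the directly constrained cofold)."""
        pair = one_row_pair()
        p1 = partial([(1, 9)], 1, 0.9, [0.5])
        p2 = partial([], 2, 1.0, [0.8])
        out = thermo_step2(pair, (p1, p2), energy, Params(evo=False))
        ref = cofold_partition(
            "GGGAAACCC", "GGGUUUCCC", energy,
            CofoldConstraint(forced_unpaired=frozenset([1, 9])),
        )
        scale = 0.5 * 0.8
        free = np.ones((18, 18), dtype=bool)
        for p in (0, 8):
            free[p, :] = free[:, p] = False
        assert np.abs(
            out.pair_rows[0][free] - ref.pair_prob[free] * scale
        ).max() < 1e-12
        # single-stranded positions: same rescaling, sigma-p positions 0
        assert out.ss_rows[0][0] == 0.0 and out.ss_rows[0][8] == 0.0
        assert np.abs(
            out.ss_rows[0][1:8] - ref.unpaired_prob[1:8] * scale
        ).max() < 1e-12

    def test_constrained_pairs_get_fixed_probability(self, energy):
        pair = one_row_pair()
        p1 = partial([(1, 9)], 1, 0.9, [0.37])
        p2 = partial([], 2, 1.0, [1.0])
        out = thermo_step2(pair, (p1, p2), energy, Params(evo=False))
        assert out.pair_rows[0][0, 8] == pytest.approx(0.37)
        assert out.pair_rows[0][8, 0] == pytest.approx(0.37)

    def test_eq15_mode_scores_constrained_pairs_as_one(self, energy):
        pair = one_row_pair()
        p1 = partial([(1, 9)], 1, 0.9, [0.37])
        p2 = partial([], 2, 1.0, [1.0])
        out = thermo_step2(
            pair, (p1, p2), energy, Params(evo=False, eq15_mode=True)
        )
        assert out.pair_rows[0][0, 8] == 1.0

    def test_no_pair_touches_a_constrained_position(self, energy):
        pair = one_row_pair()
        p1 = partial([(2, 8)], 1, 0.9, [0.4])
        p2 = partial([(1, 9)], 2, 0.9, [0.6])
        out = thermo_step2(pair, (p1, p2), energy, Params(evo=False))
        m = out.pair_rows[0].copy()
        for i, j in [(2, 8), (10, 18)]:
            m[i - 1, j - 1] = m[j - 1, i - 1] = 0.0
        for p in (2, 8, 10, 18):
            assert m[p - 1].sum() == 0.0

    def test_rescaled_never_exceed_raw(self, energy):
        pair = two_row_pair()
        p1 = partial([(2, 11)], 1, 0.7, [0.5, 0.6])
        p2 = empty_partial(2, 2)
        out = thermo_step2(pair, (p1, p2), energy, Params(evo=False))
        for s in range(2):
            fixedmask = np.zeros((24, 24), dtype=bool)
            fixedmask[1, 10] = fixedmask[10, 1] = True
            assert np.all(
                out.pair_rows[s][~fixedmask] <= out.raw_rows[s][~fixedmask] + 1e-12
            )
            assert all(q <= 1.0 for q in out.scales[s])


class TestEvoRescaling:
    def test_empty_partials_equal_plain_joint_posterior(self, models):
        pair = two_row_pair()
        tree = estimate_tree(concatenate(pair, "evo").to_alignment("N"))
        out = evo_step2(
            pair, (empty_partial(1, 2), empty_partial(2, 2)), tree, models, Params()
        )
        concat = concatenate(pair, "evo")
        post = inside_outside(concat, tree, models)
        keep = [concat.logical_to_physical(c) - 1 for c in range(1, 25)]
        assert np.abs(out.pair - post.pair_rel[np.ix_(keep, keep)]).max() < 1e-15

    def test_product_rescaling_and_fixed_rule(self, models):
        """Raw constrained posteriors are multiplied by both evolutionary
        scale factors; constrained pairs carry the fixed probability."""
        pair = two_row_pair()
        tree = estimate_tree(concatenate(pair, "evo").to_alignment("N"))
        p1 = partial([(2, 11)], 1, 0.9, [1.0, 1.0])
        p2 = partial([(1, 9)], 2, 0.42, [1.0, 1.0])
        out = evo_step2(pair, (p1, p2), tree, models, Params())
        concat = concatenate(pair, "evo")
        phys = frozenset(
            concat.logical_to_physical(p) for p in (2, 11, 13, 21)
        )
        post = inside_outside(
            concat, tree, models, StructureConstraint(forced_unpaired=phys)
        )
        keep = [concat.logical_to_physical(c) - 1 for c in range(1, 25)]
        raw = post.pair_rel[np.ix_(keep, keep)]
        scale = 0.9 * 0.42
        free = np.ones((24, 24), dtype=bool)
        for i, j in [(2, 11), (13, 21)]:
            free[i - 1, :] = free[:, i - 1] = False
            free[j - 1, :] = free[:, j - 1] = False
        assert np.abs(out.pair[free] - raw[free] * scale).max() < 1e-12
        assert out.pair[1, 10] == pytest.approx(0.9)       # sigma-1 fixed rule
        assert out.pair[12, 20] == pytest.approx(0.42)     # sigma-2 fixed rule
        assert out.ss[1] == 0.0 and out.ss[12] == 0.0


class TestCombineStep2:
    def test_beta_zero_keeps_evolutionary_component_only(self, models, energy):
        pair = two_row_pair()
        params = Params(beta=0.0, alpha=1.0)
        tree = estimate_tree(concatenate(pair, "evo").to_alignment("N"))
        partials = (empty_partial(1, 2), empty_partial(2, 2))
        ev = evo_step2(pair, partials, tree, models, params)
        th = thermo_step2(pair, partials, energy, params)
        out = combine_step2(ev, th, params, 12)
        assert np.abs(out.pair - ev.pair).max() < 1e-15

    def test_two_row_arithmetic_matches_hand_sum(self, models, energy):
        pair = two_row_pair()
        params = Params()
        tree = estimate_tree(concatenate(pair, "evo").to_alignment("N"))
        partials = (empty_partial(1, 2), empty_partial(2, 2))
        ev = evo_step2(pair, partials, tree, models, params)
        th = thermo_step2(pair, partials, energy, params)
        out = combine_step2(ev, th, params, 12)
        hand = ev.pair + (params.beta / 2) * (th.pair_rows[0] + th.pair_rows[1])
        assert np.abs(out.pair - hand).max() < 1e-15
        assert np.allclose(out.pair, out.pair.T)
        hand_ss = params.alpha * (
            ev.ss + (params.beta / 2) * (th.ss_rows[0] + th.ss_rows[1])
        )
        assert np.abs(out.ss - hand_ss).max() < 1e-15


class TestConsistencyReduction:
    def test_empty_partials_reduce_to_direct_concat_scoring(self, models, energy):
        """With nothing constrained the Step-2 pipeline must equal plain
        combined scoring of the concatenated alignment to 1e-12."""
        pair = two_row_pair()
        params = Params()
        tree = estimate_tree(concatenate(pair, "evo").to_alignment("N"))
        full = run_step2(
            pair, (empty_partial(1, 2), empty_partial(2, 2)),
            tree, models, energy, params,
        )
        direct = direct_concat_scoring(pair, tree, models, energy, params)
        assert np.abs(full.pair - direct.pair).max() <= 1e-12
        assert np.abs(full.ss - direct.ss).max() <= 1e-12
        # independently assembled reference: posterior + cofold + combination
        concat = concatenate(pair, "evo")
        post = inside_outside(concat, tree, models)
        keep = [concat.logical_to_physical(c) - 1 for c in range(1, 25)]
        ref_pair = post.pair_rel[np.ix_(keep, keep)].copy()
        for s in range(2):
            s1, s2 = pair.aln1.ungapped(s), pair.aln2.ungapped(s)
            res = cofold_partition(s1, s2, energy)
            n1 = len(s1)
            pos = []
            for c in range(1, 13):
                p = pair.aln1.col_to_seqpos(s, c)
                pos.append(int(p) if p else 0)
            for c in range(1, 13):
                p = pair.aln2.col_to_seqpos(s, c)
                pos.append(int(p) + n1 if p else 0)
            pos = np.array(pos)
            nz = pos > 0
            block = np.zeros((24, 24))
            block[np.ix_(nz, nz)] = res.pair_prob[np.ix_(pos[nz] - 1, pos[nz] - 1)]
            ref_pair += (params.beta / 2) * block
        assert np.abs(full.pair - ref_pair).max() <= 1e-12
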