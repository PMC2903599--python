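"""Partial-structure selection, the probability gate and stem extension."""

import math

import numpy as np
import pytest

from jointfold.msa_io import MultipleAlignment
from jointfold.params import Params
from jointfold.scoring import ReliabilityMatrix
from jointfold.step1 import PartialStructure, extend_stems, gate, select_partial


def rel_from_pairs(L, entries, beta=0.0):
    """Reliability matrix whose normalised values equal ``entries``."""
    pair = np.zeros((L, L))
    for (i, j), v in entries.items():
        pair[i - 1, j - 1] = pair[j - 1, i - 1] = v * (1.0 + beta)
    return ReliabilityMatrix(pair, np.zeros(L), beta=beta)


class ScriptedCtx:
    """Stand-in evaluation context returning hand-tuned probabilities."""

    def __init__(self, table, default=(1.0, (1.0,))):
        self.table = {frozenset(k): v for k, v in table.items()}
        self.default = default
        self.calls = 0

    def probabilities(self, pairs, part, delta):
        self.calls += 1
        ev, th = self.table.get(frozenset(pairs), self.default)
        return PartialStructure(frozenset(pairs), part, delta, ev, tuple(th))


class TestGate:
    def make(self, ev, th):
        return PartialStructure(frozenset(), 1, 0.9, ev, tuple(th))

    def test_empty_partial_passes_any_gamma(self):
        assert gate(self.make(1.0, (1.0,)), 1.0)

    def test_min_rule_fails_when_one_sequence_is_improbable(self):
        assert not gate(self.make(0.05, (0.5, 0.04)), 0.1)

    def test_passes_when_every_sequence_is_probable(self):
        assert gate(self.make(0.05, (0.5, 0.2)), 0.1)

    def test_evolutionary_model_alone_can_pass(self):
        assert gate(self.make(0.2, (0.01, 0.01)), 0.1)

    def test_mean_aggregation_flag(self):
        p = self.make(0.0, (0.3, 0.01))
        assert not gate(p, 0.1, "min")
        assert gate(p, 0.1, "mean")

    def test_monotone_in_gamma(self):
        p = self.make(0.05, (0.3, 0.2))
        assert gate(p, 0.1) and gate(p, 0.05)


class TestSelectPartial:
    def test_nothing_above_cutoff_gives_empty_partial(self):
        rel = rel_from_pairs(10, {(1, 8): 0.4, (2, 7): 0.3})
        ctx = ScriptedCtx({})
        params = Params(delta=0.6)
        got = select_partial(rel, None, None, None, params, ctx=ctx)
        assert got.pairs == frozenset()
        assert got.ev_prob == 1.0 and all(t == 1.0 for t in got.th_probs)
        assert ctx.calls == 1

    def test_selection_above_half_is_automatically_conflict_free(self, rng):
        """Pairs above 1/2 of a per-column unit-sum posterior never conflict."""
        from oracles import has_conflict, random_structure_mixture, select_above

        for _ in range(50):
            pair, _, _ = random_structure_mixture(12, rng)
            sel = select_above(pair, 0.51)
            assert not has_conflict(sel)

    def test_cutoff_adapts_until_gate_passes(self):
        """Scripted adaptation: the full selection fails the gate, the
        tighter one passes; iteration count respects the bound."""
        A, B = (1, 8), (2, 7)
        rel = rel_from_pairs(10, {A: 0.85, B: 0.65})
        ctx = ScriptedCtx({
            frozenset({A, B}): (0.05, (0.04,)),
            frozenset({A}): (0.5, (0.9,)),
        })
        params = Params(delta=0.6, gamma=0.1, delta_step=0.05)
        got = select_partial(rel, None, None, None, params, ctx=ctx)
        assert got.pairs == frozenset({A})
        assert got.delta_used == pytest.approx(0.65)
        assert ctx.calls <= math.ceil((1 - 0.5) / params.delta_step) + 1

    def test_adaptation_can_end_empty(self):
        A = (1, 8)
        rel = rel_from_pairs(10, {A: 0.9})
        ctx = ScriptedCtx({frozenset({A}): (0.0, (0.0,))})
        params = Params(delta=0.6, gamma=0.5)
        got = select_partial(rel, None, None, None, params, ctx=ctx)
        assert got.pairs == frozenset()

    def test_end_to_end_on_real_alignment(self, models, tree2):
        """Integration: a clean covarying helix is selected and the stored
        probabilities are genuine ensemble probabilities."""
        rows = ["GGCGCAAAAGCGCC", "GGUGCAAAAGCACC"]
        aln = MultipleAlignment(["t0", "t1"], rows)
        from jointfold.evoscfg import inside_outside
        from jointfold.scoring import combine_reliabilities
        from jointfold.step1 import _Ctx
        from jointfold.thermo import EnergyModel

        params = Params(delta=0.55, gamma=0.05)
        energy = EnergyModel()
        ctx = _Ctx(aln, tree2, models, energy, params)
        evo = inside_outside(aln, tree2, models, emissions=ctx.emissions)
        rel = combine_reliabilities(evo, ctx.thermo_bases, aln, params.beta, params.alpha)
        got = select_partial(rel, aln, tree2, models, params, energy, ctx=ctx)
        assert got.pairs  # the helix is reliable
        assert all(0.0 <= p <= 1.0 for p in (got.ev_prob, *got.th_probs))
        # invariants: non-crossing, disjoint, delta floor respected
        assert got.delta_used >= 0.5


class TestExtendStems:
    L = 12

    def base_partial(self):
        return PartialStructure(
            frozenset({(2, 9), (3, 8)}), 1, 0.6, 0.9, (0.9,)
        )

    def test_inner_then_outer_extension(self):
        rel = rel_from_pairs(
            self.L, {(2, 9): 0.8, (3, 8): 0.8, (4, 7): 0.7, (1, 10): 0.75}
        )
        ctx = ScriptedCtx({})
        got = extend_stems(
            self.base_partial(), rel, Params(delta=0.6), None, None, None, ctx=ctx
        )
        assert got.pairs == frozenset({(1, 10), (2, 9), (3, 8), (4, 7)})

    def test_low_average_reliability_stops_extension(self):
        rel = rel_from_pairs(self.L, {(2, 9): 0.65, (3, 8): 0.65, (4, 7): 0.1})
        got = extend_stems(
            self.base_partial(), rel, Params(delta=0.6), None, None, None,
            ctx=ScriptedCtx({}),
        )
        assert got.pairs == self.base_partial().pairs

    def test_gate_failure_stops_extension(self):
        rel = rel_from_pairs(self.L, {(2, 9): 0.8, (3, 8): 0.8, (4, 7): 0.9})
        ctx = ScriptedCtx(
            {frozenset({(2, 9), (3, 8), (4, 7)}): (0.01, (0.01,))}
        )
        got = extend_stems(
            self.base_partial(), rel, Params(delta=0.6, gamma=0.1),
            None, None, None, ctx=ctx,
        )
        assert got.pairs == self.base_partial().pairs

    def test_position_collision_blocks_candidate(self):
        partial = PartialStructure(
            frozenset({(2, 9), (3, 8), (10, 12)}), 1, 0.6, 0.9, (0.9,)
        )
        rel = rel_from_pairs(
            self.L, {(2, 9): 0.9, (3, 8): 0.9, (10, 12): 0.9, (1, 10): 0.95}
        )
        got = extend_stems(
            partial, rel, Params(delta=0.6), None, None, None, ctx=ScriptedCtx({})
        )
        assert (1, 10) not in got.pairs

    def test_empty_partial_unchanged(self):
        empty = PartialStructure(frozenset(), 1, 0.6, 1.0, (1.0,))
        rel = rel_from_pairs(self.L, {})
        got = extend_stems(
            empty, rel, Params(), None, None, None, ctx=ScriptedCtx({})
        )
        assert got is empty

    def test_never_removes_pairs_and_keeps_gate(self):
        rel = rel_from_pairs(
            self.L, {(2, 9): 0.8, (3, 8): 0.8, (4, 7): 0.7, (1, 10): 0.75}
        )
        params = Params(delta=0.6, gamma=0.1)
        ctx = ScriptedCtx({}, default=(0.5, (0.5,)))
        base = self.base_partial()
        got = extend_stems(base, rel, params, None, None, None, ctx=ctx)
        assert base.pairs <= got.pairs
        assert gate(got, params.gamma, params.gamma_agg)
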