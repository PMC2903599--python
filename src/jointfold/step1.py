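"""Step 1: reliable, conflict-free intra-molecular partial structures.

For each of the two alignments, base pairs whose combined reliability
(normalised to [0, 1] by 1 + beta) exceeds the cutoff ``delta`` are
selected.  Because per-column reliability mass sums to at most one on the
normalised scale, any cutoff >= 1/2 makes the selected set automatically
free of position conflicts and crossings.

The cutoff is then adapted: if the ensemble of structures compatible with
the selection is not probable enough — probability >= ``gamma`` in the
evolutionary model or in (each of) the thermodynamic ensembles — the
cutoff is raised by ``delta_step`` and the selection repeated, until the
gate passes or the selection is empty.

Finally the constrained stems are extended: because Step 2 pins these
positions single-stranded, truncated helices would destabilise the
cofolding ensemble, so inner and outer pairs are appended while the
average normalised reliability of the extended stem stays above the cutoff
and the gate keeps passing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .evoscfg import (
    EmissionTable,
    StructureConstraint,
    compute_emissions,
    evo_ensemble_prob,
    inside_outside,
    pairs_conflict,
)
from .msa_io import MultipleAlignment
from .params import ParameterSet, Params
from .phylo import PhyloTree
from .scoring import ReliabilityMatrix
from .thermo import (
    EnergyModel,
    ThermoResult,
    legal_projected_pairs,
    map_consensus_to_seq,
    partition,
    thermo_ensemble_prob,
)

log = logging.getLogger(__name__)


@dataclass
class PartialStructure:
    """The conflict-free partial structure of one part, with its probabilities.

    ``pairs`` are consensus column pairs (1-based, part-local);
    ``ev_prob`` is the evolutionary ensemble probability of the partial
    structure and ``th_probs`` the per-sequence thermodynamic ensemble
    probabilities of its per-row projections.
    """

    pairs: frozenset
    part: int
    delta_used: float
    ev_prob: float
    th_probs: tuple
    #: per-row projected (legal) pair sets in ungapped sequence coordinates
    seq_pairs: tuple = ()

    def __post_init__(self):
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                if pairs_conflict(plist[a], plist[b]):
                    raise ValueError(
                        f"partial structure pairs {plist[a]} / {plist[b]} conflict"
                    )
        if self.delta_used < 0.5:
            raise ValueError("delta_used must be >= 0.5")
        probs = [self.ev_prob, *self.th_probs]
        if any(not (0.0 <= p <= 1.0 + 1e-9) for p in probs):
            raise ValueError("ensemble probabilities must lie in [0, 1]")

    @property
    def positions(self) -> frozenset:
        return frozenset(p for ij in self.pairs for p in ij)


def gate(partial: PartialStructure, gamma: float, agg: str = "min") -> bool:
    """True when the partial structure's ensemble is probable enough.

    Passes when the evolutionary ensemble probability reaches ``gamma`` OR
    the aggregated per-sequence thermodynamic ensemble probabilities do
    (strict reading: every sequence must be probable, ``agg='min'``).
    """
    if partial.ev_prob >= gamma:
        return True
    if not partial.th_probs:
        return False
    th = (
        min(partial.th_probs)
        if agg == "min"
        else sum(partial.th_probs) / len(partial.th_probs)
    )
    return th >= gamma


@dataclass
class _Ctx:
    """Cached per-part state reused across delta-adaptation rounds."""

    aln: MultipleAlignment
    tree: PhyloTree | None
    models: ParameterSet | None
    energy: EnergyModel
    params: Params
    emissions: EmissionTable | None = None
    base_loglik: float | None = None
    thermo_bases: list[ThermoResult] | None = None

    def __post_init__(self):
        if self.params.evo and self.emissions is None:
            self.emissions = compute_emissions(self.aln, self.tree, self.models)
        if self.params.evo and self.base_loglik is None:
            self.base_loglik = inside_outside(
                self.aln, self.tree, self.models, emissions=self.emissions
            ).loglik
        if self.thermo_bases is None:
            self.thermo_bases = [
                partition(self.aln.ungapped(s), self.energy)
                for s in range(self.aln.n_seqs)
            ]

    def probabilities(self, pairs: frozenset, part: int, delta: float) -> PartialStructure:
        if self.params.evo:
            ev = evo_ensemble_prob(
                self.aln, self.tree, self.models, pairs,
                emissions=self.emissions, unconstrained_loglik=self.base_loglik,
            )
        else:
            ev = 0.0 if pairs else 1.0
        th = []
        seq_pairs = []
        for s in range(self.aln.n_seqs):
            proj = map_consensus_to_seq(pairs, self.aln, s)
            legal = legal_projected_pairs(proj, self.aln.ungapped(s), self.energy)
            seq_pairs.append(legal)
            th.append(
                thermo_ensemble_prob(
                    self.aln.ungapped(s), self.energy, legal,
                    base=self.thermo_bases[s],
                )
            )
        return PartialStructure(
            pairs, part, delta, ev, tuple(th), tuple(seq_pairs)
        )


def select_partial(
    rel: ReliabilityMatrix,
    aln: MultipleAlignment,
    tree: PhyloTree | None,
    models: ParameterSet | None,
    params: Params,
    energy: EnergyModel | None = None,
    part: int = 1,
    ctx: _Ctx | None = None,
) -> PartialStructure:
    """Select the reliable partial structure of one part, adapting the cutoff."""
    energy = energy or EnergyModel(allow_isolated=params.allow_isolated)
    ctx = ctx or _Ctx(aln, tree, models, energy, params)
    norm = rel.normalised_pair()
    delta = params.delta_init
    L = rel.length
    iu, ju = np.triu_indices(L, k=1)
    while True:
        sel = frozenset(
            (int(i) + 1, int(j) + 1)
            for i, j in zip(iu[norm[iu, ju] > delta], ju[norm[iu, ju] > delta])
        )
        partial = ctx.probabilities(sel, part, max(delta, 0.5))
        if not sel or gate(partial, params.gamma, params.gamma_agg):
            log.info(
                "part %d: selected %d pairs at delta=%.3f (ev=%.3g, th_min=%.3g)",
                part, len(sel), delta, partial.ev_prob,
                min(partial.th_probs) if partial.th_probs else float("nan"),
            )
            return partial
        delta = round(delta + params.delta_step, 10)
        if delta >= 1.0 + params.delta_step:
            return ctx.probabilities(frozenset(), part, 1.0)


def _helices(pairs: frozenset) -> list[list[tuple[int, int]]]:
    """Maximal helices (runs of stacked pairs), 5' to 3' by outer pair."""
    ps = set(pairs)
    out = []
    seen = set()
    for p in sorted(ps):
        if p in seen:
            continue
        i, j = p
        if (i - 1, j + 1) in ps:
            continue  # not outermost
        h = [(i, j)]
        seen.add(p)
        while (i + 1, j - 1) in ps:
            i, j = i + 1, j - 1
            h.append((i, j))
            seen.add((i, j))
        out.append(h)
    return out


def extend_stems(
    partial: PartialStructure,
    rel: ReliabilityMatrix,
    params: Params,
    aln: MultipleAlignment,
    tree: PhyloTree | None,
    models: ParameterSet | None,
    energy: EnergyModel | None = None,
    ctx: _Ctx | None = None,
) -> PartialStructure:
    """Extend each constrained stem by inner, then outer, base pairs.

    A candidate pair is accepted if the average normalised reliability of
    the extended stem stays above the cutoff used in selection, the gamma
    gate still passes with the pair added, and no position conflict or
    crossing arises.  The gate is re-evaluated after every single added
    pair.  Helices are processed 5' to 3'; never removes a pair.
    """
    if not partial.pairs:
        return partial
    energy = energy or EnergyModel(allow_isolated=params.allow_isolated)
    ctx = ctx or _Ctx(aln, tree, models, energy, params)
    norm = rel.normalised_pair()
    L = rel.length
    current = partial

    def conflict_free(cand, pairs):
        return not any(pairs_conflict(cand, p) for p in pairs)

    def try_add(cand, stem):
        nonlocal current
        i, j = cand
        if not (1 <= i < j <= L):
            return False
        if not conflict_free(cand, current.pairs):
            return False
        avg = float(np.mean([norm[a - 1, b - 1] for a, b in stem + [cand]]))
        if not avg > current.delta_used:
            return False
        trial = ctx.probabilities(
            current.pairs | {cand}, current.part, current.delta_used
        )
        if not gate(trial, params.gamma, params.gamma_agg):
            return False
        current = trial
        return True

    for helix in _helices(partial.pairs):
        stem = list(helix)
        # inner extensions
        a, b = stem[-1]
        while b - a > 2:
            if not try_add((a + 1, b - 1), stem):
                break
            stem.append((a + 1, b - 1))
            a, b = a + 1, b - 1
        # outer extensions
        a, b = stem[0]
        while a > 1 and b < L:
            if not try_add((a - 1, b + 1), stem):
                break
            stem.insert(0, (a - 1, b + 1))
            a, b = a - 1, b + 1
    if current.pairs != partial.pairs:
        log.info(
            "part %d: stems extended from %d to %d pairs",
            partial.part, len(partial.pairs), len(current.pairs),
        )
    return current
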