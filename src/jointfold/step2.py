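"""Step 2: constrained expected-accuracy scoring of the concatenation.

The partial structures fixed in Step 1 are constrained single-stranded and
each row's concatenated sequence is cofolded under that constraint, which
selects exactly the structures nested on the remaining positions and
compatible with the partial structures — the hierarchical trick that
admits pseudoknots between the constrained layer and the new layer.

Raw constrained probabilities are conditional on the partial structures,
so they are rescaled by the ensemble probabilities of the two partial
structures (per model, and per sequence in the thermodynamic part); the
partial-structure pairs themselves are scored with their fixed ensemble
probability rather than a competing cofold probability.  The evolutionary
part runs the constrained phylo-SCFG on the concatenated alignment with
three prior-free linker columns and a tree estimated from the concatenated
alignment, and is rescaled the same way.

All outputs are on the logical coordinates of the concatenation
(1..L1+L2, linker excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evoscfg import StructureConstraint, inside_outside
from .msa_io import AlignmentPair, ConcatenatedAlignment, concatenate
from .params import ParameterSet, Params
from .phylo import PhyloTree
from .step1 import PartialStructure
from .thermo import CofoldConstraint, EnergyModel, cofold_partition

log = logging.getLogger(__name__)


def global_partial_pairs(p1: PartialStructure, p2: PartialStructure, L1: int):
    """Partial pairs of both parts in logical concatenated coordinates."""
    out = {(i, j): 1 for i, j in p1.pairs}
    out.update({(i + L1, j + L1): 2 for i, j in p2.pairs})
    return out


@dataclass
class ThermoStep2:
    """Per-row rescaled thermodynamic probabilities on logical coordinates."""

    pair_rows: list          # list of (Lc, Lc) arrays
    ss_rows: list            # list of (Lc,) arrays
    raw_rows: list           # unrescaled cofold matrices (audit)
    scales: list             # (q1_s, q2_s) per row


def thermo_step2(
    pair_aln: AlignmentPair,
    partials: tuple[PartialStructure, PartialStructure],
    model: EnergyModel,
    params: Params,
) -> ThermoStep2:
    """Constrained cofolding of every row, rescaled to joint probabilities.

    For each row: project the partial structures, force their positions
    single-stranded, cofold, then (a) give partial-structure pairs their
    fixed per-sequence ensemble probability from Step 1 (or 1 in the
    simplified scoring mode) and (b) multiply all other pair probabilities
    by both per-sequence ensemble probabilities.  A row where a projection
    was illegal everywhere simply carries scale 0 and is flagged.
    """
    p1, p2 = partials
    aln1, aln2 = pair_aln.aln1, pair_aln.aln2
    L1, L2 = aln1.length, aln2.length
    Lc = L1 + L2
    fixed = global_partial_pairs(p1, p2, L1)
    pair_rows, ss_rows, raw_rows, scales = [], [], [], []
    for s in range(pair_aln.n_seqs):
        s1, s2 = aln1.ungapped(s), aln2.ungapped(s)
        n1 = len(s1)
        forced = set()
        for i, j in p1.seq_pairs[s]:
            forced.update((i, j))
        for i, j in p2.seq_pairs[s]:
            forced.update((i + n1, j + n1))
        res = cofold_partition(
            s1, s2, model, CofoldConstraint(forced_unpaired=frozenset(forced))
        )
        q1s, q2s = p1.th_probs[s], p2.th_probs[s]
        if q1s == 0.0 or q2s == 0.0:
            log.warning("row %d: a partial-structure projection has zero "
                        "ensemble probability; its scale factor is 0", s)
        # map raw ungapped-concatenation probabilities to logical columns
        pos = np.zeros(Lc, dtype=int)
        for c in range(1, L1 + 1):
            p = aln1.col_to_seqpos(s, c)
            pos[c - 1] = int(p) if p else 0
        for c in range(1, L2 + 1):
            p = aln2.col_to_seqpos(s, c)
            pos[L1 + c - 1] = int(p) + n1 if p else 0
        nz = pos > 0
        idx = pos[nz] - 1
        raw = np.zeros((Lc, Lc))
        raw[np.ix_(nz, nz)] = res.pair_prob[np.ix_(idx, idx)]
        raw_unp = np.ones(Lc)
        raw_unp[nz] = res.unpaired_prob[idx]

        scale = q1s * q2s
        pair = raw * scale
        ss = raw_unp * scale
        ss[~nz] = 1.0  # gapped columns carry no evidence for this row
        for (i, j), part in fixed.items():
            q = (p1.th_probs[s] if part == 1 else p2.th_probs[s])
            v = 1.0 if params.eq15_mode else q
            pair[i - 1, j - 1] = pair[j - 1, i - 1] = v
            ss[i - 1] = ss[j - 1] = 0.0
        pair_rows.append(pair)
        ss_rows.append(ss)
        raw_rows.append(raw)
        scales.append((q1s, q2s))
    return ThermoStep2(pair_rows, ss_rows, raw_rows, scales)


@dataclass
class EvoStep2:
    pair: np.ndarray
    ss: np.ndarray
    raw_pair: np.ndarray
    raw_ss: np.ndarray
    scales: tuple


def evo_step2(
    pair_aln: AlignmentPair,
    partials: tuple[PartialStructure, PartialStructure],
    tree_joint: PhyloTree,
    models: ParameterSet,
    params: Params,
) -> EvoStep2:
    """Constrained phylo-SCFG posterior on the concatenated alignment.

    The partial-structure positions are forced unpaired, the linker is
    three prior-free columns, and raw posteriors are rescaled by the
    product of the two evolutionary ensemble probabilities from Step 1.
    """
    p1, p2 = partials
    concat = concatenate(pair_aln, "evo")
    L1, Lc = concat.L1, concat.logical_length
    fixed = global_partial_pairs(p1, p2, L1)
    forced_logical = set(p for ij in fixed for p in ij)
    forced_phys = frozenset(concat.logical_to_physical(p) for p in forced_logical)
    post = inside_outside(
        concat, tree_joint, models,
        StructureConstraint(forced_unpaired=forced_phys),
    )
    keep = np.array(
        [concat.logical_to_physical(c) - 1 for c in range(1, Lc + 1)], dtype=int
    )
    raw_pair = post.pair_rel[np.ix_(keep, keep)]
    raw_ss = post.ss_rel[keep]
    scale = p1.ev_prob * p2.ev_prob
    pair = raw_pair * scale
    ss = raw_ss * scale
    for (i, j), part in fixed.items():
        q = p1.ev_prob if part == 1 else p2.ev_prob
        v = 1.0 if params.eq15_mode else q
        pair[i - 1, j - 1] = pair[j - 1, i - 1] = v
        ss[i - 1] = ss[j - 1] = 0.0
    return EvoStep2(pair, ss, raw_pair, raw_ss, (p1.ev_prob, p2.ev_prob))


@dataclass
class Step2Reliabilities:
    """Combined Step-2 reliabilities over logical concatenated coordinates."""

    pair: np.ndarray
    ss: np.ndarray
    evo: EvoStep2 | None
    thermo: ThermoStep2
    L1: int
    beta: float
    alpha: float


def combine_step2(
    evo_out: EvoStep2 | None,
    thermo_out: ThermoStep2,
    params: Params,
    L1: int,
) -> Step2Reliabilities:
    """Mirror of the Step-1 combination on the Step-2 components."""
    n = len(thermo_out.pair_rows)
    Lc = thermo_out.pair_rows[0].shape[0]
    pair = np.zeros((Lc, Lc))
    ss = np.zeros(Lc)
    if evo_out is not None:
        if evo_out.pair.shape != (Lc, Lc):
            raise ValueError("evolutionary and thermodynamic dimensions differ")
        pair += evo_out.pair
        ss += evo_out.ss
    pair += (params.beta / n) * sum(thermo_out.pair_rows)
    ss = params.alpha * (ss + (params.beta / n) * sum(thermo_out.ss_rows))
    return Step2Reliabilities(
        pair, ss, evo_out, thermo_out, L1, params.beta, params.alpha
    )


def run_step2(
    pair_aln: AlignmentPair,
    partials: tuple[PartialStructure, PartialStructure],
    tree_joint: PhyloTree | None,
    models: ParameterSet | None,
    model: EnergyModel,
    params: Params,
) -> Step2Reliabilities:
    th = thermo_step2(pair_aln, partials, model, params)
    ev = (
        evo_step2(pair_aln, partials, tree_joint, models, params)
        if params.evo
        else None
    )
    return combine_step2(ev, th, params, pair_aln.aln1.length)


def empty_partial(part: int, n_seqs: int) -> PartialStructure:
    """The trivial partial structure (all ensemble probabilities 1)."""
    return PartialStructure(
        frozenset(), part, 0.5, 1.0, tuple([1.0] * n_seqs),
        tuple([frozenset()] * n_seqs),
    )


def direct_concat_scoring(
    pair_aln: AlignmentPair,
    tree_joint: PhyloTree | None,
    models: ParameterSet | None,
    model: EnergyModel,
    params: Params,
) -> Step2Reliabilities:
    """Unconstrained scoring of the concatenated alignment.

    With empty partial structures every scale factor is 1 and no pair is
    fixed, so this is the plain combined scoring of the concatenation; the
    constrained Step-2 machinery reduces to it exactly.
    """
    n = pair_aln.n_seqs
    return run_step2(
        pair_aln, (empty_partial(1, n), empty_partial(2, n)),
        tree_joint, models, model, params,
    )
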