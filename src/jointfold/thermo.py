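"""Per-sequence thermodynamic ensembles with structure constraints.

The energy model is a simplified nearest-neighbour model authored for this
package: stacking energies for the six canonical pair steps and affine
hairpin / interior-bulge / multiloop penalties in loop size.  It defines a
Boltzmann ensemble over nested structures — including the cofolding
ensemble of two concatenated strands, where any loop containing the strand
nick is scored as an exterior-like region and inter-molecular pairs are
exempt from the minimum hairpin size.  No dangling-end terms are defined.

The quantities exposed here are ensemble probabilities and base-pair
probability matrices; free energies are reported as -RT log Z in the
model's kcal/mol scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._thermo_kernels import cofold_inside_outside

log = logging.getLogger(__name__)

_NT = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIR_TYPES = {
    ("A", "U"): 0, ("U", "A"): 1, ("G", "C"): 2,
    ("C", "G"): 3, ("G", "U"): 4, ("U", "G"): 5,
}
#: per-pair stacking "strength" used to build the default symmetric table
_STRENGTH = {0: 0.9, 1: 0.9, 2: 1.5, 3: 1.5, 4: 0.6, 5: 0.6}


def default_stack_table() -> np.ndarray:
    """Stacking energies (kcal/mol, negative) for outer-over-inner pair steps."""
    t = np.zeros((6, 6))
    for a in range(6):
        for b in range(6):
            t[a, b] = -(_STRENGTH[a] + _STRENGTH[b])
    return t


@dataclass
class EnergyModel:
    """Simplified nearest-neighbour energy model.

    stack[a, b]      : stacking energy of pair-type a over pair-type b
    hairpin_a/_b     : hairpin penalty  a + b * loop_size   (size >= min_hairpin)
    interior_a/_b    : interior/bulge penalty  a + b * total_unpaired
    multi_a/_b/_c    : multiloop penalty  a + b * branches + c * unpaired
    max_interior     : cap on total unpaired in an interior loop (model choice)
    rt               : RT in kcal/mol (default 310.15 K)
    """

    stack: np.ndarray = field(default_factory=default_stack_table)
    hairpin_a: float = 4.0
    hairpin_b: float = 0.2
    interior_a: float = 1.6
    interior_b: float = 0.4
    multi_a: float = 3.4
    multi_b: float = 0.4
    multi_c: float = 0.1
    min_hairpin: int = 3
    max_interior: int = 30
    rt: float = 0.61633
    allow_isolated: bool = True

    def boltz(self, e: float) -> float:
        return float(np.exp(-e / self.rt))

    def weights(self, n: int):
        whp = np.zeros(n + 2)
        for u in range(self.min_hairpin, n + 2):
            whp[u] = self.boltz(self.hairpin_a + self.hairpin_b * u)
        wip = np.zeros(self.max_interior + 1)
        for u in range(1, self.max_interior + 1):
            wip[u] = self.boltz(self.interior_a + self.interior_b * u)
        wst = np.exp(-self.stack / self.rt)
        wa = self.boltz(self.multi_a)
        wb = self.boltz(self.multi_b)
        wc = self.boltz(self.multi_c)
        return wst, whp, wip, wa, wb, wc


@dataclass
class ThermoResult:
    """Partition function result on one sequence (or concatenation)."""

    logZ: float
    pair_prob: np.ndarray     # (n, n) symmetric
    unpaired_prob: np.ndarray
    rt: float
    nick: int | None = None   # 0-based start of strand 2, None for one strand

    @property
    def ensemble_free_energy(self) -> float:
        return -self.rt * self.logZ

    @property
    def feasible(self) -> bool:
        return np.isfinite(self.logZ)


@dataclass
class CofoldConstraint:
    """Constraints for (co)folding, 1-based sequence positions.

    ``forced_unpaired`` positions may not pair (used for the Step-1 partial
    structure in the cofolding stage); ``forced_pairs`` must be present
    (used for ensemble probabilities of partial structures).
    """

    forced_unpaired: frozenset = frozenset()
    forced_pairs: frozenset = frozenset()


def encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("T", "U")
    return np.array([_NT.get(ch, 4) for ch in seq], dtype=np.int8)


def _masks(seq: str, n: int, nick: int, constraint: CofoldConstraint, model: EnergyModel):
    enc = encode(seq)
    can = np.zeros((n, n), dtype=np.uint8)
    pt = np.full((n, n), -1, dtype=np.int8)
    cu = np.ones(n)
    partner = np.full(n, -1, dtype=int)
    for i, j in constraint.forced_pairs:
        if not (1 <= i < j <= n):
            raise ValueError(f"forced pair ({i}, {j}) out of range")
        partner[i - 1], partner[j - 1] = j - 1, i - 1
        cu[i - 1] = cu[j - 1] = 0.0
    no_pair = np.zeros(n, dtype=bool)
    for i in constraint.forced_unpaired:
        no_pair[i - 1] = True
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seq[i], seq[j]
            key = (a, b)
            if key not in _PAIR_TYPES:
                continue
            if no_pair[i] or no_pair[j]:
                continue
            if partner[i] >= 0 or partner[j] >= 0:
                if partner[i] != j:
                    continue
            spans_nick = nick >= 0 and i < nick <= j
            if not spans_nick and j - i - 1 < model.min_hairpin:
                continue
            can[i, j] = 1
            pt[i, j] = _PAIR_TYPES[key]
    return can, pt, cu


def _run(seq: str, nick: int, model: EnergyModel, constraint: CofoldConstraint) -> ThermoResult:
    n = len(seq)
    if n < 1:
        raise ValueError("empty sequence")
    can, pt, cu = _masks(seq, n, nick, constraint, model)
    wst, whp, wip, wa, wb, wc = model.weights(n)
    Z, P, Punp = cofold_inside_outside(
        n, nick, can, pt, cu, wst, whp, wip, wa, wb, wc,
        model.max_interior, not model.allow_isolated,
    )
    if Z <= 0.0 or not np.isfinite(Z):
        return ThermoResult(-np.inf, np.zeros((n, n)), np.zeros(n), model.rt,
                            nick if nick >= 0 else None)
    P = P + P.T
    return ThermoResult(float(np.log(Z)), P, Punp, model.rt,
                        nick if nick >= 0 else None)


def partition(
    seq: str, model: EnergyModel | None = None,
    constraint: CofoldConstraint | None = None,
) -> ThermoResult:
    """Partition function and pair probabilities of a single RNA sequence."""
    model = model or EnergyModel()
    constraint = constraint or CofoldConstraint()
    return _run(seq.upper().replace("T", "U"), -1, model, constraint)


def cofold_partition(
    s1: str, s2: str, model: EnergyModel | None = None,
    constraint: CofoldConstraint | None = None,
) -> ThermoResult:
    """Cofolding partition function of ``s1 & s2``.

    Positions of ``s2`` continue the numbering of ``s1`` (constraint
    positions len(s1)+1 .. len(s1)+len(s2) refer to the second strand).
    The returned matrices are over the concatenation without a physical
    linker column; ``ThermoResult.nick`` records the cut point.
    """
    model = model or EnergyModel()
    constraint = constraint or CofoldConstraint()
    seq = (s1 + s2).upper().replace("T", "U")
    return _run(seq, len(s1), model, constraint)


def thermo_ensemble_prob(
    seq: str, model: EnergyModel | None = None, partial_on_seq=frozenset(),
    base: ThermoResult | None = None,
) -> float:
    """Probability mass of all structures containing the given pairs.

    Z(constrained to contain the pairs) / Z; pairs that are non-canonical
    in this sequence (possible after projecting consensus pairs through
    gaps) make the ensemble empty and yield 0, with a logged notice.
    """
    model = model or EnergyModel()
    pairs = frozenset((int(i), int(j)) for i, j in partial_on_seq)
    if not pairs:
        return 1.0
    seq = seq.upper().replace("T", "U")
    for i, j in pairs:
        if (seq[i - 1], seq[j - 1]) not in _PAIR_TYPES:
            log.info("pair (%d, %d) = %s%s is non-canonical; ensemble empty",
                     i, j, seq[i - 1], seq[j - 1])
            return 0.0
    if base is None:
        base = partition(seq, model)
    con = partition(seq, model, CofoldConstraint(forced_pairs=pairs))
    if not con.feasible:
        return 0.0
    return float(np.exp(con.logZ - base.logZ))


def dump_pair_probs(res: ThermoResult, fh, threshold: float = 1e-6) -> None:
    """Write `i j probability` lines (1-based) for debugging/audit."""
    n = res.pair_prob.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            p = res.pair_prob[i, j]
            if p >= threshold:
                fh.write(f"{i + 1} {j + 1} {p:.9f}\n")


def map_consensus_to_seq(partial_pairs, aln, seq_index: int) -> frozenset:
    """Project consensus column pairs onto one row's ungapped coordinates.

    Pairs with a gapped end in this row are dropped; non-canonical
    projected pairs are kept here and rejected (with probability 0) by the
    ensemble computation, or dropped by callers that need a legal set.
    """
    out = set()
    for i, j in partial_pairs:
        pi = aln.col_to_seqpos(seq_index, i)
        pj = aln.col_to_seqpos(seq_index, j)
        if not pi or not pj:
            continue
        out.add((int(pi), int(pj)))
    return frozenset(out)


def legal_projected_pairs(pairs, seq: str, model: EnergyModel | None = None) -> frozenset:
    """Drop projected pairs that are non-canonical in this sequence."""
    seq = seq.upper().replace("T", "U")
    keep = set()
    for i, j in pairs:
        if (seq[i - 1], seq[j - 1]) in _PAIR_TYPES:
            keep.add((i, j))
        else:
            log.info("dropping non-canonical projected pair (%d, %d)", i, j)
    return frozenset(keep)
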