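"""Phylo-SCFG posteriors over consensus structures, with constraints.

The evolutionary model combines the lightweight structure grammar with
column emissions computed by Felsenstein pruning on a phylogenetic tree:
single columns under a 4-state model, base-paired column pairs under a
16-state model.  Inside-outside gives per-column posterior reliabilities
of base pairs and single-strandedness, and constrained variants give the
ensemble probability of a partial structure (the probability mass of all
consensus structures extending it).

All probabilities are over parse trees, as in the original formulation of
the model; the grammar is ambiguous for some structures, so a structure's
probability is the summed probability of its parse trees.

Coordinates in constraints and posteriors are 1-based alignment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._scfg_kernels import scfg_inside, scfg_outside
from .msa_io import ConcatenatedAlignment, MultipleAlignment
from .params import Grammar, ParameterSet
from .phylo import PhyloTree, column_logliks, paircol_logliks

log = logging.getLogger(__name__)

#: minimum enclosed columns of a consensus pair implied by the grammar
#: (L -> dFd where F derives at least two symbols)
MIN_PAIR_SPAN = 3


class ConstraintError(ValueError):
    pass


def pairs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((tuple(p), tuple(q)))
    return i < k < j < l


def pairs_conflict(p, q) -> bool:
    """Two pairs conflict if they share a position or cross."""
    return bool(set(p) & set(q)) or pairs_cross(p, q)


@dataclass
class StructureConstraint:
    """Constraints on the consensus structure.

    ``forced_pairs`` must be present, mutually non-crossing and
    position-disjoint; ``forced_unpaired`` positions may not pair;
    ``prior_free`` columns (the evolutionary linker) are unpaired with unit
    emission and contribute no production-probability factor.
    """

    forced_pairs: frozenset = frozenset()
    forced_unpaired: frozenset = frozenset()
    prior_free: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "forced_pairs",
                           frozenset((int(i), int(j)) for i, j in self.forced_pairs))
        object.__setattr__(self, "forced_unpaired",
                           frozenset(int(i) for i in self.forced_unpaired))
        object.__setattr__(self, "prior_free",
                           frozenset(int(i) for i in self.prior_free))
        seen: set[int] = set()
        plist = sorted(self.forced_pairs)
        for i, j in plist:
            if not i < j:
                raise ConstraintError(f"pair ({i}, {j}) must satisfy i < j")
            if i in seen or j in seen:
                raise ConstraintError(f"position reused in forced pairs at ({i}, {j})")
            seen.update((i, j))
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                if pairs_cross(plist[a], plist[b]):
                    raise ConstraintError(
                        f"forced pairs {plist[a]} and {plist[b]} cross"
                    )
        if seen & self.forced_unpaired:
            raise ConstraintError("forced pairs overlap forced-unpaired positions")
        if seen & self.prior_free:
            raise ConstraintError("forced pairs overlap prior-free columns")


@dataclass
class EvoPosterior:
    """Posterior reliabilities from the constrained phylo-SCFG.

    ``pair_rel[i-1, j-1]`` is the posterior probability that columns (i, j)
    are base-paired, ``ss_rel[i-1]`` that column i is single-stranded, and
    ``loglik`` the log of the (constrained) total parse-tree probability
    mass Pr[alignment, constraint | T, M].  ``feasible`` is False when the
    constraints admit no parse.
    """

    pair_rel: np.ndarray
    ss_rel: np.ndarray
    loglik: float
    feasible: bool = True


@dataclass
class EmissionTable:
    """Cached pruning likelihoods for one (alignment, tree, models) triple."""

    es_log: np.ndarray        # (L,) log-likelihood of each column unpaired
    ep_log: np.ndarray        # (L, L) log-likelihood of column pairs (i < j)

    @property
    def length(self) -> int:
        return self.es_log.shape[0]


def compute_emissions(
    aln: MultipleAlignment, tree: PhyloTree, models: ParameterSet
) -> EmissionTable:
    """Pruning log-likelihoods for all single columns and column pairs."""
    L = aln.length
    es = column_logliks(tree, models.single_model, aln)
    pairs = np.array(
        [(i, j) for i in range(L) for j in range(i + MIN_PAIR_SPAN, L)], dtype=int
    ).reshape(-1, 2)
    ep = np.full((L, L), -np.inf)
    if len(pairs):
        vals = paircol_logliks(tree, models.pair_model, aln, pairs)
        ep[pairs[:, 0], pairs[:, 1]] = vals
    return EmissionTable(es, ep)


def _as_alignment(aln) -> tuple[MultipleAlignment, frozenset]:
    """Return a plain alignment plus the prior-free physical columns."""
    if isinstance(aln, ConcatenatedAlignment):
        plain = MultipleAlignment(
            [a if a == b else f"{a}&{b}" for a, b in aln.parent.taxon_map],
            aln.physical_rows(linker_char="-"),
        )
        return plain, frozenset(aln.prior_free_physical())
    return aln, frozenset()


def inside_outside(
    aln,
    tree: PhyloTree,
    models: ParameterSet,
    constraint: StructureConstraint | None = None,
    emissions: EmissionTable | None = None,
    grammar: Grammar | None = None,
) -> EvoPosterior:
    """Constrained inside-outside posteriors for an alignment.

    ``aln`` may be a :class:`MultipleAlignment` or a
    :class:`ConcatenatedAlignment` (whose linker columns are added to the
    constraint's prior-free set).  Emissions can be precomputed with
    :func:`compute_emissions` and reused across constraint variants.
    """
    plain, linker_free = _as_alignment(aln)
    constraint = constraint or StructureConstraint()
    if linker_free:
        constraint = StructureConstraint(
            constraint.forced_pairs,
            constraint.forced_unpaired,
            constraint.prior_free | linker_free,
        )
    if tree.taxa != plain.taxon_ids:
        raise ValueError("tree leaves do not match alignment taxa")
    if emissions is None:
        emissions = compute_emissions(plain, tree, models)
    g = grammar or models.grammar
    L = emissions.length
    for i, j in constraint.forced_pairs:
        if not (1 <= i < j <= L):
            raise ConstraintError(f"forced pair ({i}, {j}) out of range 1..{L}")

    # per-column scaling by the single-column emission keeps values in range
    t_log = emissions.es_log.copy()
    pf = np.zeros(L, dtype=bool)
    for i in constraint.prior_free:
        pf[i - 1] = True
    t_log[pf] = 0.0
    if np.any(np.isneginf(t_log)):
        # a column with zero likelihood makes the whole alignment impossible
        return EvoPosterior(np.zeros((L, L)), np.zeros(L), -np.inf, feasible=False)

    must_pair = np.zeros(L, dtype=bool)
    partner = np.full(L, -1, dtype=int)
    for i, j in constraint.forced_pairs:
        must_pair[i - 1] = must_pair[j - 1] = True
        partner[i - 1], partner[j - 1] = j - 1, i - 1
    no_pair = np.zeros(L, dtype=bool)
    for i in constraint.forced_unpaired:
        no_pair[i - 1] = True
    no_pair |= pf

    u = np.where(pf, 1.0, g.L_s)
    u[must_pair] = 0.0

    ep = np.zeros((L, L))
    iu, ju = np.triu_indices(L, k=MIN_PAIR_SPAN)
    with np.errstate(over="ignore"):
        vals = np.exp(emissions.ep_log[iu, ju] - t_log[iu] - t_log[ju])
    ok = ~(no_pair[iu] | no_pair[ju])
    restricted = (partner[iu] >= 0) | (partner[ju] >= 0)
    ok &= ~restricted | (partner[iu] == ju)
    ep[iu[ok], ju[ok]] = vals[ok]

    IS, IL, IF = scfg_inside(u, ep, g.S_LS, g.S_L, g.L_dFd, g.F_dFd, g.F_LS)
    Z = IS[0, L - 1] if L > 1 else IS[0, 0]
    if not np.isfinite(Z) or Z <= 0.0:
        return EvoPosterior(
            np.zeros((L, L)), np.zeros(L), -np.inf, feasible=False
        )
    OS, OL, OF = scfg_outside(u, ep, g.S_LS, g.S_L, g.L_dFd, g.F_dFd, g.F_LS, IS, IL, IF)

    pair = np.zeros((L, L))
    inner = np.zeros((L, L))
    inner[: L - 1, 1:] = IF[1:, : L - 1]  # inner[i, j] = IF[i+1, j-1]
    pair_upper = (g.L_dFd * OL + g.F_dFd * OF) * ep * inner / Z
    pair = pair_upper + pair_upper.T
    ss = np.diag(OL) * u / Z
    loglik = float(np.log(Z) + t_log.sum())
    return EvoPosterior(pair, ss, loglik, feasible=True)


def evo_ensemble_prob(
    aln,
    tree: PhyloTree,
    models: ParameterSet,
    partial_pairs,
    emissions: EmissionTable | None = None,
    base_constraint: StructureConstraint | None = None,
    unconstrained_loglik: float | None = None,
) -> float:
    """Probability mass of all consensus structures extending the partial one.

    Computed as exp(logZ constrained-to-contain-the-pairs minus logZ
    unconstrained); returns 0 for an infeasible partial structure.
    """
    partial_pairs = frozenset((int(i), int(j)) for i, j in partial_pairs)
    base = base_constraint or StructureConstraint()
    if emissions is None:
        plain, _ = _as_alignment(aln)
        emissions = compute_emissions(plain, tree, models)
    if unconstrained_loglik is None:
        unconstrained_loglik = inside_outside(
            aln, tree, models, base, emissions
        ).loglik
    if not partial_pairs:
        return 1.0
    constrained = StructureConstraint(
        base.forced_pairs | partial_pairs, base.forced_unpaired, base.prior_free
    )
    post = inside_outside(aln, tree, models, constrained, emissions)
    if not post.feasible:
        return 0.0
    return float(np.exp(post.loglik - unconstrained_loglik))
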