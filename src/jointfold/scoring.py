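"""Combined reliabilities and maximum-expected-accuracy decoding.

The combined score of a consensus structure is the evolutionary expected
accuracy plus ``beta`` times the per-sequence average thermodynamic
expected accuracy; it decomposes over base-pair and single-stranded
reliabilities, so the optimal structure is found with a Nussinov-style
dynamic program over

    R_bp(i, j) = P_ev(i, j) + (beta / n) * sum_s P_th(i, j | s)
    R_ss(i)    = alpha * [ P_ev(i) + (beta / n) * sum_s P_th_ss(i | s) ]

A base pair credits its two columns (factor 2 against one per unpaired
column); only the ratio of pair to single-stranded credit matters to the
argmax, and ``alpha`` rebalances it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evoscfg import EvoPosterior, StructureConstraint, pairs_cross
from .msa_io import MultipleAlignment
from .thermo import ThermoResult

#: accuracy credit of a base pair (its two columns)
PAIR_CREDIT = 2.0


@dataclass
class ReliabilityMatrix:
    """Combined pair/single-stranded reliabilities on alignment columns."""

    pair: np.ndarray     # (L, L) symmetric, entries >= 0
    ss: np.ndarray       # (L,)
    beta: float = 1.0
    alpha: float = 0.2
    provenance: str = "step1"

    @property
    def length(self) -> int:
        return self.ss.shape[0]

    def normalised_pair(self) -> np.ndarray:
        """Pair reliabilities rescaled to [0, 1] by 1 + beta.

        The conflict-free guarantee of a > 1/2 cutoff holds on a unit
        scale; the raw combined reliability ranges up to 1 + beta.
        """
        return self.pair / (1.0 + self.beta)


def combine_reliabilities(
    evo: EvoPosterior | None,
    thermo_list: list[ThermoResult],
    aln: MultipleAlignment,
    beta: float = 1.0,
    alpha: float = 0.2,
) -> ReliabilityMatrix:
    """Combine the evolutionary posterior with per-sequence ensembles.

    Per-sequence pair probabilities are mapped to alignment columns through
    the gap maps; a pair with a gapped end in a row contributes 0 for that
    row, and a gapped column contributes 1 to that row's single-stranded
    term.  ``evo=None`` (evolutionary part disabled) scores thermodynamics
    only.
    """
    L = aln.length
    n = aln.n_seqs
    if len(thermo_list) != n:
        raise ValueError(f"{len(thermo_list)} thermo results for {n} sequences")
    pair = np.zeros((L, L))
    ss = np.zeros(L)
    if evo is not None:
        if evo.pair_rel.shape != (L, L):
            raise ValueError("evolutionary posterior has wrong dimensions")
        pair += evo.pair_rel
        ss += evo.ss_rel
    th_pair = np.zeros((L, L))
    th_ss = np.zeros(L)
    for s, res in enumerate(thermo_list):
        pos = np.array(
            [aln.col_to_seqpos(s, c) or 0 for c in range(1, L + 1)], dtype=int
        )
        nz = pos > 0
        idx = pos[nz] - 1
        sub = res.pair_prob[np.ix_(idx, idx)]
        block = np.zeros((L, L))
        block[np.ix_(nz, nz)] = sub
        th_pair += block
        th_ss[nz] += res.unpaired_prob[idx]
        th_ss[~nz] += 1.0
    pair += (beta / n) * th_pair
    ss = alpha * (ss + (beta / n) * th_ss)
    return ReliabilityMatrix(pair, ss, beta=beta, alpha=alpha)


def _check_nested(pairs):
    plist = sorted(pairs)
    seen: set[int] = set()
    for i, j in plist:
        if i in seen or j in seen:
            raise ValueError(f"position reused at pair ({i}, {j})")
        seen.update((i, j))
    for a in range(len(plist)):
        for b in range(a + 1, len(plist)):
            if pairs_cross(plist[a], plist[b]):
                raise ValueError(f"pairs {plist[a]} and {plist[b]} cross")
    return plist


def expected_accuracy(pairs, rel: ReliabilityMatrix) -> float:
    """Expected-accuracy score of a nested structure (1-based pairs)."""
    plist = _check_nested(pairs)
    L = rel.length
    paired = set()
    score = 0.0
    for i, j in plist:
        if not (1 <= i < j <= L):
            raise ValueError(f"pair ({i}, {j}) out of range")
        score += PAIR_CREDIT * rel.pair[i - 1, j - 1]
        paired.update((i, j))
    for i in range(1, L + 1):
        if i not in paired:
            score += rel.ss[i - 1]
    return float(score)


def mea_decode(
    rel: ReliabilityMatrix,
    constraint: StructureConstraint | None = None,
    pair_weight_overrides: dict | None = None,
) -> frozenset:
    """Maximum-expected-accuracy nested structure by Nussinov-style DP.

    Deterministic tie-break: prefer leaving a column unpaired, then the
    smallest left index, then the smallest right partner.  The constraint's
    forced-unpaired positions never pair and forced pairs are always made.
    """
    L = rel.length
    constraint = constraint or StructureConstraint()
    over = {tuple(sorted(p)): w for p, w in (pair_weight_overrides or {}).items()}
    no_pair = np.zeros(L + 2, dtype=bool)
    for p in constraint.forced_unpaired:
        no_pair[p] = True
    for p in constraint.prior_free:
        no_pair[p] = True
    partner = np.zeros(L + 2, dtype=int)
    for i, j in constraint.forced_pairs:
        partner[i], partner[j] = j, i

    def w(i, j):
        if (i, j) in over:
            return over[(i, j)]
        return PAIR_CREDIT * rel.pair[i - 1, j - 1]

    def allowed(i, j):
        if no_pair[i] or no_pair[j]:
            return False
        if partner[i] and partner[i] != j:
            return False
        if partner[j] and partner[j] != i:
            return False
        return True

    NEG = -np.inf
    M = np.zeros((L + 2, L + 2))
    for i in range(L + 1, 0, -1):
        for j in range(i, L + 1):
            best = NEG
            if not partner[i]:
                best = rel.ss[i - 1] + M[i + 1, j]
            for k in range(i + 1, j + 1):
                if allowed(i, k):
                    v = w(i, k) + M[i + 1, k - 1] + M[k + 1, j]
                    if v > best + 1e-15:
                        best = v
            M[i, j] = best
    if not np.isfinite(M[1, L]) and L > 0:
        raise ValueError("constraints admit no structure")

    pairs = set()
    stack = [(1, L)]
    while stack:
        i, j = stack.pop()
        if i > j:
            continue
        target = M[i, j]
        if not partner[i] and abs(rel.ss[i - 1] + M[i + 1, j] - target) <= 1e-12 * max(1.0, abs(target)):
            stack.append((i + 1, j))
            continue
        done = False
        for k in range(i + 1, j + 1):
            if allowed(i, k):
                v = w(i, k) + M[i + 1, k - 1] + M[k + 1, j]
                if abs(v - target) <= 1e-12 * max(1.0, abs(target)):
                    pairs.add((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    done = True
                    break
        if not done:
            # numeric guard: fall back to leaving i unpaired
            stack.append((i + 1, j))
    return frozenset(pairs)
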