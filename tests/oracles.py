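"""Independent brute-force oracles used by the test-suite.

Everything here is deliberately naive: explicit enumeration of nested
structures, loop-decomposition energies evaluated structure by structure,
explicit parse-tree enumeration for the structure grammar, and exhaustive
search for the best-scoring nested structure.  None of it shares code with
the dynamic programs it checks.
"""

from __future__ import annotations

import numpy as np

from jointfold.params import default_parameter_set
from jointfold.thermo import _PAIR_TYPES

# ---------------------------------------------------------------------------
# nested-structure enumeration and Boltzmann sums


def enum_structures(seq, nick, model, forced_unpaired=(), forced_pairs=()):
    """All nested structures (0-based pair lists) legal for the constraints."""
    n = len(seq)
    no_pair = set(i - 1 for i in forced_unpaired)
    partner = {}
    for i, j in forced_pairs:
        partner[i - 1] = j - 1
        partner[j - 1] = i - 1

    def can(i, j):
        if (seq[i], seq[j]) not in _PAIR_TYPES:
            return False
        if i in no_pair or j in no_pair:
            return False
        if (i in partner or j in partner) and partner.get(i) != j:
            return False
        spans = nick is not None and i < nick <= j
        if not spans and j - i - 1 < model.min_hairpin:
            return False
        return True

    def rec(i, j):
        if i > j:
            yield []
            return
        for rest in rec(i + 1, j):
            yield rest
        for k in range(i + 1, j + 1):
            if can(i, k):
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield [(i, k)] + left + right

    for pairs in rec(0, n - 1):
        paired = set(x for p in pairs for x in p)
        if any(p not in paired for p in partner):
            continue
        yield sorted(pairs)


def helices(pairs, nick=None):
    """Maximal runs of stacked pairs.

    Stacking follows the energy model: the size-0 loop between (a, b) and
    (a+1, b-1) is a stack only when it does not contain the strand nick
    (nick on a loop segment means the loop is exterior-like, hence no
    stacked neighbour)."""

    def stacked(a, b):
        return nick is None or (nick != a + 1 and nick != b)

    ps = set(pairs)
    out, seen = [], set()
    for i, j in sorted(ps):
        if (i, j) in seen:
            continue
        if (i - 1, j + 1) in ps and stacked(i - 1, j + 1):
            continue
        h = [(i, j)]
        seen.add((i, j))
        a, b = i, j
        while (a + 1, b - 1) in ps and stacked(a, b):
            a, b = a + 1, b - 1
            h.append((a, b))
            seen.add((a, b))
        out.append(h)
    return out


def loop_energy(seq, pairs, nick, model):
    """Loop-decomposition energy of one structure; None if illegal."""
    ps = sorted(pairs)
    parent = {}
    children = {p: [] for p in ps}
    for p in ps:
        par = None
        for q in ps:
            if q != p and q[0] < p[0] and p[1] < q[1]:
                if par is None or q[0] > par[0]:
                    par = q
        parent[p] = par
        if par is not None:
            children[par].append(p)
    spans = lambda a, b: nick is not None and a < nick <= b
    e = 0.0
    for (i, j) in ps:
        kids = sorted(children[(i, j)])
        junc_in_loop = spans(i, j) and not any(spans(a, b) for a, b in kids)
        if junc_in_loop:
            continue
        if not kids:
            e += model.hairpin_a + model.hairpin_b * (j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            u = (k - i - 1) + (j - l - 1)
            if u == 0:
                e += model.stack[
                    _PAIR_TYPES[(seq[i], seq[j])], _PAIR_TYPES[(seq[k], seq[l])]
                ]
            else:
                if u > model.max_interior:
                    return None
                e += model.interior_a + model.interior_b * u
        else:
            unp = (j - i - 1) - sum(b - a + 1 for a, b in kids)
            e += (
                model.multi_a
                + model.multi_b * (len(kids) + 1)
                + model.multi_c * unp
            )
    return e


def boltzmann_oracle(seq, nick, model, forced_unpaired=(), forced_pairs=()):
    """(Z, pair-probability matrix) by exhaustive enumeration."""
    n = len(seq)
    Z = 0.0
    P = np.zeros((n, n))
    for pairs in enum_structures(seq, nick, model, forced_unpaired, forced_pairs):
        if not model.allow_isolated and any(
            len(h) < 2 for h in helices(pairs, nick)
        ):
            continue
        e = loop_energy(seq, pairs, nick, model)
        if e is None:
            continue
        w = np.exp(-e / model.rt)
        Z += w
        for i, j in pairs:
            P[i, j] += w
    if Z > 0:
        P /= Z
    return Z, P


# ---------------------------------------------------------------------------
# parse-tree enumeration for the structure grammar


def enum_parse_trees(L, u, ep, grammar=None):
    """All parse trees as (probability, frozenset of 0-based pairs).

    ``u[i]`` is the weight of an unpaired column (grammar factor included),
    ``ep[i, j]`` the raw pair-emission weight (zero where disallowed).
    """
    g = grammar or default_parameter_set().grammar

    def gen(nt, i, j):
        out = []
        if nt == "L":
            if i == j:
                if u[i] > 0:
                    out.append((u[i], frozenset()))
            elif ep[i, j] > 0:
                for p, s in gen("F", i + 1, j - 1):
                    out.append((g.L_dFd * ep[i, j] * p, s | {(i, j)}))
        elif nt == "F":
            if j > i and ep[i, j] > 0:
                for p, s in gen("F", i + 1, j - 1):
                    out.append((g.F_dFd * ep[i, j] * p, s | {(i, j)}))
            for k in range(i, j):
                for pl, sl in gen("L", i, k):
                    for pr, sr in gen("S", k + 1, j):
                        out.append((g.F_LS * pl * pr, sl | sr))
        else:  # S
            for p, s in gen("L", i, j):
                out.append((g.S_L * p, s))
            for k in range(i, j):
                for pl, sl in gen("L", i, k):
                    for pr, sr in gen("S", k + 1, j):
                        out.append((g.S_LS * pl * pr, sl | sr))
        return out

    return gen("S", 0, L - 1)


def scfg_oracle_emissions(aln, tree, models, constraint=None):
    """Raw emission weights for the oracle, with constraints applied."""
    from jointfold.evoscfg import MIN_PAIR_SPAN, StructureConstraint, compute_emissions

    constraint = constraint or StructureConstraint()
    em = compute_emissions(aln, tree, models)
    L = aln.length
    u = np.exp(em.es_log) * models.grammar.L_s
    ep = np.zeros((L, L))
    for i in range(L):
        for j in range(i + MIN_PAIR_SPAN, L):
            ep[i, j] = np.exp(em.ep_log[i, j])
    no_pair = set(x - 1 for x in constraint.forced_unpaired)
    pf = set(x - 1 for x in constraint.prior_free)
    partner = {}
    for i, j in constraint.forced_pairs:
        partner[i - 1] = j - 1
        partner[j - 1] = i - 1
    for i in range(L):
        if i in pf:
            u[i] = 1.0
        if i in partner:
            u[i] = 0.0
        for j in range(L):
            if i in no_pair or j in no_pair or i in pf or j in pf:
                ep[i, j] = 0.0
            if (i in partner or j in partner) and partner.get(i) != j:
                ep[i, j] = 0.0
    return u, ep


def scfg_posterior_oracle(aln, tree, models, constraint=None):
    """(Z, pair posterior, unpaired posterior) by parse-tree enumeration."""
    u, ep = scfg_oracle_emissions(aln, tree, models, constraint)
    L = aln.length
    parses = enum_parse_trees(L, u, ep, models.grammar)
    Z = sum(p for p, _ in parses)
    P = np.zeros((L, L))
    S = np.zeros(L)
    for p, s in parses:
        for i, j in s:
            P[i, j] += p
        paired = set(x for pr in s for x in pr)
        for i in range(L):
            if i not in paired:
                S[i] += p
    if Z > 0:
        P /= Z
        S /= Z
    return Z, P, S


# ---------------------------------------------------------------------------
# exhaustive maximum-expected-accuracy search


def enum_nested_pairsets(L, allowed):
    """All nested sets of 1-based pairs over 1..L with pairs from ``allowed``."""

    def rec(i, j):
        if i > j:
            yield frozenset()
            return
        for rest in rec(i + 1, j):
            yield rest
        for k in range(i + 1, j + 1):
            if (i, k) in allowed:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield frozenset({(i, k)}) | left | right

    yield from rec(1, L)


def best_structure_oracle(rel, allowed=None):
    """Exhaustive argmax of the expected-accuracy score (ties: all maxima)."""
    from jointfold.scoring import PAIR_CREDIT

    L = rel.length
    if allowed is None:
        allowed = {(i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)}
    best, best_sets = -np.inf, []
    for pairs in enum_nested_pairsets(L, allowed):
        paired = set(x for p in pairs for x in p)
        score = sum(PAIR_CREDIT * rel.pair[i - 1, j - 1] for i, j in pairs)
        score += sum(rel.ss[i - 1] for i in range(1, L + 1) if i not in paired)
        if score > best + 1e-12:
            best, best_sets = score, [pairs]
        elif abs(score - best) <= 1e-12:
            best_sets.append(pairs)
    return best, best_sets


# ---------------------------------------------------------------------------
# random posteriors realisable as mixtures of nested structures


def random_structure_mixture(L, rng, k_structures=4):
    """A per-column-normalised posterior: mixture of random nested structures.

    Returns (pair matrix, unpaired vector, list of (weight, pairs)).  By
    construction each column's pairing mass plus unpaired mass is exactly 1
    and conflicting pairs never co-occur within one component.
    """
    comps = []
    for _ in range(k_structures):
        pairs = set()
        free = list(range(1, L + 1))
        rng.shuffle(free)
        while len(free) >= 2 and rng.random() < 0.8:
            i, j = sorted(rng.choice(len(free), 2, replace=False))
            a, b = free[i], free[j]
            cand = (min(a, b), max(a, b))
            from jointfold.evoscfg import pairs_conflict

            if all(not pairs_conflict(cand, p) for p in pairs):
                pairs.add(cand)
                free = [x for x in free if x not in cand]
        comps.append(frozenset(pairs))
    w = rng.dirichlet(np.ones(len(comps)))
    pair = np.zeros((L, L))
    ss = np.ones(L)
    for wt, pairs in zip(w, comps):
        for i, j in pairs:
            pair[i - 1, j - 1] += wt
            pair[j - 1, i - 1] += wt
            ss[i - 1] -= wt
            ss[j - 1] -= wt
    return pair, ss, list(zip(w, comps))


def select_above(pair, delta):
    """1-based pairs with posterior strictly above the cutoff."""
    L = pair.shape[0]
    return {
        (i + 1, j + 1)
        for i in range(L)
        for j in range(i + 1, L)
        if pair[i, j] > delta
    }


def has_conflict(pairs):
    from jointfold.evoscfg import pairs_conflict

    plist = sorted(pairs)
    return any(
        pairs_conflict(plist[a], plist[b])
        for a in range(len(plist))
        for b in range(a + 1, len(plist))
    )
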