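"""Inside-outside dynamic programming for the lightweight structure grammar.

Grammar:  S -> LS | L,  L -> s | dFd,  F -> dFd | LS.

Probabilities are over parse trees (the grammar is ambiguous for some
structures).  The kernel works in linear space on emission weights that the
caller has rescaled per column, so values stay in floating-point range for
alignment lengths in the hundreds.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def scfg_inside(u, ep, p1, p2, q2, r1, r2):
    """Inside tables (IS, IL, IF) for spans i..j.

    ``u[i]`` is the weight of generating column i unpaired (grammar factor
    included), ``ep[i, j]`` the weight of emitting columns i, j as a base
    pair (zero where pairing is not allowed; grammar factors applied here).
    """
    n = u.shape[0]
    IS = np.zeros((n, n))
    IL = np.zeros((n, n))
    IF = np.zeros((n, n))
    for i in range(n):
        IL[i, i] = u[i]
        IS[i, i] = p2 * IL[i, i]
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            pair_term = 0.0
            if d >= 3 and ep[i, j] > 0.0:
                pair_term = ep[i, j] * IF[i + 1, j - 1]
            split = 0.0
            for k in range(i, j):
                split += IL[i, k] * IS[k + 1, j]
            IL[i, j] = q2 * pair_term
            IF[i, j] = r1 * pair_term + r2 * split
            IS[i, j] = p2 * IL[i, j] + p1 * split
    return IS, IL, IF


@njit(cache=False)
def scfg_outside(u, ep, p1, p2, q2, r1, r2, IS, IL, IF):
    n = u.shape[0]
    OS = np.zeros((n, n))
    OL = np.zeros((n, n))
    OF = np.zeros((n, n))
    OS[0, n - 1] = 1.0
    for d in range(n - 1, -1, -1):
        for i in range(n - d):
            j = i + d
            # S -> L finalises OL[i, j]
            OL[i, j] += p2 * OS[i, j]
            if d >= 1:
                # split rules S -> LS and F -> LS
                os_ij = OS[i, j]
                of_ij = OF[i, j]
                for k in range(i, j):
                    w = p1 * os_ij + r2 * of_ij
                    if w != 0.0:
                        OL[i, k] += w * IS[k + 1, j]
                        OS[k + 1, j] += w * IL[i, k]
            if d >= 3 and ep[i, j] > 0.0:
                # d F d emissions from L and F
                OF[i + 1, j - 1] += ep[i, j] * (q2 * OL[i, j] + r1 * OF[i, j])
    return OS, OL, OF
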