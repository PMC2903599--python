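"""Partition-function kernels for constrained folding and cofolding.

Inside/outside dynamic programming over nested structures on a sequence,
optionally the concatenation of two strands with a nick (cut point) at
index ``c``: positions 0..c-1 are the first strand, c..n-1 the second.
Any loop whose backbone segments contain the nick is scored as an
exterior-like region (zero energy), mirroring the cofolding convention;
base pairs spanning the nick (inter-molecular pairs) are exempt from the
minimum hairpin size.

Energy model (weights are Boltzmann factors precomputed by the caller):
stacking of adjacent pairs, affine hairpin/interior penalties in loop size
(interior loops capped at ``maxloop`` unpaired total — part of the model),
and affine multiloops (closing weight ``wa``, per-branch ``wb``,
per-unpaired ``wc``).

Decomposition, with B(i,j) the weight of a branch whose outer pair is
(i, j):

  Qb(i,j)  pair (i,j) closes a non-stack loop
  Qs(i,j)  pair (i,j) stacks on (i+1,j-1):  wst * (Qb + Qs)(i+1,j-1)
  B        = Qs (lonely pairs disallowed) or Qb + Qs
  Qm1p     multiloop chain, first branch at the left end
  Qm1u     multiloop chain, exactly one branch at the left end then unpaired
  Qm       multiloop chain, >= 1 branch anywhere
  X(a,b)   exterior-like chain within one strand (used inside nick loops)
  F / Fs   exterior prefix / suffix chains

The outside pass mirrors every inside transition, giving exact base-pair
probabilities; an enumeration oracle in the test-suite checks both to
1e-9 on small instances.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, inline="always")
def _allunp(cum, a, b):
    """True when no must-pair position lies in [a, b] (empty interval ok)."""
    if b < a:
        return True
    return cum[b + 1] - cum[a] == 0


@njit(cache=False, inline="always")
def _u0(cum, pw_wc, a, b):
    """Multiloop chain over [a, b] with zero branches (wc per position)."""
    if b < a:
        return 1.0
    if cum[b + 1] - cum[a] != 0:
        return 0.0
    return pw_wc[b - a + 1]


@njit(cache=False, inline="always")
def _xval(X, a, b):
    if b < a:
        return 1.0
    return X[a, b]


@njit(cache=False)
def cofold_inside_outside(
    n, c, can_pair, ptype, cu, wst, whp, wip, wa, wb, wc, maxloop, noLP
):
    """Returns (Z, P, Punp) for the model described in the module docstring.

    can_pair : uint8 (n, n), upper triangle, pairability incl. constraints
    ptype    : int8 (n, n), pair-type index into wst
    cu       : float64 (n,), 1.0 if the position may be unpaired else 0.0
    whp      : hairpin weight by unpaired count (0 where illegal)
    wip      : interior/bulge weight by unpaired count (index 1..maxloop)
    """
    Qb = np.zeros((n, n))
    Qs = np.zeros((n, n))
    B = np.zeros((n, n))
    Qm = np.zeros((n, n))
    Qm1p = np.zeros((n, n))
    Qm1u = np.zeros((n, n))
    X = np.zeros((n, n))

    cum = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        cum[i + 1] = cum[i] + (0 if cu[i] > 0.0 else 1)
    pw_wc = np.empty(n + 2)
    pw_wc[0] = 1.0
    for k in range(1, n + 2):
        pw_wc[k] = pw_wc[k - 1] * wc

    # ------------------------------------------------------------------
    # stage A: intra-strand spans
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            if c >= 0 and i < c <= j:
                continue  # nick-spanning pairs handled in stage C
            if can_pair[i, j]:
                acc = 0.0
                u_h = j - i - 1
                if whp[u_h] > 0.0 and _allunp(cum, i + 1, j - 1):
                    acc += whp[u_h]
                # interior / bulge (stack excluded -> handled by Qs)
                for k in range(i + 1, j - 1):
                    u1 = k - i - 1
                    if u1 > maxloop:
                        break
                    if u1 > 0 and not _allunp(cum, i + 1, k - 1):
                        break
                    for l in range(j - 1, k, -1):
                        u2 = j - 1 - l
                        if u1 + u2 > maxloop:
                            break
                        if u2 > 0 and not _allunp(cum, l + 1, j - 1):
                            break
                        if u1 + u2 == 0:
                            continue
                        if B[k, l] > 0.0:
                            acc += wip[u1 + u2] * B[k, l]
                # multiloop: last branch (k, l), >=1 branch before it
                ml = 0.0
                for k in range(i + 2, j - 1):
                    if Qm[i + 1, k - 1] > 0.0 and Qm1u[k, j - 1] > 0.0:
                        ml += Qm[i + 1, k - 1] * Qm1u[k, j - 1]
                acc += wa * wb * ml
                Qb[i, j] = acc
                if (
                    j - i >= 2
                    and can_pair[i + 1, j - 1]
                    and (Qb[i + 1, j - 1] > 0.0 or Qs[i + 1, j - 1] > 0.0)
                ):
                    Qs[i, j] = wst[ptype[i, j], ptype[i + 1, j - 1]] * (
                        Qb[i + 1, j - 1] + Qs[i + 1, j - 1]
                    )
                B[i, j] = Qs[i, j] if noLP else Qb[i, j] + Qs[i, j]
            # multiloop chains on [i, j]
            acc1p = 0.0
            acc1u = 0.0
            for l in range(i, j + 1):
                if B[i, l] > 0.0:
                    tail0 = _u0(cum, pw_wc, l + 1, j)
                    acc1u += wb * B[i, l] * tail0
                    acc1p += wb * B[i, l] * (tail0 + Qm[l + 1, j] if l + 1 <= j else tail0)
            Qm1p[i, j] = acc1p
            Qm1u[i, j] = acc1u
            accm = 0.0
            for k in range(i, j + 1):
                if Qm1p[k, j] > 0.0:
                    accm += _u0(cum, pw_wc, i, k - 1) * Qm1p[k, j]
            Qm[i, j] = accm

    # ------------------------------------------------------------------
    # stage B: exterior-like chains within each strand (for nick loops)
    if c >= 0:
        for s0, s1 in ((0, c - 1), (c, n - 1)):
            for a in range(s0, s1 + 1):
                for b in range(a, s1 + 1):
                    v = cu[b] * _xval(X, a, b - 1)
                    for k in range(a, b):
                        if B[k, b] > 0.0:
                            v += _xval(X, a, k - 1) * B[k, b]
                    X[a, b] = v

    # ------------------------------------------------------------------
    # stage C: nick-spanning pairs
    if c >= 0:
        for d in range(1, n):
            for i in range(n - d):
                j = i + d
                if not (i < c <= j):
                    continue
                if not can_pair[i, j]:
                    continue
                acc = 0.0
                # loops with a nick-spanning inner branch are scored normally
                for k in range(i + 1, c):
                    u1 = k - i - 1
                    if u1 > maxloop:
                        break
                    if u1 > 0 and not _allunp(cum, i + 1, k - 1):
                        break
                    for l in range(j - 1, max(c - 1, k), -1):
                        u2 = j - 1 - l
                        if u2 > maxloop - u1:
                            break
                        if u2 > 0 and not _allunp(cum, l + 1, j - 1):
                            break
                        if u1 + u2 == 0:
                            continue
                        if B[k, l] > 0.0:
                            acc += wip[u1 + u2] * B[k, l]
                for k in range(i + 1, c):
                    for l in range(max(c, k + 1), j):
                        if B[k, l] > 0.0:
                            left = _u0(cum, pw_wc, i + 1, k - 1) + Qm[i + 1, k - 1] if k - 1 >= i + 1 else 1.0
                            right = _u0(cum, pw_wc, l + 1, j - 1) + Qm[l + 1, j - 1] if j - 1 >= l + 1 else 1.0
                            both0 = _u0(cum, pw_wc, i + 1, k - 1) * _u0(cum, pw_wc, l + 1, j - 1)
                            acc += wa * wb * wb * B[k, l] * (left * right - both0)
                # nick inside the loop: exterior-like region
                acc += _xval(X, i + 1, c - 1) * _xval(X, c, j - 1)
                Qb[i, j] = acc
                if i + 1 < c <= j - 1 and can_pair[i + 1, j - 1] and (
                    Qb[i + 1, j - 1] > 0.0 or Qs[i + 1, j - 1] > 0.0
                ):
                    Qs[i, j] = wst[ptype[i, j], ptype[i + 1, j - 1]] * (
                        Qb[i + 1, j - 1] + Qs[i + 1, j - 1]
                    )
                B[i, j] = Qs[i, j] if noLP else Qb[i, j] + Qs[i, j]

    # ------------------------------------------------------------------
    # stage D: exterior chains
    F = np.zeros(n + 1)
    Fs = np.zeros(n + 1)
    F[0] = 1.0
    for t in range(1, n + 1):
        j = t - 1
        v = cu[j] * F[t - 1]
        for k in range(j):
            if B[k, j] > 0.0:
                v += F[k] * B[k, j]
        F[t] = v
    Fs[n] = 1.0
    for t in range(n - 1, -1, -1):
        v = cu[t] * Fs[t + 1]
        for l in range(t + 1, n):
            if B[t, l] > 0.0:
                v += B[t, l] * Fs[l + 1]
        Fs[t] = v
    Z = F[n]

    P = np.zeros((n, n))
    Punp = np.zeros(n)
    if Z <= 0.0 or not np.isfinite(Z):
        return Z, P, Punp

    # ------------------------------------------------------------------
    # outside pass
    OB = np.zeros((n, n))
    Oqp = np.zeros((n, n))
    OQm = np.zeros((n, n))
    OQm1p = np.zeros((n, n))
    OQm1u = np.zeros((n, n))
    Ob = np.zeros((n, n))
    Os = np.zeros((n, n))

    for i in range(n):
        for j in range(i + 1, n):
            if B[i, j] > 0.0:
                OB[i, j] = F[i] * Fs[j + 1]

    # stage C': nick-spanning pairs, decreasing span
    if c >= 0:
        for d in range(n - 1, 0, -1):
            for i in range(n - d):
                j = i + d
                if not (i < c <= j) or not can_pair[i, j]:
                    continue
                os_ij = OB[i, j] + Oqp[i, j]
                ob_ij = Oqp[i, j] + (0.0 if noLP else OB[i, j])
                Os[i, j] = os_ij
                Ob[i, j] = ob_ij
                if Qs[i, j] > 0.0 and os_ij != 0.0:
                    Oqp[i + 1, j - 1] += os_ij * wst[ptype[i, j], ptype[i + 1, j - 1]]
                if ob_ij == 0.0:
                    continue
                for k in range(i + 1, c):
                    u1 = k - i - 1
                    if u1 > maxloop:
                        break
                    if u1 > 0 and not _allunp(cum, i + 1, k - 1):
                        break
                    for l in range(j - 1, max(c - 1, k), -1):
                        u2 = j - 1 - l
                        if u2 > maxloop - u1:
                            break
                        if u2 > 0 and not _allunp(cum, l + 1, j - 1):
                            break
                        if u1 + u2 == 0:
                            continue
                        if B[k, l] > 0.0:
                            OB[k, l] += ob_ij * wip[u1 + u2]
                for k in range(i + 1, c):
                    for l in range(max(c, k + 1), j):
                        if B[k, l] > 0.0:
                            u0L = _u0(cum, pw_wc, i + 1, k - 1)
                            u0R = _u0(cum, pw_wc, l + 1, j - 1)
                            qmL = Qm[i + 1, k - 1] if k - 1 >= i + 1 else 0.0
                            qmR = Qm[l + 1, j - 1] if j - 1 >= l + 1 else 0.0
                            coef = ob_ij * wa * wb * wb
                            OB[k, l] += coef * ((u0L + qmL) * (u0R + qmR) - u0L * u0R)
                            if k - 1 >= i + 1:
                                OQm[i + 1, k - 1] += coef * B[k, l] * (u0R + qmR)
                            if j - 1 >= l + 1:
                                OQm[l + 1, j - 1] += coef * B[k, l] * (u0L + qmL)
                # exterior-like region around the nick
                x2 = _xval(X, c, j - 1)
                for k in range(i + 1, c):
                    for l in range(k, c):
                        if B[k, l] > 0.0:
                            OB[k, l] += (
                                ob_ij * _xval(X, i + 1, k - 1) * _xval(X, l + 1, c - 1) * x2
                            )
                x1 = _xval(X, i + 1, c - 1)
                for k in range(c, j):
                    for l in range(k, j):
                        if B[k, l] > 0.0:
                            OB[k, l] += (
                                ob_ij * x1 * _xval(X, c, k - 1) * _xval(X, l + 1, j - 1)
                            )

    # stage A': intra spans and multiloop chains, decreasing interval length
    for length in range(n, 0, -1):
        # Qm(a, b) = sum_k u0(a, k-1) * Qm1p(k, b)
        for a in range(0, n - length + 1):
            b = a + length - 1
            if c >= 0 and a < c <= b:
                continue
            oqm = OQm[a, b]
            if oqm != 0.0:
                for k in range(a, b + 1):
                    if Qm1p[k, b] > 0.0:
                        OQm1p[k, b] += oqm * _u0(cum, pw_wc, a, k - 1)
        # Qm1p(k, b) = sum_l wb*B(k,l)*(u0(l+1,b) + Qm(l+1,b))
        for k in range(0, n - length + 1):
            b = k + length - 1
            if c >= 0 and k < c <= b:
                continue
            o1p = OQm1p[k, b]
            o1u = OQm1u[k, b]
            if o1p != 0.0 or o1u != 0.0:
                for l in range(k, b + 1):
                    if B[k, l] > 0.0:
                        tail0 = _u0(cum, pw_wc, l + 1, b)
                        qmr = Qm[l + 1, b] if l + 1 <= b else 0.0
                        OB[k, l] += wb * (o1p * (tail0 + qmr) + o1u * tail0)
                        if l + 1 <= b and o1p != 0.0:
                            OQm[l + 1, b] += o1p * wb * B[k, l]
        # intra pairs of this interval length
        d = length - 1
        if d < 1:
            continue
        for i in range(n - d):
            j = i + d
            if (c >= 0 and i < c <= j) or not can_pair[i, j]:
                continue
            os_ij = OB[i, j] + Oqp[i, j]
            ob_ij = Oqp[i, j] + (0.0 if noLP else OB[i, j])
            Os[i, j] = os_ij
            Ob[i, j] = ob_ij
            if Qs[i, j] > 0.0 and os_ij != 0.0:
                Oqp[i + 1, j - 1] += os_ij * wst[ptype[i, j], ptype[i + 1, j - 1]]
            if ob_ij == 0.0:
                continue
            for k in range(i + 1, j - 1):
                u1 = k - i - 1
                if u1 > maxloop:
                    break
                if u1 > 0 and not _allunp(cum, i + 1, k - 1):
                    break
                for l in range(j - 1, k, -1):
                    u2 = j - 1 - l
                    if u1 + u2 > maxloop:
                        break
                    if u2 > 0 and not _allunp(cum, l + 1, j - 1):
                        break
                    if u1 + u2 == 0:
                        continue
                    if B[k, l] > 0.0:
                        OB[k, l] += ob_ij * wip[u1 + u2]
            for k in range(i + 2, j - 1):
                if Qm[i + 1, k - 1] > 0.0 or Qm1u[k, j - 1] > 0.0:
                    coef = ob_ij * wa * wb
                    if Qm1u[k, j - 1] > 0.0:
                        OQm[i + 1, k - 1] += coef * Qm1u[k, j - 1]
                    if Qm[i + 1, k - 1] > 0.0:
                        OQm1u[k, j - 1] += coef * Qm[i + 1, k - 1]

    for i in range(n):
        for j in range(i + 1, n):
            if can_pair[i, j]:
                P[i, j] = (Ob[i, j] * Qb[i, j] + Os[i, j] * Qs[i, j]) / Z
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j > i:
                s += P[i, j]
            elif j < i:
                s += P[j, i]
        Punp[i] = 1.0 - s
    return Z, P, Punp
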