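"""Numba kernels for the minimum-free-energy dynamic program.

The recurrences are the classic Zuker decomposition over
non-pseudoknotted structures:

``V[i,j]``   best energy of a structure closed by pair (i,j)
             (hairpin | stacked/bulge/internal loop | multibranch);
``M1[i,j]``  multiloop segment whose first base i is paired, with an
             optionally unpaired tail;
``WM[i,j]``  multiloop segment containing at least one branch;
``W[i]``     best energy of the suffix s[i:] in the exterior loop.

The per-loop energy formulas mirror :mod:`aptevolve.scoring`, which is
the standalone (non-search) evaluator the traceback is re-scored
against. The kernels only fill matrices; traceback happens in Python.
"""
from __future__ import annotations

import numpy as np
from numba import njit

MAXLOOP = 30
MIN_HAIRPIN = 3
NBINF = np.inf


@njit(cache=True)
def _at_pen(pt, term_at):
    return term_at if pt >= 2 else 0.0


@njit(cache=True)
def _hairpin(s, i, j, pt, hairpin_t, tstackh, term_at, lxc,
             tri_seqs, tri_e, tetra_seqs, tetra_e):
    size = j - i - 1
    if size < MIN_HAIRPIN:
        return NBINF
    if size == 4:
        for t in range(tetra_seqs.shape[0]):
            ok = True
            for q in range(6):
                if tetra_seqs[t, q] != s[i + q]:
                    ok = False
                    break
            if ok:
                return tetra_e[t]
    if size <= 30:
        e = hairpin_t[size]
    else:
        e = hairpin_t[30] + lxc * np.log(size / 30.0)
    if size == 3:
        for t in range(tri_seqs.shape[0]):
            ok = True
            for q in range(5):
                if tri_seqs[t, q] != s[i + q]:
                    ok = False
                    break
            if ok:
                return tri_e[t]
        return e + _at_pen(pt, term_at)
    return e + tstackh[pt, s[i + 1] + 1, s[j - 1] + 1]


@njit(cache=True)
def _internal(s, i, j, k, l, pt1, pt2, stack, bulge_t, internal_t, tstacki,
              ninio_m, ninio_max, term_at, ptab):
    n1 = k - i - 1
    n2 = j - l - 1
    size = n1 + n2
    if size == 0:
        return stack[pt1, pt2]
    if size > MAXLOOP:
        return NBINF
    if n1 == 0 or n2 == 0:
        e = bulge_t[size]
        if size == 1:
            e += stack[pt1, pt2]
        else:
            ptkl = ptab[s[k], s[l]]
            e += _at_pen(pt1, term_at) + _at_pen(ptkl, term_at)
        return e
    sz = size if size >= 4 else 4
    e = internal_t[sz]
    asym = ninio_m * abs(n1 - n2)
    if asym > ninio_max:
        asym = ninio_max
    e += asym
    mn = n1 if n1 < n2 else n2
    mx = n1 if n1 > n2 else n2
    if mn >= 2 and mx >= 3:
        e += tstacki[pt1, s[i + 1] + 1, s[j - 1] + 1]
        e += tstacki[pt2, s[l + 1] + 1, s[k - 1] + 1]
    return e


@njit(cache=True)
def fill_matrices(s, ptab, stack, tstackh, tstacki, mm_multi, mm_ext,
                  hairpin_t, bulge_t, internal_t,
                  ninio_m, ninio_max, ml_u, ml_c, ml_b, term_at, lxc,
                  use_d2, tri_seqs, tri_e, tetra_seqs, tetra_e):
    n = s.shape[0]
    V = np.full((n, n), NBINF)
    M1 = np.full((n, n), NBINF)
    WM = np.full((n, n), NBINF)
    W = np.zeros(n + 1)

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = ptab[s[i], s[j]]
            if pt >= 0:
                best = _hairpin(s, i, j, pt, hairpin_t, tstackh, term_at, lxc,
                                tri_seqs, tri_e, tetra_seqs, tetra_e)
                # stacked pair, bulge and internal loops
                kmax = i + MAXLOOP + 1
                if kmax > j - MIN_HAIRPIN - 1:
                    kmax = j - MIN_HAIRPIN - 1
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = k + MIN_HAIRPIN + 1
                    lo = j - 1 - (MAXLOOP - n1)
                    if lo > lmin:
                        lmin = lo
                    for l in range(lmin, j):
                        if V[k, l] == NBINF:
                            continue
                        pt2 = ptab[s[l], s[k]]
                        if pt2 < 0:
                            continue
                        e = _internal(s, i, j, k, l, pt, pt2, stack, bulge_t,
                                      internal_t, tstacki, ninio_m, ninio_max,
                                      term_at, ptab) + V[k, l]
                        if e < best:
                            best = e
                # multibranch closure
                if span >= 2 * (MIN_HAIRPIN + 2) + 1:
                    close = ml_c + ml_b + _at_pen(pt, term_at)
                    if use_d2:
                        ptr = ptab[s[j], s[i]]
                        close += mm_multi[ptr, s[j - 1] + 1, s[i + 1] + 1]
                    for k in range(i + 2, j - MIN_HAIRPIN - 1):
                        if WM[i + 1, k - 1] == NBINF or M1[k, j - 1] == NBINF:
                            continue
                        e = WM[i + 1, k - 1] + M1[k, j - 1] + close
                        if e < best:
                            best = e
                V[i, j] = best

            # M1: first base paired, optionally unpaired tail (needs both
            # flanking bases, so only defined away from the ends)
            if 0 < i and j < n - 1:
                m1 = NBINF
                if j - 1 >= i and M1[i, j - 1] != NBINF:
                    m1 = M1[i, j - 1] + ml_u
                if V[i, j] != NBINF:
                    ptij = ptab[s[i], s[j]]
                    b = V[i, j] + ml_b + _at_pen(ptij, term_at)
                    if use_d2:
                        b += mm_multi[ptij, s[i - 1] + 1, s[j + 1] + 1]
                    if b < m1:
                        m1 = b
                M1[i, j] = m1

                wm = M1[i, j]
                if WM[i + 1, j] != NBINF and WM[i + 1, j] + ml_u < wm:
                    wm = WM[i + 1, j] + ml_u
                for k in range(i + 1, j):
                    if WM[i, k - 1] == NBINF or M1[k, j] == NBINF:
                        continue
                    e = WM[i, k - 1] + M1[k, j]
                    if e < wm:
                        wm = e
                WM[i, j] = wm

    # exterior loop over suffixes
    for i in range(n - 1, -1, -1):
        w = W[i + 1]
        for j in range(i + MIN_HAIRPIN + 1, n):
            if V[i, j] == NBINF:
                continue
            pt = ptab[s[i], s[j]]
            e = V[i, j] + _at_pen(pt, term_at)
            if use_d2:
                x = s[i - 1] + 1 if i > 0 else 0
                y = s[j + 1] + 1 if j < n - 1 else 0
                e += mm_ext[pt, x, y]
            e += W[j + 1]
            if e < w:
                w = e
        W[i] = w
    return V, M1, WM, W
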