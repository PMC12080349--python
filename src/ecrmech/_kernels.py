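"""Numba inner loops for the alignment engines and the helix DP.

Sequences are passed as int8 code arrays (A=0, C=1, G=2, T=3, N=4; N never
matches anything, including N).  All kernels are pure score/matrix fills;
tracebacks live in Python where the control flow is easier to audit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18

# global-aligner state indices
M, X, Y, XL, YL, XT, YT = 0, 1, 2, 3, 4, 5, 6


@njit(cache=False)
def gotoh_endgap_fill(a, b, match, mismatch, gopen, gext, eopen, eext):
    """Affine global alignment with separately-priced terminal gaps.

    A gap run of length L costs gopen + L*gext internally; runs lying in
    the leading block (before the first aligned column) or the trailing
    block (after the last aligned column) cost eopen + L*eext instead.
    Returns the (n+1, m+1, 7) state-score array.
    """
    n = a.shape[0]
    m = b.shape[0]
    S = np.full((n + 1, m + 1, 7), NEG)
    # leading gaps
    for i in range(1, n + 1):
        if i == 1:
            S[i, 0, XL] = -(eopen + eext)
        else:
            S[i, 0, XL] = S[i - 1, 0, XL] - eext
    for j in range(1, m + 1):
        if j == 1:
            S[0, j, YL] = -(eopen + eext)
        else:
            S[0, j, YL] = S[0, j - 1, YL] - eext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # interleaved leading runs (all-gap prefix consuming both sequences)
            v = S[i - 1, j, XL] - eext
            w = S[i - 1, j, YL] - (eopen + eext)
            S[i, j, XL] = v if v > w else w
            v = S[i, j - 1, YL] - eext
            w = S[i, j - 1, XL] - (eopen + eext)
            S[i, j, YL] = v if v > w else w
            # aligned column
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            best = S[i - 1, j - 1, M]
            for st in (X, Y, XL, YL):
                if S[i - 1, j - 1, st] > best:
                    best = S[i - 1, j - 1, st]
            if i == 1 and j == 1:
                best = 0.0
            if best > NEG / 2:
                S[i, j, M] = best + sub
            # internal gap in b (consumes a)
            v = S[i - 1, j, M] - (gopen + gext)
            w = S[i - 1, j, Y] - (gopen + gext)
            if w > v:
                v = w
            w = S[i - 1, j, X] - gext
            if w > v:
                v = w
            S[i, j, X] = v
            # internal gap in a (consumes b)
            v = S[i, j - 1, M] - (gopen + gext)
            w = S[i, j - 1, X] - (gopen + gext)
            if w > v:
                v = w
            w = S[i, j - 1, Y] - gext
            if w > v:
                v = w
            S[i, j, Y] = v
            # trailing gap in b
            v = S[i - 1, j, M] - (eopen + eext)
            w = S[i - 1, j, Y] - (eopen + eext)
            if w > v:
                v = w
            w = S[i - 1, j, YT] - (eopen + eext)
            if w > v:
                v = w
            w = S[i - 1, j, XT] - eext
            if w > v:
                v = w
            S[i, j, XT] = v
            # trailing gap in a
            v = S[i, j - 1, M] - (eopen + eext)
            w = S[i, j - 1, X] - (eopen + eext)
            if w > v:
                v = w
            w = S[i, j - 1, XT] - (eopen + eext)
            if w > v:
                v = w
            w = S[i, j - 1, YT] - eext
            if w > v:
                v = w
            S[i, j, YT] = v
    # trailing gaps along the borders (other sequence fully consumed)
    for i in range(1, n + 1):
        v = S[i - 1, m, M] - (eopen + eext) if m > 0 else NEG
        w = S[i - 1, m, Y] - (eopen + eext)
        if w > v:
            v = w
        w = S[i - 1, m, YT] - (eopen + eext)
        if w > v:
            v = w
        w = S[i - 1, m, XT] - eext
        if w > v:
            v = w
        if v > S[i, m, XT]:
            S[i, m, XT] = v
    for j in range(1, m + 1):
        v = S[n, j - 1, M] - (eopen + eext) if n > 0 else NEG
        w = S[n, j - 1, X] - (eopen + eext)
        if w > v:
            v = w
        w = S[n, j - 1, XT] - (eopen + eext)
        if w > v:
            v = w
        w = S[n, j - 1, YT] - eext
        if w > v:
            v = w
        if v > S[n, j, YT]:
            S[n, j, YT] = v
    return S


@njit(cache=False)
def sw_fill(a, b, match, mismatch, gopen, gext):
    """Smith–Waterman fill with affine gaps (length-L gap costs gopen+L*gext).

    Returns (H, E, F): H = best local alignment score ending at (i, j) in
    an aligned column, E = ending in a gap in b, F = gap in a.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i - 1, j] - gext
            w = H[i - 1, j] - (gopen + gext)
            E[i, j] = e if e > w else w
            f = F[i, j - 1] - gext
            w = H[i, j - 1] - (gopen + gext)
            F[i, j] = f if f > w else w
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            prev = H[i - 1, j - 1]
            e2 = E[i - 1, j - 1]
            if e2 > prev:
                prev = e2
            f2 = F[i - 1, j - 1]
            if f2 > prev:
                prev = f2
            h = prev + sub
            if h < sub:
                h = sub
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@njit(cache=False)
def helix_exists(comp, n, m_unpaired, min_loop, min_bp, win_start, win_end, need_window):
    """Early-exit variant of :func:`helix_best`: 1 iff a qualifying chain exists."""
    T = 2 if need_window else 1
    G = m_unpaired + 1
    dp = np.zeros((n, n, G, T), dtype=np.int16)
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            if comp[i, j] == 0:
                continue
            tj = 1 if (need_window and win_start <= j < win_end) else 0
            for g in range(G):
                for t in range(T):
                    best = 0
                    if g == 0 and (T == 1 or t == tj):
                        best = 1
                    for da in range(0, g + 1):
                        i2 = i - 1 - da
                        if i2 < 0:
                            break
                        for db in range(0, g + 1 - da):
                            j2 = j + 1 + db
                            if j2 >= n:
                                break
                            gprev = g - da - db
                            if comp[i2, j2] == 0:
                                continue
                            if T == 1:
                                v = dp[i2, j2, gprev, 0]
                            elif tj == 1:
                                if t == 1:
                                    v = dp[i2, j2, gprev, 0]
                                    w = dp[i2, j2, gprev, 1]
                                    if w > v:
                                        v = w
                                else:
                                    v = 0
                            else:
                                v = dp[i2, j2, gprev, t]
                            if v > 0 and v + 1 > best:
                                best = v + 1
                    dp[i, j, g, t] = best
                    if best >= min_bp and (T == 1 or t == 1):
                        return 1
    return 0


@njit(cache=False)
def helix_best(comp, n, m_unpaired, min_loop, min_bp, win_start, win_end, need_window):
    """Best mismatch-free antiparallel helix within one sequence.

    comp: (n, n) uint8 complementarity matrix (1 where position i can pair
    position j).  A helix is a chain of pairs (i1<i2<...) x (j1>j2>...),
    every pair complementary and separated from its predecessor by at most
    m_unpaired skipped nucleotides in total across the chain (bulges /
    internal loops); every pair satisfies j - i - 1 >= min_loop.  If
    need_window is nonzero, at least one paired j-position must fall in
    [win_start, win_end).

    Returns (best_bp, best_unpaired, maxbp_by_budget, dp): the optimum
    under (max bp, then min unpaired), the max bp achievable at each exact
    unpaired budget 0..m_unpaired, and the full DP table for traceback.
    """
    T = 2 if need_window else 1
    G = m_unpaired + 1
    dp = np.zeros((n, n, G, T), dtype=np.int16)
    maxbp = np.zeros(G, dtype=np.int16)
    best_bp = 0
    best_g = 0
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            if comp[i, j] == 0:
                continue
            tj = 1 if (need_window and win_start <= j < win_end) else 0
            for g in range(G):
                for t in range(T):
                    # base: a single-pair chain uses no unpaired budget and
                    # carries this pair's own window flag
                    best = 0
                    if g == 0 and (T == 1 or t == tj):
                        best = 1
                    # extend a previous pair (i2, j2), i2 < i, j2 > j; the new
                    # window flag is (previous flag OR this pair's flag)
                    for da in range(0, g + 1):
                        i2 = i - 1 - da
                        if i2 < 0:
                            break
                        for db in range(0, g + 1 - da):
                            j2 = j + 1 + db
                            if j2 >= n:
                                break
                            gprev = g - da - db
                            if comp[i2, j2] == 0:
                                continue
                            if T == 1:
                                v = dp[i2, j2, gprev, 0]
                            elif tj == 1:
                                if t == 1:
                                    v = dp[i2, j2, gprev, 0]
                                    w = dp[i2, j2, gprev, 1]
                                    if w > v:
                                        v = w
                                else:
                                    v = 0  # flag can never be 0 after this pair
                            else:
                                v = dp[i2, j2, gprev, t]
                            if v > 0 and v + 1 > best:
                                best = v + 1
                    dp[i, j, g, t] = best
                    if T == 2:
                        ok_t = t == 1
                    else:
                        ok_t = True
                    if best > 0 and ok_t:
                        if best > best_bp or (best == best_bp and g < best_g):
                            best_bp = best
                            best_g = g
                        if best > maxbp[g]:
                            maxbp[g] = best
    return best_bp, best_g, maxbp, dp
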