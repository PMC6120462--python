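"""Compiled inner loops for affine-gap alignment.

Two independent routes to the same optimum live here:

* :func:`affine_dp` — the three-state (match / gap-in-subject / gap-in-query)
  dynamic programme used by the package, on a precomputed cell-score matrix,
  so the same kernel serves residue-residue and profile-profile alignment.
* :func:`brute_force_global` / :func:`brute_force_local` — exhaustive
  enumeration of every alignment path, used only as a test oracle. They share
  no recurrence with the DP: each path is walked explicitly and scored as it
  is extended.

Gap convention: a gap run of length L costs ``gap_open + (L-1)*gap_extend``
(both negative), i.e. a single-residue gap costs ``gap_open``. Switching
directly from a gap in one sequence to a gap in the other opens a new gap.

Pointer codes in the traceback matrices: 0 = came from M (diagonal),
1 = came from X (gap in subject, consumes query), 2 = came from Y
(gap in query, consumes subject), 3 = alignment start.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30

M_STATE, X_STATE, Y_STATE, START = 0, 1, 2, 3


@njit(cache=True)
def affine_dp(S, gap_open, gap_extend, local):
    """Fill the affine-gap DP on cell-score matrix S (m x n).

    Returns (best_score, end_i, end_j, end_state, ptrM, ptrX, ptrY).
    Tie-breaking prefers the diagonal (M), then X, then Y, which fixes the
    traceback deterministically.
    """
    m, n = S.shape
    M = np.full((m + 1, n + 1), NEG_INF)
    X = np.full((m + 1, n + 1), NEG_INF)
    Y = np.full((m + 1, n + 1), NEG_INF)
    ptrM = np.full((m + 1, n + 1), START, dtype=np.int8)
    ptrX = np.full((m + 1, n + 1), START, dtype=np.int8)
    ptrY = np.full((m + 1, n + 1), START, dtype=np.int8)

    M[0, 0] = 0.0
    if not local:
        for i in range(1, m + 1):
            X[i, 0] = gap_open + (i - 1) * gap_extend
            ptrX[i, 0] = X_STATE if i > 1 else M_STATE
        for j in range(1, n + 1):
            Y[0, j] = gap_open + (j - 1) * gap_extend
            ptrY[0, j] = Y_STATE if j > 1 else M_STATE

    best = 0.0
    bi, bj, bs = 0, 0, M_STATE
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # M: consume both
            prev_m = M[i - 1, j - 1]
            prev_x = X[i - 1, j - 1]
            prev_y = Y[i - 1, j - 1]
            bestprev = prev_m
            code = M_STATE
            if prev_x > bestprev:
                bestprev = prev_x
                code = X_STATE
            if prev_y > bestprev:
                bestprev = prev_y
                code = Y_STATE
            val = bestprev + S[i - 1, j - 1]
            if local:
                if val < S[i - 1, j - 1]:
                    # start fresh local alignment at this cell
                    val = S[i - 1, j - 1]
                    code = START
                if val < 0.0:
                    val = NEG_INF
            M[i, j] = val
            ptrM[i, j] = code

            # X: gap in subject (consume query residue i)
            vm = M[i - 1, j] + gap_open
            vx = X[i - 1, j] + gap_extend
            vy = Y[i - 1, j] + gap_open
            bestprev = vm
            code = M_STATE
            if vx > bestprev:
                bestprev = vx
                code = X_STATE
            if vy > bestprev:
                bestprev = vy
                code = Y_STATE
            X[i, j] = bestprev
            ptrX[i, j] = code

            # Y: gap in query (consume subject residue j)
            vm = M[i, j - 1] + gap_open
            vx = X[i, j - 1] + gap_open
            vy = Y[i, j - 1] + gap_extend
            bestprev = vm
            code = M_STATE
            if vx > bestprev:
                bestprev = vx
                code = X_STATE
            if vy > bestprev:
                bestprev = vy
                code = Y_STATE
            Y[i, j] = bestprev
            ptrY[i, j] = code

            if local and M[i, j] > best:
                best = M[i, j]
                bi, bj, bs = i, j, M_STATE

    if local:
        return best, bi, bj, bs, ptrM, ptrX, ptrY

    best = M[m, n]
    bs = M_STATE
    if X[m, n] > best:
        best = X[m, n]
        bs = X_STATE
    if Y[m, n] > best:
        best = Y[m, n]
        bs = Y_STATE
    return best, m, n, bs, ptrM, ptrX, ptrY


@njit(cache=True)
def brute_force_global(S, gap_open, gap_extend):
    """Best global alignment score by explicit enumeration of all paths.

    Iterative depth-first walk over every monotone path from (0,0) to (m,n);
    no subproblem reuse, so it is an oracle independent of the DP.
    """
    m, n = S.shape
    cap = 4 * (m + n + 2) + 8
    si = np.empty(cap, dtype=np.int64)
    sj = np.empty(cap, dtype=np.int64)
    st = np.empty(cap, dtype=np.int64)
    sc = np.empty(cap, dtype=np.float64)
    top = 0
    si[top], sj[top], st[top], sc[top] = 0, 0, START, 0.0
    top += 1
    best = NEG_INF
    while top > 0:
        top -= 1
        i, j, state, score = si[top], sj[top], st[top], sc[top]
        if i == m and j == n:
            if score > best:
                best = score
            continue
        if top + 3 >= cap:
            # grow stack
            cap2 = cap * 2
            si2 = np.empty(cap2, dtype=np.int64)
            sj2 = np.empty(cap2, dtype=np.int64)
            st2 = np.empty(cap2, dtype=np.int64)
            sc2 = np.empty(cap2, dtype=np.float64)
            si2[:top] = si[:top]
            sj2[:top] = sj[:top]
            st2[:top] = st[:top]
            sc2[:top] = sc[:top]
            si, sj, st, sc, cap = si2, sj2, st2, sc2, cap2
        if i < m and j < n:
            si[top], sj[top], st[top] = i + 1, j + 1, M_STATE
            sc[top] = score + S[i, j]
            top += 1
        if i < m:
            pen = gap_extend if state == X_STATE else gap_open
            si[top], sj[top], st[top] = i + 1, j, X_STATE
            sc[top] = score + pen
            top += 1
        if j < n:
            pen = gap_extend if state == Y_STATE else gap_open
            si[top], sj[top], st[top] = i, j + 1, Y_STATE
            sc[top] = score + pen
            top += 1
    return best


@njit(cache=True)
def brute_force_local(S, gap_open, gap_extend):
    """Best local alignment score by explicit enumeration.

    An optimal local alignment under negative gap costs starts and ends with
    an aligned residue pair, so every path beginning with a diagonal step is
    enumerated from every start cell and the score is recorded after each
    diagonal step. The empty alignment scores 0.
    """
    m, n = S.shape
    best = 0.0
    cap = 4 * (m + n + 2) + 8
    si = np.empty(cap, dtype=np.int64)
    sj = np.empty(cap, dtype=np.int64)
    st = np.empty(cap, dtype=np.int64)
    sc = np.empty(cap, dtype=np.float64)
    for i0 in range(m):
        for j0 in range(n):
            top = 0
            # first step is forced diagonal
            si[top], sj[top], st[top] = i0 + 1, j0 + 1, M_STATE
            sc[top] = S[i0, j0]
            top += 1
            while top > 0:
                top -= 1
                i, j, state, score = si[top], sj[top], st[top], sc[top]
                if state == M_STATE and score > best:
                    best = score
                if top + 3 >= cap:
                    cap2 = cap * 2
                    si2 = np.empty(cap2, dtype=np.int64)
                    sj2 = np.empty(cap2, dtype=np.int64)
                    st2 = np.empty(cap2, dtype=np.int64)
                    sc2 = np.empty(cap2, dtype=np.float64)
                    si2[:top] = si[:top]
                    sj2[:top] = sj[:top]
                    st2[:top] = st[:top]
                    sc2[:top] = sc[:top]
                    si, sj, st, sc, cap = si2, sj2, st2, sc2, cap2
                if i < m and j < n:
                    si[top], sj[top], st[top] = i + 1, j + 1, M_STATE
                    sc[top] = score + S[i, j]
                    top += 1
                if i < m:
                    pen = gap_extend if state == X_STATE else gap_open
                    si[top], sj[top], st[top] = i + 1, j, X_STATE
                    sc[top] = score + pen
                    top += 1
                if j < n:
                    pen = gap_extend if state == Y_STATE else gap_open
                    si[top], sj[top], st[top] = i, j + 1, Y_STATE
                    sc[top] = score + pen
                    top += 1
    return best


def traceback(end_i, end_j, end_state, ptrM, ptrX, ptrY, local):
    """Walk the pointer matrices back to the alignment start.

    Returns the list of (i, j) column pairs, 1-based, with 0 marking a gap.
    """
    cols: list[tuple[int, int]] = []
    i, j, state = end_i, end_j, end_state
    while True:
        if state == M_STATE:
            if i == 0 and j == 0:
                break
            code = ptrM[i, j]
            cols.append((i, j))
            i -= 1
            j -= 1
            if local and code == START:
                break
            state = code
        elif state == X_STATE:
            code = ptrX[i, j]
            cols.append((i, 0))
            i -= 1
            state = code
        elif state == Y_STATE:
            code = ptrY[i, j]
            cols.append((0, j))
            j -= 1
            state = code
        else:  # START
            break
        if i == 0 and j == 0 and state == M_STATE:
            break
    cols.reverse()
    return cols
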