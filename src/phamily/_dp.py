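"""Numba dynamic-programming kernels for the align module.

Affine-gap convention: a gap of length L costs ``gap_open + L * gap_extend``
(the BLAST convention: open=11/extend=1 means a length-1 gap costs 12).

Traceback op codes (query = rows, subject = columns):
  0 = aligned pair (consumes one of each)
  1 = insertion (gap in subject, consumes query)
  2 = deletion  (gap in query, consumes subject)

Determinism: among co-optimal end cells the first in row-major order wins;
the traceback prefers starting fresh over extending a zero-scoring prefix
(local mode), and aligned pairs over insertions over deletions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 9)


@njit(cache=True)
def align_seq(q, s, sub, go, ge, local):
    """Affine-gap alignment of two encoded sequences.

    local=True: Smith-Waterman; local=False: end-to-end Needleman-Wunsch.
    Returns (score, qstart, sstart, ops array).

    Values are kept in rolling 1-D arrays; the traceback is one packed int8
    matrix (bits 0-1: M predecessor, 2-3: X, 4-5: Y).
    """
    n, m = q.shape[0], s.shape[0]
    prevM = np.empty(m + 1, dtype=np.int64)
    prevX = np.empty(m + 1, dtype=np.int64)
    curM = np.empty(m + 1, dtype=np.int64)
    curX = np.empty(m + 1, dtype=np.int64)
    tb = np.zeros((n + 1, m + 1), dtype=np.uint8)
    # boundary row i=0
    for j in range(m + 1):
        prevX[j] = NEG
        prevM[j] = 0 if (local or j == 0) else NEG
    prevY_row = np.empty(m + 1, dtype=np.int64)
    if local:
        for j in range(m + 1):
            prevY_row[j] = NEG
    else:
        prevY_row[0] = NEG
        for j in range(1, m + 1):
            prevY_row[j] = -(go + j * ge)
            tb[0, j] = (2 if j > 1 else 0) << 4
    best = 0
    bi = 0
    bj = 0
    bst = 0
    curY_row = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        qi = q[i - 1]
        subrow = sub[qi]
        # j = 0 boundary
        if local:
            curM[0] = 0
            curX[0] = NEG
        else:
            curM[0] = NEG
            curX[0] = -(go + i * ge)
            tb[i, 0] = (1 if i > 1 else 0) << 2
        curY_row[0] = NEG
        diagM = prevM[0]
        diagX = prevX[0]
        diagY = prevY_row[0]
        mleft = curM[0]
        yleft = curY_row[0]
        for j in range(1, m + 1):
            sc = subrow[s[j - 1]]
            # enter/extend M
            vm = 0 if local else NEG
            t = 3
            if diagM > vm:
                vm = diagM
                t = 0
            if diagX > vm:
                vm = diagX
                t = 1
            if diagY > vm:
                vm = diagY
                t = 2
            vm += sc
            upM = prevM[j]
            upX = prevX[j]
            # X: gap in subject (consume query)
            vo = upM - (go + ge)
            ve = upX - ge
            if vo >= ve:
                vx = vo
                tx = 0
            else:
                vx = ve
                tx = 1
            # Y: gap in query (consume subject)
            vo = mleft - (go + ge)
            ve = yleft - ge
            if vo >= ve:
                vy = vo
                ty = 0
            else:
                vy = ve
                ty = 2
            tb[i, j] = t | (tx << 2) | (ty << 4)
            diagM = upM
            diagX = upX
            diagY = prevY_row[j]
            curM[j] = vm
            curX[j] = vx
            curY_row[j] = vy
            mleft = vm
            yleft = vy
            if local and vm > best:
                best = vm
                bi = i
                bj = j
        tmp = prevM
        prevM = curM
        curM = tmp
        tmp = prevX
        prevX = curX
        curX = tmp
        tmp = prevY_row
        prevY_row = curY_row
        curY_row = tmp
    if not local:
        best = prevM[m]
        bst = 0
        if prevX[m] > best:
            best = prevX[m]
            bst = 1
        if prevY_row[m] > best:
            best = prevY_row[m]
            bst = 2
        bi = n
        bj = m
    # traceback
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j, st = bi, bj, bst
    if local and best == 0:
        return 0, 0, 0, ops[:0]
    while i > 0 or j > 0:
        cell = tb[i, j]
        if st == 0:
            prev = cell & 3
            ops[k] = 0
            k += 1
            i -= 1
            j -= 1
            if prev == 3:
                break
            st = prev
        elif st == 1:
            prev = (cell >> 2) & 3
            ops[k] = 1
            k += 1
            i -= 1
            st = prev
        else:
            prev = (cell >> 4) & 3
            ops[k] = 2
            k += 1
            j -= 1
            st = prev
    return best, i, j, ops[:k][::-1]


@njit(cache=True)
def local_score_only(q, s, sub, go, ge):
    """Smith-Waterman score without traceback (prefilter for all-vs-all)."""
    n, m = q.shape[0], s.shape[0]
    prevM = np.zeros(m + 1, dtype=np.int64)
    prevX = np.full(m + 1, NEG, dtype=np.int64)
    curM = np.zeros(m + 1, dtype=np.int64)
    curX = np.empty(m + 1, dtype=np.int64)
    prevY = np.full(m + 1, NEG, dtype=np.int64)
    curY = np.empty(m + 1, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        subrow = sub[qi]
        curM[0] = 0
        curX[0] = NEG
        curY[0] = NEG
        diagM = prevM[0]
        diagX = prevX[0]
        diagY = prevY[0]
        mleft = 0
        yleft = NEG
        for j in range(1, m + 1):
            sc = subrow[s[j - 1]]
            vm = 0
            if diagM > vm:
                vm = diagM
            if diagX > vm:
                vm = diagX
            if diagY > vm:
                vm = diagY
            vm += sc
            upM = prevM[j]
            upX = prevX[j]
            vo = upM - (go + ge)
            ve = upX - ge
            vx = vo if vo >= ve else ve
            vo = mleft - (go + ge)
            ve = yleft - ge
            vy = vo if vo >= ve else ve
            diagM = upM
            diagX = upX
            diagY = prevY[j]
            curM[j] = vm
            curX[j] = vx
            curY[j] = vy
            mleft = vm
            yleft = vy
            if vm > best:
                best = vm
        tmp = prevM
        prevM = curM
        curM = tmp
        tmp = prevX
        prevX = curX
        curX = tmp
        tmp = prevY
        prevY = curY
        curY = tmp
    return best


@njit(cache=True)
def align_pssm(q, psm, go, ge):
    """Local alignment of an encoded protein against a PSSM (float scores).

    psm has shape (profile_length, alphabet_size); rows are profile columns.
    The profile plays the subject role.  Returns (score, qstart, pstart, ops).
    """
    n = q.shape[0]
    m = psm.shape[0]
    BAD = -1e18
    M = np.full((n + 1, m + 1), BAD)
    X = np.full((n + 1, m + 1), BAD)
    Y = np.full((n + 1, m + 1), BAD)
    tM = np.full((n + 1, m + 1), 3, dtype=np.int8)
    tX = np.full((n + 1, m + 1), 3, dtype=np.int8)
    tY = np.full((n + 1, m + 1), 3, dtype=np.int8)
    for i in range(n + 1):
        M[i, 0] = 0.0
    for j in range(m + 1):
        M[0, j] = 0.0
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            sc = psm[j - 1, qi]
            vm = 0.0
            tb = np.int8(3)
            if M[i - 1, j - 1] > vm:
                vm = M[i - 1, j - 1]
                tb = np.int8(0)
            if X[i - 1, j - 1] > vm:
                vm = X[i - 1, j - 1]
                tb = np.int8(1)
            if Y[i - 1, j - 1] > vm:
                vm = Y[i - 1, j - 1]
                tb = np.int8(2)
            M[i, j] = vm + sc
            tM[i, j] = tb
            vo = M[i - 1, j] - (go + ge)
            ve = X[i - 1, j] - ge
            if vo >= ve:
                X[i, j] = vo
                tX[i, j] = 0
            else:
                X[i, j] = ve
                tX[i, j] = 1
            vo = M[i, j - 1] - (go + ge)
            ve = Y[i, j - 1] - ge
            if vo >= ve:
                Y[i, j] = vo
                tY[i, j] = 0
            else:
                Y[i, j] = ve
                tY[i, j] = 2
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j, st = bi, bj, 0
    if best <= 0.0:
        return 0.0, 0, 0, ops[:0]
    while i > 0 or j > 0:
        if st == 0:
            prev = tM[i, j]
            ops[k] = 0
            k += 1
            i -= 1
            j -= 1
            if prev == 3:
                break
            st = prev
        elif st == 1:
            prev = tX[i, j]
            ops[k] = 1
            k += 1
            i -= 1
            st = prev
        else:
            prev = tY[i, j]
            ops[k] = 2
            k += 1
            j -= 1
            st = prev
    return best, i, j, ops[:k][::-1]


@njit(cache=True)
def extend_gapless(q, s, q0, s0, length, match, mismatch, xdrop):
    """Extend an exact seed q[q0:q0+length) == s[s0:s0+length) without gaps.

    Returns (qstart, sstart, seg_len, matches) of the x-drop-extended segment.
    """
    n, m = q.shape[0], s.shape[0]
    score = length * match
    best = score
    qi = q0 + length
    si = s0 + length
    best_right = qi
    while qi < n and si < m:
        score += match if q[qi] == s[si] else mismatch
        qi += 1
        si += 1
        if score > best:
            best = score
            best_right = qi
        if best - score > xdrop:
            break
    cur = best
    score = best
    qi = q0
    si = s0
    best_left = q0
    while qi > 0 and si > 0:
        qi -= 1
        si -= 1
        cur += match if q[qi] == s[si] else mismatch
        if cur > score:
            score = cur
            best_left = qi
        if score - cur > xdrop:
            break
    seg_len = best_right - best_left
    matches = 0
    off = s0 - q0
    for t in range(best_left, best_right):
        if q[t] == s[t + off]:
            matches += 1
    return best_left, best_left + off, seg_len, matches
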