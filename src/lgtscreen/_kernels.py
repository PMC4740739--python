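"""Numba kernels: the DUST sweep, ungapped X-drop extension, and banded
affine Smith-Waterman with traceback.

Gap convention throughout: a gap of length L costs ``gap_open + L * gap_extend``
(both negative), i.e. ``gap_open`` is the opening surcharge.  Base codes are
0..3 for ACGT and 4 for N; an N never matches anything, including another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -(2 ** 30)


@njit(cache=False)
def dust_sweep(trip, w, threshold):
    """For each window start i over the triplet array, the furthest masked end.

    ``trip`` holds triplet codes (0..63) of one N-free segment; a window
    starting at base i covering k triplets (bases i .. i+k+1, length k+2 <= w)
    is low-complexity when sum_t c_t(c_t-1)/2 / (k-1) > threshold.  Returns
    ``end`` where end[i] is the largest i+k+2 over qualifying k (0 if none).
    """
    m = trip.shape[0]
    end = np.zeros(m, np.int64)
    counts = np.zeros(64, np.int64)
    for i in range(m):
        for t in range(64):
            counts[t] = 0
        pairs = 0
        kmax = min(m - i, w - 2)
        best = 0
        for k in range(1, kmax + 1):
            t = trip[i + k - 1]
            pairs += counts[t]
            counts[t] += 1
            if k >= 2 and pairs / (k - 1) > threshold:
                best = i + k + 2
        end[i] = best
    return end


@njit(cache=False)
def ungapped_extend(q, s, qpos, spos, k, match, mismatch, xdrop):
    """X-drop ungapped extension of an exact k-mer seed at (qpos, spos).

    Returns (q0, q1, score): the maximal-scoring ungapped segment through the
    seed, half-open on the query; subject coordinates follow the diagonal.
    """
    nq = q.shape[0]
    ns = s.shape[0]
    score = k * match
    # right
    best_r = 0
    run = 0
    i = qpos + k
    j = spos + k
    right = 0
    while i < nq and j < ns:
        if q[i] < 4 and q[i] == s[j]:
            run += match
        else:
            run += mismatch
        if run > best_r:
            best_r = run
            right = i - (qpos + k) + 1
        if best_r - run > xdrop:
            break
        i += 1
        j += 1
    # left
    best_l = 0
    run = 0
    i = qpos - 1
    j = spos - 1
    left = 0
    while i >= 0 and j >= 0:
        if q[i] < 4 and q[i] == s[j]:
            run += match
        else:
            run += mismatch
        if run > best_l:
            best_l = run
            left = qpos - i
        if best_l - run > xdrop:
            break
        i -= 1
        j -= 1
    return qpos - left, qpos + k + right, score + best_l + best_r


@njit(cache=False)
def banded_sw(q, s, diag_lo, diag_hi, match, mismatch, gap_open, gap_extend):
    """Affine-gap local alignment restricted to diagonals j - i in [diag_lo, diag_hi].

    Returns (score, q0, q1, s0, s1, n_match, n_mismatch, gap_opens, aln_len)
    with half-open coordinates; score 0 means no positive-scoring alignment.
    Setting the diagonal range to cover [-len(q), len(s)] makes this the full
    Smith-Waterman matrix.
    """
    nq = q.shape[0]
    ns = s.shape[0]
    B = diag_hi - diag_lo + 1
    H = np.full((nq + 1, B), NEG_INF, np.int32)
    E = np.full((nq + 1, B), NEG_INF, np.int32)
    F = np.full((nq + 1, B), NEG_INF, np.int32)
    ptrH = np.zeros((nq + 1, B), np.uint8)   # 0 stop, 1 diag, 2 from E, 3 from F
    ptrE = np.zeros((nq + 1, B), np.uint8)   # 1 opened from H, 0 extended
    ptrF = np.zeros((nq + 1, B), np.uint8)

    best = 0
    bi = 0
    bjj = 0
    for i in range(0, nq + 1):
        for jj in range(B):
            j = i + diag_lo + jj
            if j < 0 or j > ns:
                continue
            if i == 0 or j == 0:
                H[i, jj] = 0
                continue
            # E: gap in query (consumes s[j-1]); predecessor at (i, j-1) -> jj-1
            e = NEG_INF
            if jj - 1 >= 0:
                open_e = H[i, jj - 1] + gap_open + gap_extend
                ext_e = E[i, jj - 1] + gap_extend
                if open_e >= ext_e:
                    e = open_e
                    ptrE[i, jj] = 1
                else:
                    e = ext_e
                    ptrE[i, jj] = 0
            E[i, jj] = e
            # F: gap in subject (consumes q[i-1]); predecessor at (i-1, j) -> jj+1
            f = NEG_INF
            if jj + 1 < B:
                open_f = H[i - 1, jj + 1] + gap_open + gap_extend
                ext_f = F[i - 1, jj + 1] + gap_extend
                if open_f >= ext_f:
                    f = open_f
                    ptrF[i, jj] = 1
                else:
                    f = ext_f
                    ptrF[i, jj] = 0
            F[i, jj] = f
            # H
            sub = mismatch
            if q[i - 1] < 4 and q[i - 1] == s[j - 1]:
                sub = match
            diag = H[i - 1, jj] + sub  # (i-1, j-1) is same jj
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            H[i, jj] = h
            ptrH[i, jj] = p
            if h > best:
                best = h
                bi = i
                bjj = jj
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    jj = bjj
    j = i + diag_lo + jj
    q1 = i
    s1 = j
    n_match = 0
    n_mismatch = 0
    gap_opens = 0
    aln_len = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptrH[i, jj]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] < 4 and q[i - 1] == s[j - 1]:
                    n_match += 1
                else:
                    n_mismatch += 1
                aln_len += 1
                i -= 1
                j -= 1
                # jj unchanged
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # E consumes s[j-1]
            opened = ptrE[i, jj]
            aln_len += 1
            j -= 1
            jj -= 1
            if opened == 1:
                gap_opens += 1
                state = 0
        else:  # F consumes q[i-1]
            opened = ptrF[i, jj]
            aln_len += 1
            i -= 1
            jj += 1
            if opened == 1:
                gap_opens += 1
                state = 0
    q0 = i
    s0 = j
    return best, q0, q1, s0, s1, n_match, n_mismatch, gap_opens, aln_len
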