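"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: the DUST enumerator
recomputes every window from a prefix-count matrix, and the Smith-Waterman
oracle is a naive full dynamic program.  Both are the normative definitions
the production implementations must match.
"""

from __future__ import annotations

import numpy as np

_TRIPLET = {b: i for i, b in enumerate("ACGT")}


def dust_oracle(seq: str, window: int = 64, level: int = 20) -> list[tuple[int, int]]:
    """Exhaustive DUST: union of every interval of length <= window whose
    triplet score sum c_t(c_t-1)/2 / (k-1) strictly exceeds level/10."""
    n = len(seq)
    masked = np.zeros(n, dtype=bool)
    threshold = level / 10.0
    # split into N-free segments
    seg_start = None
    segments = []
    for i, ch in enumerate(seq + "N"):
        if ch.upper() in "ACGT":
            if seg_start is None:
                seg_start = i
        else:
            if seg_start is not None:
                segments.append((seg_start, seq[seg_start:i]))
                seg_start = None
    for offset, seg in segments:
        m = len(seg) - 2
        if m < 2:
            continue
        trip = np.array([(_TRIPLET[seg[i].upper()] << 4)
                         | (_TRIPLET[seg[i + 1].upper()] << 2)
                         | _TRIPLET[seg[i + 2].upper()] for i in range(m)])
        # prefix counts: C[j, t] = count of triplet t among trip[:j]
        C = np.zeros((m + 1, 64), dtype=np.int64)
        for j in range(m):
            C[j + 1] = C[j]
            C[j + 1, trip[j]] += 1
        for i in range(m):
            kmax = min(m - i, window - 2)
            counts = C[i + 2: i + kmax + 1] - C[i]   # rows: k = 2..kmax
            if len(counts) == 0:
                continue
            pairs = (counts * (counts - 1) // 2).sum(axis=1)
            ks = np.arange(2, kmax + 1)
            hot = pairs / (ks - 1) > threshold
            if hot.any():
                kbest = ks[np.nonzero(hot)[0][-1]]
                masked[offset + i: offset + i + kbest + 2] = True
    # maximal runs
    out = []
    i = 0
    while i < n:
        if masked[i]:
            j = i
            while j < n and masked[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def sw_oracle(a: str, b: str, match: int = 1, mismatch: int = -2,
              gap_open: int = -5, gap_extend: int = -2) -> int:
    """Naive affine-gap local alignment optimum (gap L costs open + L*ext)."""
    na, nb = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (nb + 1) for _ in range(na + 1)]
    E = [[NEG] * (nb + 1) for _ in range(na + 1)]
    F = [[NEG] * (nb + 1) for _ in range(na + 1)]
    best = 0
    au = a.upper()
    bu = b.upper()
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend,
                          H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend,
                          H[i - 1][j] + gap_open + gap_extend)
            ai, bj = au[i - 1], bu[j - 1]
            s = match if (ai == bj and ai in "ACGT") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
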