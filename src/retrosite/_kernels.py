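"""Numba dynamic-programming kernels for local alignment.

Affine gap convention: a gap of length L costs ``gap_open + (L-1) *
gap_extend`` (the opening base pays ``gap_open``).  Pointer bytes pack the
traceback: bits 0-1 give the H-state move (0 stop, 1 diagonal, 2 left/E,
3 up/F); bit 2 marks an E cell opened from H; bit 3 marks an F cell
opened from H.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(2**30))


@njit(cache=True)
def sw_full(a, b, match, mismatch, gap_open, gap_extend):
    """Full Smith-Waterman. Returns (best score, end_i, end_j, ptr)."""
    n = a.shape[0]
    m = b.shape[0]
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    hp = np.zeros(m + 1, dtype=np.int32)
    fp = np.full(m + 1, NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        hc = np.zeros(m + 1, dtype=np.int32)
        fc = np.full(m + 1, NEG, dtype=np.int32)
        e = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            p = np.uint8(0)
            e_open = hc[j - 1] + gap_open
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e = e_open
                p |= np.uint8(4)
            else:
                e = e_ext
            f_open = hp[j] + gap_open
            f_ext = fp[j] + gap_extend
            if f_open >= f_ext:
                f = f_open
                p |= np.uint8(8)
            else:
                f = f_ext
            fc[j] = f
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            diag = hp[j - 1] + s
            h = np.int32(0)
            d = np.uint8(0)
            if diag > h:
                h = diag
                d = np.uint8(1)
            if e > h:
                h = e
                d = np.uint8(2)
            if f > h:
                h = f
                d = np.uint8(3)
            hc[j] = h
            ptr[i, j] = p | d
            if h > best:
                best = h
                bi = i
                bj = j
        hp = hc
        fp = fc
    return best, bi, bj, ptr


@njit(cache=True)
def sw_banded(a, b, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Banded Smith-Waterman restricted to diagonals dlo <= j-i <= dhi.

    Returns (best score, end_i, end_jb, ptr) with band column
    ``jb = j - i - dlo``.
    """
    n = a.shape[0]
    m = b.shape[0]
    w = dhi - dlo + 1
    ptr = np.zeros((n + 1, w), dtype=np.uint8)
    # row 0: any in-band cell may start an alignment
    hp = np.zeros(w, dtype=np.int32)
    fp = np.full(w, NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bjb = 0
    for i in range(1, n + 1):
        hc = np.full(w, NEG, dtype=np.int32)
        fc = np.full(w, NEG, dtype=np.int32)
        e = NEG
        ai = a[i - 1]
        jb_lo = 0
        if i + dlo < 1:
            jb_lo = 1 - (i + dlo)
        jb_hi = w - 1
        if i + dlo + jb_hi > m:
            jb_hi = m - (i + dlo)
        for jb in range(jb_lo, jb_hi + 1):
            j = i + dlo + jb
            p = np.uint8(0)
            if jb > 0:
                hl = hc[jb - 1]
            else:
                hl = NEG
            e_open = hl + gap_open
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e = e_open
                p |= np.uint8(4)
            else:
                e = e_ext
            if jb + 1 < w:
                f_open = hp[jb + 1] + gap_open
                f_ext = fp[jb + 1] + gap_extend
            else:
                f_open = NEG
                f_ext = NEG
            if f_open >= f_ext:
                f = f_open
                p |= np.uint8(8)
            else:
                f = f_ext
            fc[jb] = f
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            diag = hp[jb] + s
            h = np.int32(0)
            d = np.uint8(0)
            if diag > h:
                h = diag
                d = np.uint8(1)
            if e > h:
                h = e
                d = np.uint8(2)
            if f > h:
                h = f
                d = np.uint8(3)
            hc[jb] = h
            ptr[i, jb] = p | d
            if h > best:
                best = h
                bi = i
                bjb = jb
        hp = hc
        fp = fc
    return best, bi, bjb, ptr
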