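"""Numba kernel for exact affine-gap Smith-Waterman local alignment.

Scoring convention: +match for an identical non-N base pair, -mismatch
otherwise (N never matches anything, including N); a gap of length k costs
open + k*extend (the first gap base pays both the open and the extend
penalty).  Traceback is deterministic: the best cell is the first maximum
in row-major order (smallest query index, then smallest target index), and
ties among moves prefer diagonal, then vertical (gap in target, 'I'), then
horizontal (gap in query, 'D').
"""

from __future__ import annotations

import numpy as np
from numba import njit

# cigar op codes
OP_M = 0  # consumes query + target
OP_I = 1  # consumes query only (insertion relative to target)
OP_D = 2  # consumes target only (deletion relative to target)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    """Encode a base string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return np.frombuffer(
        seq.encode("ascii").translate(_ENCODE_TABLE), dtype=np.uint8
    ).copy()


_ENCODE_TABLE = bytes(
    _BASE_CODE.get(chr(c), 4) for c in range(256)
)


@njit(cache=True)
def _sw_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = t.shape[0]
    NEG = -(1 << 30)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in query (horizontal)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in target (vertical)
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] - gap_extend
            ho = H[i, j - 1] - go
            if ho > e:
                e = ho
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            vo = H[i - 1, j] - go
            if vo > f:
                f = vo
            F[i, j] = f
            if qi == t[j - 1] and qi != 4:
                sub = match
            else:
                sub = -mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _sw_traceback(q, t, H, E, F, bi, bj, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    # returns ops (reversed order), q_start, t_start
    ops = np.empty(q.shape[0] + t.shape[0], dtype=np.uint8)
    nops = 0
    i = bi
    j = bj
    go = gap_open + gap_extend
    state = 0  # 0 = H, 1 = E (horizontal), 2 = F (vertical)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if q[i - 1] == t[j - 1] and q[i - 1] != 4:
                sub = match
            else:
                sub = -mismatch
            if h == H[i - 1, j - 1] + sub:
                ops[nops] = OP_M
                nops += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 2:  # vertical: gap in target, consumes query
            ops[nops] = OP_I
            nops += 1
            f = F[i, j]
            if f == H[i - 1, j] - go:
                state = 0
            i -= 1
        else:  # horizontal: gap in query, consumes target
            ops[nops] = OP_D
            nops += 1
            e = E[i, j]
            if e == H[i, j - 1] - go:
                state = 0
            j -= 1
    return ops[:nops], i, j


def sw_align(q: np.ndarray, t: np.ndarray, match: int, mismatch: int,
             gap_open: int, gap_extend: int):
    """Optimal local alignment of encoded q against encoded t.

    Returns (score, q_start, q_end, t_start, t_end, ops) with half-open
    coordinates and ops a list of (op_char, length) pairs; score 0 means
    no positive-scoring local alignment (empty ops).
    """
    H, E, F, best, bi, bj = _sw_fill(q, t, match, mismatch, gap_open, gap_extend)
    if best <= 0:
        return 0, 0, 0, 0, 0, []
    ops_rev, qs, ts = _sw_traceback(
        q, t, H, E, F, bi, bj, match, mismatch, gap_open, gap_extend
    )
    # compress reversed op codes into (char, length) run list in forward order
    ops: list[tuple[str, int]] = []
    chars = "MID"
    for k in range(len(ops_rev) - 1, -1, -1):
        c = chars[ops_rev[k]]
        if ops and ops[-1][0] == c:
            ops[-1] = (c, ops[-1][1] + 1)
        else:
            ops.append((c, 1))
    return int(best), int(qs), int(bi), int(ts), int(bj), ops
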