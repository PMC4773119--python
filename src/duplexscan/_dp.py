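"""Numba kernels for affine-gap local alignment.

The duplex problem is transformed to an ordinary local alignment of the query
against the reverse complement of the target, so these kernels know nothing
about base pairing: they receive integer-encoded sequences and a substitution
matrix. Encoding: A=0 C=1 G=2 T=3 N=4, plus 5 as the masking sentinel used by
the iterated search (scored so low it can never be crossed).

DP recurrences (Gotoh), with gap run cost gap_open + g * gap_extend:

    M[i,j]  = sub(q[i], t[j]) + max(0, M[i-1,j-1], Ix[i-1,j-1], Iy[i-1,j-1])
    Ix[i,j] = max(M[i-1,j] + go + ge, Ix[i-1,j] + ge)    # gap in t
    Iy[i,j] = max(M[i,j-1] + go + ge, Iy[i,j-1] + ge)    # gap in q

Local alignments start and end in pairing (M) columns.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**7))

N_SYMBOLS = 6  # A C G T N + mask sentinel
MASK_CODE = 5

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


@njit(cache=True)
def fill_matrices(q, t, sub, go, ge, M, Ix, Iy):  # pragma: no cover - numba
    nq = q.shape[0]
    nt = t.shape[0]
    for j in range(nt + 1):
        M[0, j] = 0
        Ix[0, j] = NEG
        Iy[0, j] = NEG
    best = 0
    for i in range(1, nq + 1):
        M[i, 0] = 0
        Ix[i, 0] = NEG
        Iy[i, 0] = NEG
        qi = q[i - 1]
        for j in range(1, nt + 1):
            prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
            if prev < 0:
                prev = 0
            m = sub[qi, t[j - 1]] + prev
            M[i, j] = m
            a = M[i - 1, j] + go + ge
            b = Ix[i - 1, j] + ge
            Ix[i, j] = a if a > b else b
            a = M[i, j - 1] + go + ge
            b = Iy[i, j - 1] + ge
            Iy[i, j] = a if a > b else b
            if m > best:
                best = m
    return best


@njit(cache=True)
def best_score_only(q, t, sub, go, ge):  # pragma: no cover - numba
    """Best local score with O(nt) memory (for calibration nulls)."""
    nq = q.shape[0]
    nt = t.shape[0]
    m_prev = np.zeros(nt + 1, dtype=np.int32)
    ix_prev = np.full(nt + 1, NEG, dtype=np.int32)
    iy_prev = np.full(nt + 1, NEG, dtype=np.int32)
    m_cur = np.zeros(nt + 1, dtype=np.int32)
    ix_cur = np.full(nt + 1, NEG, dtype=np.int32)
    iy_cur = np.full(nt + 1, NEG, dtype=np.int32)
    best = 0
    for i in range(1, nq + 1):
        m_cur[0] = 0
        ix_cur[0] = NEG
        iy_cur[0] = NEG
        qi = q[i - 1]
        for j in range(1, nt + 1):
            prev = m_prev[j - 1]
            if ix_prev[j - 1] > prev:
                prev = ix_prev[j - 1]
            if iy_prev[j - 1] > prev:
                prev = iy_prev[j - 1]
            if prev < 0:
                prev = 0
            m = sub[qi, t[j - 1]] + prev
            m_cur[j] = m
            a = m_prev[j] + go + ge
            b = ix_prev[j] + ge
            ix_cur[j] = a if a > b else b
            a = m_cur[j - 1] + go + ge
            b = iy_cur[j - 1] + ge
            iy_cur[j] = a if a > b else b
            if m > best:
                best = m
        m_prev, m_cur = m_cur, m_prev
        ix_prev, ix_cur = ix_cur, ix_prev
        iy_prev, iy_cur = iy_cur, iy_prev
    return best


@njit(cache=True)
def traceback(i, j, q, t, sub, go, ge, M, Ix, Iy):  # pragma: no cover - numba
    """Trace one optimal local alignment ending at M[i, j].

    Returns (i0, j0, ops) where ops is an int8 array over the alignment
    columns in order: 0 = pairing column, 1 = gap in t (consumes q),
    2 = gap in q (consumes t). Tie preference: pairing > gap-in-t > gap-in-q
    > local start, which is deterministic.
    """
    ops = np.empty(i + j, dtype=np.int8)
    k = ops.shape[0]
    state = 0  # 0=M, 1=Ix, 2=Iy
    while True:
        if state == 0:
            k -= 1
            ops[k] = 0
            need = M[i, j] - sub[q[i - 1], t[j - 1]]
            i -= 1
            j -= 1
            if need <= 0:
                break  # local start: predecessor contribution was 0
            if M[i, j] == need:
                state = 0
            elif Ix[i, j] == need:
                state = 1
            else:
                state = 2  # Iy[i, j] == need by construction
        elif state == 1:
            k -= 1
            ops[k] = 1
            from_m = M[i - 1, j] + go + ge == Ix[i, j]
            i -= 1
            state = 0 if from_m else 1
        else:
            k -= 1
            ops[k] = 2
            from_m = M[i, j - 1] + go + ge == Iy[i, j]
            j -= 1
            state = 0 if from_m else 2
    return i, j, ops[k:].copy()
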