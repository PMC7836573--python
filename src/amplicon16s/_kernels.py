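"""Numba kernel for banded local alignment with affine gaps (Gotoh).

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(the first gap base pays open + extend). Sequences are passed as small
integer codes: A=0, C=1, G=2, T=3; code 4 marks any other symbol and never
matches.

The band is expressed in diagonals ``d = j - i`` (query index i, target
index j, both 0-based): cell (i, j) is computed only when
``dlo <= j - i <= dhi``. Cell origins (the local alignment start) are
propagated alongside scores so spans can be reported without a traceback
matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_B2C = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _B2C[ord(_b)] = _i

NEG = np.int32(-(10**8))


def encode(seq: str) -> np.ndarray:
    """Uppercase-insensitive 2-bit-ish encoding (non-ACGT -> 4)."""
    a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _B2C[a]


@njit(cache=True)
def banded_local_affine(q, t, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Best local alignment score of q vs t restricted to a diagonal band.

    Returns ``(score, q_start, q_end, t_start, t_end)`` with half-open
    spans. Ties prefer the first-seen end cell (row-major scan order).
    """
    n = q.shape[0]
    m = t.shape[0]
    W = dhi - dlo + 1  # offsets: off = j - i - dlo, valid range [0, W)
    go_ge = gap_open + gap_extend

    # padded band rows; index off+1 (pads at 0 and W+1)
    Hp = np.full(W + 2, NEG, np.int32)
    Ep = np.full(W + 2, NEG, np.int32)
    Fp = np.full(W + 2, NEG, np.int32)
    Hc = np.full(W + 2, NEG, np.int32)
    Ec = np.full(W + 2, NEG, np.int32)
    Fc = np.full(W + 2, NEG, np.int32)
    OHp = np.zeros(W + 2, np.int64)
    OEp = np.zeros(W + 2, np.int64)
    OFp = np.zeros(W + 2, np.int64)
    OHc = np.zeros(W + 2, np.int64)
    OEc = np.zeros(W + 2, np.int64)
    OFc = np.zeros(W + 2, np.int64)

    # row 0: empty alignments ending at (0, j)
    jlo0 = max(0, dlo)
    jhi0 = min(m, dhi)
    for j in range(jlo0, jhi0 + 1):
        off = j - 0 - dlo
        Hp[off + 1] = 0
        OHp[off + 1] = np.int64(0) * (m + 1) + j

    best = np.int32(0)
    best_i = 0
    best_j = jlo0 if jlo0 <= jhi0 else 0
    best_o = np.int64(best_i) * (m + 1) + best_j

    for i in range(1, n + 1):
        jlo = i + dlo
        if jlo < 0:
            jlo = 0
        jhi = i + dhi
        if jhi > m:
            jhi = m
        Hc[:] = NEG
        Ec[:] = NEG
        Fc[:] = NEG
        if jlo > jhi:
            Hp, Hc = Hc, Hp
            Ep, Ec = Ec, Ep
            Fp, Fc = Fc, Fp
            OHp, OHc = OHc, OHp
            OEp, OEc = OEc, OEp
            OFp, OFc = OFc, OFp
            continue
        qi = q[i - 1]
        for j in range(jlo, jhi + 1):
            off = j - i - dlo + 1

            # E: gap in query (move left), within current row
            e = NEG
            oe = np.int64(0)
            if j > jlo:
                hl = Hc[off - 1]
                el = Ec[off - 1]
                a = el + gap_extend
                b = hl + go_ge
                if a >= b:
                    e = a
                    oe = OEc[off - 1]
                else:
                    e = b
                    oe = OHc[off - 1]
            Ec[off] = e
            OEc[off] = oe

            # F: gap in target (move up), from previous row same j -> off+1
            f = NEG
            of = np.int64(0)
            hu = Hp[off + 1]
            fu = Fp[off + 1]
            a = fu + gap_extend
            b = hu + go_ge
            if a >= b:
                f = a
                of = OFp[off + 1]
            else:
                f = b
                of = OHp[off + 1]
            Fc[off] = f
            OFc[off] = of

            # H: diagonal
            if j == 0:
                h = np.int32(0)
                oh = np.int64(i) * (m + 1)
            else:
                hd = Hp[off]  # (i-1, j-1)
                tj = t[j - 1]
                s = match if (qi == tj and qi < 4) else mismatch
                h = hd + s
                oh = OHp[off]
                if h < 0:
                    h = np.int32(0)
                    oh = np.int64(i) * (m + 1) + j
            if e > h:
                h = e
                oh = oe
            if f > h:
                h = f
                oh = of
            if h < 0:
                h = np.int32(0)
                oh = np.int64(i) * (m + 1) + j
            Hc[off] = h
            OHc[off] = oh
            if h > best:
                best = h
                best_i = i
                best_j = j
                best_o = oh
        Hp, Hc = Hc, Hp
        Ep, Ec = Ec, Ep
        Fp, Fc = Fc, Fp
        OHp, OHc = OHc, OHp
        OEp, OEc = OEc, OEp
        OFp, OFc = OFc, OFp

    oi = int(best_o // (m + 1))
    oj = int(best_o % (m + 1))
    return int(best), oi, int(best_i), oj, int(best_j)
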