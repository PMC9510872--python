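"""Brute-force local alignment oracle (quadratic Gotoh DP).

Independent of the package's seed-and-extend aligner: full dynamic
programming with affine gaps under the toolkit scoring scheme
(match +1, mismatch -2, gap open -4, gap extend -1), with traceback
to count matched columns. Used only to cross-check best-hit score and
identity on small instances.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is expected to be present
    def njit(**kwargs):
        def deco(f):
            return f
        return deco

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(s: str) -> np.ndarray:
    return np.array([_CODE[c] for c in s], dtype=np.int8)


@njit(cache=True)
def _gotoh_local(a, b):  # pragma: no cover - exercised via wrapper
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap consuming b
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap consuming a
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + GAP_OPEN, E[i, j - 1] + GAP_EXTEND)
            F[i, j] = max(H[i - 1, j] + GAP_OPEN, F[i - 1, j] + GAP_EXTEND)
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            h = H[i - 1, j - 1] + sub
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    # traceback with an explicit matrix state: 0=H, 1=E, 2=F
    matches = 0
    columns = 0
    i, j = bi, bj
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if H[i, j] == H[i - 1, j - 1] + sub:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            if E[i, j] == H[i, j - 1] + GAP_OPEN:
                state = 0
            j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] + GAP_OPEN:
                state = 0
            i -= 1
    return best, matches, columns


def local_align_oracle(a: str, b: str) -> tuple[int, float]:
    """Best local alignment (score, identity) of two sequences."""
    score, matches, columns = _gotoh_local(_encode(a), _encode(b))
    identity = matches / columns if columns else 0.0
    return int(score), float(identity)
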