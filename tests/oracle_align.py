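"""Independent brute-force local aligner used only as a test oracle.

A full Gotoh dynamic program (no k-mer prefilter, no library aligner) with
the same scoring convention as the package: match +1, mismatch -2, a gap of
length L costs 5 + 2L.  Compiled with numba purely for speed; the recurrences
are written out explicitly here and share no code with amp2bgc.align.
"""

import numpy as np
from numba import njit

NEG = -1_000_000.0


@njit(cache=True)
def _gotoh(a, b):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - 7.0, E[i, j - 1] - 2.0)
            F[i, j] = max(H[i - 1, j] - 7.0, F[i - 1, j] - 2.0)
            s = 1.0 if a[i - 1] == b[j - 1] else -2.0
            h = H[i - 1, j - 1] + s
            if h < E[i, j]:
                h = E[i, j]
            if h < F[i, j]:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _traceback(a, b, H, E, F, bi, bj):
    """Walk one optimal alignment back from (bi, bj); returns (identities, length)."""
    i, j = bi, bj
    identities = 0
    length = 0
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0.0:
                break
            s = 1.0 if a[i - 1] == b[j - 1] else -2.0
            if H[i, j] == H[i - 1, j - 1] + s:
                if a[i - 1] == b[j - 1]:
                    identities += 1
                length += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            length += 1
            if E[i, j] == H[i, j - 1] - 7.0:
                state = 0
            j -= 1
        else:
            length += 1
            if F[i, j] == H[i - 1, j] - 7.0:
                state = 0
            i -= 1
    return identities, length


def oracle_align(a: str, b: str) -> tuple[float, int, int]:
    """(identity %, alignment length, score) of the best local alignment."""
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    H, E, F, best, bi, bj = _gotoh(av, bv)
    if best == 0.0:
        return 0.0, 0, 0
    identities, length = _traceback(av, bv, H, E, F, bi, bj)
    return 100.0 * identities / length, length, int(round(best))
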