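"""LZ76 exhaustive-history word counting.

The sequence is parsed left to right into "words": each word is the shortest
extension of the already-parsed prefix that cannot be copied from anywhere in
the extended history (self-overlap allowed).  The final word is counted even
when it is still reproducible (non-exhaustive).  The word count is the raw
diversity score.

Two interchangeable backends: a numba-compiled production-counting loop
(Kaspar-Schuster scheme) and a pure-Python bytes-search version used when
numba is unavailable.  Both are pinned to the same semantics by an
exhaustive brute-force oracle in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyInputError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _lz76_bytes(bits: np.ndarray) -> int:
    """Pure-Python backend: shortest-unreproducible-extension parsing.

    Relies on the C-level ``bytes.__contains__`` substring search.
    """
    b = bits.tobytes()
    n = len(b)
    c = 0
    p = 0
    while p < n:
        length = 1
        # grow the candidate word while it can be copied from the history
        # extended up to (but not including) its last symbol
        while p + length <= n and b[p : p + length] in b[: p + length - 1]:
            length += 1
        c += 1
        p += length
    return c


if _HAVE_NUMBA:

    @njit(cache=True)
    def _lz76_ks(a):  # pragma: no cover - compiled
        n = a.size
        c = 1
        u = 1  # length of parsed prefix
        v = 1  # current candidate word length
        vmax = 1
        i = 0  # candidate copy start within history
        while u + v <= n:
            if a[i + v - 1] == a[u + v - 1]:
                v += 1
            else:
                if v > vmax:
                    vmax = v
                i += 1
                if i == u:  # every start tried: word complete
                    c += 1
                    u += vmax
                    v = 1
                    i = 0
                    vmax = 1
                else:
                    v = 1
        if v != 1:  # trailing (possibly reproducible) word
            c += 1
        return c


def lz76_count_bits(bits) -> int:
    """Number of LZ76 words in a 0/1 (or small-alphabet) symbol array."""
    a = np.ascontiguousarray(bits, dtype=np.uint8)
    if a.size == 0:
        raise EmptyInputError("cannot parse an empty sequence")
    if _HAVE_NUMBA:
        return int(_lz76_ks(a))
    return _lz76_bytes(a)
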