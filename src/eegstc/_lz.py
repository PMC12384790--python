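"""Lempel-Ziv (LZ76) exhaustive-history parsing.

The phrase count of the exhaustive production history of a symbol string:
scanning left to right, each new phrase is the shortest substring starting
at the current position that has not occurred (with overlap allowed) in the
prefix ending just before the phrase's last character.  This is the C(N)
of the classic complexity normalisation C(N) log2(N) / N.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lz76_phrase_count"]


def lz76_phrase_count(symbols) -> int:
    """Number of phrases in the LZ76 exhaustive history of ``symbols``.

    Parameters
    ----------
    symbols : sequence of hashable
        Symbol sequence; integers, booleans or characters.  Alphabet size
        is unrestricted (no binarisation is performed here).

    Returns
    -------
    int
        Phrase count C(N); 1 for a length-1 input, 2 for a constant string
        of length >= 2.
    """
    s = _as_string(symbols)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence has no LZ parse")
    c = 0
    i = 0
    while i < n:
        ln = 1
        # extend the phrase while s[i:i+ln] already occurs starting before i
        while i + ln <= n and s.find(s[i:i + ln], 0, i + ln - 1) != -1:
            ln += 1
        c += 1
        i += ln
    return c


def _as_string(symbols) -> str:
    arr = np.asarray(symbols)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D symbol sequence")
    if arr.dtype.kind in "iub":
        # map distinct values to consecutive code points (relabel-invariant)
        _, codes = np.unique(arr, return_inverse=True)
        return "".join(map(chr, codes.tolist()))
    if arr.dtype.kind in "US":
        return "".join(arr.tolist())
    raise TypeError(f"unsupported symbol dtype {arr.dtype}")
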