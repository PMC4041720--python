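"""Optional numba-accelerated scan for exact-matching pattern counting.

The dominance scan is a per-position, longest-length-first dictionary
lookup; for 8-bit symbols and pattern lengths up to 16 each pattern packs
into two 64-bit integers, so one typed dictionary keyed by
(length index, hi, lo) serves every table.  Falls back transparently to
the pure-Python scan when numba is unavailable or the input does not fit
the packed representation.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised indirectly
    import numba
    from numba import njit, types
    from numba.typed import Dict

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

__all__ = ["HAVE_NUMBA", "scan_exact_fast", "supports_fast"]


def supports_fast(codes: np.ndarray, lengths) -> bool:
    return (
        HAVE_NUMBA
        and codes.size > 0
        and int(codes.max(initial=0)) <= 255
        and int(codes.min(initial=0)) >= 0
        and max(lengths) <= 16
    )


if HAVE_NUMBA:

    _KEY_T = types.UniTuple(types.int64, 3)
    _VAL_T = types.int64

    @njit(cache=False)
    def _scan_exact_kernel(codes, lengths, stride):  # pragma: no cover - jit
        W = codes.shape[0]
        L = lengths.shape[0]
        counts = np.zeros((L, W), np.int64)
        reps_hi = np.zeros((L, W), np.int64)
        reps_lo = np.zeros((L, W), np.int64)
        ncl = np.zeros(L, np.int64)
        d = Dict.empty(key_type=_KEY_T, value_type=_VAL_T)
        for t in range(0, W, stride):
            matched = False
            for li in range(L):
                n = lengths[li]
                if t + n > W:
                    continue
                hi = np.int64(0)
                lo = np.int64(0)
                for j in range(n):
                    v = np.int64(codes[t + j])
                    if j < 8:
                        hi = (hi << 8) | v
                    else:
                        lo = (lo << 8) | v
                key = (np.int64(li), hi, lo)
                if key in d:
                    counts[li, d[key]] += 1
                    matched = True
                    break
            if not matched:
                for li in range(L):
                    n = lengths[li]
                    if t + n > W:
                        continue
                    hi = np.int64(0)
                    lo = np.int64(0)
                    for j in range(n):
                        v = np.int64(codes[t + j])
                        if j < 8:
                            hi = (hi << 8) | v
                        else:
                            lo = (lo << 8) | v
                    key = (np.int64(li), hi, lo)
                    idx = ncl[li]
                    d[key] = idx
                    reps_hi[li, idx] = hi
                    reps_lo[li, idx] = lo
                    counts[li, idx] = 1
                    ncl[li] += 1
        return reps_hi, reps_lo, counts, ncl


def _unpack(hi: int, lo: int, n: int) -> bytes:
    out = bytearray(n)
    for j in range(n - 1, -1, -1):
        if j < 8:
            out[j] = hi & 0xFF
            hi >>= 8
        else:
            out[j] = lo & 0xFF
            lo >>= 8
    return bytes(out)


def scan_exact_fast(codes: np.ndarray, lengths, stride: int):
    """Run the packed kernel; returns per-length (reps_bytes, counts)."""
    codes_u8 = np.ascontiguousarray(codes, dtype=np.uint8)
    lengths_arr = np.asarray(lengths, dtype=np.int64)
    reps_hi, reps_lo, counts, ncl = _scan_exact_kernel(
        codes_u8, lengths_arr, stride
    )
    out = {}
    for li, n in enumerate(lengths):
        k = int(ncl[li])
        out[int(n)] = (reps_hi[li, :k], reps_lo[li, :k], counts[li, :k])
    return out
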