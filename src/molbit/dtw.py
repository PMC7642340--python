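"""Dynamic time warping distance between squiggles.

DTW aligns two time series allowing local stretching, which matches the
physics of nanopore reads: per-base dwell time is stochastic, so the same
barcode yields locally stretched/compressed versions of one underlying
level sequence. The distance used throughout barcode design is:

* computed on z-normalized event-level vectors (amplitude offsets and
  global scale carry no barcode information),
* classic DP over steps (i-1,j), (i,j-1), (i-1,j-1) with local cost
  |a_i - b_j|,
* divided by the length of the optimal warping path, so sequences of
  different length remain comparable.

DTW is a symmetric premetric (d(x,x)=0, d >= 0) but violates the triangle
inequality; nothing here relies on it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .squiggle import Squiggle


@njit(cache=True)
def _dtw_kernel(a, b):
    n, m = len(a), len(b)
    INF = np.inf
    cost = np.empty((n + 1, m + 1), dtype=np.float64)
    plen = np.zeros((n + 1, m + 1), dtype=np.int64)
    cost[:] = INF
    cost[0, 0] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            c = ai - b[j - 1]
            if c < 0:
                c = -c
            # tie-break prefers the diagonal (shortest) predecessor
            best = cost[i - 1, j - 1]
            steps = plen[i - 1, j - 1]
            if cost[i - 1, j] < best:
                best = cost[i - 1, j]
                steps = plen[i - 1, j]
            if cost[i, j - 1] < best:
                best = cost[i, j - 1]
                steps = plen[i, j - 1]
            cost[i, j] = best + c
            plen[i, j] = steps + 1
    return cost[n, m], plen[n, m]


def z_normalize(x: np.ndarray) -> np.ndarray:
    """(x - mean) / SD; degenerate inputs (length < 2 or SD == 0) are
    returned unchanged so that constant signals stay comparable."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        return x
    sd = x.std()
    if sd == 0:
        return x
    return (x - x.mean()) / sd


def dtw_distance(
    s1: "Squiggle | np.ndarray",
    s2: "Squiggle | np.ndarray",
    z_norm: bool = True,
) -> float:
    """Path-length-normalized DTW distance between two signals.

    Accepts :class:`Squiggle` objects (their ``event_levels`` if present,
    else ``samples``) or plain vectors. Set ``z_norm=False`` to compare
    raw values.
    """
    a = _extract(s1)
    b = _extract(s2)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compute DTW of an empty signal")
    if z_norm:
        a = z_normalize(a)
        b = z_normalize(b)
    total, path_len = _dtw_kernel(
        np.ascontiguousarray(a, dtype=np.float64),
        np.ascontiguousarray(b, dtype=np.float64),
    )
    return float(total) / int(path_len)


def _extract(s) -> np.ndarray:
    if isinstance(s, Squiggle):
        if s.event_levels is not None:
            return np.asarray(s.event_levels, dtype=np.float64)
        return np.asarray(s.samples, dtype=np.float64)
    return np.asarray(s, dtype=np.float64)


def pairwise_dtw_matrix(vectors: list[np.ndarray], z_norm: bool = True) -> np.ndarray:
    """Symmetric pairwise DTW matrix (zero diagonal)."""
    n = len(vectors)
    prepped = [
        z_normalize(np.asarray(v, dtype=np.float64)) if z_norm else np.asarray(v, float)
        for v in vectors
    ]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total, plen = _dtw_kernel(
                np.ascontiguousarray(prepped[i]), np.ascontiguousarray(prepped[j])
            )
            out[i, j] = out[j, i] = total / plen
    return out
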