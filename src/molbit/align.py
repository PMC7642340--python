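"""Smith–Waterman scoring used for barcode dissimilarity and read labeling.

Two variants are exposed:

* ``local`` — the classic maximal-scoring local alignment (floor 0), used
  as the sequence-dissimilarity constraint between barcodes: two barcodes
  are "too similar" when their local SW score exceeds a cap.
* ``semilocal`` — the first sequence (a barcode) must align end-to-end,
  while gaps at either end of the second sequence (a full-length read) are
  free. Used to label basecalled reads with their barcode identity.

Scoring is the affine-free triple (match, mismatch, gap), default
(+1, -1, -8): a heavy linear gap penalty, so high scores require long
contiguous matching stretches.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes; rejects non-ACGT characters."""
    if not seq:
        raise ValueError("empty sequence")
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


@njit(cache=True)
def _sw_local(a, b, match, mismatch, gap):
    m, n = len(a), len(b)
    prev = np.zeros(n + 1, dtype=np.int64)
    cur = np.zeros(n + 1, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        cur[0] = 0
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = match if ai == b[j - 1] else mismatch
            v = prev[j - 1] + s
            if prev[j] + gap > v:
                v = prev[j] + gap
            if cur[j - 1] + gap > v:
                v = cur[j - 1] + gap
            if v < 0:
                v = 0
            cur[j] = v
            if v > best:
                best = v
        prev, cur = cur, prev
    return best


@njit(cache=True)
def _sw_semilocal(a, b, match, mismatch, gap):
    # a consumed end-to-end; leading/trailing gaps in b are free
    m, n = len(a), len(b)
    NEG = np.int64(-(1 << 60))
    prev = np.zeros(n + 1, dtype=np.int64)
    cur = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        cur[0] = np.int64(i) * gap
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = match if ai == b[j - 1] else mismatch
            v = prev[j - 1] + s
            if prev[j] + gap > v:
                v = prev[j] + gap
            if cur[j - 1] + gap > v:
                v = cur[j - 1] + gap
            if v < NEG:
                v = NEG
            cur[j] = v
        prev, cur = cur, prev
    best = prev[0]
    for j in range(1, n + 1):
        if prev[j] > best:
            best = prev[j]
    return best


def sw_score(
    a: str,
    b: str,
    params: tuple[int, int, int] = (1, -1, -8),
    mode: str = "local",
) -> int:
    """Smith–Waterman score of ``a`` vs ``b``.

    ``params`` is (match, mismatch, gap) with match > 0 and mismatch,
    gap <= 0. ``mode='local'`` is symmetric; ``mode='semilocal'`` aligns
    ``a`` end-to-end inside ``b`` with free end gaps on ``b``.
    """
    match, mismatch, gap = params
    if match <= 0:
        raise ValueError("match score must be positive")
    ea, eb = encode_seq(a), encode_seq(b)
    if mode == "local":
        return int(_sw_local(ea, eb, match, mismatch, gap))
    if mode == "semilocal":
        return int(_sw_semilocal(ea, eb, match, mismatch, gap))
    raise ValueError(f"unknown mode {mode!r}")
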