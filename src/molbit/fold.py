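"""Bounded hairpin folding-energy proxy for barcode screening.

Barcodes with stable intramolecular secondary structure translocate
irregularly and fold during assembly, so design rejects sequences whose
predicted minimum free energy falls below a floor (default -8 kcal/mol).
This module provides a deliberately bounded proxy rather than a full
partition-function fold: it scans every perfect hairpin (a pair of
reverse-complementary substrings forming a stem of >= 4 bp enclosing a
loop of >= 3 nt), scores the stem with nearest-neighbor stacking free
energies (unified DNA/DNA parameters at 37 degC) plus a hairpin-loop
penalty, and returns the most stable value found (0 if no hairpin exists).

The proxy underestimates structure involving bulges, internal loops or
multiloops; it is a screen, not a thermodynamic model. A callable backend
can replace it wherever a full secondary-structure tool is available.
"""

from __future__ import annotations

from math import log
from typing import Callable

import numpy as np

from .align import encode_seq

MIN_STEM = 4
MIN_LOOP = 3

# Unified nearest-neighbor stack dG37 (kcal/mol), keyed by the 5'->3'
# top-strand dinucleotide; the table is closed under reverse complement.
_STACK_DG = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}

# Hairpin loop initiation penalties (kcal/mol) by loop length; lengths
# beyond the table are extrapolated with a Jacobson-Stockmayer term.
_LOOP_DG = {3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.4}
_RT37 = 0.616  # kcal/mol at 310.15 K


def loop_penalty(loop_len: int) -> float:
    if loop_len < MIN_LOOP:
        raise ValueError(f"hairpin loop must be >= {MIN_LOOP} nt")
    if loop_len in _LOOP_DG:
        return _LOOP_DG[loop_len]
    return _LOOP_DG[10] + 1.75 * _RT37 * log(loop_len / 10.0)


def stem_energy(top_strand: str) -> float:
    """Sum of NN stack energies along a perfect stem's top strand."""
    return sum(_STACK_DG[top_strand[i : i + 2]] for i in range(len(top_strand) - 1))


def fold_energy_proxy(
    seq: str, backend: Callable[[str], float] | None = None
) -> float:
    """Estimated MFE (kcal/mol, <= 0) of the most stable hairpin in ``seq``.

    Returns 0.0 when no hairpin with a >= 4 bp perfect stem and >= 3 nt
    loop exists. ``backend``, if given, is called instead (signature
    ``seq -> kcal/mol``), letting an external thermodynamic tool stand in.
    """
    if backend is not None:
        return float(backend(seq))
    codes = encode_seq(seq)  # validates alphabet
    n = len(codes)
    if n < 2 * MIN_STEM + MIN_LOOP:
        return 0.0
    # pairlen[i, j]: length of the perfect complementary run pairing
    # (i, j), (i+1, j-1), ... -- Watson-Crick only (A=0<->T=3, C=1<->G=2).
    paired = (codes[:, None] + codes[None, :]) == 3
    pairlen = np.zeros((n, n), dtype=np.int32)
    for span in range(1, n):  # j - i = span, increasing
        i = np.arange(0, n - span)
        j = i + span
        hit = paired[i, j]
        if span >= 3:
            pairlen[i[hit], j[hit]] = pairlen[i[hit] + 1, j[hit] - 1] + 1
        else:
            pairlen[i[hit], j[hit]] = 1
    best = 0.0
    for i in range(n):
        for j in range(i + 2 * MIN_STEM + MIN_LOOP - 1, n):
            run = pairlen[i, j]
            if run < MIN_STEM:
                continue
            s = min(int(run), (j - i - MIN_LOOP + 1) // 2)
            if s < MIN_STEM:
                continue
            loop = j - i - 2 * s + 1
            dg = stem_energy(seq[i : i + s]) + loop_penalty(loop)
            if dg < best:
                best = dg
    return best
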