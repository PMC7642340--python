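"""k-mer pore models: the lookup tables that drive squiggle simulation.

A pore model maps every DNA k-mer to the mean ionic current (pA) observed
while that k-mer occupies the nanopore's sensing region, plus a per-k-mer
noise level. Models are stored as plain TSV (``kmer``, ``level_mean``,
``level_stdv``) so that vendor-published tables can be dropped in directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"


class PoreModelError(ValueError):
    """Raised for malformed or incomplete pore model tables."""


@dataclass
class PoreModel:
    """Expected current level and noise for every k-mer.

    Parameters
    ----------
    k
        k-mer length in nucleotides.
    levels
        Mapping ``kmer -> (level_mean, level_stdv)`` in pA, with exactly
        ``4**k`` entries.
    samples_per_base
        Expected dwell of each k-mer in raw samples (sampling rate divided
        by translocation speed).
    source_tag
        Free-text provenance of the table.
    """

    k: int
    levels: dict[str, tuple[float, float]]
    samples_per_base: float = 10.0
    source_tag: str = ""
    _mean_arr: np.ndarray = field(init=False, repr=False)
    _stdv_arr: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        expected = 4**self.k
        if len(self.levels) != expected:
            raise PoreModelError(
                f"pore model must contain all {expected} {self.k}-mers, "
                f"got {len(self.levels)}"
            )
        if self.samples_per_base <= 0:
            raise PoreModelError("samples_per_base must be positive")
        mean = np.empty(expected)
        stdv = np.empty(expected)
        for kmer, (m, s) in self.levels.items():
            if len(kmer) != self.k or any(b not in BASES for b in kmer):
                raise PoreModelError(f"invalid k-mer {kmer!r}")
            if s <= 0:
                raise PoreModelError(f"level_stdv must be > 0 for {kmer}")
            idx = kmer_index(kmer)
            mean[idx] = m
            stdv[idx] = s
        self._mean_arr = mean
        self._stdv_arr = stdv

    def lookup(self, kmer: str) -> tuple[float, float]:
        return self.levels[kmer]

    def event_means(self, seq: str) -> np.ndarray:
        """Per-k-mer expected levels for ``seq`` (length ``len(seq)-k+1``)."""
        idx = sequence_kmer_indices(seq, self.k)
        return self._mean_arr[idx]

    def event_stdvs(self, seq: str) -> np.ndarray:
        idx = sequence_kmer_indices(seq, self.k)
        return self._stdv_arr[idx]


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of a k-mer over the A<C<G<T alphabet."""
    idx = 0
    for b in kmer:
        idx = idx * 4 + BASES.index(b)
    return idx


def sequence_kmer_indices(seq: str, k: int) -> np.ndarray:
    """Indices of all overlapping k-mers of ``seq`` (vectorised rolling rank)."""
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
    digits = table[codes]
    if (digits < 0).any():
        bad = seq[int(np.argmax(digits < 0))]
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    n = len(seq) - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(digits, k)[:n]
    return windows @ weights


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def load_pore_model(path, samples_per_base: float = 10.0) -> PoreModel:
    """Load a pore model from TSV with columns kmer, level_mean, level_stdv.

    Rejects tables with duplicate or missing k-mers and names the offending
    line for malformed rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"kmer": str})
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise PoreModelError(f"cannot parse pore model TSV: {exc}") from exc
    required = {"kmer", "level_mean", "level_stdv"}
    if not required.issubset(df.columns):
        raise PoreModelError(
            f"pore model TSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    for col in ("level_mean", "level_stdv"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.argmax(bad.values)) + 2  # header is line 1
            raise PoreModelError(f"malformed {col} value at line {line}")
        df[col] = pd.to_numeric(df[col])
    if df["kmer"].duplicated().any():
        dup = df["kmer"][df["kmer"].duplicated()].iloc[0]
        raise PoreModelError(f"duplicate k-mer {dup!r} in pore model")
    kmers = df["kmer"].tolist()
    k = len(kmers[0])
    if len(df) != 4**k:
        raise PoreModelError(
            f"expected {4 ** k} {k}-mers, table has {len(df)} rows"
        )
    levels = {
        row.kmer: (float(row.level_mean), float(row.level_stdv))
        for row in df.itertuples()
    }
    return PoreModel(
        k=k,
        levels=levels,
        samples_per_base=samples_per_base,
        source_tag=str(path),
    )


def save_pore_model(model: PoreModel, path) -> None:
    rows = [
        (kmer, *model.levels[kmer]) for kmer in sorted(model.levels)
    ]
    pd.DataFrame(rows, columns=["kmer", "level_mean", "level_stdv"]).to_csv(
        path, sep="\t", index=False
    )


def synthetic_pore_model(
    k: int = 6,
    seed: int = 0,
    samples_per_base: float = 10.0,
    level_range: tuple[float, float] = (60.0, 120.0),
    stdv_range: tuple[float, float] = (1.0, 3.0),
) -> PoreModel:
    """Deterministic random pore model for simulation and testing.

    Level means are drawn uniformly in ``level_range`` (pA, matching the
    dynamic range of R9-class pores) and noise levels in ``stdv_range``.
    """
    if not 2 <= k <= 8:
        raise PoreModelError(f"k must be in 2..8, got {k}")
    rng = np.random.default_rng(seed)
    kmers = all_kmers(k)
    means = rng.uniform(*level_range, size=len(kmers))
    stdvs = rng.uniform(*stdv_range, size=len(kmers))
    levels = {km: (float(m), float(s)) for km, m, s in zip(kmers, means, stdvs)}
    return PoreModel(
        k=k,
        levels=levels,
        samples_per_base=samples_per_base,
        source_tag=f"synthetic(k={k}, seed={seed})",
    )
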