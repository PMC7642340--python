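"""Random linear error-correcting code for molbit tags.

A tag is a 96-bit codeword; its bits are realized physically as the
presence/absence of the 96 molbits. Messages are k = 32 bits, encoded by
multiplying with a random k x n generator matrix over GF(2). A matrix is
accepted only when a low-weight codeword search finds no nonzero codeword
of weight below 2t+1 = 19, which guarantees unique correction of up to
t = 9 bit errors.

Decoding is nearest-codeword: exhaustive enumeration for small k, and
Prange-style information-set decoding (ISD) for the shipped [96, 32]
code — repeatedly pick k independent columns, assume them error-free,
re-encode the implied message and accept when the re-encoded codeword is
within Hamming distance t of the received word.

Count-to-bit conversion is a threshold sweep: classified read counts are
rescaled by a fixed calibration vector (to flatten systematic per-molbit
abundance bias), binarized at every candidate threshold, and the decoding
with the smallest distance to a valid codeword wins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

# ---------------------------------------------------------------------------
# types


@dataclass(frozen=True)
class CodeSpec:
    n: int = 96
    k: int = 32
    t: int = 9
    required_min_distance: int = 19

    def __post_init__(self) -> None:
        if not self.k < self.n:
            raise ValueError("require k < n")
        if self.t != (self.required_min_distance - 1) // 2:
            raise ValueError(
                "t must equal floor((required_min_distance - 1) / 2)"
            )


@dataclass
class GeneratorMatrix:
    bits: np.ndarray  # (k, n) uint8 in {0, 1}
    seed: int = 0
    verified_weight_floor: int = 0  # no nonzero codeword below this was found
    search_iters: int = 0

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8) % 2
        if gf2_rank(self.bits) != self.bits.shape[0]:
            raise ValueError("generator matrix must have full rank over GF(2)")

    @property
    def k(self) -> int:
        return self.bits.shape[0]

    @property
    def n(self) -> int:
        return self.bits.shape[1]


@dataclass
class CountVector:
    counts: np.ndarray  # (n,) non-negative reads per molbit
    run_id: str = ""
    total_reads: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.total_reads is None:
            self.total_reads = int(self.counts.sum())


@dataclass
class ScalingVector:
    factors: np.ndarray  # (n,) positive multipliers
    source: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=np.float64)
        if (self.factors <= 0).any():
            raise ValueError("scaling factors must be positive")


@dataclass
class DecodeResult:
    message: np.ndarray | None  # (k,) uint8, None on failure
    distance: int
    threshold_used: float | None = None
    candidates_tried: int = 0
    status: str = "failure"  # "unique" | "failure"


# ---------------------------------------------------------------------------
# GF(2) basics


def gf2_rank(M: np.ndarray) -> int:
    A = (np.asarray(M, dtype=np.uint8) % 2).copy()
    rank = 0
    rows, cols = A.shape
    for c in range(cols):
        pivot = np.flatnonzero(A[rank:, c])
        if pivot.size == 0:
            continue
        pr = rank + pivot[0]
        if pr != rank:
            A[[rank, pr]] = A[[pr, rank]]
        mask = A[:, c].copy()
        mask[rank] = 0
        A[mask.astype(bool)] ^= A[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def _pack_rows(bits: np.ndarray, width_words: int) -> np.ndarray:
    """Pack (r, c) 0/1 rows into (r, width_words) uint64, LSB-first."""
    r, c = bits.shape
    out = np.zeros((r, width_words), dtype=np.uint64)
    for j in range(c):
        out[:, j >> 6] |= bits[:, j].astype(np.uint64) << np.uint64(j & 63)
    return out


def _unpack_row(words: np.ndarray, n_bits: int) -> np.ndarray:
    out = np.zeros(n_bits, dtype=np.uint8)
    for j in range(n_bits):
        out[j] = (int(words[j >> 6]) >> (j & 63)) & 1
    return out


_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)


@njit(cache=True, inline="always")
def _popcount64(x):
    x = x - ((x >> np.uint64(1)) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return (x * _H01) >> np.uint64(56)


@njit(cache=True)
def _eliminate(rows, perm, k):
    """In-place GF(2) elimination sweeping columns in ``perm`` order.

    Only the column indices in perm participate in pivot selection; XORs
    apply to whole rows (so augmented words are carried along). Returns
    (number of pivots found, pivot column per pivot row).
    """
    npiv = 0
    pivots = np.full(k, -1, dtype=np.int64)
    one = np.uint64(1)
    ncols = rows.shape[1]
    for ci in range(len(perm)):
        col = perm[ci]
        w = col >> 6
        b = np.uint64(col & 63)
        pr = -1
        for r in range(npiv, k):
            if (rows[r, w] >> b) & one:
                pr = r
                break
        if pr < 0:
            continue
        if pr != npiv:
            for c in range(ncols):
                tmp = rows[npiv, c]
                rows[npiv, c] = rows[pr, c]
                rows[pr, c] = tmp
        for r in range(k):
            if r != npiv and ((rows[r, w] >> b) & one):
                for c in range(ncols):
                    rows[r, c] ^= rows[npiv, c]
        pivots[npiv] = col
        npiv += 1
        if npiv == k:
            break
    return npiv, pivots


@njit(cache=True)
def _shuffle_inplace(perm):
    for i in range(len(perm) - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = perm[i]
        perm[i] = perm[j]
        perm[j] = tmp


@njit(cache=True)
def _min_weight_kernel(packed, n, k, w_words, iters, seed):
    """Information-set low-weight search: min nonzero weight over systematic
    rows and all row-pair sums across random information sets."""
    np.random.seed(seed)
    best = n + 1
    perm = np.arange(n, dtype=np.int64)
    rows = np.empty_like(packed)
    for _ in range(iters):
        _shuffle_inplace(perm)
        rows[:] = packed
        npiv, _ = _eliminate(rows, perm, k)
        if npiv < k:
            continue
        for i in range(k):
            w = 0
            for c in range(w_words):
                w += int(_popcount64(rows[i, c]))
            if 0 < w < best:
                best = w
        for i in range(k):
            for j in range(i + 1, k):
                w = 0
                for c in range(w_words):
                    w += int(_popcount64(rows[i, c] ^ rows[j, c]))
                if 0 < w < best:
                    best = w
    return best


@njit(cache=True)
def _isd_decode_kernel(aug, recv, n, k, w_words, t, iters, seed):
    """Prange ISD: returns (best distance, best message words, iterations
    used, found_within_t)."""
    np.random.seed(seed)
    perm = np.arange(n, dtype=np.int64)
    rows = np.empty_like(aug)
    total_words = aug.shape[1]
    best_dist = n + 1
    best_msg = np.zeros(total_words - w_words, dtype=np.uint64)
    cand = np.empty(total_words, dtype=np.uint64)
    one = np.uint64(1)
    for it in range(iters):
        _shuffle_inplace(perm)
        rows[:] = aug
        npiv, pivots = _eliminate(rows, perm, k)
        if npiv < k:
            continue
        for c in range(total_words):
            cand[c] = np.uint64(0)
        for i in range(k):
            col = pivots[i]
            if (recv[col >> 6] >> np.uint64(col & 63)) & one:
                for c in range(total_words):
                    cand[c] ^= rows[i, c]
        dist = 0
        for c in range(w_words):
            dist += int(_popcount64(cand[c] ^ recv[c]))
        if dist < best_dist:
            best_dist = dist
            for c in range(w_words, total_words):
                best_msg[c - w_words] = cand[c]
            if best_dist <= t:
                return best_dist, best_msg, it + 1, True
    return best_dist, best_msg, iters, False


# ---------------------------------------------------------------------------
# codec operations


def text_to_bits(text: str) -> np.ndarray:
    """ASCII encode, 8 bits per character, MSB first."""
    data = text.encode("ascii")  # raises UnicodeEncodeError on non-ASCII
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
    return bits.astype(np.uint8)


def bits_to_text(bits: np.ndarray) -> str:
    bits = np.asarray(bits, dtype=np.uint8) % 2
    if len(bits) % 8 != 0:
        raise ValueError("bit length must be a multiple of 8")
    data = np.packbits(bits).tobytes()
    return data.decode("ascii")


def encode_message(message: np.ndarray, G: GeneratorMatrix) -> np.ndarray:
    message = np.asarray(message, dtype=np.uint8) % 2
    if len(message) != G.k:
        raise ValueError(f"message must be {G.k} bits, got {len(message)}")
    return (message @ G.bits) % 2


def _exhaustive_codewords(G: GeneratorMatrix, chunk: int = 1 << 16):
    """Yield (messages, codewords) chunks over all 2^k messages."""
    k, n = G.k, G.n
    Gb = G.bits.astype(np.uint8)
    shifts = np.arange(k, dtype=np.uint64)
    for start in range(0, 1 << k, chunk):
        stop = min(start + chunk, 1 << k)
        ints = np.arange(start, stop, dtype=np.uint64)
        msgs = ((ints[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
        cws = (msgs @ Gb) % 2
        yield msgs, cws


def min_weight_search(
    G: GeneratorMatrix, iters: int = 10_000, seed: int = 0
) -> int:
    """Smallest nonzero codeword weight found (an upper bound on the true
    minimum distance). Exhaustive for k <= 20, ISD search otherwise."""
    if G.k <= 20:
        best = G.n + 1
        for msgs, cws in _exhaustive_codewords(G):
            w = cws.sum(axis=1)
            w = w[w > 0]
            if w.size:
                best = min(best, int(w.min()))
        return best
    packed = _pack_rows(G.bits, (G.n + 63) // 64)
    return int(
        _min_weight_kernel(
            packed, G.n, G.k, (G.n + 63) // 64, iters, seed % (2**31)
        )
    )


def make_generator_matrix(
    spec: CodeSpec,
    seed: int = 0,
    search_iters: int = 2000,
    max_matrices: int = 200,
) -> GeneratorMatrix:
    """Rejection-sample random full-rank k x n matrices until the low-weight
    search finds no nonzero codeword below ``required_min_distance``."""
    rng = np.random.default_rng(seed)
    for attempt in range(max_matrices):
        bits = rng.integers(0, 2, size=(spec.k, spec.n), dtype=np.uint8)
        if gf2_rank(bits) != spec.k:
            continue
        G = GeneratorMatrix(bits=bits, seed=seed)
        found = min_weight_search(
            G, iters=search_iters, seed=int(rng.integers(2**31))
        )
        if found >= spec.required_min_distance:
            G.verified_weight_floor = spec.required_min_distance
            G.search_iters = search_iters
            return G
    raise RuntimeError(
        f"no matrix with min weight >= {spec.required_min_distance} found in "
        f"{max_matrices} samples; lower required_min_distance"
    )


def decode_nearest(
    received: np.ndarray,
    G: GeneratorMatrix,
    spec: CodeSpec | None = None,
    strategy: str = "auto",
    iters: int = 3000,
    seed: int = 0,
) -> DecodeResult:
    """Nearest-codeword decoding with bounded-distance acceptance.

    ``status='unique'`` only when the best codeword found is within the
    guaranteed-correction radius t; anything farther is reported as a
    failure carrying the best distance seen.
    """
    spec = spec or CodeSpec(n=G.n, k=G.k)
    received = np.asarray(received, dtype=np.uint8) % 2
    if len(received) != G.n:
        raise ValueError(f"received word must be {G.n} bits")
    if strategy == "auto":
        strategy = "exhaustive" if G.k <= 24 else "isd"
    if strategy == "exhaustive":
        best_d, best_m, tried = G.n + 1, None, 0
        for msgs, cws in _exhaustive_codewords(G):
            d = (cws != received[None, :]).sum(axis=1)
            i = int(d.argmin())
            tried += len(msgs)
            if d[i] < best_d:
                best_d, best_m = int(d[i]), msgs[i].copy()
        if best_d <= spec.t:
            return DecodeResult(best_m, best_d, None, tried, "unique")
        return DecodeResult(None, best_d, None, tried, "failure")
    if strategy != "isd":
        raise ValueError(f"unknown strategy {strategy!r}")
    w_words = (G.n + 63) // 64
    k_words = (G.k + 63) // 64
    aug = np.zeros((G.k, w_words + k_words), dtype=np.uint64)
    aug[:, :w_words] = _pack_rows(G.bits, w_words)
    aug[:, w_words:] = _pack_rows(np.eye(G.k, dtype=np.uint8), k_words)
    recv = _pack_rows(received[None, :], w_words)[0]
    dist, msg_words, used, found = _isd_decode_kernel(
        aug, recv, G.n, G.k, w_words, spec.t, iters, seed % (2**31)
    )
    if found and dist <= spec.t:
        return DecodeResult(
            _unpack_row(msg_words, G.k), int(dist), None, int(used), "unique"
        )
    return DecodeResult(None, int(dist), None, int(used), "failure")


# ---------------------------------------------------------------------------
# counts -> bits


def fit_scaling_vector(
    calibration: list[CountVector], presence: list[np.ndarray]
) -> ScalingVector:
    """Fit per-molbit rescaling factors from calibration runs.

    Counts are normalized within each run over the molbits present there;
    a molbit's expected relative abundance is its mean normalized count
    across the runs where it was present. Factors are the reciprocal
    abundances, renormalized to mean 1. Molbits never present get factor
    1 with a warning.
    """
    if len(calibration) != len(presence):
        raise ValueError("need one presence vector per calibration run")
    n = len(calibration[0].counts)
    sums = np.zeros(n)
    seen = np.zeros(n)
    for cv, pres in zip(calibration, presence):
        pres = np.asarray(pres, dtype=bool)
        total = cv.counts[pres].sum()
        if total == 0:
            continue
        norm = cv.counts / total
        sums[pres] += norm[pres]
        seen[pres] += 1
    factors = np.ones(n)
    covered = seen > 0
    expected = np.divide(sums, seen, out=np.zeros(n), where=covered)
    never = ~covered
    if never.any():
        warnings.warn(
            f"{int(never.sum())} molbits absent from all calibration runs; "
            "their scaling factor defaults to 1"
        )
    positive = covered & (expected > 0)
    factors[positive] = 1.0 / expected[positive]
    if positive.any():
        factors[positive] /= factors[positive].mean()
    return ScalingVector(
        factors=factors, source=tuple(cv.run_id for cv in calibration)
    )


def decode_tag(
    counts: CountVector,
    scaling: ScalingVector | None,
    G: GeneratorMatrix,
    spec: CodeSpec | None = None,
    isd_iters: int = 1200,
    seed: int = 0,
) -> DecodeResult:
    """Decode a tag from per-molbit read counts via a threshold sweep.

    Scaled counts are binarized (count > threshold) at every candidate
    threshold — midpoints between consecutive distinct sorted values,
    plus 0 and max+1 — and each binarization is decoded to the nearest
    codeword. Among thresholds whose decoding lands within distance t,
    the minimum-distance one wins (ties: lowest threshold). Failure is a
    result, not an exception.

    The zero codeword (the empty tag) is never accepted: a tag with no
    molbits cannot have produced reads, yet every nearly-empty
    binarization from an over-high threshold lies within the correction
    radius of the zero codeword and would otherwise shadow the real
    decoding.
    """
    spec = spec or CodeSpec(n=G.n, k=G.k)
    scaled = counts.counts.astype(np.float64)
    if scaling is not None:
        scaled = scaled * scaling.factors
    distinct = np.unique(scaled)
    thresholds = [0.0]
    thresholds += [
        (distinct[i] + distinct[i + 1]) / 2 for i in range(len(distinct) - 1)
    ]
    thresholds.append(float(distinct[-1]) + 1.0)
    best: DecodeResult | None = None
    tried = 0
    for thr in thresholds:
        word = (scaled > thr).astype(np.uint8)
        if word.sum() == 0:
            continue
        res = decode_nearest(
            word, G, spec, strategy="auto", iters=isd_iters, seed=seed
        )
        tried += 1
        res.threshold_used = thr
        if res.status == "unique" and res.message.sum() == 0:
            continue  # empty-tag decoding, see docstring
        if res.status == "unique":
            if best is None or best.status != "unique" or res.distance < best.distance:
                best = res
        elif best is None or (
            best.status == "failure" and res.distance < best.distance
        ):
            best = res
    if best is None:  # every binarization was degenerate (e.g. no counts)
        best = DecodeResult(None, G.n, None, tried, "failure")
    best.candidates_tried = tried
    return best


def classify_by_length(signal_length: int, cutoff: int = 9800) -> str:
    """Spacer-length channel: signals at or below the cutoff are called as
    the short (400 nt) class, longer ones as the long (1600 nt) class."""
    if signal_length <= 0:
        raise ValueError("signal length must be positive")
    return "short" if signal_length <= cutoff else "long"


@dataclass
class ErrorEstimate:
    value: float
    ci_low: float
    ci_high: float
    method: str


def estimate_error_probability(
    p_bit: float,
    spec: CodeSpec,
    method: str = "binomial_tail",
    G: GeneratorMatrix | None = None,
    trials: int = 500,
    seed: int = 0,
    isd_iters: int = 3000,
) -> ErrorEstimate:
    """Probability that a tag fails to decode correctly at bit error rate
    ``p_bit``.

    ``binomial_tail`` returns P(Binomial(n, p) > t): the chance of more
    errors than the guaranteed-correction radius, an upper bound on the
    failure probability. ``monte_carlo`` flips bits on random codewords of
    ``G``, decodes, and reports the observed not-correctly-decoded
    fraction with a 95% Clopper-Pearson interval.
    """
    if not 0 <= p_bit <= 1:
        raise ValueError("p_bit must be in [0, 1]")
    if method == "binomial_tail":
        p = float(stats.binom.sf(spec.t, spec.n, p_bit))
        return ErrorEstimate(p, p, p, method)
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    if G is None:
        raise ValueError("monte_carlo requires a generator matrix")
    rng = np.random.default_rng(seed)
    failures = 0
    for _ in range(trials):
        msg = rng.integers(0, 2, size=G.k, dtype=np.uint8)
        word = encode_message(msg, G)
        flips = rng.random(G.n) < p_bit
        word = word ^ flips.astype(np.uint8)
        res = decode_nearest(
            word, G, spec, iters=isd_iters, seed=int(rng.integers(2**31))
        )
        if res.status != "unique" or not np.array_equal(res.message, msg):
            failures += 1
    lo, hi = stats.beta.ppf(
        [0.025, 0.975], [failures, failures + 1], [trials - failures + 1, trials - failures]
    )
    lo = 0.0 if failures == 0 else float(lo)
    hi = 1.0 if failures == trials else float(hi)
    return ErrorEstimate(failures / trials, lo, hi, method)


# ---------------------------------------------------------------------------
# I/O and the shipped matrix


def save_generator_matrix(G: GeneratorMatrix, path) -> None:
    hex_width = (G.n + 3) // 4
    payload = {
        "n": G.n,
        "k": G.k,
        "seed": G.seed,
        "verified_weight_floor": G.verified_weight_floor,
        "search_iters": G.search_iters,
        "rows_hex": [
            format(int("".join(map(str, row)), 2), f"0{hex_width}x")
            for row in G.bits
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _matrix_from_payload(payload: dict) -> GeneratorMatrix:
    n, k = payload["n"], payload["k"]
    bits = np.zeros((k, n), dtype=np.uint8)
    for i, hx in enumerate(payload["rows_hex"]):
        row = format(int(hx, 16), f"0{n}b")
        bits[i] = np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
    return GeneratorMatrix(
        bits=bits,
        seed=payload.get("seed", 0),
        verified_weight_floor=payload.get("verified_weight_floor", 0),
        search_iters=payload.get("search_iters", 0),
    )


def load_generator_matrix(path) -> GeneratorMatrix:
    return _matrix_from_payload(json.loads(Path(path).read_text()))


def shipped_generator_matrix() -> GeneratorMatrix:
    """The package's verified [96, 32] generator matrix (no nonzero
    codeword of weight < 19 found by a 10^5-iteration search)."""
    text = (
        resources.files("molbit.data").joinpath("generator_96_32.json").read_text()
    )
    return _matrix_from_payload(json.loads(text))


def load_counts_tsv(path, n: int | None = None, run_id: str = "") -> CountVector:
    df = pd.read_csv(path, sep="\t")
    if not {"molbit_id", "count"}.issubset(df.columns):
        raise ValueError("counts TSV needs columns molbit_id, count")
    size = n or int(df["molbit_id"].max()) + 1
    counts = np.zeros(size)
    counts[df["molbit_id"].to_numpy()] = df["count"].to_numpy()
    return CountVector(counts=counts, run_id=run_id)


def save_counts_tsv(counts: CountVector, path) -> None:
    pd.DataFrame(
        {"molbit_id": np.arange(len(counts.counts)), "count": counts.counts}
    ).to_csv(path, sep="\t", index=False)
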