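"""Evolutionary design of mutually separable nanopore barcodes.

The goal is a set of n short barcodes (default 96 x 40 nt) whose simulated
squiggles are as mutually distinguishable as possible under DTW, while
every sequence stays synthesizable and assemblable:

* independent constraints (per sequence): GC content within bounds, no
  hairpin more stable than the folding floor, no forbidden motifs (the
  BsaI site GGTCTC and its reverse complement by default — the enzyme
  cuts double-stranded DNA), homopolymers capped at 5 (A/T) and 4 (C/G);
* dependent constraints (pairwise): local Smith-Waterman score <= a cap
  so sequence-based labeling stays unambiguous, and DTW distance >= a
  floor so squiggles stay separable.

Evolution proceeds in rounds: sequence order is shuffled, then each
sequence in turn receives up to ``max_tries`` random two-adjacent-base
mutations; a mutation sticks only if all constraints hold *and* it
strictly improves both the minimum and the mean DTW distance between the
mutated sequence and all others. This acceptance rule makes the global
minimum pairwise DTW non-decreasing across rounds. Evolution stops when
accepted mutations concentrate on at most two sequences for several
consecutive rounds (the search has collapsed to a local optimum) or at a
round cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import reverse_complement, sw_score
from .dtw import _dtw_kernel, pairwise_dtw_matrix, z_normalize
from .fold import fold_energy_proxy
from .pore_model import PoreModel
from .squiggle import Squiggle

BASES = "ACGT"


class DesignError(RuntimeError):
    """Raised when a constraint-satisfying barcode set cannot be built."""


@dataclass(frozen=True)
class DesignConfig:
    n_barcodes: int = 96
    barcode_length: int = 40
    gc_min: float = 0.30
    gc_max: float = 0.70
    mfe_floor: float = -8.0  # kcal/mol
    forbidden_motifs: tuple[str, ...] = ("GGTCTC", "GAGACC")
    max_homopolymer_at: int = 5
    max_homopolymer_cg: int = 4
    sw_max_score: int = 15
    sw_match: int = 1
    sw_mismatch: int = -1
    sw_gap: int = -8
    dtw_floor: float | None = None  # None: frozen to the initial global min
    max_tries: int = 100
    max_rounds: int = 50
    stall_rounds: int = 3
    init_retry_budget: int = 10_000

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min < self.gc_max <= 1:
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if self.max_tries < 1:
            raise ValueError("max_tries must be >= 1")
        if self.sw_match <= 0:
            raise ValueError("sw_match must be positive")

    @property
    def sw_params(self) -> tuple[int, int, int]:
        return (self.sw_match, self.sw_mismatch, self.sw_gap)


@dataclass
class ConstraintReport:
    passed: bool
    failures: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failures) == 0)


@dataclass
class RoundRecord:
    round: int
    min_dtw: float
    mean_dtw: float
    n_accepted: int
    accepted_ids: tuple[int, ...]


@dataclass
class DesignState:
    """A barcode set plus its pairwise separability matrices and history."""

    sequences: list[str]
    squiggles: list[Squiggle]
    dtw_matrix: np.ndarray
    sw_matrix: np.ndarray
    round: int = 0
    history: list[RoundRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.sequences)

    def _offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.dtw_matrix[iu]

    @property
    def min_dtw(self) -> float:
        return float(self._offdiag().min())

    @property
    def mean_dtw(self) -> float:
        return float(self._offdiag().mean())


# ---------------------------------------------------------------------------
# constraints

def gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str, bases: str) -> int:
    best = run = 0
    prev = None
    for b in seq:
        if b in bases and b == prev:
            run += 1
        elif b in bases:
            run = 1
        else:
            run = 0
        prev = b
        best = max(best, run)
    return best


def check_independent_constraints(
    seq: str, config: DesignConfig
) -> ConstraintReport:
    """Evaluate all single-sequence constraints; reports every failure."""
    if len(seq) != config.barcode_length:
        raise ValueError(
            f"expected length {config.barcode_length}, got {len(seq)}"
        )
    failures: list[tuple[str, object]] = []
    gc = gc_content(seq)
    if not config.gc_min <= gc <= config.gc_max:
        failures.append(("gc_content", gc))
    for motif in config.forbidden_motifs:
        if motif in seq:
            failures.append(("forbidden_motif", motif))
    run_at = max_homopolymer(seq, "AT")
    if run_at > config.max_homopolymer_at:
        failures.append(("homopolymer_AT", run_at))
    run_cg = max_homopolymer(seq, "CG")
    if run_cg > config.max_homopolymer_cg:
        failures.append(("homopolymer_CG", run_cg))
    mfe = fold_energy_proxy(seq)
    if mfe < config.mfe_floor:
        failures.append(("fold_energy", mfe))
    return ConstraintReport(passed=not failures, failures=failures)


def mutate_sequence(seq: str, rng: np.random.Generator) -> str:
    """Mutate two adjacent positions, both guaranteed to change."""
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    p = int(rng.integers(0, len(seq) - 1))
    out = list(seq)
    for q in (p, p + 1):
        alternatives = [b for b in BASES if b != seq[q]]
        out[q] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# initialization

def _random_valid_sequence(config: DesignConfig, rng: np.random.Generator) -> str:
    for _ in range(config.init_retry_budget):
        seq = "".join(
            BASES[i] for i in rng.integers(0, 4, size=config.barcode_length)
        )
        if check_independent_constraints(seq, config).passed:
            return seq
    raise DesignError(
        "could not sample a constraint-satisfying sequence; relax the "
        "independent constraints (GC bounds, folding floor, homopolymers)"
    )


def _event_squiggle(seq: str, model: PoreModel, seq_id: str) -> Squiggle:
    levels = model.event_means(seq)
    return Squiggle(samples=levels, event_levels=levels, seq_id=seq_id)


def _state_from_sequences(
    sequences: list[str], model: PoreModel, config: DesignConfig
) -> DesignState:
    squiggles = [
        _event_squiggle(s, model, f"molbit_{i:02d}")
        for i, s in enumerate(sequences)
    ]
    dtw = pairwise_dtw_matrix([sq.event_levels for sq in squiggles])
    n = len(sequences)
    sw = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        sw[i, i] = len(sequences[i]) * config.sw_match
        for j in range(i + 1, n):
            sw[i, j] = sw[j, i] = sw_score(
                sequences[i], sequences[j], config.sw_params, "local"
            )
    state = DesignState(
        sequences=list(sequences), squiggles=squiggles, dtw_matrix=dtw,
        sw_matrix=sw,
    )
    state.history.append(
        RoundRecord(0, state.min_dtw, state.mean_dtw, 0, ())
    )
    return state


def init_barcodes(
    config: DesignConfig,
    model: PoreModel,
    strategy: str = "random",
    rng: np.random.Generator | int | None = None,
) -> DesignState:
    """Build an initial constraint-satisfying barcode set.

    ``random`` rejection-samples each slot; ``warm_start`` samples a pool
    of 10x the target size and greedily keeps a max-min-DTW subset, which
    starts evolution from a more separable set.
    """
    rng = np.random.default_rng(rng)
    n = config.n_barcodes
    if strategy == "random":
        chosen: list[str] = []
        for _ in range(n):
            for _ in range(config.init_retry_budget):
                seq = _random_valid_sequence(config, rng)
                if seq in chosen:
                    continue
                if all(
                    sw_score(seq, other, config.sw_params, "local")
                    <= config.sw_max_score
                    for other in chosen
                ):
                    chosen.append(seq)
                    break
            else:
                raise DesignError(
                    "could not extend the barcode set under the SW cap; "
                    "relax sw_max_score or shorten the set"
                )
        return _state_from_sequences(chosen, model, config)
    if strategy == "warm_start":
        pool: list[str] = []
        while len(pool) < 10 * n:
            seq = _random_valid_sequence(config, rng)
            if seq not in pool:
                pool.append(seq)
        levels = [model.event_means(s) for s in pool]
        pool_dtw = pairwise_dtw_matrix(levels)
        # seed with the most distant admissible pair, then greedy max-min
        iu = np.triu_indices(len(pool), k=1)
        order = np.argsort(pool_dtw[iu])[::-1]
        for idx in order:
            i, j = iu[0][idx], iu[1][idx]
            if (
                sw_score(pool[i], pool[j], config.sw_params, "local")
                <= config.sw_max_score
            ):
                selected = [int(i), int(j)]
                break
        else:
            raise DesignError("no admissible seed pair in warm-start pool")
        while len(selected) < n:
            best_cand, best_min = -1, -np.inf
            for c in range(len(pool)):
                if c in selected:
                    continue
                d = pool_dtw[c, selected].min()
                if d > best_min and all(
                    sw_score(pool[c], pool[s], config.sw_params, "local")
                    <= config.sw_max_score
                    for s in selected
                ):
                    best_cand, best_min = c, d
            if best_cand < 0:
                raise DesignError(
                    "warm-start pool exhausted under the SW cap; enlarge "
                    "the pool or relax sw_max_score"
                )
            selected.append(best_cand)
        return _state_from_sequences([pool[i] for i in selected], model, config)
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# evolution

def _dtw_row(
    levels: np.ndarray, others: list[np.ndarray], skip: int
) -> np.ndarray:
    """DTW of ``levels`` vs every other barcode's levels (self = +inf)."""
    a = np.ascontiguousarray(z_normalize(levels))
    out = np.empty(len(others))
    for j, other in enumerate(others):
        if j == skip:
            out[j] = np.inf
            continue
        total, plen = _dtw_kernel(a, np.ascontiguousarray(z_normalize(other)))
        out[j] = total / plen
    return out


def evolve_barcodes(
    state: DesignState,
    config: DesignConfig,
    model: PoreModel,
    rng: np.random.Generator | int | None = None,
) -> DesignState:
    """Run rounds of mutate-and-test evolution on a barcode set.

    Returns a new DesignState; the input state is not modified. Per
    accepted mutation the mutated sequence's min and mean DTW to all
    others strictly increase, so the global minimum never decreases.
    """
    rng = np.random.default_rng(rng)
    seqs = list(state.sequences)
    levels = [np.asarray(sq.event_levels, float) for sq in state.squiggles]
    dtw = state.dtw_matrix.copy()
    sw = state.sw_matrix.copy()
    history = list(state.history)
    n = len(seqs)
    floor = config.dtw_floor
    if floor is None:
        iu = np.triu_indices(n, k=1)
        floor = float(dtw[iu].min())
    round_no = state.round
    stall = 0
    for _ in range(config.max_rounds):
        round_no += 1
        accepted_ids: list[int] = []
        n_accepted = 0
        order = rng.permutation(n)
        for r in order:
            r = int(r)
            row = dtw[r].copy()
            row[r] = np.inf
            old_min = row.min()
            old_mean = row[np.isfinite(row)].mean()
            for _try in range(config.max_tries):
                cand = mutate_sequence(seqs[r], rng)
                if not check_independent_constraints(cand, config).passed:
                    continue
                sw_row = np.array(
                    [
                        0 if j == r else sw_score(
                            cand, seqs[j], config.sw_params, "local"
                        )
                        for j in range(n)
                    ]
                )
                if (np.delete(sw_row, r) > config.sw_max_score).any():
                    continue
                cand_levels = model.event_means(cand)
                d_row = _dtw_row(cand_levels, levels, skip=r)
                finite = np.delete(d_row, r)
                if (finite < floor).any():
                    continue
                if not (finite.min() > old_min and finite.mean() > old_mean):
                    continue
                # accept
                seqs[r] = cand
                levels[r] = cand_levels
                d_row[r] = 0.0
                dtw[r, :] = d_row
                dtw[:, r] = d_row
                sw_row[r] = len(cand) * config.sw_match
                sw[r, :] = sw_row
                sw[:, r] = sw_row
                n_accepted += 1
                accepted_ids.append(r)
                break
        iu = np.triu_indices(n, k=1)
        history.append(
            RoundRecord(
                round_no,
                float(dtw[iu].min()),
                float(dtw[iu].mean()),
                n_accepted,
                tuple(sorted(set(accepted_ids))),
            )
        )
        if len(set(accepted_ids)) <= 2:
            stall += 1
            if stall >= config.stall_rounds:
                break
        else:
            stall = 0
    squiggles = [
        _event_squiggle(s, model, f"molbit_{i:02d}") for i, s in enumerate(seqs)
    ]
    return DesignState(
        sequences=seqs, squiggles=squiggles, dtw_matrix=dtw, sw_matrix=sw,
        round=round_no, history=history,
    )


def partition_sets(state: DesignState, n_sets: int) -> list[list[int]]:
    """Partition barcodes into ``n_sets`` groups of equal size, greedily
    keeping within-group DTW high (so easily confused barcodes are never
    pooled in the same sequencing run)."""
    n = state.n
    if n % n_sets != 0:
        raise ValueError(f"{n} barcodes not divisible into {n_sets} sets")
    cap = n // n_sets
    row = state.dtw_matrix + np.where(np.eye(n, dtype=bool), np.inf, 0)
    # hardest (least isolated) barcodes placed first
    order = np.argsort(row.min(axis=1))
    sets: list[list[int]] = [[] for _ in range(n_sets)]
    for idx in order:
        idx = int(idx)
        best_set, best_d = -1, -np.inf
        for s, members in enumerate(sets):
            if len(members) >= cap:
                continue
            d = np.inf if not members else state.dtw_matrix[idx, members].min()
            if d > best_d:
                best_set, best_d = s, d
        sets[best_set].append(idx)
    return [sorted(s) for s in sets]


# ---------------------------------------------------------------------------
# I/O

def write_barcodes_fasta(state: DesignState, path) -> None:
    records = [
        SeqRecord(Seq(s), id=str(i), description="")
        for i, s in enumerate(state.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_barcodes_fasta(path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def write_design_report(state: DesignState, path) -> None:
    import pandas as pd

    rows = [
        {
            "round": h.round,
            "min_dtw": h.min_dtw,
            "mean_dtw": h.mean_dtw,
            "n_accepted": h.n_accepted,
            "accepted_ids": ",".join(map(str, h.accepted_ids)),
        }
        for h in state.history
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
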