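"""Squiggle simulation and raw-signal preprocessing.

A *squiggle* is the ionic-current time series produced as a DNA strand
translocates a nanopore. Simulation here is a k-mer lookup model: each
overlapping k-mer contributes its expected current level, repeated for a
fixed or geometric dwell, optionally with Gaussian noise at the k-mer's
noise level. Preprocessing mirrors what the raw-signal classifier expects:
robust MAD rescaling, removal of the low-variance stall region at the read
start, and truncation to a fixed number of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pore_model import PoreModel, sequence_kmer_indices


class DegenerateSignalError(ValueError):
    """Raised when a signal has zero spread and cannot be normalized."""


@dataclass
class Squiggle:
    """A 1-D current trace plus provenance.

    ``samples`` are raw model units (pA) or normalized values depending on
    ``normalized``; ``event_levels``, when present, holds the per-k-mer
    expected levels the samples were generated from.
    """

    samples: np.ndarray
    event_levels: np.ndarray | None = None
    seq_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError("squiggle samples must be nonempty")
        if self.event_levels is not None:
            self.event_levels = np.asarray(self.event_levels, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class PreprocessConfig:
    """Knobs for raw-signal preprocessing.

    truncate_to: samples kept after trimming (classifier input budget).
    mad_scale_constant: 1.4826 makes MAD a consistent estimator of the
        standard deviation under normality.
    stall_window / stall_sd_fraction: rolling window (samples) and the
        fraction of the global SD a window must exceed to count as real
        translocation signal rather than stall.
    fixed_skip: samples always dropped from the very start (open-pore and
        adapter transient).
    """

    truncate_to: int = 3000
    mad_scale_constant: float = 1.4826
    stall_window: int = 50
    stall_sd_fraction: float = 0.2
    fixed_skip: int = 200

    def __post_init__(self) -> None:
        if self.truncate_to <= 0:
            raise ValueError("truncate_to must be > 0")
        if self.stall_window < 1:
            raise ValueError("stall_window must be >= 1")


def simulate_squiggle(
    seq: str,
    model: PoreModel,
    mode: str = "noisy",
    dwell_model: str = "geometric",
    seed: int | None = 0,
    seq_id: str = "",
) -> Squiggle:
    """Simulate the nanopore current trace of ``seq`` under ``model``.

    ``mode='noiseless'`` emits each k-mer's expected level verbatim;
    ``mode='noisy'`` adds per-sample Gaussian noise at the k-mer's
    level_stdv. ``dwell_model='fixed'`` repeats each level exactly
    ``samples_per_base`` times (rounded); ``'geometric'`` draws dwells from
    a geometric distribution with that mean (minimum 1 sample), emulating
    the stochastic per-base translocation time of a real pore.
    """
    if mode not in ("noiseless", "noisy"):
        raise ValueError(f"unknown mode {mode!r}")
    if dwell_model not in ("fixed", "geometric"):
        raise ValueError(f"unknown dwell_model {dwell_model!r}")
    if len(seq) < model.k:
        raise ValueError(
            f"sequence length {len(seq)} < pore model k={model.k}"
        )
    levels = model.event_means(seq)  # validates alphabet
    n_events = len(levels)
    rng = np.random.default_rng(seed)
    if dwell_model == "fixed":
        dwells = np.full(n_events, int(round(model.samples_per_base)))
    else:
        dwells = rng.geometric(1.0 / model.samples_per_base, size=n_events)
    samples = np.repeat(levels, dwells)
    if mode == "noisy":
        stdvs = np.repeat(model.event_stdvs(seq), dwells)
        samples = samples + rng.normal(0.0, stdvs)
    return Squiggle(
        samples=samples, event_levels=levels, seq_id=seq_id, normalized=False
    )


def event_levels(seq: str, model: PoreModel) -> np.ndarray:
    """Noiseless per-k-mer level vector (no dwell expansion)."""
    return model.event_means(seq)


def mad_normalize(
    samples: np.ndarray, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Robustly rescale: (x - median) / (c * MAD).

    With c = 1.4826 the output is in approximate SD units. Constant
    signals (MAD = 0) cannot be normalized and raise
    :class:`DegenerateSignalError`.
    """
    config = config or PreprocessConfig()
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateSignalError("MAD is zero; degenerate signal")
    return (x - med) / (config.mad_scale_constant * mad)


def trim_stall(
    samples: np.ndarray, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Remove the low-variance stall region at the start of a read.

    Drops ``fixed_skip`` samples, then advances past leading windows whose
    rolling SD is below ``stall_sd_fraction`` times the global SD. Never
    returns an empty signal: if everything looks stalled (or the read is
    shorter than the skip), it falls back to the fixed skip alone, and to
    the untouched input as a last resort.
    """
    config = config or PreprocessConfig()
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    after_skip = x[config.fixed_skip:]
    if after_skip.size == 0:
        return x
    w = config.stall_window
    if after_skip.size <= w:
        return after_skip
    global_sd = np.std(x)
    threshold = config.stall_sd_fraction * global_sd
    # rolling SD over contiguous windows of length w
    n_win = after_skip.size - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(after_skip, w)[:n_win]
    active = windows.std(axis=1) > threshold
    if not active.any():
        return after_skip
    start = int(np.argmax(active))
    return after_skip[start:]


def preprocess_signal(
    samples: np.ndarray, config: PreprocessConfig | None = None, seq_id: str = ""
) -> Squiggle:
    """Full preprocessing pipeline: MAD-normalize, trim stall, truncate.

    Output is at most ``config.truncate_to`` samples; short reads are kept
    unpadded (the classifier zero-pads).
    """
    config = config or PreprocessConfig()
    x = mad_normalize(samples, config)
    x = trim_stall(x, config)
    x = x[: config.truncate_to]
    return Squiggle(samples=x, seq_id=seq_id, normalized=True)
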