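# Methods

This note documents the models and algorithmic choices behind `molbit`, in
the order data flows through the system: squiggle simulation, barcode
design, raw-signal classification, the tag code, and the synthetic-run
generator used for end-to-end evaluation.

## Squiggle simulation

Nanopore current is modeled at the k-mer level: while a strand
translocates, the ~k bases inside the sensing region set the current, so a
sequence of length L produces L − k + 1 *events*, each with an expected
level (pA) and a noise SD taken from a pore-model table. Simulation
expands each event to a dwell of raw samples — either exactly
`samples_per_base` (useful for deterministic fixtures) or geometric with
that mean (minimum one sample), which reproduces the stochastic per-base
dwell of a real pore — and optionally adds Gaussian noise at the k-mer's
noise level.

Defaults are k = 6 and `samples_per_base` = 10, typical of R9-class pores
at standard sampling and translocation rates. The bundled
`synthetic_pore_model` draws level means uniformly in 60–120 pA and noise
SDs in 1–3 pA, matching the dynamic range of published pore models while
remaining fully seedable; any real model can be loaded from TSV instead.
This lookup simulator deliberately ignores neighbor-dependent convolution
effects, so absolute DTW separability numbers are not comparable to those
obtained with convolutional simulators — all separability claims in the
test suite are therefore relative (before vs after evolution), never
absolute.

## Signal preprocessing

Classification input is normalized in three steps:

1. **MAD rescale**: x → (x − median) / (1.4826 · MAD). The constant makes
   MAD a consistent SD estimate under normality, so outputs are in
   approximate SD units; constant signals are rejected as degenerate.
2. **Stall trim**: reads begin with a low-variance stall before
   translocation starts. After an unconditional skip (`fixed_skip` = 200
   samples), the trimmer advances past leading windows (50 samples) whose
   rolling SD is below 0.2× the global SD. The heuristic is deliberately
   simple and fully config-exposed; it always returns a nonempty signal
   (falling back to the fixed skip alone, then to the untouched input).
3. **Truncate** to the first 3000 samples. Shorter reads are kept
   unpadded; zero-padding to the classifier's fixed input happens at
   dataset assembly, keeping preprocessing lossless.

## Barcode dissimilarity measures

**Sequence space.** Local Smith–Waterman with (match, mismatch, gap) =
(+1, −1, −8) — the heavy linear gap penalty means scores reflect long
contiguous matches. Two barcodes are too similar when their local score
exceeds 15 (a 15-mer exact match out of 40 nt). The *semilocal* variant
(barcode consumed end-to-end, free end gaps on the read) is used to label
basecalled reads; both orientations of each barcode are tried because a
strand can thread the pore from either end.

**Signal space.** DTW on the noiseless event-level vectors (35 values for
a 40-mer at k = 6), z-normalized per sequence, with step set
{(i−1,j), (i,j−1), (i−1,j−1)}, local cost |a−b|, and the final cost
divided by the optimal warping path's length (ties between predecessors
broken toward the diagonal, i.e. the shortest path). Path-length
normalization keeps distances comparable across lengths; z-normalization
removes offset/scale, which carry no barcode information. DTW on event
levels rather than on dwell-expanded samples makes design independent of
dwell stochasticity and two orders of magnitude cheaper.

## Folding constraint

Stable secondary structure interferes with synthesis, Golden Gate
assembly, and translocation, so design rejects sequences whose predicted
minimum free energy is below −8 kcal/mol. The built-in predictor is a
bounded hairpin proxy: every pair of reverse-complementary substrings
forming a perfect stem (≥ 4 bp) around a loop (≥ 3 nt) is scored as the
sum of unified nearest-neighbor stack energies (37 °C) plus a
hairpin-loop initiation penalty with Jacobson–Stockmayer extrapolation
beyond 10 nt; the minimum over all such hairpins (or 0) is returned. The
proxy ignores bulges, internal loops, and multiloops, so it
underestimates some structures; the backend is pluggable (`backend=`
callable) wherever a full thermodynamic tool is available.

## Evolutionary barcode design

The designer maintains n sequences (default 96 × 40 nt) with their
pairwise SW and DTW matrices. Constraints:

* independent (per sequence): GC in [30, 70]%, fold proxy ≥ −8 kcal/mol,
  no BsaI site on either strand (GGTCTC/GAGACC — the enzyme cuts dsDNA,
  so both orientations are excluded), homopolymers ≤ 5 (A/T) and ≤ 4
  (C/G);
* dependent (pairwise): SW ≤ 15 and DTW ≥ a floor. The floor defaults to
  the initial set's global minimum, so evolution may never create a pair
  worse than the starting set.

Each round shuffles the sequence order; each sequence then receives up to
100 mutations (two adjacent positions, both forced to change — a
double-base mutation shifts k-mer content enough to move the squiggle,
where single-base changes mostly do not). A mutation is kept only when
all constraints hold *and* the mutated sequence's minimum and mean DTW to
all others both strictly increase (ties reject, preventing neutral-drift
cycles). Because accepted mutations only ever raise a row's minimum, the
global minimum pairwise DTW is non-decreasing across rounds — asserted on
every run. Evolution stops when accepted mutations touch ≤ 2 distinct
sequences for 3 consecutive rounds (the search has collapsed to bouncing
between a few sequences) or at `max_rounds` (default 50).

Initialization is rejection sampling (uniform bases, retry budget 10,000
per slot), either directly (`random`) or with a warm start that samples a
10× pool and greedily keeps a max-min-DTW subset. `partition_sets` splits
a designed set into equal sequencing groups, placing the least isolated
barcodes first and greedily maximizing within-group minimum DTW, so
easily confused barcodes are never pooled in one training run.

## Raw-signal classifier

Architecture: five identical blocks of (1-D convolution → ReLU → average
pooling → batch normalization), two fully connected layers with 50%
dropout, and a softmax output. Default shapes — channels (16, 32, 64,
128, 256), kernel 9, pool 3, FC (512, 256) — are a design choice of this
package: the layer-level hyperparameters of the original architecture are
not public, so ours are config-exposed and chosen to keep the parameter
count modest at input length 3000. Training uses Adam with batch size 32
and learning rate 2 × 10⁻³, selected from a small grid on the synthetic
16-class task (1 × 10⁻³/64 underfits badly within 5 epochs; 5 × 10⁻³/16
diverges). "Epochs" is the iteration unit throughout.

The network runs on a small numpy layer stack bundled with the package
(im2col convolutions, exact batch-norm backprop, inverted dropout, Adam);
backpropagation is verified against numerical gradients in the test
suite, and training is deterministic for a fixed seed on a fixed BLAS.

Datasets are balanced by capping every class at 6000 reads, split
stratified 85/15 into train/validation, and zero-padded to 3000 samples
after preprocessing. At decode time a read is assigned its argmax class
only when the softmax maximum reaches 0.9; otherwise it is left
unclassified — there is no junk class, the threshold alone absorbs
adapters, chimeras, and reverse-oriented reads.

## The tag code

A tag is a [96, 32] binary linear code word. The generator matrix is
drawn uniformly over full-rank 32 × 96 matrices and accepted only when an
information-set low-weight search finds no nonzero codeword of weight
< 19, which guarantees unique correction of t = ⌊(19−1)/2⌋ = 9 bit
errors. (A published distance bound for this construction is "at least
18"; 18 would only guarantee t = 8, so this package requires 19 — the
parameter is exposed for users who prefer the weaker bound.) The shipped
matrix (`molbit/data/generator_96_32.json`) passed a 10⁵-iteration search
at floor 19; tests re-verify with fresh seeds.

Low-weight search and decoding both use information sets: randomly
permute columns, Gaussian-eliminate over GF(2) to systematic form, and
read codewords off the rows (search records row and row-pair weights;
Prange decoding re-encodes the message implied by the received bits on
the pivot columns and accepts at Hamming distance ≤ t). Exhaustive
enumeration of all 2^k codewords replaces the randomized search for
k ≤ 20 (weights) and k ≤ 24 (decoding). Kernels operate on bit-packed
rows (uint64) under numba.

**Counts → bits.** Classified read counts are first multiplied by a
calibration vector: per calibration run, counts over present molbits are
normalized to relative abundances; each molbit's expected abundance is
averaged over the runs containing it; factors are reciprocal abundances
normalized to mean 1 (never-calibrated molbits keep factor 1). Scaled
counts are then binarized at every candidate threshold — midpoints
between consecutive distinct values, plus 0 and max+1 — and each
binarization is decoded; among decodings within distance t the smallest
distance wins, ties to the lowest threshold. One guard is deliberate: the
zero codeword (the empty tag) is never accepted, because any over-high
threshold leaves ≤ t molbits above it and would otherwise "decode"
perfectly to an empty tag that cannot have produced reads.

The spacer-length channel is a single cutoff on raw signal length
(default 9800 samples, boundary assigned to "short"); decoding failure
probability is reported either as the binomial tail P(Bin(96, p) > 9) —
an upper bound, since more than t errors does not necessarily decode
wrongly — or by Monte-Carlo simulation with a Clopper–Pearson interval.

## Synthetic runs

`simulate_counts`/`simulate_run` generate the decoder's two adversaries:

* **Dispersion**: present molbits receive static log-normal abundance
  factors (σ = 0.67 by default, giving a median max/min spread of ~25×
  across 96 molbits — the order-statistics expectation for the range of
  96 standard normals is ≈ 5 SD units, and e^{0.67·5} ≈ 28). The factor
  is a per-molbit property, reusable across runs, which is exactly the
  consistency that count rescaling exploits.
* **Background**: each read is misassigned to a uniform random molbit
  with probability 0.005, so absent molbits accumulate nonzero counts.
  Carry-over contamination between runs is not separately modeled.

Timed streams are Poisson at 10,000 reads/minute. `decode_time_curve`
subsamples reads without replacement at each time point (10 repetitions),
decodes, and reports distance and correctness per repetition, and
`remap_tag` relabels a run's counts onto a new same-popcount codeword so
one physical (or simulated) run can stand in for many tags.

## What the synthetic tests do and do not show

The synthetic generator reproduces the statistical *shape* of real runs
(k-mer-level signals, dwell stochasticity, Gaussian noise, stall-free
starts, count dispersion, background counts) but not basecalling noise,
pore degradation over a run, carry-over between washes, or the
convolutional neighbor effects of real pore chemistry. Passing the
classifier and end-to-end suites therefore demonstrates that the
pipeline's machinery is correct and that the code's correction radius
holds under realistic count statistics — not that any particular
real-data accuracy would be achieved. Real-run accuracies require the
original deposited datasets and are out of scope here.

Problem sizes used by the test suite (chosen as comfortable desk scale):
design properties on n = 16 barcodes × 12 rounds; classifier acceptance
on 16 classes × 300 reads × 5 epochs; correction-radius measurement with
500 trials per error weight; low-weight certification with 10⁵
information sets; end-to-end recovery over 20 seeds × 2000 reads.

## Known limitations

* The hairpin proxy scores only perfect stems; a sequence with a strong
  bulged structure can slip under the floor.
* The stall trimmer is a heuristic; pathological real signals (e.g. long
  low-variance homopolymer stretches at the read start) can be
  over-trimmed.
* ISD decoding is Las Vegas: with the default iteration budgets the
  probability of missing a within-radius codeword is ≪ 10⁻⁸ per decode,
  but it is not literally zero; exhaustive decoding is available for
  small codes.
* Classifier training determinism holds for a fixed seed and BLAS; a
  different BLAS/thread configuration can change results at the margin.
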