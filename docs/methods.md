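# Methods

This note documents the models and procedures implemented in squigmap, the
parameters that matter, the numerical choices, and what the synthetic test
bed does and does not establish about real data.

## Signal-domain reference model

A pore model assigns each k-mer over {A,C,G,T} an expected current level
(model units). Sliding a k-base window over a base sequence and looking
each window up yields the synthetic signal: a sequence of L − k + 1
expected levels for an L-base reference. Because DNA is double stranded,
the index holds two signals — the forward sequence and its reverse
complement, each synthesized, normalized and quantized independently.

Normalization is z-score with the *population* standard deviation
(divide by n). Nothing in the method requires one variance convention over
the other; the population form is used everywhere (reference strands and
query event means alike) so all paths are mutually consistent and
deterministic.

Quantization multiplies the z-normalized signal by an integer scaling
factor (default 32) and rounds to the nearest integer, ties away from
zero, clamping into the representable range of the configured word width
(default 16 bits, i.e. [−32768, 32767]). Clamping is silent but counted.
For z-normalized data with |z| ≤ 6 and any scale ≤ 128 no clamping can
occur. The dequantized signal is within 0.5/scale of the input wherever
unclamped.

Ambiguity codes (N) are rejected at indexing time with a clear error
rather than skipped or imputed, so reference coordinates always equal
k-mer window coordinates. Incomplete pore models are accepted for toy
work but raise a lookup error naming the missing k-mer and its position.

## Event segmentation

Raw reads are compressed into events — runs of approximately constant
level, nominally one per k-mer dwell. Boundaries are called in two stages:

1. **Peak calling.** Two sliding Welch t-statistics compare the w samples
   before and after each position (short window w=4, long window w=8 by
   default). Each detector tracks a running extremum with hysteresis
   (peak height 0.2) and fires once its statistic has exceeded its
   threshold (1.4 short, 9.0 long) and fallen back; a firing short
   detector masks the long one over one window so a sharp step is not
   reported twice. Thresholds and windows follow the widely used R9.4 DNA
   settings and are fully configurable.
2. **Significance pruning.** At threshold 1.4 on a 4-sample window the
   short detector fires freely on pure noise (a Welch t with ~6 degrees of
   freedom exceeds 1.4 about 20% of the time), which in isolation yields
   ~40% spurious boundaries on white-noise dwell. Every candidate boundary
   is therefore re-tested with a Welch t over the two *full* flanking
   events, and the weakest boundary below the long threshold (9.0, or
   `prune_threshold`) is agglomeratively merged away until all survivors
   are supported. Genuine level steps in R9.4-like data exceed this bar by
   one to two orders of magnitude. On the synthetic test bed the detected
   event count lands within a few percent of truth (slightly under, since
   adjacent k-mers occasionally share near-identical levels).

Events partition the read exactly — no gaps, no overlaps — and each
event's mean is the exact arithmetic mean of its samples.

## Adapter trimming and query assembly

The first events of a read come from the library adapter and stall, which
sit at systematically lower current than genomic signal. The query is the
250 events (`query_size`) *following* the adapter. By default the adapter
end is located per read as the least-squares two-segment changepoint over
the event means (maximizing n₁n₂(m₁−m₂)², the classic L2/CUSUM
criterion), accepted only when the split is supported by a Welch t ≥ 9
between the two segments; otherwise — and always in `adapter_trim="fixed"`
mode — a fixed 50-event prefix (`prefix_trim`) is dropped. The fixed-50
default matches the conventional "50 + 250" prefix-plus-query
configuration; the adaptive mode exists because adapters range from ~50 to
~300 events, and a fixed 50-event trim can leave up to 250 adapter events
inside a 250-event query, which caps end-position recovery around 80% on
the synthetic test bed versus ~100% with adaptive trimming. Reads with too
few events for trim + query are reported unmapped ("insufficient events")
rather than padded.

Query event means are z-normalized over the selected 250 events only —
mirroring the per-strand reference normalization — and quantized with the
same fixed-point configuration as the index.

## sDTW engines

The recurrence, boundary conditions and Manhattan distance are given in
the README. Numerical commitments shared by all engines:

- Last-row argmin ties take the smallest reference index.
- Oracle backtracking prefers diagonal, then left (j−1), then up (i−1) on
  ties; the path uses unit steps {(1,0),(1,1),(0,1)} and starts in query
  row 1. γ(0,0) = 0, so an alignment may begin before the first reference
  sample.
- Float engines use float64 throughout with a fixed per-cell expression
  (|x−y| + min of three neighbors); since every cell is a function of
  exact neighbor values, the full-matrix and cost-array sweeps produce
  identical results, not merely close ones.
- The runner-up ("second best") is the last-row minimum at index distance
  greater than an exclusion window (default 2M) from the best end — one
  query length on each side, so the runner-up cannot be the same alignment
  jittered by noise. Because the window is centered on the *final* best,
  the linear and wavefront engines keep the O(N) last row and scan it
  twice; the O(M) memory claim concerns the DP cost array, which holds.

Fixed-point semantics (sequential sweep and wavefront engine, bit-identical
by construction): the subtraction, absolute value and accumulate-add are
each evaluated in the configured word width under the overflow policy —
`wraparound` (two's complement; the default, modelling hardware
accumulators) or `saturate`. Negating the minimum word value under
wraparound yields itself, as in hardware. The ∞ boundary column is the
maximum representable value, treated as a sticky sentinel: a cell whose
minimum neighbor equals the sentinel stays at the sentinel rather than
being incremented past the range. Overflow events are counted and
reported. No Sakoe–Chiba band or lower bounding is applied; for
subsequence search against a static kilobase reference the admissible
region is essentially the whole matrix.

The wavefront engine evaluates cell (i, j) at step t = i + j − 2 (PE i−1
of an M-element chain), reading γ(i−1,j) and γ(i,j−1) from the previous
anti-diagonal register array and γ(i−1,j−1) from the second-previous one,
and reports exactly M + N − 1 steps.

## Mapping, MAPQ and selection

Both strands are searched; the lower best score wins, forward on exact
ties. Signal end index e converts to 1-based forward-strand base
coordinates as end_base = e + k (forward) or start_base = L − e − k + 1
(reverse), with the query footprint spanning M + k − 1 bases (M windows of
a k-mer model); intervals are clipped to [1, L] and always satisfy
start ≤ end, with the strand flag carrying orientation.

MAPQ = min(60, ⌊60·(second − best)/second⌋), with the conventions 60 for
no runner-up or a zero best score and 0 for second ≤ best. This formula is
this package's own operationalization — the selective-sequencing decision
only needs a monotone confidence score — and is isolated behind
`compute_mapq`. A wrapped (negative) fixed-point score yields MAPQ 0.
Selection accepts a read iff it is mapped, MAPQ ≥ `mapq_min` (default 20),
its interval overlaps a target region by ≥ 1 base (no regions = no
constraint), and optionally its per-event float score is below
`score_max`.

## Synthetic data generator

Each simulated read emulates the beginning of a pore trace: an adapter
prefix of 50–300 events (uniform) drawn from a low-current band (between a
quarter of the level range below the model minimum and the first level
quartile — outside the central genomic range, as real adapter/stall
current is), followed by 400 genomic events taken from a uniformly chosen
strand and position of the reference. Every event emits dwell samples of
its level plus Gaussian noise (default σ = 0.5 model units, i.e. ~2% of
the 60–140 level range; σ = 0.3 for the low-noise recovery studies).
Dwell is 4 + geometric with mean 10 samples (or fixed); the 4-sample
minimum keeps ideal events resolvable by the default detection windows.
Pore models are uniform on 60–140 units with a minimum pairwise level gap
enforced by rejection, so no two k-mers collide. Generation is a pure
function of the seed; the dataset RNG is split per read by counter, making
parallel generation reproducible. The truth record keeps per-event levels
and dwells (including the adapter), so evaluations map any raw sample back
to its true reference coordinate without assuming perfect segmentation.

**What this does not emulate:** pA-calibrated current, correlated
(low-pass) noise, homopolymer dwell inflation, stalls and back-steps,
real adapter chemistry, or R10.4/RNA conditions. Passing the recovery and
accuracy suites therefore demonstrates the correctness and numerical
behavior of the pipeline — segmentation, trimming, quantization,
alignment, coordinates — under controlled conditions, not field accuracy
on flowcell data.

## Problem sizes and study conditions

The test suites run at desk scale by design: engine-equivalence checks use
500 random instances with M ≤ 64, N ≤ 512 (plus exhaustive tiny cases
against pure-Python brute-force evaluators); the scaling-factor study uses
200 simulated reads against a 30 kb reference over scales {2,4,8,16,32}
plus a wraparound run at 256; truth recovery uses 5 seeds × 40 reads at
σ = 0.3. Fixed/float agreement in the scaling study is scored as exact
(strand, end) equality — the strictest reading of position similarity;
with that metric the match fraction rises monotonically with scale and
collapses at 256, where per-cell costs of ~250 scaled units accumulated
over 250 rows exceed the 16-bit range mid-reference.

## Known limitations

- SLOW5/BLOW5 input requires the optional pyslow5 dependency; without it
  only the TSV read format is available.
- The linear and wavefront engines report end positions only; warp paths
  require the O(MN) oracle.
- Multi-record references are indexed independently and searched
  sequentially; there is no cross-record chaining.
- References are assumed kilobase-scale; the O(MN) software engines are
  not intended for megabase genomes.
- No live sequencer integration: the toolkit maps batches, it does not
  eject reads.
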