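# Methods

This note records the model assumptions, the tunable parameters, the
numerical conventions, and the design choices made where the procedure
left genuine freedom.  The README describes the three pipeline steps;
here we concentrate on what is *not* obvious from the equations.

## Model and assumptions

The pipeline treats a transcriptional response as a cascade of waves: a
small set of early (Initiation) regulators moves first, and their
change-in-expression patterns reappear — delayed, possibly
sign-inverted, and corrupted by noise — in targets of the next stage.
Three assumptions follow:

1. *The modal change interval marks the boundary.*  The interval in
   which the largest number of genes attain their maximum signed change
   is taken as the peak of the response wave, and the sampling time
   preceding it becomes the Initiation–Response boundary.  This
   presumes the input is restricted to differentially expressed genes;
   genes that are flat up to noise acquire unit variance under the
   per-gene standardization and can populate arbitrary gene sets (their
   per-hour change is largest over the shortest sampling intervals,
   which biases them toward early intervals).  Upstream
   differential-expression filtering is therefore part of the contract,
   not a nicety.
2. *Influence shows up as delayed pattern similarity.*  The
   dissimilarity score compares max-rescaled change signals, so only
   the shape of the response matters, not its amplitude — the
   composition of standardization, differentiation and max-rescaling is
   invariant to per-gene affine transforms of the raw data (property
   tested).
3. *One regulator per comparison.*  Combinatorial regulation is out of
   scope; each candidate pair is scored in isolation, and the predicted
   sign assumes the target tracks (or mirrors) that single regulator.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `c` | 1 | sampling intervals in the Primary Response window; the first post-boundary interval carries the bulk of the wave on the canonical grid |
| `k1`, `k2` | 4 | k-means cluster counts per assignment round; four shapes (up, down, oscillatory, flat) are what sparse windows support; a silhouette-based selector was considered and deliberately left out of the default path for reproducibility |
| `thresholds` | none, 0.2, 0.4 | event-threshold levels; on max-rescaled signals 0.2/0.4 write off roughly a quarter / half of per-gene changes as noise |
| `cutoff` | 0.4 | maximum admissible row-minimum dissimilarity; on ternarized 4-point grids this admits at most one unit mismatch |
| `min_support` | 2 | threshold levels a candidate must pass (2 of 3) |
| `restarts` | 50 | k-means restarts; best inertia kept, fixed `random_state` |
| `ddof` | 0 | population convention for the standardization; immaterial downstream because of max-rescaling |

## Numerical conventions

- **Stage windows are half-open** `(start, end]`; the step signal is
  undefined at the first sampling time.  The evaluation set of the
  dissimilarity is accordingly the ΔT grid `{start+ΔT, …, start+MΔT}`
  over the regulator's stage window — the only reading under which the
  1/M prefactor is a true mean and every evaluation point is inside the
  signal's domain (on the canonical grid: 𝒯 = {3, 6, 9, 12} h, M = 4).
- **Delays** are `0, ΔT, …, (M−1)ΔT` with ΔT the gcd of the sampling
  intervals (3 h on the canonical grid), computed by Euclid's algorithm
  at a resolution of 1e−6 h and validated against every interval.
- **Ties.**  A gene whose maximum change is attained in several
  intervals joins the earliest one (favors early detection).  A
  cardinality tie between gene sets moves the boundary to the latest
  qualifying interval (maximizes the Initiation stage; logged).  A
  candidate whose row minimum is attained at delay 0 *and* at a
  positive delay is kept and reported at the smallest positive delay —
  delayed agreement is still evidence; `strict_zero_delay` inverts
  this.  Equal direct and inverted scores resolve to the direct
  orientation.
- **Event thresholding** maps values strictly above `thr` to +1,
  strictly below `−thr` to −1, and everything else — including values
  exactly at the threshold — to 0, the conservative no-regulation
  call.
- **Exactly one cluster per round is inactive**, the one whose centroid
  has the smallest maximum absolute value over the window (alternatives:
  centroid variance, mean per-gene range).  A warning is emitted when
  the most active centroid is less than twice the inactive amplitude.
- **Degenerate inputs.**  Zero-variance genes are rejected by name at
  standardization (`drop_constant` drops them with a count instead);
  a modal first interval aborts staging, since no Initiation window
  would precede it; a boundary override is honored but flagged as
  manual in the run manifest.
- The early-window threshold diagnostic counts changes over the
  sampling intervals that end at or before the boundary (three on the
  canonical grid).

## Synthetic data generator

`cdaa.synthetic.generate_cascade` emulates the statistical structure
the method assumes, not transcriptional kinetics (no ODEs):

- **Regulators** are piecewise-constant change patterns on the ΔT grid
  of the Initiation window, drawn from five fixed templates (early
  peak, pulse, oscillation, ramp, transient).  The templates were
  chosen once, by construction, to be mutually distinguishable under
  the alignment score — across relative delays, under sign inversion,
  and after ternarization at 0.2/0.4.  With arbitrary shapes the
  five-regulator identification problem is not solvable on a seven-point
  grid, so template separability is a designed property of the
  generator, documented rather than hidden.
- **Targets** carry the regulator's pattern as read on the delay-probe
  grid: the delayed step signal is sampled at the ΔT probe points and
  projected onto the target's sampling intervals by averaging within
  each interval.  (A literal continuous-time shift is representable on
  an uneven grid only for degenerate patterns, because one late
  sampling interval spans several ΔT cells.)  Each target also carries
  a small change over the first sampling interval, mimicking baseline
  co-fluctuation; a side effect is that unrelated regulators tend to
  align best at delay 0, where zero-delay exclusion removes them.
  Targets of short-delay edges genuinely straddle the boundary — the
  delay grid only reaches (M−1)ΔT, which is shorter than the Initiation
  window — so their clustering-derived stage can be Initiation; edge
  recovery is therefore benchmarked with the planted regulator pool and
  target list (standard planted-benchmark protocol), and exact stage
  recovery is asserted on the waves-only configuration (`n_targets=0`).
- **Background wave** (`n_background`, default 60): transiently induced
  or repressed genes (3:1 induction bias, partial relaxation in the
  following interval) spread over the post-boundary intervals with
  weights 0.7/0.2/0.1.  They make the post-boundary interval modal, as
  the dominant response wave does in real stress data; without them,
  constant-plus-noise genes would relocate the detected boundary.
- **Inert genes** (`n_inert`, default 30) are constant plus noise.
  After standardization they are unit-variance noise and cluster
  unpredictably; they exist to stress the pipeline, not to carry truth
  labels.
- **Noise** is additive Gaussian on expression values after rows are
  scaled to unit variance, so `noise_sd` reads as a fraction of signal
  amplitude (default 0.05).
- Ground truth (edges, signs, delays, stage labels) is a deterministic
  function of the spec; the seed only drives the noise realization.

What passing the synthetic tests does *not* show: real targets are not
noisy copies of single regulator patterns (combinatorial inputs,
saturation, post-transcriptional regulation), real data have no
guarantee that the modal-interval heuristic finds a biologically
meaningful boundary, and measured sign accuracy says nothing about
causal direction.  The synthetic results validate the machinery, not
the biology.

## Problem sizes

The test suite and the acceptance script run cascades of ~105–125 genes
on the canonical 7-point grid, 20 seeds per noise level, with alignment
oracle checks on 1,000 random small instances (≤ 6 time points).  These
sizes exercise every code path; all pipeline stages are linear or
near-linear in gene count, and a 2,754-gene table runs in seconds.

## Known limitations

- Only one boundary and at most three stages are detected
  (`c` subdivides the response; multi-boundary staging is not
  implemented).
- The signed-maximum gene-set rule places purely down-regulated,
  noise-free genes by tie-break (their maximum signed change is zero
  everywhere); with real noisy data this is immaterial, and `--abs-max`
  offers the magnitude-based alternative.
- Cluster memberships depend on k-means seeds and restarts; exact
  reproduction of any particular published clustering is not expected,
  only stable stage-level counts.
- The 2-of-3 consensus rule applied to a published appearance matrix of
  candidate iron-response regulators retains five candidates; the
  accompanying prose mentions four.  The implementation follows the
  rule (and the five-name list) — the discrepancy is in the source, not
  resolvable here.
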