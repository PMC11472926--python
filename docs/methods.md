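# Methods

This note documents the models, conventions and parameter choices behind
`apoclust`, in the order the pipeline runs.

## Track tables and cell fates

The pipeline consumes long-format spot tables (one row per cell per frame)
as exported by nucleus trackers; the TrackMate spot-export dialect is the
default column mapping and any other dialect can be bound with
`column_map`. Death is operationalized as **track termination**: nuclear
breakdown ends the nuclear signal, so a cell's death frame is the last
frame its track is present. Cells still present at the final movie frame
are censored survivors. The frame interval is a configuration value
(default 10 min, the imaging cadence the analysis conventions assume).

Trackers can emit gap frames. A single-frame gap is filled by linear
interpolation of position and intensity and flagged in the `interpolated`
column; gaps of two or more frames split the track into separate cells
with a logged warning. The rationale: an unfilled gap would end a track
early and fabricate a death, while silently bridging a long gap would hide
a real one. This policy is a stated convention of this package — the
upstream tracker's own gap-closing settings are outside its scope.

Region filtering (bounding box and/or segment whitelist) is judged at each
cell's **first-frame** position and applied to whole tracks, because cells
migrate and the randomized null is defined on initial positions.

## Neighbor graphs

Adjacency in the monolayer is the Delaunay triangulation of nucleus
centroids, pruned at a maximum edge length to remove spurious long
connections (hull edges, bridges across the segmental boundary; an
optional segment filter drops edges joining different segments). The
pruning threshold defaults to **2.0 × the median Delaunay edge length at
the first frame** — scale-free, hence robust to magnification — and can be
overridden in micrometres. On a jittered hexagonal monolayer this retains
the ~6 nearest neighbors of interior cells.

Degenerate inputs are well-defined: two points give their single edge;
collinear sets give the path of consecutive points; duplicate points are a
hard error naming the ids; cocircular quadruples may resolve to either
diagonal (backend choice — both are valid triangulations).

Pair adjacency for death detection is evaluated on the graph of the last
frame both cells are alive (the earlier of the two death frames), with
tracked positions (`position_mode="at_frame"`). The randomized null
instead uses one static triangulation of **all** cells at their
first-frame positions (`position_mode="initial"`), since the null ignores
migration. When an observed movie is compared against its null (the
calibration and mode-discrimination analyses), the observed count is
measured on the same static graph so both arms are matched; the report
surfaces this convention.

## Concurrent-death pairs and clusters

Two graph-adjacent cells dying at the same frame or one frame apart
(`margin_frames=1`; the 10-min interval is the margin for nuclear
breakdown) form a concurrent-death pair. Pairs sharing a cell are merged
transitively; connected components of the pair graph are death clusters.
Components with ≥ 3 cells (`min_cluster_size=3`) count as clustered
apoptosis; isolated pairs are reported but excluded from clustered counts
by default. Transitive chaining means a component can span more than the
margin end to end (A@12–B@13, B@13–C@14); the merge rule is applied as
written. A curation table (cluster id → accept/reject) can exclude
candidate clusters from counts, mirroring visual inspection of raw movies;
rejected clusters stay in the report. An `extended_margin_frames`
sensitivity setting (e.g. 3 frames ≈ 30 min) captures shortly-delayed
deaths; it is off by default.

Cluster onset is the earliest member death frame; the per-hour timecourse
bins clusters by onset. Phase proportions divide cells dying in accepted
clusters (onset in phase) by all deaths in that phase; the early and late
phases default to 20–25 and 25–40 hAPF. A phase with zero deaths yields a
missing value, not 0. The elimination curve is the percentage of cells
remaining relative to the count at a reference time (default 20 hAPF);
with all tracks starting at the first frame it is exactly 100% at the
reference and non-increasing.

## Randomized-removal null

Each null iteration preserves (1) every cell's first-frame position and
(2) the per-frame observed death counts, drawing which cells die uniformly
without replacement from those still alive — no spatial weighting. When
every cell is present from the start this is implemented as a single
uniform permutation, which is distributionally identical and fast; the
per-frame counts are conserved exactly in every iteration, and runs are
bit-identical under a fixed seed. Cluster detection runs on the static
initial-position graph; per-iteration clustered-cell totals (and per-hour
counts) form the null distribution. Default 6 iterations per sample
mirrors the original study design; ≥ 200 is recommended whenever empirical
p-values are wanted, and is what the built-in analyses use. The comparison
reports `z = (obs − mean)/SD` (undefined, reported as NaN, when SD = 0)
and `p = (1 + #{null ≥ obs}) / (1 + n)`. The z/empirical-p formalization
is this package's addition; the original comparison was visual.

## Reporter dynamics

The nuclear reporter accumulates when ERK is low, so an ERK pulse is a
transient **decrease** of nuclear intensity. Conventions:

* **Ratio** — nuclear / cytoplasmic intensity of the same cell; records
  with non-positive cytoplasm are rejected with a warning.
* **Normalization** — division by the cell's temporal mean (normalized
  mean exactly 1).
* **Pulse calling** — the trace is smoothed with a centered moving average
  (default 30 min = 3 frames); pulses are maximal decreasing runs of the
  smoothed trace lasting ≥ 20 min with depth (start − minimum) ≥ the depth
  threshold. The default threshold is **4 × the per-trace residual SD**
  (residual = raw − smoothed). This factor was set by measuring the
  detector on pure noise: at 2 × residual SD a 20-h noise-only trace
  (σ = 3 AU) produces ~3 spurious shallow pulses, which would dominate
  per-cell means on long traces; at 4 × the spurious rate is ~0.01 per
  trace while genuine pulses (tens of AU) remain far above threshold. A
  cell with zero detected pulses reports a missing mean decrease, not 0,
  so population comparisons are not diluted.
* **Event time** — a death's event time is its last frame plus half a
  frame interval (breakdown completes between the last-seen and
  first-absent frames).
* **Roles** — graph-neighbors of the primary dying within the margin are
  secondary/concurrent; all other graph-neighbors are surviving neighbors;
  everything else is a non-neighbor. A neighbor dying, say, 40 min after
  the primary is labelled a surviving neighbor (it escaped the concurrent
  death) but its trace simply ends early and is flagged `partial` at
  alignment; the nominal surviving-neighbor window extends to +60 min.
* **Alignment and windows** — traces are re-timed to minutes relative to
  the event (negative = before); primary/secondary traces truncate at 0,
  neighbors extend to +60. The windowed change is value(t_b) − value(t_a)
  with linear interpolation for off-grid endpoints (10-min sampling vs
  minute-valued windows); defaults (−50, −20) min, the pre-apoptotic ERK
  up-regulation period, so a negative change means ERK rose. Changes are
  computed on raw intensities by default (normalized optional). The
  induced-apoptosis response is value(t₀) − value(t₆₀) on exposure-aligned
  traces (positive = ERK rose).

## Synthetic tissue generator

The generator emulates the statistical structure of the imaging data, not
its biology or mechanics:

| Parameter | Default | Meaning |
|---|---|---|
| lattice | 30 × 20, pitch 30 μm, jitter SD 3 μm | jittered hex monolayer of 600 nuclei |
| movie | 120 frames × 10 min from 20 hAPF | ~20 h of imaging |
| hazard | 0.5 %/h early, 5 %/h late, boundary 25 hAPF | two-phase per-cell elimination rate |
| protection | refractory 60 min, probability 1 | neighbor protection on death |
| contagion | ×20 for 60 min | neighbor hazard boost on death |
| reporter | baseline 100 AU, drift +4 AU/h, noise SD 3 | nuclear channel; cytoplasm constant 100 |
| pulse | 30 AU deep, 60-min lead, 30-min fall | injected neighbor dip (ERK pulse) |
| migration | off | optional midline drift |

Hazards are per-frame Bernoulli with p = rate × interval. Four modes:
**random** (no interaction), **protected** (each surviving neighbor of a
death becomes refractory, i.e. cannot die, for the refractory period;
within a frame deaths are resolved sequentially in random order with
refractoriness applied immediately, so adjacent concurrent deaths are
structurally impossible), **contagion** (a death multiplies neighbors'
hazard for the window; boosts act from the next frame), and **graded**
(each neighbor is protected with probability `protection_prob`, otherwise
contagion-sensitized — the survival-signalling model itself, used for
condition sweeps). Migration is off by default because the null ignores
it; an optional midline drift exists to probe the at-frame vs initial
position modes.

Reporter traces are baseline + drift·t + Gaussian noise; protected
neighbors receive a dip per protection event (linear fall over the lead-in
to −amplitude, hold through the event +20 min, 30-min recovery), and dying
cells rise by 20 AU over their last 40 min (ERK falls before a cell's own
death). Traces end at the death frame. The closed form used in recovery
tests follows directly: the (−50, −20) window overlaps the 30-min falling
ramp (−60 to −30 relative to the event) for 20 min, so the expected
windowed change is −amplitude × 20/30.

Fixtures are emitted as the standard spot-table dialect plus a truth file
(mode, true death frames, injected pulse windows, and — for contagion —
"potential lineage" components linking adjacent cells dying within one
contagion window of each other; detector clusters are subsets of these by
construction since the margin is shorter than the window).

## Condition choices in the built-in analyses

* The **null-calibration** experiment uses the default two-phase hazard:
  random-mode movies are themselves draws from the null's assumptions, so
  the observed clustered count should land inside the central 95% of the
  null distribution in ~95% of replicates; coverage is reported over
  replicate experiments.
* The **mode-discrimination** and **sweep** conditions use a flat basal
  hazard of 1 %/h instead. At the default late rate with a ×20 contagion
  boost, virtually the whole tissue is eliminated and even randomly
  reshuffled deaths cluster heavily — the contrast would measure
  saturation, not mechanism. At 1 %/h roughly 40% of cells die over the
  movie (an accelerated-early-phase regime, comparable to conditions that
  eliminate massively from the start), elimination is driven by the
  neighbor interaction, and the contagion-versus-null contrast isolates
  spatial correlation at matched death counts.
* The **pulse-recovery** fixture sets reporter drift to 0 so the injected
  dip is the only systematic trace feature; its no-pulse control (cells
  with no dip near the probe window) then tests that the windowed change
  is unbiased. Drift stays at its default everywhere else.
* The **protection sweep** couples condition-level reporter baseline to
  protection strength (offset 40 × (1 − strength) AU): conditions lacking
  the survival pulse also sit at globally lower ERK, as both are
  downstream of the same signalling axis in the system being emulated.
  The recovered correlation is therefore a property of the generator's
  condition design as much as of the estimator — which is exactly what the
  sweep is meant to verify (sign and strength of the estimator on a known
  monotone coupling).

## What passing tests do and do not show

The generator produces statistically idealized data: stationary Gaussian
noise, identical cells, exact per-frame hazards, no segmentation or
tracking errors, no histoblast boundary, no apoptosis-driven passive
motion, and (by default) no migration. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to real imaging artifacts. In particular, the null model shares
the generator's "no migration" assumption; on real late-phase data, where
cells migrate toward the midline, the static-position null is an
approximation whose direction of bias depends on how migration compacts
the tissue.

## Numerical conventions

* Frame-quantized refractory periods round up to whole frames; infinite
  refractory periods are supported.
* Empirical quantiles use numpy's default (linear) interpolation.
* Percent-remaining curves use exact integer alive counts.
* All simulations and tests are deterministic under explicit integer
  seeds; the acceptance script derives independent sub-streams (< 2³¹)
  from its single `--seed` via `numpy.random.SeedSequence`.
* Problem sizes in the built-in analyses (600-cell tissues, 120-frame
  movies, 200 null iterations, 3 replicates per condition, 10–20
  calibration replicates) were chosen as the smallest sizes at which the
  measured quantities are stable across seeds.
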