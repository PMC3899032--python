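# Methods

## The density delay map

A delay (Poincaré / return) map plots x(n) against x(n+1).  For an RR
series it summarizes the joint distribution of consecutive beats: a
comet-like cloud along the identity line signals short-range correlation,
a circular cloud uncorrelated dynamics.  A plain scatter hides point
density and, computed over a whole record, hides time: the same static map
arises whether a bistable system alternates every minute or sits half the
night in each state.  The dynamical density delay map addresses both by
(a) replacing the scatter with a binned, smoothed relative-density surface
h(x(n), x(n+1)) ∈ [0, 1], and (b) recomputing it in a moving window and
animating the frames.

The height h is a *relative occupancy*: each window's histogram is divided
by the count m of its highest bin, not by the total mass, so h = 1 marks
the modal bin of every frame.  This is deliberate — frames remain visually
comparable as the number of in-window beats varies — but h is therefore
not a probability density.

### Binning

Uniform `nbins × nbins` grid (default 200) over a fixed range shared by
every window of one animation: per-window ranges would make states appear
to drift between frames.  When no range is given it is the full-record
[min, max] RR padded by 2 %.  Bins are half-open [e_i, e_{i+1}) with the
last bin closed; out-of-range pairs are dropped and counted in the run
log.  A pair exactly on an interior edge belongs to the upper bin.

### Smoothing

The histogram smoother is the penalized least-squares (Whittaker-type)
scheme used by density-scatter routines: each column y of the grid is
replaced by the solution of

    (I + 2 λ D₁ᵀD₁ + λ² D₂ᵀD₂) z = y,     λ = nbins / λ_user,

where D₁ and D₂ are first- and second-difference matrices, then the same
smoother runs along the rows.  λ_user defaults to 20; *larger* λ_user
means *less* smoothing (the effective penalty shrinks).  Two algebraic
facts are load-bearing and tested: the penalty annihilates constants
(a flat grid passes through unchanged to 1e-10) and has zero column sums
(total mass is conserved to 1e-8 relative), so smoothing redistributes
counts without inventing or destroying them.  The sparse solve is checked
against a dense `numpy.linalg.solve` oracle to 1e-8 on small grids.
Smoothing is applied to raw counts *before* max-normalization so the final
maximum is exactly 1.  Grids smaller than 3×3 are rejected (second
differences undefined).

### Windowing

Windows are time-based, anchored at the first beat's onset: the k-th
window is [t₀ + kS, t₀ + kS + W), beats selected by onset time.  The
window count is exactly floor((T − W)/S) + 1 with T the first-to-last
onset span; trailing data shorter than W is dropped (logged).  Delay pairs
are formed within a window only.  Presets: `sleep` = 500 s / 10 s,
`af` = 1200 s / 300 s.

### States, boundary, occupancy

States are local maxima of the normalized grid: bins ≥ all 8 neighbours
with h ≥ `min_height` (default 0.2).  A flat plateau contributes only its
lowest (row, col) bin; peaks closer than `min_separation` (default 0.1 s,
Euclidean between bin centers) merge keeping the higher, ties breaking to
the lowest index — all deterministic.  The defaults separate landmark
structures 0.35 s apart while suppressing smoothing ripples; both are
exposed in the CLI.

The boundary between two on-diagonal states is operationalized as the RR
value minimizing the density profile along the identity diagonal strictly
between the two peaks' diagonal positions — a scalar reduction of the
separating line one would draw through the density trough.  State
occupancy is then a threshold partition, reported both beat-weighted
(fraction of beats, sums to 1 exactly) and duration-weighted (weight =
RR), with dwell times from maximal runs.  Duration weighting matters:
slow-state beats last longer, so the heart spends proportionally more
clock time there than beat counting suggests.

### Shuffle demonstration

Shuffling the intervals preserves the 1D histogram exactly (multiset
identity) but destroys serial correlation.  The map-divergence statistic
is the L1 distance between *mass*-normalized (sum-to-1) grids — a
total-variation-style metric in [0, 2] — computed on unsmoothed grids so
it compares raw occupancies.  Significance comes from a resampling null:
the 99th percentile of the divergence between two independent shuffles
(200 resamples).  For correlated dynamics the original-vs-shuffle
divergence exceeds this null by a wide margin (≈ 1.44 vs ≈ 0.56 for the
default bistable generator at 30 000 beats).

### Rendering and animation

Colour is a pure function of h: linear lookup into the colourmap, default
a pinned 9-anchor classic jet table (dark blue → cyan → yellow → dark
red) so output does not depend on a backend's own jet variant.
Out-of-range h is clamped with a warning.  Frames are drawn on an Agg
canvas with explicit Figure objects — no global pyplot state — so
identical inputs give byte-identical rasters.  The composite layout is 3D
surface (fixed view, azimuth −37.5°, elevation 30°) over contour map over
raw segment; the contour panel exists because the back of the surface is
hidden at any fixed view.  Contour levels are linear in h.  Axis limits
are frozen per animation.  Empty windows render blank panels with a
caption flag rather than aborting.

GIF is the reference animation format (palette-stable, hence reproducible
to the byte); MP4/AVI are offered through imageio's ffmpeg backend and
raise a clear error naming the missing encoder when none is installed.
Default 10 fps.  The pipeline streams frames into the encoder one at a
time: a multi-hour record at the 500/10 s preset yields thousands of
frames, far more than fit in memory as a raster list.

## Synthetic generators

Real nocturnal and atrial-fibrillation recordings are not redistributable
with the package, so three generators emulate the statistical structure
that drives each landmark picture; all downstream stages are developed and
tested against them.

* **Bistable** (`gen_bistable`): hidden symmetric two-state Markov chain,
  state means 0.65 s and 1.0 s (heart rates ≈ 92 and 60 beats/min — the
  two sleep states, plausibly REM/transient-awakening vs deep sleep),
  stay probability 0.998 per beat (mean dwell ≈ 500 beats, long enough
  that single windows are often pure-state), plus an AR(1) fluctuation
  (φ = 0.9, stationary sd 0.03 s) giving the comet-shaped within-state
  cloud of short-range-correlated beats.
* **IID** (`gen_iid`): truncated-Gaussian i.i.d. intervals (mean 0.6 s,
  sd 0.1 s, floor 0.2 s) — the uncorrelated, circular-map dynamics of a
  typical atrial-fibrillation ventricular response.
* **Cluster switching** (`gen_cluster_switching`): alternation between
  0.4 s and 0.8 s levels with minimum run 3 beats and post-minimum switch
  probability 0.3 (mean run ≈ 5.3 beats), noise sd 0.02 s.  Dwelling
  yields the two on-diagonal loci; every level change contributes one
  off-diagonal pair, yielding the (0.4, 0.8) and (0.8, 0.4) loci — four
  clusters total.

Noise is Gaussian with a 0.2 s positivity floor (physiologic RR > 0).
State paths and noise use independent sub-streams of one seed, so output
is bitwise reproducible and the state path survives noise-parameter
changes.  What the generators do **not** emulate: respiratory sinus
arrhythmia, circadian trends, ectopy/artefact, or any continuous drift of
state means.  Passing tests therefore demonstrate that the pipeline
recovers abrupt-switching multistable structure and correlation breakdown;
they do not certify behaviour on gradually drifting real records, where
the fixed-axes windowing is the relevant safeguard.

## Numerical and design choices

* Landmark analyses use fixed axis ranges (0.3–1.4 s for the sleep-like
  record, 0.2–1.0 s for the alternation record) so that "within 2 bins"
  is defined on a stable grid; at nbins = 200 these bins are 5.5 and 4 ms
  wide and recovered peak centers land within ≈ 1–2 bins of the
  generating means.
* Problem sizes in tests and in the acceptance script (20 000–30 000
  beats, 200 shuffle resamples, 20 recovery seeds) are chosen to give
  sampling error well inside every asserted tolerance while keeping a full
  run in seconds.
* Ties anywhere (max bin, equal peaks, flat minima) resolve to the lowest
  index, making every reported quantity deterministic.
* Two-column input files may carry elapsed time *or* beat index in column
  1; the method never uses it, so the reader accepts either and rebuilds
  onset times from the cumulative RR sum (anchored at the first column-1
  value) for internal consistency.  A `--ms` flag divides by 1000 for
  millisecond exports.

## Known limitations

* State assignment is a scalar RR threshold; a genuinely 2D separating
  boundary (e.g. perpendicular to the diagonal) is not fitted.
* Only lag-1, 2D maps are rendered; the lag parameter exists but
  higher-dimensional embeddings are out of scope.
* Animation durations/frame rates of published movies are descriptive;
  this implementation fixes 10 fps by default and makes no claim of
  pixel-level reproduction of any published figure.
* Peak detection on *unsmoothed* grids is noisy by construction; the
  defaults assume the smoother has run.
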