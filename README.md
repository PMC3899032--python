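# d3map — dynamical density delay maps for interbeat-interval time series

Physiologic signals such as cardiac interbeat (RR) intervals are highly
nonstationary: their mean, variance and correlation structure drift over
time, and a conventional time-series graph — or a whole-record Poincaré
plot — hides *when* those changes happen.  `d3map` implements the dynamical
density delay map: a moving-window generalization of the Poincaré plot in
which each window's lag-1 pairs (RR(n), RR(n+1)) are binned into a 2D
histogram, smoothed, normalized so the highest bin has relative density
h = 1, colourised, and rendered as an animated sequence of composite
figures (3D surface + contour map + raw segment).  The animation makes
state transitions, bistability and hidden temporal patterning — e.g. the
anomalous four-cluster ventricular response seen in some atrial
fibrillation recordings — directly visible.

It is intended for researchers and trainees in heart-rate-variability and
nonlinear-dynamics work, but applies to any sufficiently long time series.

## Method

For a series x(n), n = 1..N:

1. **Window** — segment the record with a moving time window (width W,
   shift S seconds; presets 500/10 s and 1200/300 s).
2. **Density** — for each window, bin the delay pairs (x(n), x(n+1)) into
   an `nbins × nbins` histogram on a fixed range shared by all windows;
   optionally smooth it with a difference-penalized (Whittaker-type)
   least-squares smoother: each column y is replaced by the solution of
   (I + 2λD₁ᵀD₁ + λ²D₂ᵀD₂) z = y with λ = nbins/λ_user, then the rows
   likewise; divide by the maximum bin so h ∈ [0, 1].
3. **Colourise** — map h linearly onto a colourmap (classic jet by default:
   blue = lowest, dark red = highest density).
4. **Compose** — render the 3D surface Poincaré plot, its 2D contour map
   and the raw segment in one figure with frame-invariant axes.
5. **Animate** — write the ordered frames as an animated GIF (MP4/AVI via
   an ffmpeg backend when available).

The library also quantifies what the animation shows: local density maxima
("states"), the density minimum separating two on-diagonal states, beat-
and duration-weighted state occupancy, and an L1 map-divergence statistic
that demonstrates the delay map's sensitivity to temporal ordering (a
shuffled surrogate has an identical interval histogram but a drastically
different map).

## Worked example

Simulate a sleep-like bistable record (30 000 beats switching between RR
states at 0.65 s ≈ 92 beats/min and 1.0 s ≈ 60 beats/min), then locate its
states and run the shuffle demonstration:

```sh
$ d3map simulate --kind bistable --n 30000 --seed 42 --out sleep_sim.dat
wrote 30000 beats to sleep_sim.dat

$ d3map peaks --input sleep_sim.dat
x_center  y_center  height  row  col
0.6511    0.6511    1.0000  38   38
0.9977    0.9977    0.9950  155  155

$ d3map shuffle-demo --input sleep_sim.dat --seed 42 --resamples 200
divergence(original, shuffled) = 1.4542
null 99th percentile (shuffle vs shuffle, 200 resamples) = 0.5748
exceeds null p99: True
```

The peak table recovers the two generating states (0.651 s and 0.998 s,
both with relative density near 1).  The divergence statistic, 1.45, is
far above the 0.57 that chance alone (shuffle vs shuffle) produces, even
though shuffling leaves the interval histogram exactly unchanged — the
delay map is reading temporal structure, not the amplitude distribution.

Render the animation (non-overlapping windows shown here for speed; use
`--preset sleep` for the standard 500 s / 10 s configuration):

```sh
$ d3map render --input sleep_sim.dat --window 500 --shift 500 --out sleep.gif --mode 3d
wrote 49 frames to sleep.gif
```

A machine-readable run summary (`sleep.gif.summary.json`) records the
resolved configuration, per-window pair counts and the full-record peak
table.

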