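"""Quantifying the structure the animations display.

Local maxima of the density surface are the system's "states"; for bistable
dynamics the density minimum along the identity diagonal between the two
on-diagonal states gives a scalar RR boundary, from which state occupancy
(beat- and duration-weighted) and dwell times follow.  The map-divergence
statistic — the L1 distance between mass-normalized grids — quantifies how
strongly shuffling the intervals deforms the delay map, which it does for
correlated dynamics even though the interval histogram is untouched.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .delay_density import DensityGrid
from .rr_io import RRSeries

__all__ = [
    "Peak",
    "StatePartition",
    "find_density_maxima",
    "find_separating_minimum",
    "state_occupancy",
    "map_divergence",
]


@dataclasses.dataclass(frozen=True)
class Peak:
    """A local density maximum ("state") of a delay map."""

    x_center: float
    y_center: float
    height: float
    bin_ij: tuple[int, int]

    @property
    def on_diagonal_rr(self) -> float:
        """Diagonal RR coordinate of the peak: mean of its two axes."""
        return 0.5 * (self.x_center + self.y_center)


@dataclasses.dataclass(frozen=True)
class StatePartition:
    """Two-state partition of a series by a scalar RR threshold.

    ``occupancy`` is beat-weighted (fraction of beats per state, summing to
    1 exactly); ``occupancy_time`` weights each beat by its RR interval, the
    elapsed time the heart spends in the state.  State 0 is RR < boundary
    (fast), state 1 is RR >= boundary (slow).  ``dwell_times`` holds the
    elapsed duration of every maximal run, per state.
    """

    boundary_rr: float
    occupancy: tuple[float, float]
    occupancy_time: tuple[float, float]
    dwell_times: tuple[np.ndarray, np.ndarray]


def _local_maxima_mask(values: np.ndarray) -> np.ndarray:
    """Bins that are >= all 8 neighbours (edges padded with -inf)."""
    padded = np.pad(values, 1, constant_values=-np.inf)
    center = padded[1:-1, 1:-1]
    mask = np.ones_like(values, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            mask &= center >= padded[1 + di : padded.shape[0] - 1 + di,
                                     1 + dj : padded.shape[1] - 1 + dj]
    return mask


def find_density_maxima(
    grid: DensityGrid,
    min_height: float = 0.2,
    min_separation: float = 0.1,
) -> list[Peak]:
    """Detect the local maxima ("states") of a normalized density grid.

    A bin qualifies when its value is >= all 8 neighbours and >= min_height.
    A flat plateau contributes only its lowest (row, col) bin.  Peaks closer
    than ``min_separation`` (Euclidean distance between bin centers, in
    seconds) are merged keeping the higher one; ties break toward the lowest
    (row, col) index.  Peaks are returned height-descending.
    """
    if not grid.normalized:
        raise ValueError("find_density_maxima expects a normalized grid")
    if not (0.0 < min_height < 1.0):
        raise ValueError(f"min_height must be in (0, 1): {min_height}")
    if min_separation < 0:
        raise ValueError(f"min_separation must be >= 0: {min_separation}")
    if grid.is_empty:
        return []

    values = grid.values
    mask = _local_maxima_mask(values) & (values >= min_height)
    rows, cols = np.nonzero(mask)

    # plateau rule: drop a candidate when an equal-valued neighbour has a
    # lexicographically lower (row, col) index
    keep = []
    candset = set(zip(rows.tolist(), cols.tolist()))
    for i, j in sorted(candset):
        dominated = False
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if (ni, nj) in candset and values[ni, nj] == values[i, j] and (ni, nj) < (i, j):
                    dominated = True
        if not dominated:
            keep.append((i, j))

    xc, yc = grid.x_centers, grid.y_centers
    peaks = [
        Peak(x_center=float(xc[i]), y_center=float(yc[j]),
             height=float(values[i, j]), bin_ij=(i, j))
        for i, j in keep
    ]
    # height-descending, deterministic tie-break on lowest (row, col)
    peaks.sort(key=lambda p: (-p.height, p.bin_ij))

    merged: list[Peak] = []
    for p in peaks:
        close = any(
            np.hypot(p.x_center - q.x_center, p.y_center - q.y_center) < min_separation
            for q in merged
        )
        if not close:
            merged.append(p)
    return merged


def find_separating_minimum(grid: DensityGrid, peak_a: Peak, peak_b: Peak) -> float:
    """RR value of the density minimum on the identity diagonal strictly
    between two on-diagonal peaks.

    The returned boundary is always interior to the open interval between
    the peaks' diagonal bin positions, never an endpoint.
    """
    if peak_a.bin_ij == peak_b.bin_ij:
        raise ValueError("peaks occupy the same bin; no separating minimum exists")
    ia = int(round(0.5 * (peak_a.bin_ij[0] + peak_a.bin_ij[1])))
    ib = int(round(0.5 * (peak_b.bin_ij[0] + peak_b.bin_ij[1])))
    lo, hi = sorted((ia, ib))
    if hi - lo < 2:
        raise ValueError("peaks are adjacent on the diagonal; no interior bin between them")
    profile = np.diagonal(grid.values)[lo + 1 : hi]
    k = int(np.argmin(profile))  # argmin takes the lowest index on ties
    return float(grid.x_centers[lo + 1 + k])


def state_occupancy(series: RRSeries, boundary_rr: float) -> StatePartition:
    """Partition beats by RR below/above a scalar boundary and measure
    occupancy both beat-weighted and duration-weighted (weight = RR)."""
    rr = series.intervals
    if not (rr.min() <= boundary_rr <= rr.max()):
        raise ValueError(
            f"boundary {boundary_rr} outside observed RR range [{rr.min()}, {rr.max()}]"
        )
    slow = rr >= boundary_rr
    n = len(rr)
    occ_beats = (float(np.sum(~slow)) / n, float(np.sum(slow)) / n)
    total_t = float(rr.sum())
    occ_time = (float(rr[~slow].sum()) / total_t, float(rr[slow].sum()) / total_t)

    # dwell times: elapsed duration of each maximal same-state run
    change = np.flatnonzero(np.diff(slow.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    dwell: tuple[list[float], list[float]] = ([], [])
    for s, e in zip(starts, ends):
        dwell[int(slow[s])].append(float(rr[s:e].sum()))
    return StatePartition(
        boundary_rr=float(boundary_rr),
        occupancy=occ_beats,
        occupancy_time=occ_time,
        dwell_times=(np.asarray(dwell[0]), np.asarray(dwell[1])),
    )


def map_divergence(grid_a: DensityGrid, grid_b: DensityGrid) -> float:
    """L1 distance between the mass-normalized (sum-to-1) surfaces of two
    grids on identical edges; lies in [0, 2] (total-variation style)."""
    if not (
        np.array_equal(grid_a.x_edges, grid_b.x_edges)
        and np.array_equal(grid_a.y_edges, grid_b.y_edges)
    ):
        raise ValueError("grids must share identical bin edges")

    def _mass_norm(v: np.ndarray) -> np.ndarray:
        s = v.sum()
        return v / s if s > 0 else v

    return float(np.abs(_mass_norm(grid_a.values) - _mass_norm(grid_b.values)).sum())
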