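"""Delay pairs, 2D density histograms, max-normalization and smoothing.

The density delay map of a segment is built in three stages:

1. lag-k delay pairs ``(RR(n), RR(n+k))`` (default lag 1, the Poincaré
   plot's point set);
2. a 2D histogram on a uniform grid, optionally smoothed by the
   difference-penalized least-squares (Whittaker-type) smoother used by the
   ``dscatter`` density-scatter routine: each column y of the grid is
   replaced by the solution of ``(I + 2*lam*D1'D1 + lam^2*D2'D2) z = y``
   with D1, D2 the first/second difference matrices and
   ``lam = nbins / lambda_user``, then the same smoother is applied along
   the rows;
3. division by the count m of the highest bin, mapping the surface onto
   [0, 1] — a relative occupancy of the delay plane, not a probability
   density.

Smoothing precedes normalization, so the final maximum is exactly 1.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .rr_io import InsufficientDataError, RRSeries

__all__ = [
    "DelayPairs",
    "DensityGrid",
    "DensityConfig",
    "make_delay_pairs",
    "compute_histogram2d",
    "normalize_to_unit_max",
    "smooth_density_2d",
    "compute_density_map",
    "shuffle_intervals",
    "histogram1d",
    "default_range",
    "save_grid_txt",
    "load_grid_txt",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DelayPairs:
    """The point set of a lag-k delay (return) map: x = RR(n), y = RR(n+k)."""

    x: np.ndarray
    y: np.ndarray
    lag: int = 1

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")

    def __len__(self) -> int:
        return len(self.x)


@dataclasses.dataclass
class DensityGrid:
    """A binned delay-density surface on a uniform grid.

    ``values[i, j]`` is the (possibly smoothed / normalized) density of the
    bin with x in ``[x_edges[i], x_edges[i+1])`` and y in
    ``[y_edges[j], y_edges[j+1])``; the last bin on each axis is closed.
    ``max_count_m`` records the count m of the highest bin of the raw
    histogram; normalization divides by the current maximum (equal to m when
    no smoothing intervenes).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    total_count: int
    max_count_m: float
    normalized: bool = False
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        nx, ny = len(self.x_edges) - 1, len(self.y_edges) - 1
        if self.values.shape != (nx, ny):
            raise ValueError(f"values shape {self.values.shape} != ({nx}, {ny})")
        for edges in (self.x_edges, self.y_edges):
            widths = np.diff(edges)
            if np.any(widths <= 0):
                raise ValueError("bin edges must be strictly increasing")
            if np.ptp(widths) > 1e-9 * widths[0]:
                raise ValueError("bins must be uniform")

    @property
    def nbins(self) -> int:
        return self.values.shape[0]

    @property
    def is_empty(self) -> bool:
        """True when no pair fell inside the grid range."""
        return self.total_count == 0

    @property
    def bin_width(self) -> float:
        return float(self.x_edges[1] - self.x_edges[0])

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def argmax(self) -> tuple[int, int]:
        """Lowest (row, col) index attaining the maximum value."""
        flat = int(np.argmax(self.values))
        return np.unravel_index(flat, self.values.shape)  # type: ignore[return-value]


@dataclasses.dataclass(frozen=True)
class DensityConfig:
    """Knobs of the density-map pipeline.

    ``range`` is the common (lo, hi) axis interval in seconds; when None it
    is derived from the full record with :func:`default_range` and must be
    held fixed across all windows of one animation so frames share axes.
    ``lambda_user`` is the user-facing smoothing parameter (the effective
    penalty is ``nbins / lambda_user``); larger values smooth less.
    """

    nbins: int = 200
    range: tuple[float, float] | None = None
    lambda_user: float = 20.0
    smooth: bool = True
    lag: int = 1


def default_range(series: RRSeries, pad_frac: float = 0.02) -> tuple[float, float]:
    """Full-record [min, max] RR interval padded by ``pad_frac`` each side."""
    lo, hi = float(np.min(series.intervals)), float(np.max(series.intervals))
    pad = (hi - lo) * pad_frac if hi > lo else max(abs(hi) * pad_frac, 1e-6)
    return lo - pad, hi + pad


def make_delay_pairs(series: RRSeries, lag: int = 1) -> DelayPairs:
    """Form the lag-k delay pairs (RR(n), RR(n+lag)) of a series, in order."""
    if lag < 1:
        raise ValueError(f"lag must be >= 1: {lag}")
    n = len(series)
    if n <= lag:
        raise InsufficientDataError(f"need more than lag={lag} beats, have {n}")
    rr = series.intervals
    return DelayPairs(x=rr[:-lag], y=rr[lag:], lag=lag)


def compute_histogram2d(
    pairs: DelayPairs, nbins: int, range: tuple[float, float]
) -> DensityGrid:
    """Bin delay pairs on a uniform nbins x nbins grid over ``range`` squared.

    Bins are half-open ``[e_i, e_{i+1})`` with the last bin closed; pairs
    outside the range are dropped and counted in ``n_out_of_range``.  An
    empty result is flagged, not raised, so silent windows do not abort an
    animation.
    """
    if nbins < 2:
        raise ValueError(f"nbins must be >= 2: {nbins}")
    lo, hi = range
    if not lo < hi:
        raise ValueError(f"range must satisfy lo < hi: {range}")
    counts, x_edges, y_edges = np.histogram2d(
        pairs.x, pairs.y, bins=nbins, range=[[lo, hi], [lo, hi]]
    )
    total = int(counts.sum())
    dropped = len(pairs) - total
    if dropped:
        logger.info("dropped %d of %d delay pairs outside [%g, %g]", dropped, len(pairs), lo, hi)
    return DensityGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        values=counts,
        total_count=total,
        max_count_m=float(counts.max()) if total else 0.0,
        normalized=False,
        n_out_of_range=dropped,
    )


def normalize_to_unit_max(grid: DensityGrid) -> DensityGrid:
    """Divide every bin by the maximum bin value, mapping the surface to [0, 1].

    An all-zero grid passes through unchanged (no division by zero); a grid
    that is already normalized is rejected to prevent double normalization.
    """
    if grid.normalized:
        raise ValueError("grid is already normalized")
    m = float(grid.values.max()) if grid.values.size else 0.0
    values = grid.values / m if m > 0 else grid.values.copy()
    return dataclasses.replace(grid, values=values, normalized=True)


def _difference_penalty(n: int, lam: float) -> sparse.csc_matrix:
    """The dscatter smoothing operator ``I + 2*lam*D1'D1 + lam^2*D2'D2``."""
    eye = sparse.identity(n, format="csc")
    d1 = sparse.diags_array([-np.ones(n - 1), np.ones(n - 1)], offsets=[0, 1], shape=(n - 1, n))
    d2 = sparse.diags_array(
        [np.ones(n - 2), -2.0 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
    )
    return (eye + 2.0 * lam * (d1.T @ d1) + lam**2 * (d2.T @ d2)).tocsc()


def smooth_density_2d(grid: DensityGrid, lambda_user: float = 20.0) -> DensityGrid:
    """Smooth a grid by the separable difference-penalized solver.

    Every column is replaced by the solution z of
    ``(I + 2*lam*D1'D1 + lam^2*D2'D2) z = y`` with ``lam = nbins/lambda_user``,
    then the rows of the result are smoothed the same way.  The penalty
    matrices annihilate constants and have zero column sums, so constants
    pass through unchanged and total mass is conserved.
    """
    if lambda_user <= 0:
        raise ValueError(f"lambda_user must be positive: {lambda_user}")
    n = grid.nbins
    if n < 3:
        raise ValueError(f"smoothing needs nbins >= 3 (second differences), got {n}")
    lam = n / lambda_user
    lu = splu(_difference_penalty(n, lam))
    z = lu.solve(grid.values)      # smooth down each column of the delay plane
    z = lu.solve(z.T).T            # then along each row
    return dataclasses.replace(grid, values=z)


def compute_density_map(series: RRSeries, config: DensityConfig = DensityConfig()) -> DensityGrid:
    """Full pipeline: delay pairs -> 2D histogram -> (smooth) -> unit-max normalize.

    Smoothing is applied to the raw counts before normalization so the
    output maximum is exactly 1 for any non-empty input.
    """
    pairs = make_delay_pairs(series, lag=config.lag)
    rng = config.range if config.range is not None else default_range(series)
    grid = compute_histogram2d(pairs, nbins=config.nbins, range=rng)
    if config.smooth and not grid.is_empty:
        grid = smooth_density_2d(grid, lambda_user=config.lambda_user)
    return normalize_to_unit_max(grid)


def shuffle_intervals(series: RRSeries, seed: int) -> RRSeries:
    """Randomise the order of the RR intervals (surrogate that destroys
    correlations while leaving the interval histogram exactly unchanged).

    Onset times are rebuilt by cumulative summation from the original start.
    """
    if len(series) < 2:
        raise InsufficientDataError("need at least 2 beats to shuffle")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(series.intervals)
    return RRSeries.from_intervals(
        shuffled, t0=float(series.onset_times[0]), label=f"{series.label}|shuffled"
    )


def histogram1d(series: RRSeries, nbins: int, range: tuple[float, float]) -> np.ndarray:
    """1D interval histogram with the same binning conventions as the 2D grid."""
    if nbins < 2:
        raise ValueError(f"nbins must be >= 2: {nbins}")
    lo, hi = range
    if not lo < hi:
        raise ValueError(f"range must satisfy lo < hi: {range}")
    counts, _ = np.histogram(series.intervals, bins=nbins, range=(lo, hi))
    return counts


def save_grid_txt(grid: DensityGrid, path: str | Path) -> Path:
    """Write a grid as a plain-text matrix with a 3-line header."""
    path = Path(path)
    header = (
        f"nbins {grid.nbins}\n"
        f"x_range {grid.x_edges[0]:.9g} {grid.x_edges[-1]:.9g}\n"
        f"y_range {grid.y_edges[0]:.9g} {grid.y_edges[-1]:.9g}"
    )
    np.savetxt(path, grid.values, header=header, comments="# ")
    return path


def load_grid_txt(path: str | Path) -> DensityGrid:
    """Read a grid written by :func:`save_grid_txt`."""
    path = Path(path)
    with open(path) as fh:
        lines = [fh.readline() for _ in range(3)]
    meta = {}
    for line in lines:
        parts = line.lstrip("# ").split()
        meta[parts[0]] = [float(v) for v in parts[1:]]
    nbins = int(meta["nbins"][0])
    values = np.loadtxt(path)
    values = values.reshape(nbins, nbins)
    x_edges = np.linspace(meta["x_range"][0], meta["x_range"][1], nbins + 1)
    y_edges = np.linspace(meta["y_range"][0], meta["y_range"][1], nbins + 1)
    total = int(round(values.sum()))
    return DensityGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        values=values,
        total_count=total,
        max_count_m=float(values.max()) if values.size else 0.0,
        normalized=bool(values.size and abs(values.max() - 1.0) < 1e-12),
    )
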