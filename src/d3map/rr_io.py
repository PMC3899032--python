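"""Reading and writing RR-interval series in plain-ASCII beat tables.

The on-disk layout is one beat per row, whitespace-delimited, no header:
either two columns (beat onset time or index, RR interval in seconds) or a
single column of RR intervals.  Lines starting with ``#`` are comments.
This is the layout of the PhysioNet-derived ``.dat`` exports the method was
designed around.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "RRSeries",
    "read_rr_ascii",
    "write_rr_ascii",
    "InsufficientDataError",
    "RRParseError",
]


class RRParseError(ValueError):
    """A row of an RR file could not be parsed as numbers."""


class InsufficientDataError(ValueError):
    """Fewer beats than the operation requires."""


@dataclasses.dataclass(frozen=True)
class RRSeries:
    """An ordered sequence of heartbeats.

    Parameters
    ----------
    onset_times : ndarray
        Per-beat onset time in seconds, non-decreasing.  When reconstructed
        from intervals, ``onset_times[n] == onset_times[0] + sum(intervals[:n])``.
    intervals : ndarray
        RR interval RR(n) in seconds, one per beat, strictly positive.
    label : str
        Free-text identifier carried through the pipeline.
    """

    onset_times: np.ndarray
    intervals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onset_times, dtype=float)
        ivals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "onset_times", onsets)
        object.__setattr__(self, "intervals", ivals)
        if onsets.ndim != 1 or ivals.ndim != 1:
            raise ValueError("onset_times and intervals must be 1-D")
        if len(onsets) != len(ivals):
            raise ValueError(
                f"length mismatch: {len(onsets)} onset times vs {len(ivals)} intervals"
            )
        if len(ivals) and not np.all(ivals > 0):
            bad = int(np.argmin(ivals > 0))
            raise ValueError(f"RR intervals must be positive (beat {bad}: {ivals[bad]})")
        if len(onsets) > 1 and np.any(np.diff(onsets) < 0):
            raise ValueError("onset_times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration(self) -> float:
        """Elapsed time from first to last beat onset, in seconds."""
        if len(self) == 0:
            return 0.0
        return float(self.onset_times[-1] - self.onset_times[0])

    @classmethod
    def from_intervals(
        cls, intervals: np.ndarray, t0: float = 0.0, label: str = ""
    ) -> "RRSeries":
        """Build a series from intervals alone, reconstructing onset times.

        Onsets are the cumulative sum of the preceding intervals starting at
        ``t0``, so the n-th onset is exactly ``t0 + sum(intervals[:n])``.
        """
        ivals = np.asarray(intervals, dtype=float)
        onsets = t0 + np.concatenate(([0.0], np.cumsum(ivals[:-1])))
        return cls(onsets, ivals, label=label)


def read_rr_ascii(
    path: str | Path,
    column_layout: Literal["two_column_time_rr", "one_column_rr"] = "two_column_time_rr",
    *,
    ms: bool = False,
) -> RRSeries:
    """Read an RR series from a whitespace-delimited ASCII beat table.

    For two-column input the RR intervals are taken from column 2; column 1
    (elapsed time or beat index — either is accepted, and the method never
    uses it) only anchors the reconstructed onset times, which are always
    recomputed from the cumulative RR sum for internal consistency.

    Parameters
    ----------
    path : path
        File to read.  Rows starting with ``#`` are skipped.
    column_layout : {"two_column_time_rr", "one_column_rr"}
        Number and meaning of columns.
    ms : bool
        If true, input values are milliseconds and are divided by 1000.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                rows.append([float(tok) for tok in stripped.split()])
            except ValueError:
                raise RRParseError(f"{path}: non-numeric row at line {lineno}: {stripped!r}")
    if len(rows) < 2:
        raise InsufficientDataError(f"{path}: need at least 2 beats, found {len(rows)}")

    ncol = 2 if column_layout == "two_column_time_rr" else 1
    for lineno0, row in enumerate(rows):
        if len(row) < ncol:
            raise RRParseError(
                f"{path}: expected {ncol} column(s), found {len(row)} in data row {lineno0 + 1}"
            )
    data = np.asarray([row[:ncol] for row in rows], dtype=float)
    if ms:
        data = data / 1000.0

    if column_layout == "two_column_time_rr":
        intervals = data[:, 1]
        t0 = float(data[0, 0])
    else:
        intervals = data[:, 0]
        t0 = 0.0
    if np.any(intervals <= 0):
        bad = int(np.argmax(intervals <= 0))
        raise ValueError(f"{path}: non-positive RR interval at beat {bad + 1}")
    return RRSeries.from_intervals(intervals, t0=t0, label=path.stem)


def write_rr_ascii(series: RRSeries, path: str | Path) -> Path:
    """Write a series as a two-column (onset time, RR) ASCII table, 6 decimals."""
    if len(series) == 0:
        raise InsufficientDataError("cannot write an empty RRSeries")
    path = Path(path)
    with open(path, "w") as fh:
        for t, rr in zip(series.onset_times, series.intervals):
            fh.write(f"{t:.6f} {rr:.6f}\n")
    return path
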