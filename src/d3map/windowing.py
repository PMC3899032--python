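"""Segmentation of a beat series into overlapping time-based windows.

Windows are quoted in seconds, not beats: RR series are irregularly sampled
in beat count, and the method's presets (a 500 s window shifted 10 s for
sleep recordings; 1200 s shifted 300 s for the atrial-fibrillation records)
are stated in elapsed time.  Windows are anchored at the first beat's onset;
trailing data shorter than one full window is dropped with a log message.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterator

import numpy as np

from .rr_io import RRSeries

__all__ = ["WindowSpec", "Segment", "iter_windows", "window_count", "PRESETS"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry: width and shift, both in seconds."""

    width_sec: float = 500.0
    shift_sec: float = 10.0

    def __post_init__(self) -> None:
        if self.width_sec <= 0:
            raise ValueError(f"width_sec must be positive: {self.width_sec}")
        if not (0 < self.shift_sec <= self.width_sec):
            raise ValueError(
                f"shift_sec must be in (0, width_sec]: shift={self.shift_sec}, width={self.width_sec}"
            )


#: Named window presets mirroring the two standard configurations.
PRESETS: dict[str, WindowSpec] = {
    "sleep": WindowSpec(500.0, 10.0),
    "af": WindowSpec(1200.0, 300.0),
}


@dataclasses.dataclass(frozen=True)
class Segment:
    """One window of a series: the beats whose onsets fall in [t_start, t_end)."""

    t_start: float
    t_end: float
    series: RRSeries
    index: int


def window_count(duration: float, spec: WindowSpec) -> int:
    """Number of windows: floor((T - width) / shift) + 1 for T >= width."""
    if duration < spec.width_sec:
        return 0
    return int(math.floor((duration - spec.width_sec) / spec.shift_sec)) + 1


def iter_windows(series: RRSeries, spec: WindowSpec) -> Iterator[Segment]:
    """Yield the ordered overlapping windows of a series.

    The k-th window starts at ``onset_times[0] + k * shift_sec`` and selects
    the beats with onset in ``[t_start, t_start + width_sec)``, preserving
    beat order.  Raises if the record is shorter than one window.
    """
    t0 = float(series.onset_times[0])
    duration = series.duration
    n_win = window_count(duration, spec)
    if n_win == 0:
        raise ValueError(
            f"record duration {duration:.1f} s is shorter than the "
            f"{spec.width_sec:.1f} s window"
        )
    tail = duration - ((n_win - 1) * spec.shift_sec + spec.width_sec)
    if tail > 0:
        logger.info("dropping %.1f s of trailing data shorter than one window", tail)
    onsets = series.onset_times
    for k in range(n_win):
        t_start = t0 + k * spec.shift_sec
        t_end = t_start + spec.width_sec
        i0, i1 = np.searchsorted(onsets, [t_start, t_end], side="left")
        sub = RRSeries(
            onset_times=onsets[i0:i1],
            intervals=series.intervals[i0:i1],
            label=f"{series.label}[{t_start:.0f}s,{t_end:.0f}s)",
        )
        yield Segment(t_start=t_start, t_end=t_end, series=sub, index=k)
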