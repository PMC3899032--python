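"""Assembling rendered frames into animated containers.

GIF is the reference format: it is lossless given a stable palette, so
re-encoding the same frames reproduces pixel-identical output, which the
tests rely on.  MP4/AVI writing goes through imageio's ffmpeg plugin and
raises a clear error when no ffmpeg encoder backend is present.

Long animations (thousands of frames) should be written through
:func:`open_animation_writer`, which streams frames to disk one at a time
instead of holding the whole sequence in memory.
"""

from __future__ import annotations

import contextlib
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v2 as iio2
import imageio.v3 as iio
import numpy as np

__all__ = ["write_animation", "open_animation_writer", "read_animation_frames"]

_FORMATS = {"gif", "mp4", "avi"}


class AnimationWriter:
    """Incremental frame sink; enforces a single pixel size across frames."""

    def __init__(self, backend, path: Path) -> None:
        self._backend = backend
        self.path = path
        self.n_frames = 0
        self._shape: tuple[int, ...] | None = None

    def append(self, frame: np.ndarray) -> None:
        arr = np.ascontiguousarray(np.asarray(frame, dtype=np.uint8))
        if self._shape is None:
            self._shape = arr.shape
        elif arr.shape != self._shape:
            raise ValueError(
                f"frame {self.n_frames} has size {arr.shape}, expected {self._shape}"
            )
        self._backend.append_data(arr)
        self.n_frames += 1


@contextlib.contextmanager
def open_animation_writer(
    path: str | Path, fps: float = 10.0, format: str | None = None
) -> Iterator[AnimationWriter]:
    """Context manager yielding a streaming :class:`AnimationWriter`.

    Frames are encoded as they are appended, so memory use is one frame
    regardless of animation length.
    """
    if fps <= 0:
        raise ValueError(f"fps must be positive: {fps}")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {sorted(_FORMATS)}")
    if fmt == "gif":
        # duration in ms per frame; loop forever
        backend = iio2.get_writer(path, duration=1000.0 / fps, loop=0)
    else:
        try:
            backend = iio2.get_writer(path, format="FFMPEG", fps=fps)
        except (ImportError, IndexError) as exc:
            raise RuntimeError(
                f"writing {fmt} requires an ffmpeg encoder backend "
                "(imageio-ffmpeg or an ffmpeg binary), which is not installed; "
                "use the gif format instead"
            ) from exc
    writer = AnimationWriter(backend, path)
    try:
        yield writer
    finally:
        backend.close()
    if writer.n_frames == 0:
        raise ValueError("need at least 1 frame")


def write_animation(
    frames: Sequence[np.ndarray],
    fps: float = 10.0,
    path: str | Path = "animation.gif",
    format: str | None = None,
) -> Path:
    """Write an ordered, in-memory frame sequence as an animation file.

    Parameters
    ----------
    frames : sequence of (H, W, 3) uint8 arrays
        All frames must share one pixel size.
    fps : float
        Frame rate; a 10-frame animation at 5 fps plays for 2 s.
    path : path
        Output file; its suffix supplies the format unless ``format`` is given.
    format : {"gif", "mp4", "avi"}, optional
    """
    if len(frames) == 0:
        raise ValueError("need at least 1 frame")
    shape0 = np.asarray(frames[0]).shape
    bad = [i for i, f in enumerate(frames) if np.asarray(f).shape != shape0]
    if bad:
        raise ValueError(f"frames {bad} differ in size from frame 0 {shape0}")
    with open_animation_writer(path, fps=fps, format=format) as writer:
        for frame in frames:
            writer.append(frame)
    return Path(path)


def read_animation_frames(path: str | Path) -> list[np.ndarray]:
    """Decode an animation back into a list of RGB frames."""
    frames = iio.imread(Path(path), index=None)
    return [np.asarray(f)[..., :3] for f in frames]
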