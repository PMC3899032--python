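"""Colourisation and per-window composite figures.

Each frame of a D3-Map animation is a fixed-axes composite of (top) the
colourised 3D surface Poincaré plot of the window's density grid, (middle)
its colourised 2D contour map, and (bottom) the raw interbeat-interval
segment.  The relative density h in [0, 1] is mapped linearly onto a
colourmap; the default is the classic 9-anchor "jet" table
(blue -> cyan -> yellow -> red), pinned here so the colours do not depend
on a plotting backend's own jet variant.

All rendering is done on an Agg canvas with explicit Figure objects (no
pyplot global state), so identical inputs produce byte-identical rasters.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from matplotlib import colors as mcolors
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .delay_density import DensityGrid
from .windowing import Segment

__all__ = [
    "RenderConfig",
    "JET_ANCHORS",
    "get_colormap",
    "map_to_colour",
    "render_frame",
    "render_contour_only",
]

logger = logging.getLogger(__name__)

#: Classic 9-anchor jet table: dark blue through cyan and yellow to dark red.
JET_ANCHORS: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 0.5),
    (0.0, 0.0, 1.0),
    (0.0, 0.5, 1.0),
    (0.0, 1.0, 1.0),
    (0.5, 1.0, 0.5),
    (1.0, 1.0, 0.0),
    (1.0, 0.5, 0.0),
    (1.0, 0.0, 0.0),
    (0.5, 0.0, 0.0),
)


@dataclasses.dataclass(frozen=True)
class RenderConfig:
    """Figure options shared by every frame of one animation.

    ``axis_range`` is the common RR axis interval (seconds) of the density
    panels; it must not change between frames or states would appear to
    drift.  ``size_px`` is the (width, height) of the full composite.
    """

    colormap: str = "jet"
    n_contour_levels: int = 10
    size_px: tuple[int, int] = (640, 960)
    axis_range: tuple[float, float] = (0.2, 1.5)
    dpi: int = 100

    def __post_init__(self) -> None:
        if self.n_contour_levels < 2:
            raise ValueError(f"n_contour_levels must be >= 2: {self.n_contour_levels}")
        if not self.axis_range[0] < self.axis_range[1]:
            raise ValueError(f"invalid axis_range: {self.axis_range}")


def get_colormap(name: str = "jet") -> mcolors.Colormap:
    """Resolve a colourmap name; "jet" uses the pinned anchor table."""
    if name == "jet":
        return mcolors.LinearSegmentedColormap.from_list("jet_classic", JET_ANCHORS, N=256)
    import matplotlib

    return matplotlib.colormaps[name]


def map_to_colour(h, colormap: str = "jet") -> np.ndarray:
    """Linear lookup of relative density h in [0, 1] into a colourmap.

    Returns RGB in [0, 1] (alpha stripped); scalar input gives one triple,
    array input an array of triples.  Values outside [0, 1] are clamped
    with a logged warning.
    """
    harr = np.asarray(h, dtype=float)
    if np.any(harr < 0) or np.any(harr > 1):
        logger.warning("density values outside [0, 1] clamped before colour lookup")
        harr = np.clip(harr, 0.0, 1.0)
    cmap = get_colormap(colormap)
    rgba = cmap(harr)
    return np.asarray(rgba)[..., :3]


def _contour_levels(n: int) -> np.ndarray:
    # linear in h over (0, 1]; level 0 is omitted so empty background stays blank
    return np.linspace(0.0, 1.0, n + 1)[1:]


def _figure(config: RenderConfig) -> Figure:
    w_px, h_px = config.size_px
    fig = Figure(figsize=(w_px / config.dpi, h_px / config.dpi), dpi=config.dpi)
    FigureCanvasAgg(fig)
    return fig


def _to_array(fig: Figure) -> np.ndarray:
    fig.canvas.draw()
    buf = np.asarray(fig.canvas.buffer_rgba())
    return buf[..., :3].copy()


def _draw_series_panel(ax, segment: Segment, config: RenderConfig) -> None:
    s = segment.series
    if len(s) == 0:
        ax.text(0.5, 0.5, "no beats in window", ha="center", va="center",
                transform=ax.transAxes)
    else:
        ax.plot(s.onset_times, s.intervals, lw=0.5, color="k")
    ax.set_xlim(segment.t_start, segment.t_end)
    ax.set_ylim(*config.axis_range)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("RR (s)")


def _draw_contour_panel(ax, grid: DensityGrid, config: RenderConfig) -> None:
    ax.set_xlim(*config.axis_range)
    ax.set_ylim(*config.axis_range)
    ax.set_aspect("equal")
    ax.set_xlabel("RR(n) (s)")
    ax.set_ylabel("RR(n+1) (s)")
    if grid.is_empty:
        return
    cmap = get_colormap(config.colormap)
    x, y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    ax.contourf(x, y, grid.values, levels=_contour_levels(config.n_contour_levels),
                cmap=cmap, vmin=0.0, vmax=1.0)


def _draw_surface_panel(ax3d, grid: DensityGrid, config: RenderConfig) -> None:
    ax3d.view_init(elev=30.0, azim=-37.5)
    ax3d.set_xlim(*config.axis_range)
    ax3d.set_ylim(*config.axis_range)
    ax3d.set_zlim(0.0, 1.0)
    ax3d.set_xlabel("RR(n) (s)")
    ax3d.set_ylabel("RR(n+1) (s)")
    ax3d.set_zlabel("h")
    if grid.is_empty:
        return
    cmap = get_colormap(config.colormap)
    x, y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    ax3d.plot_surface(x, y, grid.values, cmap=cmap, vmin=0.0, vmax=1.0,
                      linewidth=0, antialiased=False, rcount=min(grid.nbins, 100),
                      ccount=min(grid.nbins, 100))


def render_frame(segment: Segment, grid: DensityGrid, config: RenderConfig) -> np.ndarray:
    """Render the full three-panel composite for one window.

    Layout: 3D surface Poincaré plot (top), 2D contour map (middle),
    time-series segment (bottom).  Returns an (H, W, 3) uint8 raster.
    Empty windows render blank panels with a caption flag instead of
    raising, so an animation survives silent stretches.
    """
    fig = _figure(config)
    ax_top = fig.add_subplot(3, 1, 1, projection="3d")
    ax_mid = fig.add_subplot(3, 1, 2)
    ax_bot = fig.add_subplot(3, 1, 3)
    _draw_surface_panel(ax_top, grid, config)
    _draw_contour_panel(ax_mid, grid, config)
    _draw_series_panel(ax_bot, segment, config)
    if grid.is_empty:
        fig.suptitle("empty window", fontsize=8)
    fig.subplots_adjust(left=0.14, right=0.97, bottom=0.06, top=0.97, hspace=0.45)
    return _to_array(fig)


def render_contour_only(segment: Segment, grid: DensityGrid, config: RenderConfig) -> np.ndarray:
    """Two-panel variant: contour map (top) over the series segment (bottom)."""
    fig = _figure(config)
    ax_top = fig.add_subplot(2, 1, 1)
    ax_bot = fig.add_subplot(2, 1, 2)
    _draw_contour_panel(ax_top, grid, config)
    _draw_series_panel(ax_bot, segment, config)
    if grid.is_empty:
        fig.suptitle("empty window", fontsize=8)
    fig.subplots_adjust(left=0.14, right=0.97, bottom=0.06, top=0.97, hspace=0.35)
    return _to_array(fig)
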