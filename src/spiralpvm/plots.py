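"""Headless figure rendering (24-segment colour maps, Bland-Altman plots).

Uses matplotlib Figure objects directly so no GUI backend is ever touched;
the numeric grids stay testable without rendering.
"""

from __future__ import annotations

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .cohort import ColourGrid


def render_colour_grid(grid: ColourGrid, path, title: str | None = None) -> None:
    """Colour plot: 24 angular segments (anterior at top) against template
    time, symmetric colour scale, section boundaries as vertical lines."""
    fig = Figure(figsize=(7, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    lim = grid.colour_limit or 1.0
    im = ax.imshow(
        grid.values,
        aspect="auto",
        origin="upper",
        cmap="RdBu_r",
        vmin=-lim,
        vmax=lim,
        extent=[grid.times[0], grid.times[-1], 24, 0],
    )
    for col in grid.marker_columns:
        ax.axvline(grid.times[col], color="k", lw=0.8)
    for row in range(4, 24, 4):
        ax.axhline(row, color="k", lw=0.4, alpha=0.5)
    ax.set_xlabel("template time (ms)")
    ax.set_ylabel("segment (anterior → lateral → inferior → septal)")
    ax.set_title(title or f"{grid.direction} velocity, {grid.slice_level} slice")
    fig.colorbar(im, ax=ax, label="velocity (cm/s)")
    fig.savefig(path, dpi=110, bbox_inches="tight")


def render_bland_altman(result: dict, path, title: str = "") -> None:
    fig = Figure(figsize=(5, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    ax.plot(result["means"], result["differences"], "d", color="tab:blue")
    for key, style in (("bias", "-"), ("upper_limit", "--"), ("lower_limit", "--")):
        ax.axhline(result[key], color="tab:blue", ls=style, lw=0.9)
    ax.set_xlabel("mean of the two measurements")
    ax.set_ylabel("difference (day 2 − day 1)")
    ax.set_title(title)
    fig.savefig(path, dpi=110, bbox_inches="tight")
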