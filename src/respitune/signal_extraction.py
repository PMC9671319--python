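"""Per-block mean-luminance time series over the deforming grid.

A pixel belongs to a cell when its center falls inside the cell polygon
(pixel centers sit at integer coordinates, x = column, y = row).  Cells are
about 4x4 px, so center membership is an adequate stand-in for partial-area
weighting.  A cell that captures no pixel center keeps a value — the frame
bilinearly interpolated at the cell centroid — so the block count B stays
constant across frames.

The differenced series out(b, t) = value(b, t+1) - value(b, t) is the default
input of the spectral stage: differencing removes the static per-block offset
(rib shadows, lung thickness baseline) exactly and emphasizes the respiratory
luminance wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .block_grid import BlockGrid
from .cine_io import CineSequence
from .lung_geometry import sample_image

__all__ = [
    "BlockSignalMatrix",
    "cell_pixel_indices",
    "extract_block_means",
    "difference_frames",
]


@dataclass
class BlockSignalMatrix:
    """B blocks x T frames of mean luminance (detector counts)."""

    values: np.ndarray
    ids: list[tuple[str, int, int]]
    differenced: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (B, T)")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("ids length does not match value rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite block signal values")

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def cell_pixel_indices(poly: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels whose centers lie inside a cell polygon.

    Restricted to the polygon's bounding box; coordinates outside the image
    are clipped away.  Raises ValueError when the cell lies fully outside the
    image.
    """
    h, w = shape
    xmin, ymin = poly.min(axis=0)
    xmax, ymax = poly.max(axis=0)
    if xmax < 0 or ymax < 0 or xmin > w - 1 or ymin > h - 1:
        raise ValueError("cell polygon fully outside image bounds")
    c0, c1 = max(0, int(np.ceil(xmin))), min(w - 1, int(np.floor(xmax)))
    r0, r1 = max(0, int(np.ceil(ymin))), min(h - 1, int(np.floor(ymax)))
    if c1 < c0 or r1 < r0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = np.stack([cols.ravel(), rows.ravel()], axis=1)
    inside = MplPath(poly).contains_points(pts)
    return rows.ravel()[inside], cols.ravel()[inside]


def extract_block_means(cine: CineSequence, grid: BlockGrid) -> BlockSignalMatrix:
    """Mean luminance of every cell at every frame.

    value(b, t) is the arithmetic mean of the pixels whose centers fall inside
    cell b's polygon at frame t; empty cells fall back to the bilinear value
    at the cell centroid.
    """
    if grid.n_frames != cine.n_frames:
        raise ValueError(
            f"grid covers {grid.n_frames} frames but cine has {cine.n_frames}"
        )
    shape = cine.shape
    values = np.empty((grid.n_cells, cine.n_frames))
    for t in range(cine.n_frames):
        frame = cine.frames[t]
        for b in range(grid.n_cells):
            poly = grid.polys[t, b]
            rows, cols = cell_pixel_indices(poly, shape)
            if rows.size:
                values[b, t] = frame[rows, cols].mean()
            else:
                values[b, t] = sample_image(frame, poly.mean(axis=0))[0]
    return BlockSignalMatrix(values=values, ids=list(grid.ids))


def difference_frames(signals: BlockSignalMatrix) -> BlockSignalMatrix:
    """Adjacent-frame differences, out(b, t) = value(b, t+1) - value(b, t)."""
    if signals.differenced:
        raise ValueError("signals are already differenced")
    if signals.n_frames < 2:
        raise ValueError("need >=2 frames to difference")
    return BlockSignalMatrix(
        values=np.diff(signals.values, axis=1),
        ids=list(signals.ids),
        differenced=True,
    )
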