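"""Color rendering of the respiratory-band signal inside the lung fields.

Each grid cell is filled with a diverging colormap value of its reconstructed
respiratory signal at that frame, drawn in the deforming lung-field shape;
pixels outside both lungs show the grayscale underlay (or black) unchanged.
The color scale is fixed across frames and symmetric about zero so the
temporal oscillation and local phase reversals stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import matplotlib
import numpy as np
from scipy.ndimage import gaussian_filter

from .block_grid import BlockGrid
from .cine_io import CineSequence
from .signal_extraction import cell_pixel_indices
from .spectral import SpectralResult

__all__ = ["RenderStyle", "DynamicImage", "render_frames", "render_map", "export_video"]


@dataclass(frozen=True)
class RenderStyle:
    """Rendering options: colormap, alpha blend over the underlay, scale."""

    cmap: str = "RdBu_r"
    alpha: float = 0.5
    underlay: bool = True
    vmax: float | None = None  # default: 99th percentile of |recon|
    blur_sigma: float = 0.0  # optional inter-cell Gaussian post-blur


@dataclass
class DynamicImage:
    """Rendered color frames (T, H, W, 3) uint8 plus the scale used."""

    frames: np.ndarray
    vmax: float
    cmap: str


def _scale_limit(recon: np.ndarray, style: RenderStyle) -> float:
    if style.vmax is not None:
        return float(style.vmax)
    v = float(np.percentile(np.abs(recon), 99.0))
    return v if v > 0 else 1.0


def render_frames(
    result: SpectralResult,
    grid: BlockGrid,
    cine: CineSequence,
    style: RenderStyle = RenderStyle(),
) -> DynamicImage:
    """Fill each cell polygon with the colormap value of recon(b, t).

    The number of rendered frames is min(len(recon), len(grid)); with the
    differenced analysis signal this is one less than the cine length.
    Identical inputs and style yield bit-identical output.
    """
    if list(result.ids) != list(grid.ids):
        raise ValueError("spectral result and grid have mismatched block ids")
    n = min(result.n_frames, grid.n_frames, cine.n_frames)
    h, w = cine.shape
    cmap = matplotlib.colormaps[style.cmap]
    vmax = _scale_limit(result.recon, style)
    out = np.empty((n, h, w, 3), dtype=np.uint8)
    alpha = style.alpha if style.underlay else 1.0
    for t in range(n):
        if style.underlay:
            g = cine.frames[t].astype(float) / (cine.bit_depth - 1)
            base = np.repeat(g[:, :, None], 3, axis=2)
        else:
            base = np.zeros((h, w, 3))
        overlay = base.copy()
        signal = np.zeros((h, w))
        mask = np.zeros((h, w), dtype=bool)
        for b in range(grid.n_cells):
            rows, cols = cell_pixel_indices(grid.polys[t, b], (h, w))
            signal[rows, cols] = result.recon[b, t]
            mask[rows, cols] = True
        if style.blur_sigma > 0:
            signal = gaussian_filter(signal, style.blur_sigma)
        norm = np.clip(0.5 + signal / (2.0 * vmax), 0.0, 1.0)
        colors = cmap(norm)[:, :, :3]
        overlay[mask] = (1.0 - alpha) * base[mask] + alpha * colors[mask]
        out[t] = np.clip(np.rint(overlay * 255.0), 0, 255).astype(np.uint8)
    return DynamicImage(frames=out, vmax=vmax, cmap=style.cmap)


def render_map(
    values: np.ndarray,
    grid: BlockGrid,
    shape: tuple[int, int],
    t: int = 0,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """Still map (H, W, 3) of one scalar per block (amplitude or phase)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != grid.n_cells:
        raise ValueError("one value per block required")
    lo = float(values.min()) if vmin is None else vmin
    hi = float(values.max()) if vmax is None else vmax
    span = hi - lo if hi > lo else 1.0
    cm = matplotlib.colormaps[cmap]
    img = np.zeros((*shape, 3))
    for b in range(grid.n_cells):
        rows, cols = cell_pixel_indices(grid.polys[t, b], shape)
        img[rows, cols] = cm((values[b] - lo) / span)[:3]
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def export_video(frames: np.ndarray, path, fps: float) -> list[Path]:
    """Export rendered frames as an MP4 or a lossless PNG stack.

    A path ending in ``.mp4`` selects H.264 encoding (requires an
    ffmpeg-enabled imageio backend); any other path is treated as a directory
    receiving numbered PNG files, which round-trip bit-exactly.
    """
    frames = np.asarray(frames)
    if frames.ndim == 0 or frames.shape[0] == 0:
        raise ValueError("cannot export an empty frame sequence")
    path = Path(path)
    if path.suffix.lower() == ".mp4":
        try:
            import imageio.v2 as iio2

            writer = iio2.get_writer(path, fps=fps, codec="libx264")
        except Exception as exc:  # pragma: no cover - depends on ffmpeg
            raise RuntimeError(
                "MP4 export requires an ffmpeg-enabled imageio backend; "
                "export a PNG stack instead"
            ) from exc
        with writer:
            for frame in frames:
                writer.append_data(frame)
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for t, frame in enumerate(frames):
        f = path / f"render_{t:05d}.png"
        iio.imwrite(f, frame)
        out.append(f)
    return out
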