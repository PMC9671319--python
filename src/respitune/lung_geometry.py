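"""Lung-field geometry: Bezier contours, diaphragm tracking, respiratory phase.

The lung field is outlined by a closed chain of quadratic Bezier segments.
Odd-indexed control points are on-curve anchors at anatomical landmarks (lung
apex, costophrenic angle, diaphragm/cardiac and mediastinal intersections);
even-indexed points are the off-curve Bezier auxiliaries between them.  The
left lung uses 12 points (6 segments), the right lung 10 points (5 segments).

The respiratory phase is driven by the y-coordinate of a designated diaphragm
point (default point 5 of the left lung).  With the image origin top-left and
y increasing downward, the diaphragm y-coordinate increases on inspiration, so

    r_t = (y5_t - y5_min) / (y5_max - y5_min)

is 1 at the maximal-inspiration frame and 0 at maximal expiration.  Every
frame's contour is then the componentwise affine blend

    P_{i,t} = (1 - r_t) * EP_i + r_t * IP_i

between the expiration and inspiration control points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates
from shapely.geometry import Polygon

from .cine_io import AnchorAnnotation, CineSequence

__all__ = [
    "SEGMENTS",
    "GeometryError",
    "DiaphragmTrace",
    "PhaseSeries",
    "FrameContours",
    "bezier_point",
    "sample_segment",
    "boundary_polyline",
    "build_boundary",
    "track_diaphragm",
    "compute_phase_series",
    "interpolate_contour",
]


class GeometryError(ValueError):
    """Invalid or degenerate lung-field geometry."""


#: Quadratic segments per side as (anchor, control, anchor) 1-based triplets,
#: traversed in contour order.
SEGMENTS = {
    "left": [(1, 2, 3), (3, 4, 5), (5, 6, 7), (7, 8, 9), (9, 10, 11), (11, 12, 1)],
    "right": [(1, 2, 3), (3, 4, 5), (5, 6, 7), (7, 8, 9), (9, 10, 1)],
}


def bezier_point(a, c, b, s):
    """Evaluate the quadratic Bezier B(s) = (1-s)^2 A + 2 s (1-s) C + s^2 B.

    ``s`` may be a scalar or array; points are (x, y) pairs.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    b = np.asarray(b, dtype=float)
    s = np.asarray(s, dtype=float)[..., None]
    return (1 - s) ** 2 * a + 2 * s * (1 - s) * c + s**2 * b


def sample_segment(a, c, b, n: int) -> np.ndarray:
    """Sample one quadratic segment at ``n + 1`` evenly spaced parameters."""
    return bezier_point(a, c, b, np.linspace(0.0, 1.0, n + 1))


def boundary_polyline(points: np.ndarray, side: str, samples_per_segment: int = 32) -> np.ndarray:
    """Sample the closed contour as an open polyline (first point not repeated)."""
    pts = np.asarray(points, dtype=float)
    parts = []
    for ia, ic, ib in SEGMENTS[side]:
        seg = sample_segment(pts[ia - 1], pts[ic - 1], pts[ib - 1], samples_per_segment)
        parts.append(seg[:-1])
    return np.concatenate(parts)


def build_boundary(
    points: np.ndarray,
    side: str,
    samples_per_segment: int = 32,
    frame_index: int | None = None,
) -> np.ndarray:
    """Build and validate the closed Bezier boundary of one lung.

    Returns the sampled polyline.  Raises `GeometryError` when the polygonal
    approximation self-intersects (the downstream tiling requires a simple
    polygon).
    """
    poly = boundary_polyline(points, side, samples_per_segment)
    if not Polygon(poly).is_valid:
        where = "" if frame_index is None else f" at frame {frame_index}"
        raise GeometryError(f"self-intersecting {side} lung contour{where}")
    return poly


# ---------------------------------------------------------------------------
# diaphragm trace and phase
# ---------------------------------------------------------------------------

@dataclass
class DiaphragmTrace:
    """Per-frame y-coordinate of the designated diaphragm point (pixels)."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or self.y.size < 2:
            raise ValueError("diaphragm trace must be a 1-D series of >=2 frames")

    @property
    def y_min(self) -> float:
        return float(self.y.min())

    @property
    def y_max(self) -> float:
        return float(self.y.max())

    @property
    def t_insp(self) -> int:
        """Earliest frame achieving y_max (maximal inspiration)."""
        return int(np.argmax(self.y))

    @property
    def t_exp(self) -> int:
        """Earliest frame achieving y_min (maximal expiration)."""
        return int(np.argmin(self.y))


@dataclass
class PhaseSeries:
    """Normalized respiratory phase r_t in [0, 1] plus the extreme frames."""

    r: np.ndarray
    t_insp: int
    t_exp: int

    def __len__(self) -> int:
        return self.r.size


def track_diaphragm(
    cine: CineSequence,
    seed: tuple[float, float],
    search_halfwidth: float = 30.0,
    smooth_sigma: float = 2.0,
) -> DiaphragmTrace:
    """Track the diaphragm y-coordinate through the sequence.

    Per frame, the column intensity profile through the seed's x is smoothed
    with a 1-D Gaussian (sigma = 2 px) and the diaphragm is placed at the row
    of maximum absolute vertical gradient, restricted to a window of
    ``search_halfwidth`` around the previous frame's estimate.  A quadratic
    fit through the gradient peak refines the row to subpixel precision.

    When the annotation file already supplies a trace, call sites should use
    it directly and skip this tracker.
    """
    h = cine.shape[0]
    x = int(round(seed[0]))
    if not (0 <= x < cine.shape[1]) or not (0 <= seed[1] < h):
        raise ValueError("seed outside image bounds")
    profiles = cine.frames[:, :, x].astype(float)
    ys = np.empty(cine.n_frames)
    prev = float(seed[1])
    n_edge = 0
    for t in range(cine.n_frames):
        lo = max(0, int(np.floor(prev - search_halfwidth)))
        hi = min(h, int(np.ceil(prev + search_halfwidth)) + 1)
        prof = gaussian_filter1d(profiles[t, lo:hi], smooth_sigma)
        if prof.size < 3 or np.ptp(prof) == 0:
            raise GeometryError(f"no diaphragm edge detected at frame {t}")
        grad = np.abs(np.gradient(prof))
        k = int(np.argmax(grad))
        if k in (0, grad.size - 1):
            n_edge += 1
            y = lo + k
        else:
            # parabolic refinement of the gradient peak
            g0, g1, g2 = grad[k - 1], grad[k], grad[k + 1]
            denom = g0 - 2 * g1 + g2
            delta = 0.0 if denom == 0 else 0.5 * (g0 - g2) / denom
            y = lo + k + float(np.clip(delta, -0.5, 0.5))
        ys[t] = y
        prev = y
    if n_edge > 0.1 * cine.n_frames:
        warnings.warn(
            f"diaphragm gradient peaked at the search-window edge in "
            f"{n_edge}/{cine.n_frames} frames; possible tracking loss",
            stacklevel=2,
        )
    return DiaphragmTrace(y=ys)


def compute_phase_series(trace: DiaphragmTrace) -> PhaseSeries:
    """Normalized respiratory phase from the diaphragm trace.

    Applies r_t = (y5_t - y5_min) / (y5_max - y5_min) exactly, with no
    smoothing or clipping; r is 1 at maximal inspiration and 0 at maximal
    expiration by construction.
    """
    if trace.y_max == trace.y_min:
        raise GeometryError("no respiratory excursion: y5_max == y5_min")
    r = (trace.y - trace.y_min) / (trace.y_max - trace.y_min)
    return PhaseSeries(r=r, t_insp=trace.t_insp, t_exp=trace.t_exp)


# ---------------------------------------------------------------------------
# per-frame contours
# ---------------------------------------------------------------------------

@dataclass
class FrameContours:
    """Interpolated control points for every frame and both lungs.

    ``points[side]`` has shape (N, K, 2).
    """

    points: dict[str, np.ndarray]
    phase: PhaseSeries

    @property
    def n_frames(self) -> int:
        return next(iter(self.points.values())).shape[0]

    def at(self, t: int, side: str) -> np.ndarray:
        """Control points (K, 2) of one lung at frame t."""
        return self.points[side][t]


def interpolate_contour(
    annotation: AnchorAnnotation,
    phase: PhaseSeries,
    validate: bool = True,
    samples_per_segment: int = 32,
) -> FrameContours:
    """Interpolate both lungs' control points for every frame.

    P_{i,t} = (1 - r_t) EP_i + r_t IP_i componentwise, so the contour equals
    the IP contour exactly at r = 1 and the EP contour at r = 0.  When
    ``validate`` is true every frame's boundary is checked for simplicity.
    """
    r = phase.r[:, None, None]
    points = {}
    for side in ("left", "right"):
        lung = getattr(annotation, side)
        points[side] = (1.0 - r) * lung.ep[None] + r * lung.ip[None]
    if validate:
        for side, arr in points.items():
            for t in range(arr.shape[0]):
                build_boundary(arr[t], side, samples_per_segment, frame_index=t)
    return FrameContours(points=points, phase=phase)


def sample_image(frame: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear sample of a frame at (x, y) points (pixel centers = integers)."""
    xy = np.atleast_2d(xy)
    return map_coordinates(
        frame.astype(float), [xy[:, 1], xy[:, 0]], order=1, mode="nearest"
    )
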