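"""Fragmentation of the lung field into a deformable M x N_m block grid.

The grid is fixed once from the maximal-expiration contour (the smallest lung
field) and reused for every frame.  Construction, per lung:

1. The two "vertical axis" boundary chains running from the apex anchors to
   the base anchors are sampled densely and the shorter one is divided into
   4-pixel arc lengths; the number of divisions is M.
2. M + 1 quadratic Bezier band curves are drawn.  Curve k has its endpoints
   at the equal-arc-length fraction k/M along each side chain, and its control
   point at fraction k/M along the straight supplementary segment joining the
   apex segment's control point to the base segment's control point.  Curve 0
   therefore coincides with the apex boundary segment and curve M with the
   base segment.
3. Within band m (between curves m-1 and m) the shorter bounding curve is
   divided into 4-pixel arc lengths giving N_m; both curves are split into
   N_m equal-arc pieces and corresponding split points are joined by straight
   lines, yielding N_m quadrilateral-like cells with curved top/bottom edges.

Every frame is subdivided with the same M and N_m, so cell (m, n) is a
deforming region that approximately follows the same piece of lung tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon

from .lung_geometry import FrameContours, GeometryError, sample_segment

__all__ = [
    "SIDE_CHAINS",
    "GridSpec",
    "BlockGrid",
    "polyline_arclength",
    "points_at_fractions",
    "compute_grid_spec",
    "build_band_curves",
    "subdivide_bands",
    "build_grids",
]

#: Per side: the two apex-to-base boundary chains as (anchor, control, anchor)
#: triplets in traversal order, plus the supplementary control segment
#: (apex-segment control point, base-segment control point), 1-based.
SIDE_CHAINS = {
    "left": {
        # medial chain P1 -> P11 -> P9 -> P7 (contour segments reversed)
        "a": [(1, 12, 11), (11, 10, 9), (9, 8, 7)],
        # lateral chain P3 -> P5
        "b": [(3, 4, 5)],
        "ctrl": (2, 6),
    },
    "right": {
        # lateral chain P1 -> P9 (reverse of contour segment P9 -> P1)
        "a": [(1, 10, 9)],
        # medial chain P3 -> P5 -> P7
        "b": [(3, 4, 5), (5, 6, 7)],
        "ctrl": (2, 8),
    },
}

#: Dense sampling used for arc-length computation and inversion.
ARC_SAMPLES_PER_SEGMENT = 256
#: Samples per curved cell edge when storing cell polygons.
SAMPLES_PER_EDGE = 8


@dataclass(frozen=True)
class GridSpec:
    """Division counts of one lung, fixed at maximal expiration.

    M vertical (apex-to-base) bands; band m is split into n_m[m-1] cells.
    ``target_edge`` is the nominal cell edge (4 px).
    """

    side: str
    M: int
    n_m: tuple[int, ...]
    target_edge: float = 4.0

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_m))

    @property
    def ids(self) -> list[tuple[str, int, int]]:
        """(side, m, n) for every cell, m = 1..M, n = 1..N_m."""
        return [
            (self.side, m, n)
            for m in range(1, self.M + 1)
            for n in range(1, self.n_m[m - 1] + 1)
        ]


@dataclass
class BlockGrid:
    """Per-frame cell polygons for both lungs.

    ``polys`` has shape (N frames, B cells, V vertices, 2); every cell is a
    closed polygon stored as V sampled boundary points (curved top and bottom
    edges, straight sides).  ``ids`` lists (side, m, n) in the same order for
    every frame.
    """

    ids: list[tuple[str, int, int]]
    polys: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.polys.shape[0]

    @property
    def n_cells(self) -> int:
        return self.polys.shape[1]

    def centroids(self, t: int) -> np.ndarray:
        """Vertex-mean centroid of each cell at frame t, shape (B, 2)."""
        return self.polys[t].mean(axis=1)


# ---------------------------------------------------------------------------
# polyline arc-length utilities
# ---------------------------------------------------------------------------

def polyline_arclength(pts: np.ndarray) -> float:
    """Total length of a polyline given as (P, 2) points."""
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def points_at_fractions(pts: np.ndarray, fracs) -> np.ndarray:
    """Points at given arc-length fractions along a polyline.

    Uses cumulative-length inversion with linear interpolation between the
    polyline samples.
    """
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        raise GeometryError("degenerate curve: zero arc length")
    target = np.asarray(fracs, dtype=float) * total
    x = np.interp(target, cum, pts[:, 0])
    y = np.interp(target, cum, pts[:, 1])
    return np.stack([x, y], axis=-1)


def _sample_chain(points: np.ndarray, triplets, per_segment: int) -> np.ndarray:
    """Densely sample a chain of quadratic segments as one polyline."""
    parts = []
    for j, (ia, ic, ib) in enumerate(triplets):
        seg = sample_segment(points[ia - 1], points[ic - 1], points[ib - 1], per_segment)
        parts.append(seg if j == len(triplets) - 1 else seg[:-1])
    return np.concatenate(parts)


def _side_polylines(points: np.ndarray, side: str, per_segment: int = ARC_SAMPLES_PER_SEGMENT):
    chains = SIDE_CHAINS[side]
    a = _sample_chain(points, chains["a"], per_segment)
    b = _sample_chain(points, chains["b"], per_segment)
    return a, b


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def compute_grid_spec(
    contour_exp: np.ndarray, side: str, target_edge: float = 4.0
) -> GridSpec:
    """Division counts from the maximal-expiration contour of one lung.

    M = max(1, round(L_short / target_edge)) where L_short is the arc length
    of the shorter apex-to-base side chain; N_m is computed the same way from
    the shorter of band m's two bounding Bezier curves.
    """
    a, b = _side_polylines(np.asarray(contour_exp, dtype=float), side)
    la, lb = polyline_arclength(a), polyline_arclength(b)
    if la == 0 or lb == 0:
        raise GeometryError(f"degenerate {side} contour: zero-length side curve")
    m = max(1, round(min(la, lb) / target_edge))
    curves = build_band_curves(contour_exp, side, m)
    n_m = []
    for k in range(m):
        lu = polyline_arclength(curves[k])
        ll = polyline_arclength(curves[k + 1])
        n_m.append(max(1, round(min(lu, ll) / target_edge)))
    return GridSpec(side=side, M=m, n_m=tuple(n_m), target_edge=target_edge)


def build_band_curves(
    contour: np.ndarray,
    side: str,
    m: int,
    per_curve: int = ARC_SAMPLES_PER_SEGMENT,
    check: bool = True,
) -> np.ndarray:
    """The M + 1 quadratic band curves of one lung at one frame.

    Returns an array of shape (M + 1, per_curve + 1, 2); curve k runs from
    the fraction-k/M point of side chain a to the fraction-k/M point of side
    chain b, with its Bezier control point at fraction k/M along the straight
    supplementary segment between the apex and base control points.
    """
    pts = np.asarray(contour, dtype=float)
    a, b = _side_polylines(pts, side)
    fracs = np.arange(m + 1) / m
    ends_a = points_at_fractions(a, fracs)
    ends_b = points_at_fractions(b, fracs)
    i0, i1 = SIDE_CHAINS[side]["ctrl"]
    ctrl = (1 - fracs)[:, None] * pts[i0 - 1] + fracs[:, None] * pts[i1 - 1]
    curves = np.empty((m + 1, per_curve + 1, 2))
    for k in range(m + 1):
        curves[k] = sample_segment(ends_a[k], ctrl[k], ends_b[k], per_curve)
    if check:
        step = max(1, per_curve // 16)  # decimate for the intersection test
        for k in range(m):
            u = LineString(curves[k, ::step])
            v = LineString(curves[k + 1, ::step])
            if u.crosses(v):
                raise GeometryError(f"band curves {k} and {k + 1} intersect ({side})")
    return curves


def subdivide_bands(
    band_curves: np.ndarray,
    spec: GridSpec,
    samples_per_edge: int = SAMPLES_PER_EDGE,
    validate: bool = False,
) -> np.ndarray:
    """Cells of one lung at one frame, shape (B, 2*(samples_per_edge+1), 2).

    Band m's bounding curves are each split into N_m equal-arc-length pieces;
    straight lines join corresponding split points.  Cell (m, n) is stored as
    the n-th piece of the upper curve followed by the reversed n-th piece of
    the lower curve (the closing edges are the straight joins).
    """
    cells = []
    for m in range(1, spec.M + 1):
        nm = spec.n_m[m - 1]
        fr = np.linspace(0.0, 1.0, nm * samples_per_edge + 1)
        upper = points_at_fractions(band_curves[m - 1], fr)
        lower = points_at_fractions(band_curves[m], fr)
        for n in range(nm):
            sl = slice(n * samples_per_edge, (n + 1) * samples_per_edge + 1)
            poly = np.concatenate([upper[sl], lower[sl][::-1]])
            if validate and not Polygon(poly).is_valid:
                raise GeometryError(f"non-simple cell polygon (m={m}, n={n + 1})")
            cells.append(poly)
    return np.asarray(cells)


def build_grids(
    contours: FrameContours,
    specs: dict[str, GridSpec],
    samples_per_edge: int = SAMPLES_PER_EDGE,
    check_curves: bool = False,
) -> BlockGrid:
    """Per-frame grids for both lungs with frame-invariant (side, m, n) ids.

    ``check_curves`` enables the per-frame band-curve intersection check (the
    check always runs for the maximal-expiration frame inside
    `compute_grid_spec`; per-frame checking is optional for speed).
    """
    ids = []
    for side in ("left", "right"):
        if side in specs:
            ids.extend(specs[side].ids)
    n = contours.n_frames
    b = len(ids)
    v = 2 * (samples_per_edge + 1)
    polys = np.empty((n, b, v, 2))
    for t in range(n):
        off = 0
        for side in ("left", "right"):
            if side not in specs:
                continue
            spec = specs[side]
            curves = build_band_curves(
                contours.at(t, side), side, spec.M, check=check_curves
            )
            cells = subdivide_bands(curves, spec, samples_per_edge)
            polys[t, off : off + spec.n_cells] = cells
            off += spec.n_cells
    return BlockGrid(ids=ids, polys=polys)


def lung_polygon(contour: np.ndarray, side: str, samples_per_segment: int = 32) -> Polygon:
    """Shapely polygon of the full lung field (for area/QC checks)."""
    from .lung_geometry import boundary_polyline

    return Polygon(boundary_polyline(contour, side, samples_per_segment))
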