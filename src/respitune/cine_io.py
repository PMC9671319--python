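"""Reading and writing of cine sequences, annotations and block-signal tables.

A cine sequence is an ordered stack of grayscale fluoroscopy frames (detector
counts).  The loader applies no windowing, LUT or enhancement: pixel values are
returned exactly as stored, because the downstream spectral analysis operates
on raw luminance changes.

Supported dialects:

* ``dicom_multiframe`` -- a single multi-frame DICOM object, or a directory of
  single-frame DICOM files ordered by ``InstanceNumber`` (filename sort as a
  fallback).
* ``image_stack`` -- a directory of 8/16-bit grayscale PNG or TIFF files whose
  lexicographic filename order is the temporal order.

The annotation file is a JSON document giving the lung-field control points at
the maximal-inspiration (IP) and maximal-expiration (EP) frames::

    {"left":  {"ip": [[1, x, y], ... 12 points], "ep": [[1, x, y], ...]},
     "right": {"ip": [[1, x, y], ... 10 points], "ep": [[1, x, y], ...]},
     "diaphragm_point_index": 5,
     "diaphragm_trace": [[t, y5], ...]}          # optional

Coordinates are 0-based pixel coordinates, origin at the top-left corner, y
increasing downward (so the diaphragm y-coordinate increases on inspiration).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "CineSequence",
    "LungPoints",
    "AnchorAnnotation",
    "POINTS_PER_LUNG",
    "load_cine",
    "write_cine",
    "load_annotation",
    "write_annotation",
    "write_block_signals",
    "read_block_signals",
]

#: Number of control points per lung side (anchors + Bezier auxiliaries).
POINTS_PER_LUNG = {"left": 12, "right": 10}

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class CineSequence:
    """Ordered stack of grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (N, H, W)
        Pixel luminance in detector counts.  Frame index ``t`` is 0-based.
    frame_rate : float
        Acquisition rate in frames per second.
    bit_depth : int
        Number of gray levels (e.g. 4096); pixel values lie in
        ``[0, bit_depth - 1]``.
    """

    frames: np.ndarray
    frame_rate: float
    bit_depth: int = 4096

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (N, H, W) array")
        if self.n_frames < 2:
            raise ValueError("need >=2 frames in a cine sequence")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0 or hi > self.bit_depth - 1:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside [0, {self.bit_depth - 1}]"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:3]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class LungPoints:
    """IP/EP control points of one lung, ordered by 1-based point index."""

    side: str
    ip: np.ndarray  # (K, 2) of (x, y) at maximal inspiration
    ep: np.ndarray  # (K, 2) at maximal expiration

    def __post_init__(self) -> None:
        k = POINTS_PER_LUNG[self.side]
        for name in ("ip", "ep"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k, 2):
                raise ValueError(
                    f"{self.side} lung requires {k} control points, "
                    f"got {arr.shape[0]} for {name.upper()}"
                )
            object.__setattr__(self, name, arr)


@dataclass
class AnchorAnnotation:
    """Landmark annotation: both lungs plus optional diaphragm trace.

    ``diaphragm_point_index`` designates the control point (default 5, the
    left costophrenic point) whose per-frame y-coordinate drives the
    respiratory phase.  ``diaphragm_trace`` is an optional per-frame y5 series
    which, when present, bypasses image-based tracking entirely.
    """

    left: LungPoints
    right: LungPoints
    diaphragm_point_index: int = 5
    diaphragm_trace: np.ndarray | None = None  # (N,) y-coordinates

    def __post_init__(self) -> None:
        if self.diaphragm_trace is not None:
            self.diaphragm_trace = np.asarray(self.diaphragm_trace, dtype=float)
            if self.diaphragm_trace.ndim != 1:
                raise ValueError("diaphragm_trace must be a 1-D y5 series")
        k = POINTS_PER_LUNG["left"]
        if not 1 <= self.diaphragm_point_index <= k:
            raise ValueError("diaphragm_point_index out of range")

    def diaphragm_anchor(self, which: str = "ep") -> np.ndarray:
        """(x, y) of the designated diaphragm point on the EP or IP frame."""
        pts = getattr(self.left, which)
        return pts[self.diaphragm_point_index - 1]


# ---------------------------------------------------------------------------
# cine loading / writing
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    if path.is_file():
        return "dicom_multiframe"
    files = sorted(path.iterdir())
    if any(f.suffix.lower() == ".dcm" for f in files):
        return "dicom_multiframe"
    return "image_stack"


def _dicom_frame_rate(ds) -> float | None:
    if getattr(ds, "CineRate", None):
        return float(ds.CineRate)
    if getattr(ds, "FrameTime", None):
        return 1000.0 / float(ds.FrameTime)
    if getattr(ds, "RecommendedDisplayFrameRate", None):
        return float(ds.RecommendedDisplayFrameRate)
    return None


def load_cine(
    path,
    dialect: str | None = None,
    frame_rate: float | None = None,
    bit_depth: int | None = None,
) -> CineSequence:
    """Load a cine sequence from disk without any pixel transformation.

    Parameters
    ----------
    path : path-like
        A multi-frame DICOM file, or a directory containing a DICOM series or
        a PNG/TIFF stack.
    dialect : {"dicom_multiframe", "image_stack"}, optional
        Inferred from the path contents when omitted.
    frame_rate : float, optional
        Explicit override.  Takes precedence over any metadata; required for
        image stacks, which carry no rate metadata.
    bit_depth : int, optional
        Gray-level count.  Defaults to ``2**BitsStored`` for DICOM and to the
        container depth (256 / 65536) for image stacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _infer_dialect(path)

    if dialect == "dicom_multiframe":
        import pydicom

        if path.is_file():
            ds = pydicom.dcmread(path)
            frames = ds.pixel_array
            if frames.ndim == 2:
                frames = frames[None]
            meta_rate = _dicom_frame_rate(ds)
            bits = int(getattr(ds, "BitsStored", 16))
        else:
            files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
            dsets = [pydicom.dcmread(f) for f in files]
            order = np.argsort(
                [int(getattr(d, "InstanceNumber", i)) for i, d in enumerate(dsets)],
                kind="stable",
            )
            dsets = [dsets[i] for i in order]
            if not dsets:
                raise ValueError(f"no DICOM files in {path}")
            frames = np.stack([d.pixel_array for d in dsets])
            meta_rate = _dicom_frame_rate(dsets[0])
            bits = int(getattr(dsets[0], "BitsStored", 16))
        rate = frame_rate if frame_rate is not None else meta_rate
        if rate is None:
            raise ValueError(
                "frame rate missing from DICOM metadata; pass frame_rate="
            )
        depth = bit_depth if bit_depth is not None else 2**bits
    elif dialect == "image_stack":
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if len(files) < 2:
            raise ValueError("need >=2 frames: image stack has fewer than 2 files")
        imgs = [iio.imread(f) for f in files]
        shapes = {im.shape for im in imgs}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
        if imgs[0].ndim != 2:
            raise ValueError("image stack frames must be single-channel grayscale")
        frames = np.stack(imgs)
        if frame_rate is None:
            raise ValueError(
                "image stacks carry no frame-rate metadata; pass frame_rate="
            )
        rate = frame_rate
        if bit_depth is None:
            depth = 65536 if frames.dtype.itemsize > 1 else 256
        else:
            depth = bit_depth
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    return CineSequence(frames=frames, frame_rate=float(rate), bit_depth=depth)


def write_cine(cine: CineSequence, path) -> list[Path]:
    """Write a cine sequence as a lossless 16-bit grayscale PNG stack.

    Frames are rounded to the nearest integer count.  Returns the file paths
    in temporal order; filenames are zero-padded so a lexicographic sort
    restores the acquisition order.
    """
    if cine.bit_depth > 65536:
        raise ValueError("PNG stack supports at most 16-bit depth")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for t in range(cine.n_frames):
        frame = np.rint(cine.frames[t]).astype(np.uint16)
        f = path / f"frame_{t:05d}.png"
        iio.imwrite(f, frame)
        out.append(f)
    return out


# ---------------------------------------------------------------------------
# annotation JSON
# ---------------------------------------------------------------------------

def _parse_points(raw, side: str, which: str) -> np.ndarray:
    k = POINTS_PER_LUNG[side]
    if len(raw) != k:
        raise ValueError(
            f"{side} lung requires {k} control points, got {len(raw)} ({which})"
        )
    idx = [int(r[0]) for r in raw]
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate point index in {side}/{which}")
    if sorted(idx) != list(range(1, k + 1)):
        raise ValueError(
            f"{side}/{which} indices must be consecutive 1..{k}, got {sorted(idx)}"
        )
    pts = np.full((k, 2), np.nan)
    for i, x, y in raw:
        if x < 0 or y < 0:
            raise ValueError(f"negative coordinate at {side}/{which} point {i}")
        pts[int(i) - 1] = (float(x), float(y))
    return pts


def load_annotation(path) -> AnchorAnnotation:
    """Load and validate a landmark annotation JSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    lungs = {}
    for side in ("left", "right"):
        if side not in doc:
            raise ValueError(f"annotation missing {side!r} lung")
        lungs[side] = LungPoints(
            side=side,
            ip=_parse_points(doc[side]["ip"], side, "ip"),
            ep=_parse_points(doc[side]["ep"], side, "ep"),
        )
    trace = None
    if doc.get("diaphragm_trace") is not None:
        raw = np.asarray(doc["diaphragm_trace"], dtype=float)
        if raw.ndim != 2 or raw.shape[1] != 2:
            raise ValueError("diaphragm_trace must be a list of [t, y] pairs")
        order = np.argsort(raw[:, 0], kind="stable")
        trace = raw[order, 1]
    return AnchorAnnotation(
        left=lungs["left"],
        right=lungs["right"],
        diaphragm_point_index=int(doc.get("diaphragm_point_index", 5)),
        diaphragm_trace=trace,
    )


def write_annotation(ann: AnchorAnnotation, path) -> None:
    """Serialize an annotation to the JSON schema read by `load_annotation`."""

    def pts(arr):
        return [[i + 1, float(x), float(y)] for i, (x, y) in enumerate(arr)]

    doc = {
        "left": {"ip": pts(ann.left.ip), "ep": pts(ann.left.ep)},
        "right": {"ip": pts(ann.right.ip), "ep": pts(ann.right.ep)},
        "diaphragm_point_index": ann.diaphragm_point_index,
        "diaphragm_trace": None
        if ann.diaphragm_trace is None
        else [[int(t), float(y)] for t, y in enumerate(ann.diaphragm_trace)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# block-signal tables
# ---------------------------------------------------------------------------

def format_block_id(block_id: tuple) -> str:
    side, m, n = block_id
    return f"{side}_{m}_{n}"


def parse_block_id(s: str) -> tuple:
    side, m, n = s.rsplit("_", 2)
    return (side, int(m), int(n))


def write_block_signals(values, block_ids, path, float_format: str = "%.12g") -> None:
    """Write a B x N block-signal table as CSV.

    Header row is ``block_id,frame_0,...,frame_{N-1}``.  The stated float
    precision (12 significant digits) makes the write/read round trip lossless
    to better than 1e-9 relative.
    """
    rows = [np.asarray(v, dtype=float) for v in values]
    if rows:
        n = rows[0].shape
        if any(r.shape != n for r in rows) or rows[0].ndim != 1:
            raise ValueError("ragged block-signal table")
        if len(rows) != len(block_ids):
            raise ValueError("block_ids length does not match value rows")
        ncol = rows[0].shape[0]
    else:
        ncol = 0
    df = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(rows), ncol),
        columns=[f"frame_{t}" for t in range(ncol)],
    )
    df.insert(0, "block_id", [format_block_id(b) for b in block_ids])
    df.to_csv(path, index=False, float_format=float_format)


def read_block_signals(path) -> tuple[np.ndarray, list[tuple]]:
    """Read a CSV written by `write_block_signals`; returns (values, ids)."""
    df = pd.read_csv(path)
    ids = [parse_block_id(s) for s in df["block_id"]]
    values = df.drop(columns="block_id").to_numpy(dtype=float)
    return values, ids
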