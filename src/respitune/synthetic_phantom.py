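"""Synthetic dynamic chest X-ray phantom with known ground truth.

The phantom emulates the signal structure the analysis assumes: two
lung-shaped fields whose boundary deforms with breathing and whose interior
luminance is

    background
    + baseline(x, y)                      (apex-to-base thickness ramp)
    + A(x, y) * sin(2 pi f_r t + phi(x, y))   (respiratory wave)
    + A_c * sin(2 pi f_c t)               (cardiac-band confounder)
    + Gaussian noise.

Deformation model: a vertical stretch about a horizontal apex line, with
stretch factor 1 + e * r(t), where r(t) = (1 + sin(2 pi f_r t)) / 2 is the
respiratory phase and e is set so the designated diaphragm point moves by the
configured excursion.  The inspiration (IP) template is exactly the stretched
expiration (EP) template, and since quadratic Beziers are affine-invariant the
analysis-side control-point interpolation reconstructs the true boundary.
The luminance fields are *material*: they are defined in the expiration
reference frame and advected with the stretch, as lung tissue would be.

``generate_phantom`` returns the cine, the matching annotation (exact IP/EP
templates and exact diaphragm trace) and a per-cell ground-truth table of
respiratory amplitude and phase on the analysis' own expiration block grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon

from . import block_grid, cine_io
from .cine_io import AnchorAnnotation, CineSequence, LungPoints
from .lung_geometry import boundary_polyline
from .signal_extraction import cell_pixel_indices

__all__ = [
    "PhantomConfig",
    "Lesion",
    "PhantomData",
    "fast_profile",
    "full_profile",
    "generate_phantom",
    "make_copd_like_phantom",
    "write_phantom",
]

#: Normalized (x, y) control-point templates at maximal expiration.
#: y is a fraction of image height, increasing downward; apex near the top.
LEFT_TEMPLATE = np.array(
    [
        (0.55, 0.080),  # P1  apex, medial
        (0.66, 0.045),  # P2  apex auxiliary
        (0.76, 0.100),  # P3  apex, lateral
        (0.88, 0.320),  # P4  lateral auxiliary
        (0.82, 0.620),  # P5  costophrenic angle
        (0.70, 0.660),  # P6  base auxiliary
        (0.58, 0.600),  # P7  diaphragm / cardiac shadow
        (0.535, 0.520),  # P8
        (0.52, 0.440),  # P9  mediastinum / cardiac shadow
        (0.505, 0.330),  # P10
        (0.51, 0.220),  # P11 mediastinum / aortic arch
        (0.52, 0.140),  # P12
    ]
)
RIGHT_TEMPLATE = np.array(
    [
        (0.14, 0.090),  # P1  apex, lateral
        (0.24, 0.040),  # P2  apex auxiliary
        (0.34, 0.090),  # P3  apex, medial
        (0.415, 0.200),  # P4
        (0.42, 0.340),  # P5  mediastinum point
        (0.43, 0.480),  # P6
        (0.38, 0.620),  # P7  diaphragm / mediastinum
        (0.26, 0.660),  # P8  base auxiliary
        (0.12, 0.600),  # P9  costophrenic angle
        (0.045, 0.340),  # P10 lateral auxiliary
    ]
)
APEX_Y_NORM = 0.04  # stretch axis; at or above every template point
BASE_Y_NORM = 0.66  # deepest template point, used to normalize the ramp


@dataclass(frozen=True)
class Lesion:
    """A lesion region in expiration reference coordinates.

    ``amp_factor`` multiplies the respiratory amplitude inside the polygon;
    ``phase_offset`` (radians) is added to the respiratory phase — pi gives
    the "reversed phase" pattern.
    """

    polygon: np.ndarray  # (K, 2) of (x, y), pixels
    amp_factor: float = 1.0
    phase_offset: float = 0.0


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom study conditions.

    Defaults mirror the acquisition the method targets: 1024x1024 frames at
    12.5 fps for 20 s (250 frames) on a 4096 gray-level detector, breathing
    at 0.25 Hz with a 40 px diaphragm excursion and a cardiac confounder at
    1.2 Hz.  Amplitudes are in detector counts.
    """

    shape: tuple[int, int] = (1024, 1024)  # (H, W)
    frame_rate: float = 12.5
    n_frames: int = 250
    f_resp: float = 0.25
    excursion_px: float = 40.0
    f_cardiac: float = 1.2
    cardiac_amplitude: float = 10.0
    resp_amplitude: float = 30.0
    baseline: float = 800.0
    baseline_ramp: float = 300.0
    background: float = 100.0
    noise_sigma: float = 3.0
    phase_gradient: float = 0.0  # radians, apex to base
    bit_depth: int = 4096
    modulate_background: bool = False
    seed: int = 0

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


def fast_profile(**overrides) -> PhantomConfig:
    """Small profile for fast runs: 256x256, 101 frames (~8 s), 10 px excursion.

    101 frames keeps at least two full 0.25 Hz cycles and makes the
    differenced series (100 samples) an integer number of cycles, so the
    default differenced analysis sees the fundamental exactly on a DFT bin;
    the cardiac confounder sits at 1.25 Hz (75 bpm) which is likewise on-bin,
    mirroring the on-bin confounder of the full-length profile.
    """
    cfg = PhantomConfig(
        shape=(256, 256), n_frames=101, excursion_px=10.0, f_cardiac=1.25
    )
    return replace(cfg, **overrides)


def full_profile(**overrides) -> PhantomConfig:
    """Full-scale acquisition profile (1024x1024, 12.5 fps, 20 s)."""
    return replace(PhantomConfig(), **overrides)


@dataclass
class PhantomData:
    """Generated phantom: cine, annotation, and per-cell ground truth.

    ``truth`` columns: side, m, n, amplitude, phase, lesion_frac — the exact
    amplitude and phase of each block's respiratory luminance wave, computed
    as |mean_cell(A e^{i phi})| and its angle over the reference cell pixels.
    """

    cine: CineSequence
    annotation: AnchorAnnotation
    truth: pd.DataFrame
    config: PhantomConfig
    r: np.ndarray  # raw respiratory phase (1 + sin)/2 per frame


def _validate(config: PhantomConfig) -> None:
    fs = config.frame_rate
    if not 0.0 < config.f_resp < config.f_cardiac < fs / 2.0:
        raise ValueError("require 0 < f_resp < f_cardiac < frame_rate / 2")
    if config.n_frames * config.f_resp / fs < 2.0:
        raise ValueError("duration must cover at least 2 respiratory cycles")
    if config.noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")


def _templates(config: PhantomConfig) -> dict[str, np.ndarray]:
    h, w = config.shape
    scale = np.array([w, h], dtype=float)
    return {"left": LEFT_TEMPLATE * scale, "right": RIGHT_TEMPLATE * scale}


def _stretch(points: np.ndarray, apex_y: float, factor: float) -> np.ndarray:
    out = points.copy()
    out[..., 1] = apex_y + (out[..., 1] - apex_y) * factor
    return out


def _eval_fields(x, y_ref, config: PhantomConfig, lesions):
    """Material amplitude and phase fields at reference coordinates."""
    h = config.shape[0]
    ynorm = np.clip(
        (np.asarray(y_ref) - APEX_Y_NORM * h) / ((BASE_Y_NORM - APEX_Y_NORM) * h),
        0.0,
        1.0,
    )
    amp = np.full_like(ynorm, config.resp_amplitude, dtype=float)
    phi = config.phase_gradient * ynorm
    if lesions:
        pts = np.stack([np.asarray(x, dtype=float).ravel(), np.asarray(y_ref, dtype=float).ravel()], axis=1)
        for les in lesions:
            inside = MplPath(np.asarray(les.polygon, dtype=float)).contains_points(pts)
            inside = inside.reshape(np.shape(ynorm))
            amp[inside] *= les.amp_factor
            phi[inside] += les.phase_offset
    return amp, phi


def _baseline_field(y_ref, config: PhantomConfig):
    h = config.shape[0]
    ynorm = np.clip(
        (np.asarray(y_ref) - APEX_Y_NORM * h) / ((BASE_Y_NORM - APEX_Y_NORM) * h),
        0.0,
        1.0,
    )
    return config.baseline + config.baseline_ramp * ynorm


def generate_phantom(
    config: PhantomConfig, lesions: list[Lesion] | None = None
) -> PhantomData:
    """Generate a seeded phantom cine with matching annotation and truth."""
    _validate(config)
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    fs = config.frame_rate
    ep = _templates(config)
    apex_y = APEX_Y_NORM * h
    y5_ep = ep["left"][4, 1]  # diaphragm point P5 of the left lung
    e_rel = config.excursion_px / (y5_ep - apex_y)

    t = np.arange(config.n_frames)
    omega_r = 2.0 * np.pi * config.f_resp / fs
    omega_c = 2.0 * np.pi * config.f_cardiac / fs
    r = 0.5 * (1.0 + np.sin(omega_r * t))
    stretch = 1.0 + e_rel * r
    trace = apex_y + (y5_ep - apex_y) * stretch

    ip = {side: _stretch(pts, apex_y, 1.0 + e_rel) for side, pts in ep.items()}
    annotation = AnchorAnnotation(
        left=LungPoints("left", ip=ip["left"], ep=ep["left"]),
        right=LungPoints("right", ip=ip["right"], ep=ep["right"]),
        diaphragm_point_index=5,
        diaphragm_trace=trace,
    )

    frames = np.empty((config.n_frames, h, w))
    cols_full, rows_full = np.meshgrid(np.arange(w), np.arange(h))
    for k in range(config.n_frames):
        frame = np.full((h, w), config.background, dtype=float)
        resp_t = np.sin(omega_r * k)  # multiplied by A inside the fields
        card_t = config.cardiac_amplitude * np.sin(omega_c * k)
        if config.modulate_background:
            y_ref = apex_y + (rows_full - apex_y) / stretch[k]
            amp, phi = _eval_fields(cols_full, y_ref, config, lesions)
            frame += amp * np.sin(omega_r * k + phi) + card_t
        for side in ("left", "right"):
            pts_t = _stretch(ep[side], apex_y, stretch[k])
            poly = boundary_polyline(pts_t, side)
            c0 = max(0, int(np.floor(poly[:, 0].min())))
            c1 = min(w - 1, int(np.ceil(poly[:, 0].max())))
            r0 = max(0, int(np.floor(poly[:, 1].min())))
            r1 = min(h - 1, int(np.ceil(poly[:, 1].max())))
            cols = cols_full[r0 : r1 + 1, c0 : c1 + 1]
            rows = rows_full[r0 : r1 + 1, c0 : c1 + 1]
            pts = np.stack([cols.ravel(), rows.ravel()], axis=1)
            inside = MplPath(poly).contains_points(pts).reshape(cols.shape)
            rr = rows[inside]
            cc = cols[inside]
            y_ref = apex_y + (rr - apex_y) / stretch[k]
            patch = _baseline_field(y_ref, config)
            if not config.modulate_background:
                amp, phi = _eval_fields(cc, y_ref, config, lesions)
                patch = patch + amp * np.sin(omega_r * k + phi) + card_t
            frame[rr, cc] += patch
        if config.noise_sigma > 0:
            frame += rng.normal(0.0, config.noise_sigma, size=frame.shape)
        frames[k] = frame
    np.clip(frames, 0.0, config.bit_depth - 1, out=frames)

    cine = CineSequence(frames=frames, frame_rate=fs, bit_depth=config.bit_depth)
    truth = _ground_truth(config, ep, lesions)
    return PhantomData(cine=cine, annotation=annotation, truth=truth, config=config, r=r)


def _ground_truth(config, ep, lesions) -> pd.DataFrame:
    """Per-cell amplitude/phase of the respiratory wave on the EP grid."""
    records = []
    for side in ("left", "right"):
        spec = block_grid.compute_grid_spec(ep[side], side)
        curves = block_grid.build_band_curves(ep[side], side, spec.M, check=False)
        cells = block_grid.subdivide_bands(curves, spec)
        for (s, m, n), poly in zip(spec.ids, cells):
            rows, cols = cell_pixel_indices(poly, config.shape)
            if rows.size:
                amp, phi = _eval_fields(cols.astype(float), rows.astype(float), config, lesions)
                z = np.mean(amp * np.exp(1j * phi))
                frac = 0.0
                if lesions:
                    pts = np.stack([cols, rows], axis=1).astype(float)
                    ind = np.zeros(len(pts))
                    for les in lesions:
                        ind = np.maximum(
                            ind,
                            MplPath(np.asarray(les.polygon, dtype=float))
                            .contains_points(pts)
                            .astype(float),
                        )
                    frac = float(ind.mean())
            else:
                ctr = poly.mean(axis=0)
                amp, phi = _eval_fields(ctr[:1], ctr[1:], config, lesions)
                z = complex(amp[0] * np.exp(1j * phi[0]))
                frac = 0.0
            records.append(
                {
                    "side": s,
                    "m": m,
                    "n": n,
                    "amplitude": float(np.abs(z)),
                    "phase": float(np.angle(z)),
                    "lesion_frac": frac,
                }
            )
    return pd.DataFrame.from_records(records)


def make_copd_like_phantom(
    config: PhantomConfig, lesions: list[Lesion]
) -> PhantomData:
    """Phantom with focal amplitude-reduced / phase-shifted lesion regions.

    Emulates the patchy "mosaic" amplitude loss and locally phase-inverted
    respiratory signal seen in obstructive disease.  Each lesion polygon must
    lie inside a lung field (expiration reference coordinates).
    """
    ep = _templates(config)
    fields = {
        side: Polygon(boundary_polyline(pts, side)) for side, pts in ep.items()
    }
    for i, les in enumerate(lesions):
        poly = Polygon(np.asarray(les.polygon, dtype=float))
        if not any(f.buffer(1.0).contains(poly) for f in fields.values()):
            raise ValueError(f"lesion {i} polygon is not inside a lung field")
    return generate_phantom(config, lesions=lesions)


def write_phantom(data: PhantomData, outdir) -> dict[str, Path]:
    """Write cine (PNG stack), annotation JSON, truth CSV and metadata YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cine_dir = outdir / "cine"
    cine_io.write_cine(data.cine, cine_dir)
    ann_path = outdir / "annotation.json"
    cine_io.write_annotation(data.annotation, ann_path)
    truth_path = outdir / "truth.csv"
    data.truth.to_csv(truth_path, index=False)
    meta_path = outdir / "meta.yaml"
    cfg = data.config
    with open(meta_path, "w") as fh:
        yaml.safe_dump(
            {
                "frame_rate": cfg.frame_rate,
                "n_frames": cfg.n_frames,
                "shape": list(cfg.shape),
                "bit_depth": cfg.bit_depth,
                "f_resp": cfg.f_resp,
                "f_cardiac": cfg.f_cardiac,
                "seed": cfg.seed,
            },
            fh,
        )
    return {"cine": cine_dir, "annotation": ann_path, "truth": truth_path, "meta": meta_path}
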