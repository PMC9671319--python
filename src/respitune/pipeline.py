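"""End-to-end analysis pipeline: cine + annotation -> respiratory-band maps.

Stages run in a fixed order: diaphragm trace -> phase series -> per-frame
contours -> block grid (fixed at maximal expiration) -> block mean signals ->
(optional differencing) -> respiratory-frequency estimate -> single-bin
band-pass -> amplitude/phase maps.  Every parameter that was defaulted is
echoed into a machine-readable run log.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import block_grid, lung_geometry, signal_extraction, spectral
from .cine_io import AnchorAnnotation, CineSequence
from .lung_geometry import DiaphragmTrace

logger = logging.getLogger("respitune")

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis parameters.

    ``signal`` selects whether the spectral stage consumes the raw block
    means or the adjacent-frame differences (the default, which removes
    static structure exactly).  ``f_resp_override`` bypasses the automatic
    respiratory-frequency estimate.
    """

    signal: str = "differenced"  # "differenced" | "raw"
    half_width_bins: int = 1
    band: tuple[float, float] = (0.05, 1.0)
    f_resp_override: float | None = None
    detrend: str = "mean"  # "mean" | "linear" | "none"
    window: str = "rect"
    target_cell_px: float = 4.0
    track_search_halfwidth: float | None = None  # default from IP/EP excursion
    validate_contours: bool = True


@dataclass
class AnalysisResult:
    """All intermediate and final products of one analysis run."""

    trace: DiaphragmTrace
    phase: lung_geometry.PhaseSeries
    contours: lung_geometry.FrameContours
    specs: dict[str, block_grid.GridSpec]
    grid: block_grid.BlockGrid
    signals: signal_extraction.BlockSignalMatrix
    analyzed: signal_extraction.BlockSignalMatrix
    spectral: spectral.SpectralResult
    maps: pd.DataFrame
    run_log: dict


def _diaphragm_trace(
    cine: CineSequence, annotation: AnchorAnnotation, config: AnalysisConfig
) -> tuple[DiaphragmTrace, str]:
    if annotation.diaphragm_trace is not None:
        if annotation.diaphragm_trace.size != cine.n_frames:
            raise ValueError(
                f"diaphragm trace length {annotation.diaphragm_trace.size} "
                f"!= {cine.n_frames} frames"
            )
        return DiaphragmTrace(y=annotation.diaphragm_trace), "annotation"
    ep = annotation.diaphragm_anchor("ep")
    ip = annotation.diaphragm_anchor("ip")
    halfwidth = config.track_search_halfwidth
    if halfwidth is None:
        halfwidth = 0.75 * abs(ip[1] - ep[1]) + 10.0
    seed = (ep[0], 0.5 * (ep[1] + ip[1]))
    trace = lung_geometry.track_diaphragm(cine, seed, search_halfwidth=halfwidth)
    return trace, "tracked"


def amplitude_phase_maps(result: spectral.SpectralResult) -> pd.DataFrame:
    """Per-block amplitude/phase maps in raw luminance units.

    When the analysis ran on the differenced series, the known gain and phase
    shift of adjacent-frame differencing at the fundamental bin frequency are
    inverted, so the reported amplitude is directly comparable to the
    amplitude of the underlying luminance wave.
    """
    f_bin = result.k0 * result.frame_rate / result.recon.shape[1]
    amp = result.amplitude.copy()
    phase = result.phase.copy()
    if result.domain == "differenced":
        amp = amp / spectral.first_difference_gain(f_bin, result.frame_rate)
        phase = np.angle(
            np.exp(1j * (phase - spectral.difference_phase_shift(f_bin, result.frame_rate)))
        )
    side, m, n = zip(*result.ids)
    return pd.DataFrame(
        {
            "side": side,
            "m": m,
            "n": n,
            "amplitude": amp,
            "phase": phase,
            "raw_amplitude": result.amplitude,
            "raw_phase": result.phase,
        }
    )


def analyze(
    cine: CineSequence,
    annotation: AnchorAnnotation,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisResult:
    """Run the full pipeline on an in-memory cine and annotation."""
    trace, trace_source = _diaphragm_trace(cine, annotation, config)
    logger.info("diaphragm trace: %s, excursion %.2f px", trace_source, trace.y_max - trace.y_min)

    phase = lung_geometry.compute_phase_series(trace)
    contours = lung_geometry.interpolate_contour(
        annotation, phase, validate=config.validate_contours
    )

    specs = {}
    for side in ("left", "right"):
        specs[side] = block_grid.compute_grid_spec(
            contours.at(phase.t_exp, side), side, target_edge=config.target_cell_px
        )
        logger.info(
            "%s lung grid: M=%d, total cells=%d", side, specs[side].M, specs[side].n_cells
        )
    grid = block_grid.build_grids(contours, specs)

    signals = signal_extraction.extract_block_means(cine, grid)
    if config.signal == "differenced":
        analyzed = signal_extraction.difference_frames(signals)
    elif config.signal == "raw":
        analyzed = signals
    else:
        raise ValueError(f"unknown signal choice {config.signal!r}")

    if config.f_resp_override is not None:
        f_resp = float(config.f_resp_override)
        f_source = "override"
    else:
        f_resp = spectral.estimate_respiratory_frequency(
            phase.r, cine.frame_rate, band=config.band
        )
        f_source = "phase-spectrum peak"
    logger.info("respiratory fundamental: %.4f Hz (%s)", f_resp, f_source)

    spec_result = spectral.bandpass_block_signals(
        analyzed,
        f_resp,
        cine.frame_rate,
        half_width_bins=config.half_width_bins,
        detrend=config.detrend,
        window=config.window,
    )
    maps = amplitude_phase_maps(spec_result)

    run_log = {
        "n_frames": cine.n_frames,
        "frame_rate": cine.frame_rate,
        "bit_depth": cine.bit_depth,
        "trace_source": trace_source,
        "t_insp": phase.t_insp,
        "t_exp": phase.t_exp,
        "f_resp": f_resp,
        "f_resp_source": f_source,
        "fundamental_bin": spec_result.k0,
        "retained_bins": [int(k) for k in spec_result.retained_bins],
        "M": {s: specs[s].M for s in specs},
        "total_cells": {s: specs[s].n_cells for s in specs},
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
    }
    return AnalysisResult(
        trace=trace,
        phase=phase,
        contours=contours,
        specs=specs,
        grid=grid,
        signals=signals,
        analyzed=analyzed,
        spectral=spec_result,
        maps=maps,
        run_log=run_log,
    )
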