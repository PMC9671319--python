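"""Shared fixtures: tiny phantoms and toy geometry built at test time."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import respitune as rt

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_config() -> rt.PhantomConfig:
    """A very small, fast phantom: 96x96, 50 frames (2 cycles at 0.5 Hz)."""
    return rt.fast_profile(
        shape=(96, 96),
        n_frames=50,
        f_resp=0.5,
        excursion_px=6.0,
        noise_sigma=0.0,
        cardiac_amplitude=0.0,
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_config):
    return rt.generate_phantom(tiny_config)


@pytest.fixture(scope="session")
def tiny_analysis(tiny_phantom):
    return rt.analyze(tiny_phantom.cine, tiny_phantom.annotation)


@pytest.fixture()
def toy_left_contour() -> np.ndarray:
    """A left-lung-like 12-point contour with a straight 40 px lateral chain.

    The lateral side chain P3->P5 is collinear (degenerate Bezier), so its
    arc length is exactly 40 px; the medial chain P1->P7 is longer.
    """
    return np.array(
        [
            (20.0, 10.0),  # P1
            (40.0, 5.0),  # P2
            (60.0, 10.0),  # P3
            (60.0, 30.0),  # P4 (collinear with P3, P5)
            (60.0, 50.0),  # P5
            (40.0, 58.0),  # P6
            (20.0, 55.0),  # P7
            (15.0, 44.0),  # P8
            (14.0, 33.0),  # P9
            (14.0, 25.0),  # P10
            (15.0, 18.0),  # P11
            (16.0, 13.0),  # P12
        ]
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def de_casteljau(a, c, b, s: float) -> np.ndarray:
    """Quadratic Bezier point by repeated linear interpolation."""
    a, c, b = (np.asarray(p, dtype=float) for p in (a, c, b))
    p0 = (1 - s) * a + s * c
    p1 = (1 - s) * c + s * b
    return (1 - s) * p0 + s * p1


def point_in_polygon(x: float, y: float, poly: np.ndarray) -> bool:
    """Even-odd ray casting, independent of matplotlib/shapely."""
    inside = False
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        if (y0 > y) != (y1 > y):
            xcross = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
            if x < xcross:
                inside = not inside
    return inside
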