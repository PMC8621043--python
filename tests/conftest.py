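"""Shared fixtures and oracle helpers for the test suite."""
from __future__ import annotations

import math

import numpy as np
import pytest

from aptrack import AxonModel, ProbeGeometry, default_triode


@pytest.fixture
def triode() -> ProbeGeometry:
    return default_triode()


@pytest.fixture
def right_triangle_probe() -> ProbeGeometry:
    """The simple right-triangle layout used in hand-worked examples."""
    return ProbeGeometry(np.array([[0.0, 0.0], [80.0, 0.0], [0.0, 80.0]]), ("e1", "e2", "e3"))


def random_nondegenerate_case(rng: np.random.Generator):
    """Draw a random probe + axon whose analytic transit is well conditioned.

    Degenerate draws (collinear electrodes, axon parallel to an electrode
    pair in the rotated frame, nearly singular amplitude systems) are
    rejected and resampled; the inverse is only specified away from them.
    """
    while True:
        pts = rng.uniform(0.0, 100.0, size=(3, 2))
        a = np.linalg.norm(pts[0] - pts[1])
        area = 0.5 * abs(
            (pts[1, 0] - pts[0, 0]) * (pts[2, 1] - pts[0, 1])
            - (pts[2, 0] - pts[0, 0]) * (pts[1, 1] - pts[0, 1])
        )
        if area < 800.0 or a < 20.0:
            continue
        try:
            probe = ProbeGeometry(pts, ("e1", "e2", "e3"))
        except Exception:
            continue
        theta = rng.uniform(-math.pi, math.pi)
        speed = rng.uniform(0.2, 3.0)
        axon = AxonModel(
            x_offset_um=float(rng.uniform(-50, 50)),
            y_offset_um=float(rng.uniform(-60, 60)),
            z_height_um=float(rng.uniform(10, 120)),
            speed_mps=speed,
            direction=(math.cos(theta), math.sin(theta)),
            q_prime=float(rng.uniform(2000, 10000)),
        )
        # conditioning of the rotated lateral positions
        c, s = math.cos(theta), math.sin(theta)
        Y = -s * pts[:, 0] + c * pts[:, 1]
        dys = sorted(abs(Y[i] - Y[j]) for i, j in ((0, 1), (0, 2), (1, 2)))
        if dys[1] < 10.0:  # second-largest pair separation
            continue
        # amplitude contrast: near-equal distances make the circle system
        # ill conditioned (float error then exceeds the 1e-9 target)
        from aptrack import closest_approach

        D = [closest_approach(axon, e).distance_um for e in pts]
        if max(D) / min(D) < 1.3:
            continue
        return probe, axon
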