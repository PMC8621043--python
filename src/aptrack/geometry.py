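"""Coordinate conventions, probe and axon models, closest-approach geometry.

Conventions
-----------
The recording sites of a planar probe lie in the z = 0 plane; tissue
occupies z > 0, so every source satisfies z_height > 0.  The +x axis is the
nominal direction of neural travel (afferent).  Axons are modelled as
straight lines parallel to the probe plane — at the ~100 µm scale of a
close-spaced electrode cluster a nerve fibre is effectively straight, and
the probe is inserted parallel to the fibre tract.

The key geometric object is the *closest approach*: the point on the axon
line nearest a given electrode.  The extracellular potential recorded on
that electrode peaks exactly when the travelling charge passes this point,
which converts peak times into travel times and peak amplitudes into
inverse distances.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateDirectionError,
    ValidationError,
)
from .units import UM_PER_M
from .waveforms import Waveform

__all__ = [
    "ProbeGeometry",
    "AxonModel",
    "LocalFrame",
    "ClosestApproach",
    "closest_approach",
    "rotate_to_local",
    "triangle_area",
    "default_triode",
]


def triangle_area(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    """Unsigned area (µm²) of the triangle spanned by three planar points."""
    return 0.5 * abs(
        (q[0] - p[0]) * (r[1] - p[1]) - (r[0] - p[0]) * (q[1] - p[1])
    )


@dataclass(frozen=True)
class ProbeGeometry:
    """Planar electrode cluster: ordered (x, y) recording points at z = 0.

    At least three electrodes are required for triangulation; for exactly
    three, collinearity is rejected outright since the velocity system
    becomes singular.
    """

    electrodes: np.ndarray  # shape (n, 2), µm
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.electrodes, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("electrodes must be an (n, 2) array of µm coordinates")
        if pts.shape[0] < 3:
            raise ValidationError("at least 3 electrodes are required for triangulation")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("electrode coordinates must be finite")
        labels = tuple(self.labels) if self.labels else tuple(
            f"e{i + 1}" for i in range(pts.shape[0])
        )
        if len(labels) != pts.shape[0]:
            raise ValidationError("number of labels must match number of electrodes")
        if len(set(labels)) != len(labels):
            raise ValidationError("electrode labels must be unique")
        d = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        iu = np.triu_indices(pts.shape[0], k=1)
        if np.any(dist[iu] <= 0.0):
            raise ValidationError("electrode positions must be pairwise distinct")
        if pts.shape[0] == 3:
            scale = float(dist[iu].max())
            if triangle_area(*pts) <= 1e-9 * scale * scale:
                raise ValidationError("the three electrodes must not be collinear")
        object.__setattr__(self, "electrodes", pts)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.electrodes.shape[0]

    def position(self, label: str) -> np.ndarray:
        return self.electrodes[self.labels.index(label)]

    @property
    def positions3d(self) -> np.ndarray:
        """(n, 3) electrode coordinates with z = 0."""
        return np.hstack([self.electrodes, np.zeros((len(self), 1))])

    @property
    def centroid(self) -> np.ndarray:
        return self.electrodes.mean(axis=0)

    @property
    def max_spacing_um(self) -> float:
        d = self.electrodes[:, None, :] - self.electrodes[None, :, :]
        return float(np.hypot(d[..., 0], d[..., 1]).max())

    # -- JSON round trip ---------------------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "ProbeGeometry":
        try:
            entries = doc["electrodes"]
            pts = [(float(e["x_um"]), float(e["y_um"])) for e in entries]
            labels = tuple(str(e["label"]) for e in entries)
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed probe document: {exc}") from exc
        return cls(np.asarray(pts), labels)

    @classmethod
    def from_json(cls, path: str | Path) -> "ProbeGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "electrodes": [
                {"label": lab, "x_um": float(x), "y_um": float(y)}
                for lab, (x, y) in zip(self.labels, self.electrodes)
            ]
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def default_triode(scale_um: float = 80.0) -> ProbeGeometry:
    """Scalene triode with maximum spacing ~``scale_um`` — the minimal
    close-spaced cluster for 2-D velocity triangulation.

    No triangle side is parallel to the nominal (+x) travel axis: an axon
    running parallel to an electrode edge sees equal rotated lateral
    positions on that pair, which leaves the amplitude inversion
    underdetermined.  A scalene layout keeps all three rotated positions
    distinct for travel directions well away from the side slopes.
    """
    base = np.array([[0.0, 0.0], [75.0, 35.0], [20.0, 70.0]])
    pts = base * (scale_um / 80.0)
    return ProbeGeometry(pts, ("e1", "e2", "e3"))


@dataclass(frozen=True)
class AxonModel:
    """Ground-truth line source parallel to the probe plane.

    The axon line passes through the reference point
    ``(x_offset_um, y_offset_um, z_height_um)`` with in-plane unit
    ``direction``.  A firing launched at time ``t_f`` places the charge at
    the reference point at ``t_f`` and moves it along ``direction`` at
    ``speed_mps``.
    """

    y_offset_um: float
    z_height_um: float
    speed_mps: float
    direction: tuple[float, float] = (1.0, 0.0)
    q_prime: float = 5000.0  # potential·µm; ~100 µV peak at 50 µm
    waveform: Waveform | None = None
    firing_times_s: tuple[float, ...] = ()
    x_offset_um: float = 0.0

    def __post_init__(self) -> None:
        if not (self.speed_mps > 0.0 and np.isfinite(self.speed_mps)):
            raise ValidationError("axon speed must be positive and finite")
        if not (self.z_height_um > 0.0 and np.isfinite(self.z_height_um)):
            raise ValidationError("z_height must be positive (sources lie above the probe)")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (2,) or not np.all(np.isfinite(d)):
            raise ValidationError("direction must be a finite 2-vector")
        norm = float(np.hypot(d[0], d[1]))
        if norm == 0.0:
            raise ValidationError("direction must be non-zero")
        object.__setattr__(self, "direction", (float(d[0] / norm), float(d[1] / norm)))
        object.__setattr__(self, "firing_times_s", tuple(float(t) for t in self.firing_times_s))

    @property
    def reference_point(self) -> np.ndarray:
        return np.array([self.x_offset_um, self.y_offset_um, self.z_height_um])

    @property
    def direction3d(self) -> np.ndarray:
        return np.array([self.direction[0], self.direction[1], 0.0])

    @property
    def speed_um_per_s(self) -> float:
        return self.speed_mps * UM_PER_M

    def position_at(self, arclength_um: float) -> np.ndarray:
        """Point on the axon line at signed arclength from the reference."""
        return self.reference_point + arclength_um * self.direction3d

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        doc = {
            "y_offset_um": self.y_offset_um,
            "z_height_um": self.z_height_um,
            "speed_mps": self.speed_mps,
            "direction": list(self.direction),
            "q_prime": self.q_prime,
            "firing_times_s": list(self.firing_times_s),
            "x_offset_um": self.x_offset_um,
        }
        if self.waveform is not None:
            doc["waveform"] = {
                "kind": self.waveform.kind,
                "duration_s": self.waveform.duration_s,
            }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "AxonModel":
        wf = doc.get("waveform")
        return cls(
            y_offset_um=float(doc["y_offset_um"]),
            z_height_um=float(doc["z_height_um"]),
            speed_mps=float(doc["speed_mps"]),
            direction=tuple(doc.get("direction", (1.0, 0.0))),
            q_prime=float(doc.get("q_prime", 5000.0)),
            waveform=Waveform(wf["kind"], float(wf["duration_s"])) if wf else None,
            firing_times_s=tuple(doc.get("firing_times_s", ())),
            x_offset_um=float(doc.get("x_offset_um", 0.0)),
        )


@dataclass(frozen=True)
class ClosestApproach:
    """Closest approach of an axon line to one electrode."""

    point_um: np.ndarray  # (3,) point on the axon line
    distance_um: float
    time_s: float  # travel time from the axon reference point (firing at 0)


def closest_approach(axon: AxonModel, electrode: Sequence[float]) -> ClosestApproach:
    """Perpendicular foot of an electrode on the axon line.

    Returns the point ``s_m`` on the axon nearest the electrode, the
    distance ``D_m``, and the time ``t_m`` at which a charge launched from
    the axon reference point at t = 0 passes ``s_m``.  The recorded
    potential on that electrode is maximal at ``t_m``.
    """
    e = np.asarray(electrode, dtype=float)
    if e.shape == (2,):
        e = np.array([e[0], e[1], 0.0])
    if e.shape != (3,):
        raise ValidationError("electrode must be a 2- or 3-vector of µm coordinates")
    r0 = axon.reference_point
    d = axon.direction3d
    s_star = float(np.dot(e - r0, d))  # arclength of the foot, µm
    s_m = r0 + s_star * d
    dist = float(np.linalg.norm(s_m - e))
    t_m = s_star / axon.speed_um_per_s
    return ClosestApproach(point_um=s_m, distance_um=dist, time_s=t_m)


@dataclass(frozen=True)
class LocalFrame:
    """Frame {X, Y, Z} rotated about z by alpha = atan2(vy, vx) so the
    velocity points along +X.

    ``X``/``Y`` hold the rotated electrode coordinates.  The rotation is
    right-handed: positive alpha carries +x toward +y, and mapping *into*
    the local frame applies the inverse rotation, so an electrode at
    (80, 0) under v = (0, 1) has Y = -80 µm.
    """

    alpha: float
    X: np.ndarray
    Y: np.ndarray

    def to_global(self, x_local: float, y_local: float) -> tuple[float, float]:
        c, s = math.cos(self.alpha), math.sin(self.alpha)
        return (c * x_local - s * y_local, s * x_local + c * y_local)

    def to_local(self, x: float, y: float) -> tuple[float, float]:
        c, s = math.cos(self.alpha), math.sin(self.alpha)
        return (c * x + s * y, -s * x + c * y)


def rotate_to_local(probe: ProbeGeometry, velocity: Sequence[float]) -> LocalFrame:
    """Rotate electrode coordinates into the frame aligned with ``velocity``.

    ``alpha`` is computed with the two-argument arctangent so that vx = 0
    or vx < 0 pose no difficulty.
    """
    v = np.asarray(velocity, dtype=float)
    if v.shape != (2,) or not np.all(np.isfinite(v)):
        raise ValidationError("velocity must be a finite 2-vector")
    if v[0] == 0.0 and v[1] == 0.0:
        raise DegenerateDirectionError("zero velocity cannot define a local frame")
    alpha = math.atan2(v[1], v[0])
    c, s = math.cos(alpha), math.sin(alpha)
    x, y = probe.electrodes[:, 0], probe.electrodes[:, 1]
    return LocalFrame(alpha=alpha, X=c * x + s * y, Y=-s * x + c * y)
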