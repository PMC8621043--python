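"""Inverse solvers: velocity from peak-time differences, position and
effective charge from peak amplitudes, first-order error bound, and the
sampling/spacing resolution limits.

Velocity
--------
For a charge moving at v = (vx, vy) parallel to the probe plane, the peak
time on electrode i is the travel time to its closest-approach point,
t_i = (M_i - s_0) · v / |v|².  Differencing two electrodes,

    Δt_ij |v|² = vx Δx_ij + vy Δy_ij,

where — and this is the identity that makes the method closed-form — the
coordinate differences of the *closest-approach points* equal those of the
*electrodes themselves* once projected on v, so only the known electrode
positions enter.  With K = (Kx, Ky) = v / |v|² the relation is linear,
Δt_ij = Kx Δx_ij + Ky Δy_ij; two independent pairs (three electrodes)
determine K, and the velocity follows from the complex inversion
vx + i·vy = 1 / (Kx - i·Ky).

Position and charge
-------------------
In the frame rotated by alpha = atan2(vy, vx) the axon runs along X at
unknown (Y, Z) with unknown charge q'.  Each peak amplitude S_i = q'/D_i
taken at closest approach gives a circle equation

    q'² / S_i² = Z² + (Y - Y_i)²,

and pairwise subtraction cancels Z², leaving a linear system in (q'², Y).
Z² is then recovered per electrode; its mean gives Z (sources lie at
z > 0) and its spread is a quality metric.  Both solvers are derived by
direct elimination from the forward relations and validated against the
forward model.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    BatchDegenerateError,
    ConfigError,
    DegenerateGeometryError,
    InconsistentAmplitudesError,
    UnresolvableVelocityError,
    ValidationError,
)
from .geometry import LocalFrame, ProbeGeometry, rotate_to_local
from .preprocess import (
    MatchedTransit,
    detect_all,
    highpass_fft,
    match_across_channels,
    refine_transit_times,
    wavelet_denoise,
)
from .recording import MultichannelRecording
from .units import UM_PER_M

__all__ = [
    "VelocityEstimate",
    "SourceEstimate",
    "TrackConfig",
    "velocity_from_timings",
    "position_from_amplitudes",
    "error_bound",
    "estimate_s_max",
    "resolution_limits",
    "track_scene",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = (
    "transit_id",
    "vx_mps",
    "vy_mps",
    "speed_mps",
    "direction",
    "x_um",
    "y_um",
    "z_um",
    "q_prime",
    "z_spread_um",
    "epsilon_max",
    "flags",
)


@dataclass(frozen=True)
class VelocityEstimate:
    """Velocity vector recovered from inter-electrode peak-time delays."""

    vx_mps: float
    vy_mps: float
    kx_s_per_m: float  # vx / |v|²
    ky_s_per_m: float  # vy / |v|²

    @property
    def speed_mps(self) -> float:
        return math.hypot(self.vx_mps, self.vy_mps)

    @property
    def direction_sign(self) -> str:
        """Afferent/efferent classification by the sign of vx (+x is the
        nominal afferent axis)."""
        return "afferent" if self.vx_mps > 0.0 else "efferent"


@dataclass(frozen=True)
class SourceEstimate:
    """Closest-approach position and effective charge of one transit."""

    Y_um: float  # lateral position in the velocity-aligned frame
    Z_um: float  # height above the probe plane (>= 0)
    x_um: float  # global closest-approach point (to the reference electrode)
    y_um: float
    z_um: float
    q_prime: float
    z_spread_um: float  # disagreement among the per-electrode Z estimates
    epsilon: dict[str, float] = field(default_factory=dict)

    @property
    def epsilon_max(self) -> float:
        return max(self.epsilon.values()) if self.epsilon else float("nan")


# ---------------------------------------------------------------------------
# Velocity


def _pairs_system(
    positions: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble Δt = Kx Δx + Ky Δy rows over all electrode pairs (µm, s)."""
    rows, rhs = [], []
    for i, j in combinations(range(len(times)), 2):
        rows.append(positions[i] - positions[j])
        rhs.append(times[i] - times[j])
    return np.asarray(rows), np.asarray(rhs)


def velocity_from_timings(
    transit: MatchedTransit, probe: ProbeGeometry
) -> VelocityEstimate:
    """Solve for the velocity from the transit's per-electrode peak times.

    With exactly three electrodes the two independent pair equations are
    solved exactly; with more, the least-squares solution over all pairs is
    returned.  If every time difference vanishes the speed is beyond the
    resolution limit and :class:`UnresolvableVelocityError` is raised; a
    collinear electrode set raises :class:`DegenerateGeometryError`.
    """
    labels = transit.channels
    if len(labels) < 3:
        raise ValidationError("velocity triangulation needs >= 3 electrodes")
    positions = np.array([probe.position(lab) for lab in labels])
    times = np.array([transit.event(lab).peak_time_s for lab in labels])
    A, b = _pairs_system(positions, times)
    scale = float(np.abs(A).max())
    if len(labels) == 3:
        A2, b2 = A[:2], b[:2]
        det = A2[0, 0] * A2[1, 1] - A2[0, 1] * A2[1, 0]
        if abs(det) <= 1e-12 * scale * scale:
            raise DegenerateGeometryError("collinear electrode triad")
        kx = (b2[0] * A2[1, 1] - b2[1] * A2[0, 1]) / det
        ky = (A2[0, 0] * b2[1] - A2[1, 0] * b2[0]) / det
    else:
        sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < 2:
            raise DegenerateGeometryError("electrode set does not span the plane")
        kx, ky = float(sol[0]), float(sol[1])
    # kx, ky are in s/µm here
    k_mag = math.hypot(kx, ky)
    if k_mag < 1e-16:
        raise UnresolvableVelocityError(
            "all peak-time differences are zero: speed beyond the resolution limit"
        )
    v_complex = 1.0 / complex(kx, -ky)  # µm/s
    return VelocityEstimate(
        vx_mps=v_complex.real / UM_PER_M,
        vy_mps=v_complex.imag / UM_PER_M,
        kx_s_per_m=kx * UM_PER_M,
        ky_s_per_m=ky * UM_PER_M,
    )


# ---------------------------------------------------------------------------
# Position


def _solve_triad(
    Y: np.ndarray, S: np.ndarray, z2_rel_tol: float
) -> tuple[float, float, np.ndarray]:
    """Solve one amplitude triad for (q'², Y, per-electrode Z²).

    Of the three pairwise-difference equations only two are independent;
    the two with the largest |ΔY| are used, since a pair with coincident
    rotated positions carries no lateral information (its circles are
    concentric) and makes the system singular.
    """
    scale = float(np.abs(Y).max()) or 1.0
    pairs = sorted(combinations(range(3), 2), key=lambda p: -abs(Y[p[0]] - Y[p[1]]))
    (i, j), (k, l) = pairs[0], pairs[1]
    if abs(Y[k] - Y[l]) <= 1e-9 * scale:
        raise DegenerateGeometryError(
            "fewer than three distinct rotated electrode positions"
        )
    inv2 = 1.0 / S**2
    # rows: (1/S_i² - 1/S_j²) q'² + 2 (Y_i - Y_j) Y = Y_i² - Y_j²
    A = np.array(
        [
            [inv2[i] - inv2[j], 2.0 * (Y[i] - Y[j])],
            [inv2[k] - inv2[l], 2.0 * (Y[k] - Y[l])],
        ]
    )
    b = np.array([Y[i] ** 2 - Y[j] ** 2, Y[k] ** 2 - Y[l] ** 2])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    norm = max(np.abs(A).max() ** 2, 1e-300)
    if abs(det) <= 1e-12 * norm:
        raise DegenerateGeometryError(
            "amplitude system singular (no point equidistant-consistent source)"
        )
    q2 = (b[0] * A[1, 1] - b[1] * A[0, 1]) / det
    y_sol = (A[0, 0] * b[1] - A[1, 0] * b[0]) / det
    z2 = q2 * inv2 - (y_sol - Y) ** 2
    z2_scale = float(np.max(np.abs(q2) * inv2)) or 1.0
    if np.all(z2 < 0.0) or q2 < 0.0:
        raise InconsistentAmplitudesError("amplitudes admit no real source height")
    if np.any(z2 < -z2_rel_tol * z2_scale):
        raise InconsistentAmplitudesError(
            "a per-electrode Z² is negative beyond tolerance"
        )
    return float(q2), float(y_sol), z2


def position_from_amplitudes(
    transit: MatchedTransit,
    probe: ProbeGeometry,
    velocity: VelocityEstimate,
    z2_rel_tol: float = 1.0e-6,
) -> SourceEstimate:
    """Recover the closest-approach position and charge from amplitudes.

    Electrode coordinates are rotated into the velocity-aligned frame; the
    circle system q'²/S_i² = Z² + (Y - Y_i)² is solved pairwise for
    (q'², Y); Z is the square root of the mean per-electrode Z², with the
    max-min spread of the per-electrode Z values reported as a quality
    metric.  The local (Y, Z) is rotated back to global coordinates using
    the earliest-peak electrode as the X reference, yielding the global
    closest-approach point of the axon to that electrode.  With more than
    three electrodes the per-triad solutions are combined by the median
    over all non-degenerate triads.
    """
    labels = transit.channels
    frame = rotate_to_local(probe, (velocity.vx_mps, velocity.vy_mps))
    idx = [probe.labels.index(lab) for lab in labels]
    Y_all = frame.Y[idx]
    S_all = np.array([transit.event(lab).peak_amplitude for lab in labels])
    if np.any(S_all <= 0.0):
        raise ValidationError("all amplitudes must be positive")
    triads = list(combinations(range(len(labels)), 3))
    sols: list[tuple[float, float, float]] = []  # (q2, Y, mean Z²)
    z2_by_label: dict[str, list[float]] = {lab: [] for lab in labels}
    first_err: Exception | None = None
    for tri in triads:
        try:
            q2, y_sol, z2 = _solve_triad(Y_all[list(tri)], S_all[list(tri)], z2_rel_tol)
        except (DegenerateGeometryError, InconsistentAmplitudesError) as exc:
            if first_err is None:
                first_err = exc
            continue
        sols.append((q2, y_sol, float(np.mean(z2))))
        for t_i, z2_i in zip(tri, z2):
            z2_by_label[labels[t_i]].append(float(z2_i))
    if not sols:
        raise first_err if first_err is not None else DegenerateGeometryError(
            "no solvable electrode triad"
        )
    q2 = float(np.median([s[0] for s in sols]))
    y_sol = float(np.median([s[1] for s in sols]))
    z2_mean = float(np.median([s[2] for s in sols]))
    z_vals = [
        math.sqrt(max(0.0, float(np.mean(v)))) for v in z2_by_label.values() if v
    ]
    z_spread = max(z_vals) - min(z_vals) if z_vals else 0.0
    Z = math.sqrt(max(0.0, z2_mean))
    ref = transit.earliest_channel
    X_ref = float(frame.X[probe.labels.index(ref)])
    gx, gy = frame.to_global(X_ref, y_sol)
    return SourceEstimate(
        Y_um=y_sol,
        Z_um=Z,
        x_um=gx,
        y_um=gy,
        z_um=Z,
        q_prime=math.sqrt(max(0.0, q2)),
        z_spread_um=z_spread,
    )


# ---------------------------------------------------------------------------
# Error bound and resolution limits


def error_bound(
    d_m_um: float, s_max_um: float, displacement_um: float = 1.0
) -> float:
    """First-order relative error of the point-charge approximation.

    The extended-source correction to the potential at an electrode with
    closest-approach distance ``d_m_um`` is bounded by

        eps = (1 / D_m) * 1 / (1 + D_m² / s_max²) * |ΔD|,

    where ``s_max_um`` is the spatial half-extent of the action potential
    and ``displacement_um`` the distance mismatch |D_i - D| entering the
    first-order Taylor term (default 1 µm: the bound factor per µm of
    displacement).  It vanishes in the point-charge limit s_max → 0.
    """
    if d_m_um <= 0.0:
        raise ValidationError("closest-approach distance must be positive")
    if s_max_um < 0.0:
        raise ValidationError("s_max must be non-negative")
    if displacement_um < 0.0:
        raise ValidationError("displacement must be non-negative")
    if s_max_um == 0.0:
        return 0.0
    return (1.0 / d_m_um) / (1.0 + d_m_um**2 / s_max_um**2) * displacement_um


def estimate_s_max(
    speed_mps: float, ap_duration_s: float, multiplier: float = 0.5
) -> float:
    """Spatial half-extent of the AP: speed x duration x multiplier (µm).

    The default multiplier 0.5 takes half the full spatial footprint
    v * T as the effective half-width entering the error bound.
    """
    if speed_mps <= 0.0 or ap_duration_s <= 0.0:
        raise ValidationError("speed and duration must be positive")
    if multiplier <= 0.0:
        raise ValidationError("multiplier must be positive")
    return speed_mps * UM_PER_M * ap_duration_s * multiplier


def resolution_limits(fs_hz: float, max_spacing_um: float) -> tuple[float, float]:
    """Timing and speed resolution of a probe/digitiser combination.

    Returns ``(dt_min, v_max)``: the smallest resolvable peak-time
    difference (one sample period) and the largest speed whose transit
    across the widest electrode spacing still spans one sample.  At 40 kHz
    only delays above 25 µs register; with 80 µm spacing that caps
    detectable speeds at 3.2 m/s, while a 1 MHz / 100 µm system reaches
    100 m/s.
    """
    if fs_hz <= 0.0:
        raise ValidationError("sampling rate must be positive")
    if max_spacing_um <= 0.0:
        raise ValidationError("electrode spacing must be positive")
    dt_min = 1.0 / fs_hz
    v_max = max_spacing_um / dt_min / UM_PER_M
    return dt_min, v_max


# ---------------------------------------------------------------------------
# Whole-recording driver


@dataclass(frozen=True)
class TrackConfig:
    """Tunable parameters of the tracking pipeline (documented defaults)."""

    threshold_k: float = 4.0  # detection threshold in robust sigmas
    v_min_mps: float = 0.1  # slowest credible AP; sets the matching window
    ap_duration_ms: float = 1.0  # assumed AP duration for s_max
    epsilon_ceiling: float = 10.0  # flag estimates with eps_max above this
    smax_multiplier: float = 0.5
    highpass_cutoff_hz: float | None = 100.0  # None disables the high-pass
    wavelet: str | None = "sym5"  # None disables denoising
    refine_window_ms: float = 1.5  # cross-correlation window for delays

    @classmethod
    def from_dict(cls, doc: dict) -> "TrackConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_json(cls, path: str | Path) -> "TrackConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _estimate_row(
    transit: MatchedTransit,
    probe: ProbeGeometry,
    cfg: TrackConfig,
    v_max: float,
) -> dict:
    row: dict = {
        "transit_id": transit.transit_id,
        "vx_mps": np.nan,
        "vy_mps": np.nan,
        "speed_mps": np.nan,
        "direction": "",
        "x_um": np.nan,
        "y_um": np.nan,
        "z_um": np.nan,
        "q_prime": np.nan,
        "z_spread_um": np.nan,
        "epsilon_max": np.nan,
        "flags": "",
    }
    flags: list[str] = []
    try:
        vel = velocity_from_timings(transit, probe)
    except UnresolvableVelocityError:
        row.update(speed_mps=float("inf"), flags="unresolvable_velocity")
        return row
    except DegenerateGeometryError:
        row.update(flags="degenerate_geometry")
        return row
    row.update(
        vx_mps=vel.vx_mps,
        vy_mps=vel.vy_mps,
        speed_mps=vel.speed_mps,
        direction=vel.direction_sign,
    )
    if vel.speed_mps > v_max:
        flags.append("above_vmax")
    try:
        src = position_from_amplitudes(transit, probe, vel)
    except DegenerateGeometryError:
        flags.append("degenerate_position")
        row["flags"] = ";".join(flags)
        return row
    except InconsistentAmplitudesError:
        flags.append("inconsistent_amplitudes")
        row["flags"] = ";".join(flags)
        return row
    frame = rotate_to_local(probe, (vel.vx_mps, vel.vy_mps))
    s_max = estimate_s_max(vel.speed_mps, cfg.ap_duration_ms * 1e-3, cfg.smax_multiplier)
    idx = [probe.labels.index(lab) for lab in transit.channels]
    D = np.hypot(src.Z_um, src.Y_um - frame.Y[idx])
    d_mean = float(np.mean(D))
    eps = {
        lab: error_bound(float(d), s_max, abs(float(d) - d_mean))
        for lab, d in zip(transit.channels, D)
        if d > 0.0
    }
    src = SourceEstimate(
        Y_um=src.Y_um,
        Z_um=src.Z_um,
        x_um=src.x_um,
        y_um=src.y_um,
        z_um=src.z_um,
        q_prime=src.q_prime,
        z_spread_um=src.z_spread_um,
        epsilon=eps,
    )
    if eps and src.epsilon_max > cfg.epsilon_ceiling:
        flags.append("epsilon_over_ceiling")
    row.update(
        x_um=src.x_um,
        y_um=src.y_um,
        z_um=src.z_um,
        q_prime=src.q_prime,
        z_spread_um=src.z_spread_um,
        epsilon_max=src.epsilon_max if eps else np.nan,
        flags=";".join(flags),
    )
    return row


def track_scene(
    rec: MultichannelRecording,
    probe: ProbeGeometry,
    config: TrackConfig | None = None,
) -> pd.DataFrame:
    """Run the full chain on a recording: filter, denoise, detect, match,
    and triangulate every matched transit.

    Detection (thresholds, amplitudes, durations) runs on the high-passed
    trace, whose MAD reflects the true noise floor and whose peak
    amplitudes are not biased by wavelet shrinkage; the denoised trace is
    used afterwards to refine the inter-channel delays of each matched
    transit by waveform cross-correlation.  Per-transit degenerate
    conditions are reported as flagged rows; the batch never aborts.
    Estimates whose speed exceeds the resolution limit, or whose error
    bound exceeds the configured ceiling, are flagged but retained.
    """
    cfg = config if config is not None else TrackConfig()
    if tuple(rec.labels) != tuple(probe.labels):
        raise ValidationError("recording channels must match probe labels")
    work_hp = rec
    if cfg.highpass_cutoff_hz is not None:
        work_hp = highpass_fft(work_hp, cfg.highpass_cutoff_hz)
    work_dn = work_hp
    if cfg.wavelet is not None:
        work_dn = wavelet_denoise(work_hp, cfg.wavelet)
    events = detect_all(work_hp, threshold_k=cfg.threshold_k)
    matched, _ = match_across_channels(events, probe, v_min_mps=cfg.v_min_mps)
    matched = [
        refine_transit_times(t, work_dn, half_window_s=cfg.refine_window_ms * 1e-3)
        for t in matched
    ]
    _, v_max = resolution_limits(rec.sampling_rate_hz, probe.max_spacing_um)
    rows = [_estimate_row(t, probe, cfg, v_max) for t in matched]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
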