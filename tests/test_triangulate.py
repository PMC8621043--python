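"""Inverse solvers: velocity, position/charge, error bound, resolution limits,
and the whole-recording driver."""
import math

import numpy as np
import pytest

from aptrack import (
    AxonModel,
    DegenerateGeometryError,
    MatchedTransit,
    MultichannelRecording,
    ProbeGeometry,
    Scene,
    SpikeEvent,
    TrackConfig,
    UnresolvableVelocityError,
    ValidationError,
    analytic_transit,
    closest_approach,
    default_triode,
    error_bound,
    estimate_s_max,
    position_from_amplitudes,
    resolution_limits,
    rotate_to_local,
    simulate_recording,
    track_scene,
    velocity_from_timings,
)
from conftest import random_nondegenerate_case


def _transit(probe, times, amps=None):
    amps = amps if amps is not None else [50.0] * len(times)
    events = tuple(
        SpikeEvent(lab, t, a, 1e-3) for lab, t, a in zip(probe.labels, times, amps)
    )
    return MatchedTransit(0, events)


class TestVelocity:
    def test_pure_x_velocity_from_timings(self, right_triangle_probe):
        vel = velocity_from_timings(_transit(right_triangle_probe, [0.0, 80e-6, 0.0]),
                                    right_triangle_probe)
        assert vel.vx_mps == pytest.approx(1.0)
        assert vel.vy_mps == pytest.approx(0.0, abs=1e-12)
        assert vel.direction_sign == "afferent"

    def test_diagonal_velocity_from_timings(self, right_triangle_probe):
        vel = velocity_from_timings(_transit(right_triangle_probe, [0.0, 80e-6, 80e-6]),
                                    right_triangle_probe)
        assert vel.vx_mps == pytest.approx(0.5)
        assert vel.vy_mps == pytest.approx(0.5)
        assert vel.speed_mps == pytest.approx(math.hypot(0.5, 0.5))

    def test_complex_inversion_invariant(self, right_triangle_probe):
        vel = velocity_from_timings(_transit(right_triangle_probe, [0.0, 50e-6, 110e-6]),
                                    right_triangle_probe)
        v = complex(vel.vx_mps, vel.vy_mps)
        k = complex(vel.kx_s_per_m, -vel.ky_s_per_m)
        assert v * k == pytest.approx(1.0)

    def test_identical_peak_times_unresolvable(self, right_triangle_probe):
        with pytest.raises(UnresolvableVelocityError):
            velocity_from_timings(_transit(right_triangle_probe, [0.01, 0.01, 0.01]),
                                  right_triangle_probe)

    def test_collinear_triad_degenerate(self):
        # a 4-electrode probe whose first three sites are collinear: a
        # transit seen only by those three cannot resolve the velocity plane
        probe = ProbeGeometry(
            np.array([[0.0, 0.0], [40.0, 0.0], [80.0, 0.0], [0.0, 80.0]]),
            ("a", "b", "c", "d"),
        )
        tr = MatchedTransit(0, (
            SpikeEvent("a", 0.0, 50.0, 1e-3),
            SpikeEvent("b", 20e-6, 50.0, 1e-3),
            SpikeEvent("c", 50e-6, 50.0, 1e-3),
        ))
        with pytest.raises(DegenerateGeometryError):
            velocity_from_timings(tr, probe)


class TestPosition:
    def test_amplitude_triad_oracle(self):
        """Amplitudes generated from the forward law at (Y=40, Z=30, q'=1)
        with rotated positions (0, 40, 80) must be inverted exactly."""
        probe = ProbeGeometry(np.array([[0.0, 0.0], [10.0, 40.0], [0.0, 80.0]]),
                              ("a", "b", "c"))
        # velocity along +x: rotated Y equals the electrode y coordinates
        vel = velocity_from_timings(_transit(probe, [0.0, 10e-6, 0.0]), probe)
        tr = _transit(probe, [0.0, 1e-5, 2e-5], amps=[1 / 50.0, 1 / 30.0, 1 / 50.0])
        src = position_from_amplitudes(tr, probe, vel)
        assert src.Y_um == pytest.approx(40.0)
        assert src.Z_um == pytest.approx(30.0)
        assert src.q_prime == pytest.approx(1.0)
        assert src.z_spread_um == pytest.approx(0.0, abs=1e-9)

    def test_equal_amplitudes_on_symmetric_positions_give_midpoint(self):
        probe = ProbeGeometry(np.array([[0.0, 0.0], [10.0, 40.0], [0.0, 80.0]]),
                              ("a", "b", "c"))
        vel = velocity_from_timings(_transit(probe, [0.0, 10e-6, 0.0]), probe)
        tr = _transit(probe, [0.0, 1e-5, 2e-5], amps=[1 / 50.0, 1 / 30.0, 1 / 50.0])
        src = position_from_amplitudes(tr, probe, vel)
        assert src.Y_um == pytest.approx(40.0)  # midpoint of the equal pair

    def test_equal_amplitudes_everywhere_degenerate(self):
        probe = ProbeGeometry(np.array([[0.0, 0.0], [10.0, 40.0], [0.0, 80.0]]),
                              ("a", "b", "c"))
        vel = velocity_from_timings(_transit(probe, [0.0, 10e-6, 0.0]), probe)
        tr = _transit(probe, [0.0, 1e-5, 2e-5], amps=[0.02, 0.02, 0.02])
        with pytest.raises(DegenerateGeometryError):
            position_from_amplitudes(tr, probe, vel)


class TestErrorBoundAndLimits:
    def test_point_charge_limit_is_exact(self):
        assert error_bound(50.0, 0.0) == 0.0

    def test_half_bound_at_equal_distance_and_extent(self):
        assert error_bound(50.0, 50.0) == pytest.approx(0.01)

    def test_bound_decreases_with_distance_beyond_s_max(self):
        s_max = 50.0
        ds = np.linspace(50.0, 500.0, 100)
        eps = [error_bound(d, s_max) for d in ds]
        assert all(a > b for a, b in zip(eps, eps[1:]))

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValidationError):
            error_bound(0.0, 50.0)

    @pytest.mark.parametrize(
        "speed,duration,mult,expected",
        [(1.0, 1e-3, 0.5, 500.0), (0.5, 1e-3, 0.5, 250.0), (1.0, 1e-3, 1.0, 1000.0)],
    )
    def test_ap_spatial_extent(self, speed, duration, mult, expected):
        assert estimate_s_max(speed, duration, mult) == pytest.approx(expected)

    def test_resolution_limits(self):
        dt_min, v_max = resolution_limits(40_000.0, 80.0)
        assert dt_min == pytest.approx(25e-6)
        assert v_max == pytest.approx(3.2)
        assert resolution_limits(1e6, 100.0)[1] == pytest.approx(100.0)


class TestForwardInverseExactness:
    def test_analytic_transits_recovered_to_machine_precision(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            probe, axon = random_nondegenerate_case(rng)
            tr = analytic_transit(probe, axon, fire_time_s=0.1)
            vel = velocity_from_timings(tr, probe)
            v_true = np.array(axon.direction) * axon.speed_mps
            assert np.hypot(vel.vx_mps - v_true[0], vel.vy_mps - v_true[1]) <= 1e-9 * axon.speed_mps
            src = position_from_amplitudes(tr, probe, vel)
            frame = rotate_to_local(probe, tuple(v_true))
            y_true = (
                -math.sin(frame.alpha) * axon.x_offset_um
                + math.cos(frame.alpha) * axon.y_offset_um
            )
            # relative to the measurement scale: the largest source-electrode
            # distance (Z enters the circle system only through D²)
            scale = max(
                closest_approach(axon, e).distance_um for e in probe.electrodes
            )
            assert abs(src.Y_um - y_true) <= 1e-9 * scale
            assert abs(src.Z_um - axon.z_height_um) <= 1e-9 * scale
            assert abs(src.q_prime - axon.q_prime) <= 1e-9 * axon.q_prime
            # global closest-approach point sits on the axon line
            ref = tr.earliest_channel
            ca = closest_approach(axon, probe.position(ref))
            np.testing.assert_allclose(
                [src.x_um, src.y_um, src.z_um], ca.point_um, atol=1e-7
            )

    def test_estimates_covariant_under_scene_rotation_and_translation(self):
        rng = np.random.default_rng(7)
        probe, axon = random_nondegenerate_case(rng)
        tr = analytic_transit(probe, axon)
        vel = velocity_from_timings(tr, probe)
        src = position_from_amplitudes(tr, probe, vel)
        phi, dx, dy = 0.83, 40.0, -120.0
        c, s = math.cos(phi), math.sin(phi)
        R = np.array([[c, -s], [s, c]])
        probe2 = ProbeGeometry(probe.electrodes @ R.T + [dx, dy], probe.labels)
        p0 = R @ [axon.x_offset_um, axon.y_offset_um] + [dx, dy]
        d0 = R @ axon.direction
        axon2 = AxonModel(
            x_offset_um=float(p0[0]), y_offset_um=float(p0[1]),
            z_height_um=axon.z_height_um, speed_mps=axon.speed_mps,
            direction=(float(d0[0]), float(d0[1])), q_prime=axon.q_prime,
        )
        tr2 = analytic_transit(probe2, axon2)
        vel2 = velocity_from_timings(tr2, probe2)
        v2 = R @ [vel.vx_mps, vel.vy_mps]
        assert vel2.vx_mps == pytest.approx(v2[0], abs=1e-12)
        assert vel2.vy_mps == pytest.approx(v2[1], abs=1e-12)
        src2 = position_from_amplitudes(tr2, probe2, vel2)
        g2 = R @ [src.x_um, src.y_um] + [dx, dy]
        assert src2.x_um == pytest.approx(g2[0], abs=1e-6)
        assert src2.y_um == pytest.approx(g2[1], abs=1e-6)
        assert src2.z_um == pytest.approx(src.z_um, abs=1e-9)

    def test_estimates_invariant_under_electrode_permutation(self):
        rng = np.random.default_rng(11)
        probe, axon = random_nondegenerate_case(rng)
        tr = analytic_transit(probe, axon)
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            tr_p = MatchedTransit(0, tuple(tr.events[i] for i in perm))
            vel = velocity_from_timings(tr, probe)
            vel_p = velocity_from_timings(tr_p, probe)
            assert vel_p.vx_mps == pytest.approx(vel.vx_mps, rel=1e-12)
            assert vel_p.vy_mps == pytest.approx(vel.vy_mps, rel=1e-12)
            src = position_from_amplitudes(tr, probe, vel)
            src_p = position_from_amplitudes(tr_p, probe, vel_p)
            assert src_p.Y_um == pytest.approx(src.Y_um, rel=1e-12)
            assert src_p.Z_um == pytest.approx(src.Z_um, rel=1e-12)


def _bench_scene(fs, probe):
    """Noiseless point-model scene with four well-separated transits."""
    axons = []
    for i, (sp, y, z) in enumerate(
        [(0.25, -20.0, 30.0), (0.5, 10.0, 45.0), (1.0, 30.0, 25.0), (2.0, -5.0, 60.0)]
    ):
        axons.append(
            AxonModel(
                x_offset_um=probe.centroid[0], y_offset_um=y, z_height_um=z,
                speed_mps=sp, direction=(1.0, 0.0), q_prime=5000.0,
                firing_times_s=(0.05 + 0.06 * i,),
            )
        )
    return Scene(probe=probe, axons=tuple(axons), duration_s=0.35,
                 sampling_rate_hz=fs, model="point"), axons


def _recovery_errors(res, axons):
    """(speed rel err, point-to-true-line distance) per transit, best match."""
    out = []
    for _, r in res.iterrows():
        best = None
        for ax in axons:
            sp_err = abs(r.speed_mps - ax.speed_mps) / ax.speed_mps
            p0, d = ax.reference_point, ax.direction3d
            p = np.array([r.x_um, r.y_um, r.z_um])
            dist = float(np.linalg.norm((p - p0) - np.dot(p - p0, d) * d))
            if best is None or sp_err < best[0]:
                best = (sp_err, dist)
        out.append(best)
    return out


class TestTrackScene:
    def test_empty_recording_gives_empty_table(self, triode):
        rec = MultichannelRecording(np.zeros((3, 4000)), 40e3, triode.labels)
        res = track_scene(rec, triode)
        assert res.empty

    def test_noiseless_scene_recovered_within_tolerance(self, triode):
        scene, axons = _bench_scene(200_000.0, triode)
        rec, _ = simulate_recording(scene)
        cfg = TrackConfig(highpass_cutoff_hz=None, wavelet=None)
        res = track_scene(rec, triode, cfg)
        res = res[res["flags"] == ""]
        assert len(res) == len(axons)
        for sp_err, dist in _recovery_errors(res, axons):
            assert sp_err <= 0.05
            assert dist <= 5.0

    def test_sampling_limited_degradation_is_bounded(self, triode):
        """At 40 kHz each refined peak time is good to about one sample, so
        the speed error stays inside the first-order quantization bound."""
        scene, axons = _bench_scene(40_000.0, triode)
        rec, _ = simulate_recording(scene)
        cfg = TrackConfig(highpass_cutoff_hz=None, wavelet=None)
        res = track_scene(rec, triode, cfg).sort_values("speed_mps")
        res = res[res["flags"] == ""]
        assert len(res) == len(axons)
        dt_min = 1.0 / scene.sampling_rate_hz
        # conditioning of the exact pair system for this probe
        pts = triode.electrodes
        A = np.array([pts[0] - pts[1], pts[0] - pts[2]])
        k_bound = float(np.linalg.norm(np.linalg.inv(A), 2)) * 2.0 * math.sqrt(2) * dt_min
        for r, ax in zip(res.itertuples(), sorted(axons, key=lambda a: a.speed_mps)):
            v = ax.speed_mps * 1e6  # µm/s
            dv_bound = v * v * k_bound / max(1.0 - v * k_bound, 0.1) / 1e6
            assert abs(r.speed_mps - ax.speed_mps) <= dv_bound

    def test_flags_degenerate_rows_instead_of_aborting(self, triode):
        # two transits: one normal, one with identical peak times (beyond
        # the resolution limit) synthesised directly on the samples
        fs = 100_000.0
        n = int(0.2 * fs)
        t = np.arange(n) / fs
        data = np.zeros((3, n))
        pulse = lambda c, a: a * np.exp(-0.5 * ((t - c) / 2e-4) ** 2)
        for ch, a in enumerate([100.0, 140.0, 90.0]):
            data[ch] += pulse(0.05, a)  # simultaneous on all channels
        rec = MultichannelRecording(data, fs, triode.labels)
        cfg = TrackConfig(highpass_cutoff_hz=None, wavelet=None)
        res = track_scene(rec, triode, cfg)
        assert len(res) == 1
        assert res["flags"].iloc[0] == "unresolvable_velocity"
        assert math.isinf(res["speed_mps"].iloc[0])
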