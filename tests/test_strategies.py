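import math

import numpy as np
import pytest

from stereomotion import (
    Line3,
    MotionEvent,
    Prediction,
    StimulusSpec,
    ViewingGeometry,
    ca_predict,
    cdot_predict,
    iovd_predict,
    jemd_signature,
    make_motion_event,
    to_spherical,
    triangulate_point,
    vertical_offset_condition,
    vn_predict,
)
from stereomotion.spherical import velocity_from_angles
from stereomotion.strategies import _normal_endpoints


def closed_form_vn(theta_deg, vx, vz):
    th = math.radians(theta_deg)
    return np.array([vx * math.sin(th) ** 2, -vx * math.sin(th) * math.cos(th), vz])


class TestVectorNormal:
    def test_pure_motion_in_depth_recovered(self, geometry):
        for theta in (20.0, 45.0, 110.0):
            event = make_motion_event(geometry, StimulusSpec(theta, 0.0, 90.0, 0.0, 0.9))
            np.testing.assert_allclose(event.velocity, [0, 0, -0.9], atol=1e-12)
            pred = vn_predict(event)
            assert pred.status == "ok"
            np.testing.assert_allclose(pred.velocity, [0, 0, -0.9], atol=1e-9)

    def test_constraint_line_contains_true_end_line(self, geometry, rng):
        """The intersection of the two constraint planes is the 3D end line."""
        for _ in range(20):
            spec = StimulusSpec(
                float(rng.uniform(10, 170)),
                float(rng.uniform(-5, 5)),
                float(rng.uniform(-80, 80)),
                float(rng.uniform(-30, 30)),
                float(rng.uniform(0.1, 2)),
            )
            event = make_motion_event(geometry, spec)
            pred = vn_predict(event)
            assert pred.status == "ok"
            p = pred.diagnostics["constraint_line"]
            d = p.direction / np.linalg.norm(p.direction)
            for q in (event.end_line.p1, event.end_line.p2):
                gap = (q - p.p1) - ((q - p.p1) @ d) * d
                assert np.linalg.norm(gap) < 1e-9

    def test_velocity_is_slowest_on_constraint_line(self, geometry, rng):
        """Dense sampling of the constraint line never beats the VN speed,
        and the VN vector is perpendicular to the line."""
        for _ in range(10):
            spec = StimulusSpec(
                float(rng.uniform(15, 165)),
                float(rng.uniform(-4, 4)),
                float(rng.uniform(-70, 70)),
                0.0,
                1.0,
            )
            event = make_motion_event(geometry, spec)
            pred = vn_predict(event)
            p = pred.diagnostics["constraint_line"]
            F = geometry.fixation
            d = p.direction / np.linalg.norm(p.direction)
            speed = np.linalg.norm(pred.velocity)
            foot = F + pred.velocity
            for t in np.linspace(-20, 20, 801):
                assert speed <= np.linalg.norm(foot + t * d - F) + 1e-9
            assert abs(pred.velocity @ d) < 1e-9

    def test_matches_closed_form_at_zero_disparity(self, geometry, rng):
        for _ in range(50):
            spec = StimulusSpec(
                float(rng.uniform(5, 85)), 0.0, float(rng.uniform(-80, 80)), 0.0,
                float(rng.uniform(0.1, 2)),
            )
            event = make_motion_event(geometry, spec)
            vx, vz = event.velocity[0], event.velocity[2]
            np.testing.assert_allclose(
                vn_predict(event).velocity,
                closed_form_vn(spec.tilt_deg, vx, vz),
                atol=1e-9,
            )


class TestCyclopeanAverage:
    def test_equals_vn_at_zero_disparity(self, geometry, rng):
        for _ in range(50):
            spec = StimulusSpec(
                float(rng.uniform(1, 89)), 0.0, float(rng.uniform(-80, 80)), 0.0,
                float(rng.uniform(0.1, 2)),
            )
            event = make_motion_event(geometry, spec)
            vn, ca = vn_predict(event), ca_predict(event)
            assert vn.status == ca.status == "ok"
            assert np.linalg.norm(vn.velocity - ca.velocity) < 1e-9

    def test_fronto_parallel_motion_has_zero_disparity_change(self, geometry):
        event = make_motion_event(geometry, StimulusSpec(45.0, 0.0, 0.0, 0.0, 1.0))
        pred = ca_predict(event)
        assert pred.status == "ok"
        assert pred.diagnostics["eta"] == pytest.approx(0.0, abs=1e-12)
        assert pred.velocity[2] == pytest.approx(0.0, abs=1e-9)

    def test_differs_from_vn_when_slanted(self, geometry):
        for delta in (3.0, -3.0):
            event = make_motion_event(geometry, StimulusSpec(45.0, delta, 57.2, 0.0, 1.0))
            vn, ca = vn_predict(event), ca_predict(event)
            assert np.linalg.norm(vn.velocity - ca.velocity) > 1e-6

    def test_constructed_points_satisfy_intersection_condition(self, geometry):
        event = make_motion_event(geometry, StimulusSpec(60.0, 2.5, 40.0, 10.0, 1.0))
        pred = ca_predict(event)
        assert pred.status == "ok"
        # the split disparity points share a vertical coordinate on the screen
        cyc = pred.diagnostics["cyclopean_endpoint"]
        eta = pred.diagnostics["eta"]
        b = np.array([cyc[0] + eta / 2, cyc[1], geometry.D])
        d = np.array([cyc[0] - eta / 2, cyc[1], geometry.D])
        assert vertical_offset_condition(b, d, coplanar=True)

    def test_horizontal_image_line_is_undefined(self, geometry):
        horizontal = Line3([0.0, 1.0, 57.0], [1.0, 1.0, 57.0])
        event = MotionEvent(geometry, horizontal, np.array([-0.5, 0.0, -0.5]))
        assert ca_predict(event).status == "undefined"
        assert cdot_predict(event).status == "undefined"


class TestIOVD:
    def test_tilted_line_moving_in_depth_is_skew(self, geometry):
        event = make_motion_event(geometry, StimulusSpec(45.0, 0.0, 57.2, 0.0, 1.0))
        pred = iovd_predict(event)
        assert pred.status == "skew"
        assert pred.diagnostics["min_distance"] > 0

    def test_fronto_parallel_motion_intersects_on_screen(self, geometry):
        event = make_motion_event(geometry, StimulusSpec(45.0, 0.0, 0.0, 0.0, 1.0))
        pred = iovd_predict(event)
        assert pred.status == "ok"
        assert pred.velocity[2] == pytest.approx(0.0, abs=1e-9)

    def test_vertical_line_horizontal_motion_intersects(self, geometry):
        event = make_motion_event(geometry, StimulusSpec(90.0, 0.0, 30.0, 0.0, 1.0))
        assert iovd_predict(event).status == "ok"

    def test_skew_iff_vertical_offset_condition_fails(self, geometry, rng):
        for _ in range(100):
            spec = StimulusSpec(
                float(rng.uniform(5, 175)),
                float(rng.uniform(-4, 4)),
                float(rng.uniform(-80, 80)),
                float(rng.uniform(-30, 30)),
                float(rng.uniform(0.1, 2)),
            )
            event = make_motion_event(geometry, spec)
            pred = iovd_predict(event)
            mono = _normal_endpoints(event)
            b = np.array([*mono["left"]["endpoint"], geometry.D])
            d = np.array([*mono["right"]["endpoint"], geometry.D])
            cond = vertical_offset_condition(b, d, coplanar=True, tol=1e-7)
            if pred.status in ("ok", "skew"):
                assert (pred.status == "skew") == (not cond)


class TestCDOT:
    def test_pure_motion_in_depth_is_exact(self, geometry):
        for speed in (0.4, 1.3):
            event = make_motion_event(geometry, StimulusSpec(45.0, 0.0, -90.0, 0.0, speed))
            np.testing.assert_allclose(event.velocity, [0, 0, speed], atol=1e-12)
            pred = cdot_predict(event)
            assert pred.status == "ok"
            np.testing.assert_allclose(pred.velocity, [0, 0, speed], atol=1e-9)

    def test_lateral_motion_of_slanted_line_is_misread(self, geometry):
        """A line slanted in depth translating leftward: the true velocity is
        lateral, yet CDOT reports only motion along the line of sight — here
        nothing at all, because lateral translation leaves the line's depth
        profile, and hence the disparity at every screen height, unchanged."""
        event = make_motion_event(geometry, StimulusSpec(45.0, 3.0, 0.0, 0.0, 1.0))
        pred = cdot_predict(event, probe_y=1.0)
        assert pred.status == "ok"
        assert pred.velocity[0] == 0.0 and pred.velocity[1] == 0.0
        assert pred.diagnostics["eta_start"] != 0.0  # disparity present...
        assert pred.velocity[2] == pytest.approx(0.0, abs=1e-12)  # ...but static
        np.testing.assert_allclose(event.velocity, [-1, 0, 0], atol=1e-12)

    def test_static_line_reports_zero(self, geometry):
        event = make_motion_event(geometry, StimulusSpec(45.0, 0.0, 0.0, 0.0, 0.0))
        pred = cdot_predict(event)
        np.testing.assert_allclose(pred.velocity, [0, 0, 0], atol=1e-12)
        assert pred.diagnostics["eta_start"] == pytest.approx(0.0, abs=1e-12)

    def test_probe_height_is_configurable(self, geometry):
        # a slanted line moving in depth: the disparity change differs by height
        event = make_motion_event(geometry, StimulusSpec(45.0, 3.0, 57.2, 0.0, 1.0))
        p0 = cdot_predict(event, probe_y=0.0)
        p1 = cdot_predict(event, probe_y=2.0)
        assert p0.velocity[2] != p1.velocity[2]


class TestTriangulation:
    def test_zero_displacement(self, geometry):
        np.testing.assert_allclose(
            triangulate_point(geometry, [0, 0, 0]).velocity, [0, 0, 0], atol=1e-15
        )

    def test_reference_trajectory_azimuth(self, geometry):
        pred = triangulate_point(geometry, [-0.5417, 0.0, -0.8406])
        sph = to_spherical(pred.velocity)
        assert round(sph.azimuth_deg, 1) == 57.2
        assert round(sph.elevation_deg, 1) == 0.0

    def test_recovery_is_identity(self, geometry, rng):
        for _ in range(100):
            v = rng.uniform(-2, 2, 3)
            pred = triangulate_point(geometry, v)
            assert np.linalg.norm(pred.velocity - v) < 1e-8


class TestJEMD:
    def test_time_reversed_trajectory_is_indistinguishable(self, geometry):
        v = velocity_from_angles(57.2, 0.0, 1.0)
        fwd = jemd_signature(geometry, v, K=10)
        rev = jemd_signature(geometry, -v, K=10, start=geometry.fixation + v)
        assert fwd.as_counter() == rev.as_counter()

    def test_fronto_parallel_motion_stays_in_one_depth_bin(self, geometry):
        sig = jemd_signature(geometry, np.array([-1.0, 0.0, 0.0]), K=8)
        depth_bins = {key[0] for key, _ in sig.counts}
        assert len(depth_bins) == 1

    def test_size_scales_with_sampling(self, geometry):
        v = velocity_from_angles(57.2, 0.0, 1.0)
        assert jemd_signature(geometry, v, K=6).size == 6
        assert jemd_signature(geometry, v, K=12).size == 12

    def test_too_few_samples_rejected(self, geometry):
        with pytest.raises(ValueError):
            jemd_signature(geometry, [0, 0, -1], K=1)


def test_prediction_status_velocity_consistency():
    with pytest.raises(ValueError):
        Prediction("VN", "ok", velocity=None)
    with pytest.raises(ValueError):
        Prediction("VN", "skew", velocity=np.zeros(3))
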