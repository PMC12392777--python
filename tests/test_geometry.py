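"""Pinhole-system geometry: forward model, weighting centres and
calibration."""

import numpy as np
import pytest

import mlprecond as mlp
from mlprecond.geometry import (DEFAULT_FREE, PARAM_NAMES,
                                CalibrationAcquisition, GeometryCalibrator,
                                GeometryParams, forward_centers,
                                weighting_center)


@pytest.fixture(scope="module")
def spec():
    return mlp.DetectorSpec.toy(precond_n=24)


@pytest.fixture(scope="module")
def alpha(spec):
    return GeometryParams.default_prototype(spec)


@pytest.fixture(scope="module")
def protocol():
    """8 uniformly spaced angles at 3 axial positions = 24 views."""
    angles = np.tile(np.arange(8) * 45.0, 3)
    trans = np.repeat([-2.0, 0.0, 2.0], 8)
    return angles, trans


class TestWeightingCenter:
    def test_single_bright_bin(self):
        img = np.zeros((10, 10))
        img[3, 7] = 5.0
        u, v = weighting_center(img, pitch=0.5)
        assert (u, v) == (pytest.approx(7.5 * 0.5), pytest.approx(3.5 * 0.5))

    def test_symmetric_blob_centres(self):
        y, x = np.mgrid[0:21, 0:21]
        img = np.exp(-((x - 10.0) ** 2 + (y - 10.0) ** 2) / 8.0)
        u, v = weighting_center(img, pitch=1.0)
        assert u == pytest.approx(10.5) and v == pytest.approx(10.5)

    def test_matches_direct_weighted_sum(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 12))
        u, v = weighting_center(img, pitch=0.5)
        ys = (np.arange(8) + 0.5) * 0.5
        xs = (np.arange(12) + 0.5) * 0.5
        assert u == pytest.approx((img.sum(0) @ xs) / img.sum())
        assert v == pytest.approx((img.sum(1) @ ys) / img.sum())

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError):
            weighting_center(np.zeros((4, 4)))


class TestForwardModel:
    def test_on_axis_source_is_rotation_invariant(self, alpha, protocol):
        angles, trans = protocol
        on_axis = alpha.replace_named(radius=0.0)
        centers = forward_centers(on_axis, angles, np.zeros_like(trans))
        assert np.allclose(centers, centers[0])

    def test_unit_magnification_mirrors_source_offset(self, alpha):
        """Equal pinhole-object and detector-pinhole distances image a
        radial offset at the same magnitude (inverted)."""
        c0 = forward_centers(alpha.replace_named(radius=0.0), [0.0], [0.0])[0]
        c6 = forward_centers(alpha, [0.0], [0.0])[0]
        assert np.hypot(*(c6 - c0)) == pytest.approx(alpha.radius, rel=1e-9)

    def test_matches_homogeneous_transform_oracle(self, alpha, protocol):
        """Independent second implementation with 4x4 homogeneous
        matrices reproduces the predicted centres."""
        angles, trans = protocol
        tilted = alpha.replace_named(det_angles=(4.0, -3.0, 2.0),
                                     pinhole=(0.4, 91.0, -0.2),
                                     radius=5.5)
        expected = forward_centers(tilted, angles, trans)

        def homogeneous(alpha, ang, tr):
            th = np.deg2rad(ang + alpha.phase)
            Rz = np.array([[np.cos(th), -np.sin(th), 0, 0],
                           [np.sin(th), np.cos(th), 0, 0],
                           [0, 0, 1, 0], [0, 0, 0, 1.0]])
            T = np.eye(4)
            T[:3, 3] = np.asarray(alpha.trans_axis) * tr
            p_src = np.array([alpha.radius, 0.0, 0.0, 1.0])
            s = (T @ Rz @ p_src)[:3]
            o, eu, ev, ew = tilted.detector_frame()
            p = np.asarray(alpha.pinhole)
            tau = ((o - p) @ ew) / ((p - s) @ ew)
            hit = p + tau * (p - s)
            return np.array([(hit - o) @ eu, (hit - o) @ ev])

        got = np.array([homogeneous(tilted, a, t) for a, t in zip(angles, trans)])
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_rotation_equivariance(self, alpha, protocol):
        """Rotating the source by theta equals shifting every commanded
        angle by theta (the stage phase)."""
        angles, trans = protocol
        a = forward_centers(alpha, angles + 17.0, trans)
        b = forward_centers(alpha.replace_named(phase=17.0), angles, trans)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_vector_round_trip_has_19_components(self, alpha):
        v = alpha.to_vector()
        assert v.shape == (19,)
        assert GeometryParams.from_vector(v) == alpha
        with pytest.raises(ValueError):
            GeometryParams.from_vector(v[:16])


class TestCalibration:
    def test_24_views_consumed(self, alpha, protocol):
        angles, trans = protocol
        acq = CalibrationAcquisition(forward_centers(alpha, angles, trans),
                                     angles, trans)
        assert acq.n_views == 24

    def test_noiseless_recovery_of_identifiable_parameters(self, alpha, protocol):
        angles, trans = protocol
        centers = forward_centers(alpha, angles, trans)
        rng = np.random.default_rng(7)
        v = alpha.to_vector()
        pert = v.copy()
        for name in DEFAULT_FREE:
            i = PARAM_NAMES.index(name)
            pert[i] += rng.uniform(-3, 3) if "rot" in name else rng.uniform(-2, 2)
        cal = GeometryCalibrator(seed=1, n_restarts=4).fit(
            CalibrationAcquisition(centers, angles, trans),
            GeometryParams.from_vector(pert))
        err = cal.alpha_.to_vector() - v
        for name in DEFAULT_FREE:
            i = PARAM_NAMES.index(name)
            tol = 0.1 if "rot" in name else 0.05
            assert abs(err[i]) < tol, f"{name}: {err[i]}"

    def test_noisy_centers_fit_at_noise_level_without_bias(self, alpha, protocol):
        angles, trans = protocol
        truth = forward_centers(alpha, angles, trans)
        rng = np.random.default_rng(8)
        noisy = truth + rng.normal(0.0, 0.1, truth.shape)
        init = alpha.replace_named(radius=alpha.radius * 1.05)
        cal = GeometryCalibrator(seed=2, n_restarts=4).fit(
            CalibrationAcquisition(noisy, angles, trans), init)
        assert cal.report_["rms_residual"] == pytest.approx(0.1, abs=0.05)
        pred = forward_centers(cal.alpha_, angles, trans)
        assert np.all(np.abs((pred - truth).mean(axis=0)) < 0.05)

    def test_acquisition_requirements_enforced(self, alpha):
        angles = np.array([0.0, 120.0, 240.0])
        trans = np.zeros(3)
        centers = forward_centers(alpha, angles, trans)
        with pytest.raises(ValueError, match="axial"):
            GeometryCalibrator().fit(CalibrationAcquisition(centers, angles, trans),
                                     alpha)
        angles2 = np.array([0.0, 0.0, 0.0, 0.0])
        trans2 = np.array([-1.0, 0.0, 1.0, 2.0])
        centers2 = forward_centers(alpha, angles2, trans2)
        with pytest.raises(ValueError, match="angles"):
            GeometryCalibrator().fit(
                CalibrationAcquisition(centers2, angles2, trans2), alpha)

    def test_too_few_measurements_rejected(self, alpha):
        angles = np.array([0.0, 90.0, 180.0, 270.0])
        trans = np.array([-1.0, 0.0, 1.0, 0.0])
        centers = forward_centers(alpha, angles, trans)
        with pytest.raises(ValueError, match="free parameters"):
            GeometryCalibrator().fit(
                CalibrationAcquisition(centers, angles, trans), alpha)
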