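"""Voxel-driven system response and tomographic MLEM."""

import numpy as np
import pytest

import mlprecond as mlp
from mlprecond.attenuation import AttenuationModel, layer_fractions
from mlprecond.geometry import GeometryParams
from mlprecond.phantom import make_cylinder_phantom, make_hot_rod_phantom
from mlprecond.recon import (PinholeMLEM, SourceGrid, build_srf,
                             match_iterations_by_resolution, mlem_reconstruct,
                             simulate_pinhole_projection)


@pytest.fixture(scope="module")
def spec():
    return mlp.DetectorSpec.toy(precond_n=24)


@pytest.fixture(scope="module")
def alpha(spec):
    return GeometryParams.default_prototype(spec)


@pytest.fixture(scope="module")
def small_grid():
    return SourceGrid(np.ones((4, 16, 16)), voxel_size=0.4)


class TestSRF:
    def test_layer_weights_follow_attenuation_fractions(self, spec, alpha):
        """A point voxel on the axis spreads across DOI layers with the
        analytic exponential-attenuation fractions."""
        grid = SourceGrid(np.ones((1, 1, 1)), voxel_size=0.4)
        srf = build_srf(alpha, spec, [0.0], grid=grid, aperture_diameter=0.5)
        col = np.asarray(srf.views[0].todense()).ravel()
        nl, Hp, Wp = srf.det_shape
        per_layer = col.reshape(nl, Hp * Wp).sum(axis=1)
        expected = layer_fractions(AttenuationModel.from_spec(spec))
        np.testing.assert_allclose(per_layer / per_layer.sum(), expected, rtol=1e-9)
        # and the footprint sits at the detector centre
        img = col.reshape(nl, Hp, Wp).sum(axis=0)
        iy, ix = np.unravel_index(img.argmax(), img.shape)
        assert abs(iy - (Hp - 1) / 2) <= 1 and abs(ix - (Wp - 1) / 2) <= 1

    def test_magnification_scales_with_distances(self, spec):
        """Doubling the pinhole-to-object distance halves the image
        offset of an off-axis voxel (similar triangles)."""
        grid = SourceGrid(np.ones((1, 1, 1)), voxel_size=0.25,
                          origin=(2.0 - 0.125, -0.125, -0.125))  # x = +2 mm

        def center_u(pinhole_to_axis):
            a = GeometryParams.default_prototype(
                spec, pinhole_to_axis=pinhole_to_axis, detector_to_pinhole=90.0)
            srf = build_srf(a, spec, [0.0], grid=grid, aperture_diameter=0.3)
            col = np.asarray(srf.views[0].todense()).ravel()
            nl, Hp, Wp = srf.det_shape
            img = col.reshape(nl, Hp, Wp).sum(axis=0)
            xs = (np.arange(Wp) + 0.5) * spec.precond_pitch
            return (img.sum(axis=0) @ xs) / img.sum() - spec.precond_span[1] / 2

        off_90 = center_u(90.0)
        off_180 = center_u(180.0)
        assert off_90 == pytest.approx(-2.0, abs=0.1)
        assert off_180 == pytest.approx(-1.0, abs=0.1)

    def test_every_fov_voxel_covered_across_views(self, spec, alpha, small_grid):
        angles = np.arange(24) * 15.0
        srf = build_srf(alpha, spec, angles, grid=small_grid,
                        aperture_diameter=1.0)
        assert srf.meta["n_uncovered"] == 0
        assert np.all(srf.g > 0)

    def test_sensitivity_is_column_sum_over_views(self, spec, alpha, small_grid):
        srf = build_srf(alpha, spec, [0.0, 120.0, 240.0], grid=small_grid)
        total = sum(np.asarray(A.sum(axis=0)).ravel() for A in srf.views)
        np.testing.assert_allclose(srf.g, total)


class TestReconstruction:
    def test_zero_data_reconstructs_to_zero(self, spec, alpha, small_grid):
        srf = build_srf(alpha, spec, [0.0, 90.0, 180.0], grid=small_grid)
        zeros = [np.zeros(srf.n_det) for _ in srf.views]
        out = mlem_reconstruct(zeros, srf, n_iter=5, grid=small_grid)
        assert out.values.sum() == 0

    def test_hot_voxel_recovered_from_noiseless_projections(self, spec, alpha):
        grid = SourceGrid(np.zeros((3, 12, 12)), voxel_size=0.4)
        grid.values[1, 4, 7] = 1.0
        angles = np.arange(8) * 45.0
        srf = build_srf(alpha, spec, angles, grid=grid, aperture_diameter=0.5)
        truth = grid.values.ravel()
        data = [A @ truth for A in srf.views]
        out = mlem_reconstruct(data, srf, n_iter=20, grid=grid)
        assert out.values.argmax() == truth.argmax()
        # count conservation: sum_l g_l Q_l equals the measured total
        q = out.values.ravel()
        assert np.dot(srf.g, q) == pytest.approx(sum(d.sum() for d in data), rel=1e-9)

    def test_forward_projected_phantom_converges_in_data_space(self):
        """Noiseless data in the range of the system matrix is fitted
        to numerical zero residual (MLEM's slow tail needs a generous
        iteration budget on ill-conditioned voxel-driven systems, so
        this property is checked on a small random system)."""
        from scipy import sparse

        from mlprecond.recon import SystemResponse

        rng = np.random.default_rng(0)
        A = sparse.csr_matrix(rng.random((80, 27)) * (rng.random((80, 27)) < 0.4))
        srf = SystemResponse(views=[A], g=np.asarray(A.sum(axis=0)).ravel(),
                             det_shape=(1, 80, 1), grid_shape=(3, 3, 3))
        truth = rng.random(27) + 0.2
        data = [A @ truth]
        q = mlem_reconstruct(data, srf, n_iter=2000).values.ravel()
        assert np.abs(A @ q - data[0]).sum() / data[0].sum() < 1e-4

    def test_estimator_wrapper(self, spec, alpha, small_grid):
        angles = [0.0, 120.0, 240.0]
        srf = build_srf(alpha, spec, angles, grid=small_grid)
        data = [A @ np.ones(srf.n_vox) for A in srf.views]
        est = PinholeMLEM(alpha, spec, angles_deg=angles, grid=small_grid,
                          n_iter=5).fit(data)
        direct = mlem_reconstruct(data, srf, n_iter=5, grid=small_grid)
        np.testing.assert_allclose(est.volume_.values, direct.values)


class TestIterationMatching:
    def test_identical_series_pick_same_iteration(self):
        series = {5: 1.4, 10: 1.1, 15: 0.9}
        assert match_iterations_by_resolution(series, dict(series), 1.0) == (15, 15)

    def test_monotone_series_has_unique_crossing(self):
        a = {i: 2.0 - 0.1 * i for i in range(1, 16)}
        b = {i: 2.4 - 0.12 * i for i in range(1, 16)}
        ia, ib = match_iterations_by_resolution(a, b, 1.0)
        assert a[ia] == pytest.approx(1.0, abs=0.05)
        assert b[ib] == pytest.approx(1.0, abs=0.06)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="rods"):
            match_iterations_by_resolution({}, {1: 1.0}, 1.0)


class TestPinholeProjectionSimulator:
    def test_point_phantom_projects_to_mirrored_position(self, spec, alpha):
        phantom = SourceGrid(np.ones((1, 1, 1)), voxel_size=0.2,
                             origin=(1.5 - 0.1, -0.1, -0.1))  # x = +1.5 mm
        proj = simulate_pinhole_projection(spec, alpha, phantom, 0.0,
                                           n_events=20_000,
                                           aperture_diameter=0.3, seed=1)
        img = proj.layer_summed().astype(float)
        xs = spec.raw_centers(1)
        cx = (img.sum(axis=0) @ xs) / img.sum()
        # unit magnification inverts: +1.5 mm -> centre - 1.5 mm
        assert cx == pytest.approx(spec.raw_span[1] / 2 - 1.5, abs=0.1)

    def test_rotation_moves_projection_accordingly(self, spec, alpha):
        phantom = SourceGrid(np.ones((1, 1, 1)), voxel_size=0.2,
                             origin=(1.5 - 0.1, -0.1, -0.1))
        proj = simulate_pinhole_projection(spec, alpha, phantom, 180.0,
                                           n_events=20_000,
                                           aperture_diameter=0.3, seed=2)
        img = proj.layer_summed().astype(float)
        xs = spec.raw_centers(1)
        cx = (img.sum(axis=0) @ xs) / img.sum()
        assert cx == pytest.approx(spec.raw_span[1] / 2 + 1.5, abs=0.1)

    def test_phantom_factories(self):
        ph = make_cylinder_phantom(24, 4, 0.4, 8.0, 1.6, (-1.8, 1.8))
        assert ph.values.shape == (4, 24, 24)
        assert ph.values.max() == 1.0 and ph.values.min() == 0.0
        rods = make_hot_rod_phantom(24, 2, 0.4, 1.8, 3.6, 2)
        assert rods.values.sum() > 0
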