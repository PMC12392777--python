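"""Simulator unit and property tests: determinism, bookkeeping, depth
statistics, and the three pathologies."""

import numpy as np
import pytest
from scipy import integrate, stats

import mlprecond as mlp
from mlprecond.attenuation import AttenuationModel, layer_fractions
from mlprecond.metrics import axis_lag_autocorr


@pytest.fixture(scope="module")
def spec():
    return mlp.DetectorSpec.toy(precond_n=16)


class TestDistortionField:
    def test_zero_amplitude_gives_zero_field(self, spec):
        f = mlp.make_distortion_field(spec, 0.0, 5.0, seed=3)
        ux, uy = f.displacement(np.array([1.0, 5.0]), np.array([2.0, 6.0]))
        assert np.all(ux == 0) and np.all(uy == 0)

    def test_deterministic_for_fixed_seed(self, spec):
        f1 = mlp.make_distortion_field(spec, 0.5, 5.0, seed=7)
        f2 = mlp.make_distortion_field(spec, 0.5, 5.0, seed=7)
        assert np.array_equal(f1.dx, f2.dx) and np.array_equal(f1.dy, f2.dy)
        f3 = mlp.make_distortion_field(spec, 0.5, 5.0, seed=8)
        assert not np.array_equal(f1.dx, f3.dx)

    def test_empirical_rms_matches_requested_amplitude(self, spec):
        f = mlp.make_distortion_field(spec, 0.5, 5.0, seed=1)
        xs = np.linspace(0.1, 7.9, 60)
        X, Y = np.meshgrid(xs, xs)
        ux, uy = f.displacement(X, Y)
        rms = np.sqrt(np.mean(ux**2 + uy**2))
        assert 0.25 <= rms <= 0.75
        assert np.hypot(ux, uy).max() <= 3 * 0.5 + 1e-9

    def test_rejects_nonpositive_correlation_length(self, spec):
        with pytest.raises(ValueError):
            mlp.make_distortion_field(spec, 0.5, 0.0, seed=1)


class TestEventEngine:
    def test_zero_events_gives_zero_counts(self, spec):
        flu = np.ones(spec.raw_shape)
        proj = mlp.simulate_events(spec, flu, 0, seed=1)
        assert proj.total == 0

    def test_empty_fluence_rejected(self, spec):
        with pytest.raises(ValueError):
            mlp.simulate_events(spec, np.zeros(spec.raw_shape), 100, seed=1)

    def test_event_bookkeeping_is_exact(self, spec):
        field = mlp.make_distortion_field(spec, 0.5, 5.0, seed=2)
        gain = mlp.make_gain_map(spec, 0.1, seed=3)
        boundary = mlp.BoundaryArtifactModel(0.2, 0.4)
        proj = mlp.simulate_flood(spec, 50_000, field, boundary, gain, seed=4)
        m = proj.meta
        assert m["n_events"] == proj.total + m["n_out_of_bounds"] + m["n_gain_rejected"]

    def test_layer_totals_follow_attenuation_model(self, spec):
        """Depth sampling reproduces the analytic per-layer fractions
        (chi-square goodness of fit at alpha=0.01)."""
        proj = mlp.simulate_flood(spec, 1_000_000, seed=5)
        frac = layer_fractions(AttenuationModel.from_spec(spec))
        obs = proj.counts.reshape(spec.n_layers, -1).sum(axis=1)
        chi2, p = stats.chisquare(obs, f_exp=frac * obs.sum())
        assert p > 0.01

    def test_layer_fraction_oracle_against_quadrature(self, spec):
        """The frozen layer fractions equal direct numerical
        integration of the attenuation density over each layer."""
        model = AttenuationModel.from_spec(spec)
        mu, t, n = model.mu_total, model.t, model.n
        dens = lambda x: model.mu_pe * np.exp(-mu * x)
        raw = [integrate.quad(dens, (n - m) * t, (n - m + 1) * t)[0]
               for m in range(1, n + 1)]
        expected = np.array(raw) / np.sum(raw)
        np.testing.assert_allclose(layer_fractions(model), expected, atol=1e-10)

    def test_clean_flood_is_poisson_flat(self, spec):
        proj = mlp.simulate_flood(spec, 2_000_000, seed=6)
        img = proj.layer_summed().astype(float)
        mean = img.mean()
        # index of dispersion ~ 1 for Poisson
        assert abs(img.var() / mean - 1.0) < 0.05
        assert abs(img.std() / mean - 1.0 / np.sqrt(mean)) < 0.01


class TestBoundaryArtifact:
    def test_flood_autocorrelation_peaks_at_anode_pitch(self, spec):
        boundary = mlp.BoundaryArtifactModel(0.2, 0.3)
        proj = mlp.simulate_flood(spec, 2_000_000, boundary=boundary, seed=7)
        img = proj.layer_summed().astype(float)
        lag = int(round(spec.anode_pitch / spec.raw_bin_pitch))
        for axis in (0, 1):
            at_pitch = axis_lag_autocorr(img, lag, axis)
            mid_cell = axis_lag_autocorr(img, lag // 2, axis)
            assert at_pitch > mid_cell + 0.1

    def test_misplacement_fraction_bounds_validated(self):
        with pytest.raises(ValueError):
            mlp.BoundaryArtifactModel(0.2, 1.5)
        with pytest.raises(ValueError):
            mlp.BoundaryArtifactModel(1.0, 0.3)  # halfwidth >= pitch/2


class TestPencilBeam:
    def test_no_pathologies_hits_single_bin(self, spec):
        pos = (3.05, 4.25)
        proj = mlp.simulate_pencil_beam(spec, pos, 10_000, seed=8)
        img = proj.layer_summed()
        assert img.sum() == 10_000
        row, col = np.unravel_index(img.argmax(), img.shape)
        assert img[row, col] == 10_000
        assert col == int(pos[0] / spec.raw_bin_pitch)
        assert row == int(pos[1] / spec.raw_bin_pitch)

    def test_distortion_shifts_centroid_by_field_value(self, spec):
        field = mlp.make_distortion_field(spec, 0.4, 4.0, seed=9)
        pos = (4.05, 3.55)
        ux, uy = field.displacement(np.array([pos[0]]), np.array([pos[1]]))
        proj = mlp.simulate_pencil_beam(spec, pos, 20_000, field=field, seed=10)
        img = proj.layer_summed().astype(float)
        ys = spec.raw_centers(0)
        xs = spec.raw_centers(1)
        cx = (img.sum(0) @ xs) / img.sum()
        cy = (img.sum(1) @ ys) / img.sum()
        assert abs(cx - (pos[0] + ux[0])) < 0.06
        assert abs(cy - (pos[1] + uy[0])) < 0.06

    def test_position_outside_detector_rejected(self, spec):
        with pytest.raises(ValueError):
            mlp.simulate_pencil_beam(spec, (-1.0, 2.0), 100, seed=1)

    def test_separable_response_factorizes(self, spec):
        """With a separable distortion field d(x,y)=(dx(x), dy(y)) and
        no other pathology, the pencil response equals the outer
        product of its own marginals."""

        class Sep:
            amplitude = 0.3

            def displacement(self, x, y):
                return (0.3 * np.sin(np.asarray(x)), 0.3 * np.cos(np.asarray(y)))

        proj = mlp.simulate_pencil_beam(spec, (3.6, 4.2), 200_000, field=Sep(), seed=11)
        img = proj.layer_summed().astype(float)
        img /= img.sum()
        outer = np.outer(img.sum(axis=1), img.sum(axis=0))
        assert np.abs(img - outer).sum() < 0.05


class TestSheetBeam:
    def test_scan_produces_one_projection_per_position(self, spec):
        positions = spec.precond_centers(1)
        scans = mlp.simulate_sheet_beam_scan(spec, "x", positions, 0.5, 1000, seed=12)
        assert len(scans) == spec.precond_grid[1]

    def test_two_axis_scan_count_matches_grid(self, spec):
        """The full protocol needs one scan per precondition row plus
        one per column — N + N positions for an N x N grid."""
        n_row = len(mlp.simulate_sheet_beam_scan(
            spec, "y", spec.precond_centers(0), 0.5, 10, seed=13))
        n_col = len(mlp.simulate_sheet_beam_scan(
            spec, "x", spec.precond_centers(1), 0.5, 10, seed=14))
        assert n_row + n_col == 2 * spec.precond_grid[0]

    def test_band_support_without_pathologies(self, spec):
        pos, width = 4.25, 0.5
        proj = mlp.simulate_sheet_beam(spec, "x", pos, width, 50_000, seed=15)
        img = proj.layer_summed()
        cols = np.nonzero(img.sum(axis=0))[0]
        lo = int((pos - width / 2) / spec.raw_bin_pitch)
        hi = int((pos + width / 2) / spec.raw_bin_pitch)
        assert cols.min() >= lo - 1 and cols.max() <= hi + 1

    def test_positions_must_increase(self, spec):
        with pytest.raises(ValueError):
            mlp.simulate_sheet_beam_scan(spec, "x", [2.0, 1.0], 0.5, 10, seed=1)
        with pytest.raises(ValueError):
            mlp.simulate_sheet_beam(spec, "x", 2.0, 0.0, 10, seed=1)

    def test_distorted_scan_centroid_deviations_track_field(self, spec):
        """Fitted band centroids deviate from commanded positions with
        RMSE comparable to the field's RMS displacement."""
        field = mlp.make_distortion_field(spec, 0.5, 5.0, seed=16)
        positions = np.array([2.25, 3.75, 5.25])
        fitted = []
        for pos in positions:
            proj = mlp.simulate_sheet_beam(spec, "x", pos, 0.5, 100_000,
                                           field=field, seed=17)
            img = proj.layer_summed().astype(float)
            xs = spec.raw_centers(1)
            fitted.append((img.sum(axis=0) @ xs) / img.sum())
        rmse = np.sqrt(np.mean((np.array(fitted) - positions) ** 2))
        # per-axis RMS of an isotropic 0.5 mm RMS field is 0.35 mm; the
        # band average shrinks it further
        assert rmse < 0.5


class TestGainMap:
    def test_mean_unity_and_thinning(self, spec):
        gain = mlp.make_gain_map(spec, 0.1, seed=18)
        assert np.allclose(gain.values.mean(axis=(1, 2)), 1.0, atol=1e-9)
        proj = mlp.simulate_flood(spec, 200_000, gain=gain, seed=19)
        assert proj.meta["n_gain_rejected"] > 0

    def test_determinism_of_full_chain(self, spec, ):
        field = mlp.make_distortion_field(spec, 0.3, 5.0, seed=20)
        boundary = mlp.BoundaryArtifactModel(0.2, 0.3)
        gain = mlp.make_gain_map(spec, 0.05, seed=21)
        a = mlp.simulate_flood(spec, 30_000, field, boundary, gain, seed=22)
        b = mlp.simulate_flood(spec, 30_000, field, boundary, gain, seed=22)
        assert np.array_equal(a.counts, b.counts)
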