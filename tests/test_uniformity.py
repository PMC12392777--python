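"""Attenuation ratios and the flood-based uniformity correction."""

import warnings

import numpy as np
import pytest
from scipy import integrate, sparse

import mlprecond as mlp
from mlprecond.attenuation import (AttenuationModel, layer_count,
                                   layer_fractions, layer_ratio)
from mlprecond.drf import DRFMatrix, compute_sensitivity
from mlprecond.uniformity import UniformityCorrector, apply_full_pipeline


@pytest.fixture(scope="module")
def model():
    return AttenuationModel(mu_total=0.23, mu_pe=0.15, t=2.0, n=5)


class TestLayerCounts:
    def test_closed_form_matches_quadrature(self, model):
        for m in range(1, model.n + 1):
            num, _ = integrate.quad(
                lambda x: model.mu_pe * np.exp(-model.mu_total * x),
                (model.n - m) * model.t, (model.n - m + 1) * model.t)
            assert layer_count(model, m) == pytest.approx(num, abs=1e-10)

    def test_vanishing_attenuation_limit_is_flat(self):
        m = AttenuationModel(mu_total=1e-9, mu_pe=1e-9, t=2.0, n=5)
        counts = [layer_count(m, k) for k in range(1, 6)]
        np.testing.assert_allclose(counts, m.c0 * m.mu_pe * m.t, rtol=1e-6)

    def test_counts_increase_toward_front(self, model):
        counts = [layer_count(model, m) for m in range(1, model.n + 1)]
        assert np.all(np.diff(counts) > 0)

    def test_front_layer_ratio_is_exactly_one(self, model):
        assert layer_ratio(model, model.n) == pytest.approx(1.0, abs=1e-15)

    def test_layer3_of_5_ratio_near_point_four(self, model):
        """At mu_total=0.23/mm, t=2 mm, n=5 the third layer records
        ~0.4 of the front-layer counts (frozen from direct integration
        of the attenuation density)."""
        assert layer_ratio(model, 3) == pytest.approx(0.3985, abs=5e-4)

    def test_ratios_monotone_in_depth(self, model):
        ratios = [layer_ratio(model, m) for m in range(1, model.n + 1)]
        assert np.all(np.diff(ratios) > 0)

    def test_layer_index_validated(self, model):
        for bad in (0, 6):
            with pytest.raises(ValueError):
                layer_ratio(model, bad)

    def test_normalization_cancels_in_ratio_of_ratios(self, model):
        """ratio_m / ratio_n is unchanged whether or not the
        1 - exp(-mu t) denominator is included (it cancels)."""
        mu, t, n = model.mu_total, model.t, model.n
        for m in range(1, n + 1):
            unnormalized = np.exp(-mu * (n - m) * t) - np.exp(-mu * (n - m + 1) * t)
            unnorm_front = 1.0 - np.exp(-mu * t)
            assert layer_ratio(model, m) / layer_ratio(model, n) == pytest.approx(
                unnormalized / unnorm_front, rel=1e-12)

    def test_fractions_sum_to_one(self, model):
        assert layer_fractions(model).sum() == pytest.approx(1.0)


def _identity_drf(spec):
    n = spec.precond_shape[0] * spec.precond_shape[1]
    # precondition grid == raw grid for these synthetic cases
    assert spec.raw_shape == spec.precond_shape
    P = sparse.identity(n, format="csc")
    return DRFMatrix(P=P, s=compute_sensitivity(P), raw_shape=spec.raw_shape,
                     precond_shape=spec.precond_shape)


def _flat_flood(spec, per_pixel_front=1000.0):
    model = AttenuationModel.from_spec(spec)
    counts = np.empty((spec.n_layers, *spec.raw_shape))
    for m in range(1, spec.n_layers + 1):
        counts[m - 1] = per_pixel_front * layer_ratio(model, m)
    return mlp.RawProjection(counts=counts, spec=spec)


class TestCorrectionFactors:
    def test_flat_flood_gives_unit_factors(self):
        """A perfectly flat flood whose layers follow the analytic
        ratios needs no correction: CF = 1 on active pixels."""
        spec = mlp.DetectorSpec.toy(precond_n=8, raw_bin_pitch=0.5)
        est = UniformityCorrector(_identity_drf(spec), n_iter=50)
        est.fit(_flat_flood(spec))
        np.testing.assert_allclose(est.cf_, 1.0, rtol=1e-6)

    def test_gain_stripe_inverts_to_factor_two(self):
        spec = mlp.DetectorSpec.toy(precond_n=8, raw_bin_pitch=0.5)
        flood = _flat_flood(spec)
        flood.counts[:, :, 2] *= 0.5  # a x0.5 efficiency stripe
        est = UniformityCorrector(_identity_drf(spec), n_iter=50).fit(flood)
        stripe = est.cf_[:, :, 2]
        rest = np.delete(est.cf_, 2, axis=2)
        # total flood counts dropped slightly, rescaling all factors by
        # the same amount; the stripe-to-rest contrast is exactly 2
        np.testing.assert_allclose(stripe / rest.mean(axis=(1, 2))[:, None],
                                   2.0, rtol=1e-6)

    def test_dead_pixels_flagged_and_zeroed(self):
        spec = mlp.DetectorSpec.toy(precond_n=8, raw_bin_pitch=0.5)
        flood = _flat_flood(spec)
        flood.counts[:, 3, 3] = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = UniformityCorrector(_identity_drf(spec), n_iter=50).fit(flood)
        assert est.dead_pixels_[3, 3]
        assert np.all(est.cf_[:, 3, 3] == 0)

    def test_corrected_flood_matches_layer_ratios(self, toy_spec, toy_drf,
                                                  fitted_corrector, pathologies):
        """End to end on the pathological simulator: after correction an
        independent flood's per-layer totals follow the analytic
        ratio-of-ratios within 1%."""
        flood2 = mlp.simulate_flood(toy_spec, 4_000_000, seed=30, **pathologies)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            B = fitted_corrector.transform(flood2)
        model = AttenuationModel.from_spec(toy_spec)
        totals = B.values.reshape(toy_spec.n_layers, -1).sum(axis=1)
        for m in range(1, toy_spec.n_layers + 1):
            expected = layer_ratio(model, m) / layer_ratio(model, toy_spec.n_layers)
            assert totals[m - 1] / totals[-1] == pytest.approx(expected, rel=0.01)

    def test_pipeline_composition_with_unit_factors(self, toy_spec, toy_drf,
                                                    fitted_blur, pathologies):
        """CF = 1 reduces the full pipeline to blur + deconvolution."""
        proj = mlp.simulate_flood(toy_spec, 200_000, seed=31, **pathologies)
        est = UniformityCorrector(toy_drf, blur=fitted_blur, n_iter=10)
        est.cf_ = np.ones((toy_spec.n_layers, *toy_spec.precond_shape))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            B = est.transform(proj)
            direct = mlp.precondition(fitted_blur.transform(proj), toy_drf,
                                      n_iter=10, track_likelihood=False)
        np.testing.assert_allclose(B.values, direct.values)

    def test_functional_wrapper_apply_full_pipeline(self, toy_spec, toy_drf,
                                                    fitted_blur, fitted_corrector,
                                                    pathologies):
        proj = mlp.simulate_flood(toy_spec, 100_000, seed=32, **pathologies)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            via_func = apply_full_pipeline(proj, toy_drf, fitted_blur,
                                           fitted_corrector.factors_)
            via_est = fitted_corrector.transform(proj)
        np.testing.assert_allclose(via_func.values, via_est.values)
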