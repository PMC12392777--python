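"""Flood-based uniformity correction and full pipeline composition.

After deconvolution, residual nonuniformity remains: the un-normalized
DRF carries the sheet-beam intensity profile, and the crystal's own
gain variations are not in the response model.  A flood measurement
fixes both.  Per DOI layer ``m`` the target is a flat preconditioned
flood whose per-pixel value is

    target_m = (ratio_m / ratio_n) * sum(FP_n) / N_active

i.e. the mean active-pixel count of the front layer, scaled by the
analytic attenuation ratio, and the correction factor is the
element-wise quotient

    CF_m = target_m / P(S_m(FP_m))     (0 on inactive or dead pixels).

The full preconditioning chain for a measured projection ``A`` is then

    B_m = P(S_m(A_m)) * CF_m
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .attenuation import AttenuationModel, layer_ratio
from .blur import BlurFilterSet, RegionBlur, apply_blur
from .drf import DRFMatrix
from .mlem import precondition
from .projection import PrecondProjection, RawProjection

__all__ = ["CorrectionFactors", "UniformityCorrector",
           "compute_correction_factors", "apply_full_pipeline"]


class CorrectionFactors:
    """Per-layer, per-pixel multiplicative correction with provenance."""

    def __init__(self, cf: np.ndarray, model: AttenuationModel,
                 provenance: dict | None = None):
        cf = np.asarray(cf, dtype=float)
        if np.any(cf < 0):
            raise ValueError("correction factors must be non-negative")
        self.cf = cf
        self.model = model
        self.provenance = provenance or {}

    @property
    def n_dead(self) -> int:
        return int(self.provenance.get("n_dead", 0))


class UniformityCorrector(BaseEstimator):
    """Fit correction factors on a flood; transform = full pipeline.

    Parameters
    ----------
    drf : DRFMatrix
    blur : RegionBlur or BlurFilterSet or None
        The pre-blur operator ``S_m``; None skips blurring.
    model : AttenuationModel, optional
        Defaults to the attenuation constants of the flood's detector
        spec.
    n_iter : int
        MLEM iterations used for every deconvolution in the pipeline.
    min_mean_counts : float
        Required mean front-layer flood counts per active precondition
        pixel.

    Attributes
    ----------
    cf_ : ndarray [n_layers, rows, cols]
    factors_ : CorrectionFactors
    dead_pixels_ : ndarray of bool, active pixels with zero flood response
    """

    def __init__(self, drf: DRFMatrix, blur=None,
                 model: AttenuationModel | None = None,
                 n_iter: int = 50, min_mean_counts: float = 100.0,
                 dead_threshold: float = 0.05):
        self.drf = drf
        self.blur = blur
        self.model = model
        self.n_iter = n_iter
        self.min_mean_counts = min_mean_counts
        self.dead_threshold = dead_threshold

    def _smooth(self, A: RawProjection) -> RawProjection:
        if self.blur is None:
            return A
        if isinstance(self.blur, RegionBlur):
            return self.blur.transform(A)
        if isinstance(self.blur, BlurFilterSet):
            return apply_blur(A, self.blur)
        raise TypeError("blur must be RegionBlur, BlurFilterSet or None")

    def fit(self, flood: RawProjection, y=None) -> "UniformityCorrector":
        spec = flood.spec
        model = self.model or AttenuationModel.from_spec(spec)
        n = model.n
        drf = self.drf
        active = drf.active.reshape(spec.precond_shape)
        n_active = int(active.sum())
        if n_active == 0:
            raise ValueError("DRF has no active pixels")

        front_total = float(flood.counts[n - 1].sum())
        mean_front = front_total / n_active
        if mean_front < self.min_mean_counts:
            warnings.warn(
                f"flood statistics low: {mean_front:.1f} mean front-layer counts "
                f"per active pixel (< {self.min_mean_counts})"
            )

        F = precondition(self._smooth(flood), drf, n_iter=self.n_iter,
                         track_likelihood=False)
        ratios = np.array([layer_ratio(model, m) for m in range(1, n + 1)])
        ratio_n = ratios[-1]  # = 1 by construction; kept explicit

        cf = np.zeros_like(F.values)
        dead = np.zeros(spec.precond_shape, dtype=bool)
        for li in range(n):
            target = (ratios[li] / ratio_n) * front_total / n_active
            vals = F.values[li]
            # A vanishing flood response on an active pixel means the
            # correction would divide by (near) zero; flag it dead
            # relative to the typical response of the layer.
            floor = self.dead_threshold * np.median(vals[active])
            ok = active & (vals > floor)
            cf[li][ok] = target / vals[ok]
            layer_dead = active & ~ok
            dead |= layer_dead
            if np.any(layer_dead):
                warnings.warn(
                    f"layer {li + 1}: {int(layer_dead.sum())} active pixels with "
                    "(near-)zero preconditioned flood response flagged dead (CF = 0)"
                )

        self.cf_ = cf
        self.dead_pixels_ = dead
        self.model_ = model
        self.factors_ = CorrectionFactors(
            cf, model,
            provenance={
                "flood": flood.meta, "n_dead": int(dead.sum()),
                "n_active": n_active, "front_total": front_total,
                "n_iter": self.n_iter,
            },
        )
        return self

    def transform(self, A: RawProjection) -> PrecondProjection:
        """Full pipeline: ``B_m = P(S_m(A_m)) * CF_m``."""
        if not hasattr(self, "cf_"):
            raise RuntimeError("UniformityCorrector is not fitted")
        F = precondition(self._smooth(A), self.drf, n_iter=self.n_iter,
                         track_likelihood=False)
        out = F.values * self.cf_
        meta = dict(F.meta)
        meta["uniformity_corrected"] = True
        return PrecondProjection(values=out, spec=A.spec, n_iter=F.n_iter,
                                 loglik=F.loglik, meta=meta)


def compute_correction_factors(
    flood: RawProjection, drf: DRFMatrix, blur=None,
    model: AttenuationModel | None = None, n_iter: int = 50,
) -> CorrectionFactors:
    """Functional wrapper over :class:`UniformityCorrector.fit`."""
    est = UniformityCorrector(drf, blur=blur, model=model, n_iter=n_iter)
    return est.fit(flood).factors_


def apply_full_pipeline(
    A: RawProjection, drf: DRFMatrix, blur, factors: CorrectionFactors,
    n_iter: int = 50,
) -> PrecondProjection:
    """Compose blur, deconvolution and correction with precomputed
    factors."""
    est = UniformityCorrector(drf, blur=blur, model=factors.model, n_iter=n_iter)
    est.cf_ = factors.cf
    est.factors_ = factors
    return est.transform(A)
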