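# mlprecond

Maximum-likelihood data preconditioning for 3-D position-sensitive
gamma-ray imaging detectors, with the calibration and reconstruction
chain of a single-pinhole tomograph and a synthetic detector simulator
for end-to-end validation.

Large pixelated semiconductor detectors (CZT-style spectrometers with
depth-of-interaction readout) deliver sub-pixel spatial resolution but
suffer three systematic artifacts: events near anode-pixel boundaries
cluster onto the 1.9 mm pixel grid, the event-positioning response is
spatially distorted at the ~0.5 mm scale, and detection efficiency is
nonuniform in-plane and across depth.  `mlprecond` removes all three
from measured projections before image reconstruction.  It is written
for instrumentation physicists building or characterizing such
detectors, as sklearn-style estimators over NumPy/SciPy with a thin
command-line interface.

## The method

A raw projection `f̂` (counts on a fine detector grid, per DOI layer)
is modeled as Poisson with mean `λ = P f`, where `f` is the projection
on a coarse *preconditioned* grid and `P` is the detector response
function (DRF).  The preconditioned projection is the maximum-
likelihood estimate, found by the MLEM iteration

    f_l ← (f_l / s_l) Σ_j P_jl f̂_j / λ_j ,      s_l = Σ_j P_jl ,

which preserves total counts and increases the Poisson likelihood at
every step.  `P` is measured with two orthogonal sheet-beam scans (one
exposure per preconditioned row `R_a` and column `C_b`) and the
outer-product approximation `P[:, (a,b)] ≈ vec(R_a ∘ C_b)`.  Because
that approximation cannot carry the ~0.2 mm boundary-clustering
detail, raw projections are first smoothed with per-layer, region-wise
Gaussian filters `S_m` optimized on a flood measurement; residual
nonuniformity is removed afterwards with flood-based correction
factors `CF_m` built from the exponential-attenuation layer ratios

    ratio(m) = [e^(−μ(n−m)t) − e^(−μ(n−m+1)t)] / [1 − e^(−μ t)] .

The full chain is `B_m = P(S_m(A_m)) ∘ CF_m`.  For tomography, the
system geometry (detector pose, pinhole position, rotation stage —
a 19-component parameter vector) is calibrated from point-source
weighting centres by constrained least squares, and images are
reconstructed with voxel-driven MLEM whose system response includes
the pinhole solid angle, aperture footprint and DOI layer fractions.

The bundled simulator generates raw data exhibiting all three
pathologies (smooth displacement fields, probabilistic snap-to-boundary
misplacement, multiplicative gain thinning, exponential depth
sampling, Poisson statistics) and is the ground truth for the test
suite.  See `docs/methods.md` for models, parameters and limitations.

## Worked example

Build the whole correction chain on a simulated detector and
precondition a distorted sheet-beam exposure:

```python
import numpy as np
import mlprecond as mlp
from mlprecond.evaluate import build_study_chain
from mlprecond.metrics import fit_line_profiles

chain = build_study_chain(seed=0)          # scans -> DRF, flood -> S_m, CF_m
spec = chain.spec

scan = mlp.simulate_sheet_beam(spec, "x", position=3.25, beam_width=0.75,
                               n_events=300_000, seed=12,
                               **chain.pathologies)

raw = mlp.rebin_raw_to_precond(scan)       # no correction, just rebinned
fit_raw, = fit_line_profiles(raw.layer_summed(), axis=1,
                             expected_peaks=1, pitch=spec.precond_pitch)
pre = chain.corrector.transform(scan)      # B = P(S(A)) . CF
fit_pre, = fit_line_profiles(pre.layer_summed(), axis=1,
                             expected_peaks=1, pitch=spec.precond_pitch)
print(f"commanded 3.25 mm | raw centroid {fit_raw.centroid:.2f} mm "
      f"| preconditioned {fit_pre.centroid:.2f} mm")
```

```
commanded 3.25 mm | raw centroid 3.47 mm | preconditioned 3.25 mm
```

The raw centroid is pulled ~0.2 mm off the commanded beam position by
the simulated distortion; after preconditioning it lands on the
commanded position to within the fit precision.  Across a six-position
scan the centroid RMSE drops from a few tenths of a millimetre to
below 0.01 mm, and the
corrected flood reproduces the analytic per-layer count ratios within
1% (run `scripts/acceptance.py` below for the full set of numbers).

The same chain serves tomography:

```python
from mlprecond import GeometryParams, build_srf, mlem_reconstruct
from mlprecond.phantom import make_cylinder_phantom
from mlprecond.recon import simulate_pinhole_projection

alpha = GeometryParams.default_prototype(spec)
phantom = make_cylinder_phantom(28, 12, 0.4, diameter=9.0)
angles = np.arange(24) * 15.0
views = [chain.corrector.transform(
            simulate_pinhole_projection(spec, alpha, phantom, a,
                                        n_events=400_000, seed=500 + k,
                                        **chain.pathologies))
         for k, a in enumerate(angles)]
srf = build_srf(alpha, spec, angles, grid=phantom)
volume = mlem_reconstruct(views, srf, n_iter=15, grid=phantom)
```

A command-line interface mirrors the library
(`mlprecond simulate|build-drf|fit-blur|precondition|fit-uniformity|
correct|metrics|calibrate|reconstruct|run-all`); `mlprecond run-all`
executes the whole demo pipeline from one YAML config.

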