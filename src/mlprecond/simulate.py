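"""Synthetic detector simulator.

Generates raw projections exhibiting the three pathologies the
preconditioning framework corrects:

1. *spatial distortion* — a smooth 2-D displacement field shifts the
   apparent event position away from the true interaction position;
2. *pixel-boundary clustering* — events interacting near an anode-pixel
   boundary (1.9 mm square grid) are misplaced onto the boundary with
   some probability, producing the characteristic square-grid pattern
   in flood images;
3. *gain nonuniformity* — a multiplicative per-bin, per-layer detection
   efficiency thins the recorded events.

Depths are sampled from the exponential-attenuation model so per-layer
count fractions follow the analytic layer ratios.  Every public entry
point takes one integer seed; results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .attenuation import AttenuationModel, depth_to_layer_index, sample_depths
from .detector import DetectorSpec
from .projection import RawProjection

__all__ = [
    "DistortionField",
    "BoundaryArtifactModel",
    "GainMap",
    "make_distortion_field",
    "make_gain_map",
    "simulate_events",
    "simulate_flood",
    "simulate_pencil_beam",
    "simulate_sheet_beam",
    "simulate_sheet_beam_scan",
]


# ---------------------------------------------------------------------------
# pathology models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistortionField:
    """Smooth 2-D displacement field sampled on its own coarse grid.

    ``dx``/``dy`` hold the displacement components (mm) on a grid of
    pitch ``grid_pitch`` whose node (0, 0) sits at ``origin``;
    displacement at arbitrary points is bilinear interpolation with
    edge clamping.
    """

    dx: np.ndarray
    dy: np.ndarray
    grid_pitch: float
    origin: tuple[float, float]  # (y0, x0) of grid node (0, 0)
    amplitude: float
    correlation_length: float
    seed: int

    def displacement(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.amplitude == 0:
            z = np.zeros_like(np.asarray(x, dtype=float))
            return z, z.copy()
        iy = (np.asarray(y, dtype=float) - self.origin[0]) / self.grid_pitch
        ix = (np.asarray(x, dtype=float) - self.origin[1]) / self.grid_pitch
        coords = np.vstack([iy.ravel(), ix.ravel()])
        ux = ndimage.map_coordinates(self.dx, coords, order=1, mode="nearest")
        uy = ndimage.map_coordinates(self.dy, coords, order=1, mode="nearest")
        return ux.reshape(np.shape(x)), uy.reshape(np.shape(y))

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.dx**2 + self.dy**2)))


@dataclass(frozen=True)
class BoundaryArtifactModel:
    """Probabilistic snap-to-boundary model of the pixel-boundary
    clustering artifact.

    Events whose apparent coordinate falls within ``capture_halfwidth``
    of an anode-pixel boundary line are, with probability
    ``misplacement_fraction`` (scalar, or one value per DOI layer),
    relocated onto that boundary.
    """

    capture_halfwidth: float = 0.2
    misplacement_fraction: float | tuple[float, ...] = 0.3
    grid_pitch: float = 1.9

    def __post_init__(self) -> None:
        frac = np.atleast_1d(np.asarray(self.misplacement_fraction, dtype=float))
        if np.any((frac < 0) | (frac > 1)):
            raise ValueError("misplacement_fraction must lie in [0, 1]")
        if not 0 <= self.capture_halfwidth < self.grid_pitch / 2:
            raise ValueError("capture_halfwidth must lie in [0, grid_pitch/2)")

    def fraction_for_layers(self, n_layers: int) -> np.ndarray:
        frac = np.atleast_1d(np.asarray(self.misplacement_fraction, dtype=float))
        if frac.size == 1:
            return np.full(n_layers, frac[0])
        if frac.size != n_layers:
            raise ValueError(f"need 1 or {n_layers} misplacement fractions, got {frac.size}")
        return frac


@dataclass(frozen=True)
class GainMap:
    """Multiplicative detection efficiency per raw bin per DOI layer.

    Values are non-negative with mean 1 per layer; events are kept with
    probability proportional to the local gain (thinning against the
    map maximum), so relative efficiency is reproduced exactly.
    """

    values: np.ndarray  # [n_layers, rows, cols]

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("gain values must be non-negative")


def make_distortion_field(
    spec: DetectorSpec,
    amplitude: float,
    correlation_length: float,
    seed: int,
) -> DistortionField:
    """Seeded low-pass-filtered Gaussian noise, normalized so the RMS of
    the displacement magnitude equals ``amplitude`` and clipped so no
    displacement exceeds ``3 * amplitude``."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    span = max(max(spec.raw_span), max(spec.precond_span))
    margin = 3.0 * amplitude + correlation_length
    pitch = correlation_length / 4.0
    n = int(np.ceil((span + 2 * margin) / pitch)) + 1
    rng = np.random.default_rng(seed)
    if amplitude == 0:
        zeros = np.zeros((n, n))
        return DistortionField(zeros, zeros.copy(), pitch, (-margin, -margin),
                               0.0, correlation_length, seed)
    sigma = correlation_length / pitch
    dx = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma, mode="wrap")
    dy = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma, mode="wrap")
    rms = np.sqrt(np.mean(dx**2 + dy**2))
    dx *= amplitude / rms
    dy *= amplitude / rms
    mag = np.hypot(dx, dy)
    cap = 3.0 * amplitude
    over = mag > cap
    if np.any(over):
        scale = cap / mag[over]
        dx[over] *= scale
        dy[over] *= scale
    return DistortionField(dx, dy, pitch, (-margin, -margin),
                           amplitude, correlation_length, seed)


def make_gain_map(
    spec: DetectorSpec,
    rel_sigma: float = 0.05,
    correlation_length: float = 2.0,
    seed: int = 0,
) -> GainMap:
    """Smooth multiplicative nonuniformity with the requested relative
    standard deviation, mean exactly 1 per layer."""
    if rel_sigma < 0:
        raise ValueError("rel_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (spec.n_layers, *spec.raw_shape)
    g = np.ones(shape)
    if rel_sigma > 0:
        sigma_bins = correlation_length / spec.raw_bin_pitch
        for li in range(spec.n_layers):
            noise = ndimage.gaussian_filter(rng.standard_normal(spec.raw_shape), sigma_bins)
            noise /= max(noise.std(), 1e-300)
            g[li] = np.clip(1.0 + rel_sigma * noise, 0.0, None)
            g[li] /= g[li].mean()
    return GainMap(values=g)


# ---------------------------------------------------------------------------
# event engine
# ---------------------------------------------------------------------------

def _histogram_events(
    spec: DetectorSpec,
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    field: DistortionField | None = None,
    boundary: BoundaryArtifactModel | None = None,
    gain: GainMap | None = None,
    meta: dict | None = None,
    energy_window: tuple[float, float] | None = None,
) -> RawProjection:
    """Run true event positions through the detector pathology chain and
    histogram them onto the raw grid.

    Chain: depth sampling -> distortion -> boundary snap -> bounds
    check -> gain thinning -> binning.  Bookkeeping in ``meta``
    satisfies ``n_events == counts.sum() + n_out_of_bounds +
    n_gain_rejected``.
    """
    n_events = x.size
    model = AttenuationModel.from_spec(spec)
    depth = sample_depths(model, n_events, rng)
    layer_idx = depth_to_layer_index(model, depth)  # 0-based, m-1

    if field is not None:
        ux, uy = field.displacement(x, y)
        x = x + ux
        y = y + uy

    if boundary is not None and n_events:
        frac = boundary.fraction_for_layers(spec.n_layers)[layer_idx]
        misplaced = rng.random(n_events) < frac
        p = boundary.grid_pitch
        hw = boundary.capture_halfwidth
        jitter_scale = spec.raw_bin_pitch / 2.0
        for coord in (x, y):
            line = np.round(coord / p) * p
            snap = misplaced & (np.abs(coord - line) < hw)
            coord[snap] = line[snap] + rng.uniform(-jitter_scale, jitter_scale, int(snap.sum()))

    span_y, span_x = spec.raw_span
    inside = (x >= 0) & (x < span_x) & (y >= 0) & (y < span_y)
    n_out = int(n_events - inside.sum())
    x, y, layer_idx = x[inside], y[inside], layer_idx[inside]

    col = np.floor(x / spec.raw_bin_pitch).astype(int)
    row = np.floor(y / spec.raw_bin_pitch).astype(int)

    n_rej = 0
    if gain is not None and x.size:
        gmax = gain.values.max()
        if gmax <= 0:
            raise ValueError("gain map is identically zero")
        keep_p = gain.values[layer_idx, row, col] / gmax
        keep = rng.random(x.size) < keep_p
        n_rej = int(x.size - keep.sum())
        row, col, layer_idx = row[keep], col[keep], layer_idx[keep]

    nrow, ncol = spec.raw_shape
    flat = (layer_idx * nrow + row) * ncol + col
    counts = np.bincount(flat, minlength=spec.n_layers * nrow * ncol)
    counts = counts.reshape(spec.n_layers, nrow, ncol).astype(np.uint32)

    info = dict(meta or {})
    info.update(
        n_events=int(n_events),
        n_out_of_bounds=n_out,
        n_gain_rejected=n_rej,
    )
    return RawProjection(counts=counts, spec=spec, energy_window=energy_window, meta=info)


def simulate_events(
    spec: DetectorSpec,
    fluence: np.ndarray,
    n_events: int,
    field: DistortionField | None = None,
    boundary: BoundaryArtifactModel | None = None,
    gain: GainMap | None = None,
    seed: int = 0,
    energy_window: tuple[float, float] | None = None,
) -> RawProjection:
    """Simulate ``n_events`` interactions with true positions drawn from
    a fluence map given on the raw grid (bin-wise intensity; positions
    are uniform within each bin)."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    fluence = np.asarray(fluence, dtype=float)
    if fluence.shape != spec.raw_shape:
        raise ValueError(f"fluence shape {fluence.shape} != raw grid {spec.raw_shape}")
    if np.any(fluence < 0) or not np.any(fluence > 0):
        raise ValueError("fluence must be non-negative with at least one positive entry")
    rng = np.random.default_rng(seed)
    p = fluence.ravel() / fluence.sum()
    idx = rng.choice(p.size, size=n_events, p=p)
    row, col = np.divmod(idx, spec.raw_shape[1])
    x = (col + rng.random(n_events)) * spec.raw_bin_pitch
    y = (row + rng.random(n_events)) * spec.raw_bin_pitch
    return _histogram_events(spec, x, y, rng, field, boundary, gain,
                             {"source": "fluence"}, energy_window)


def simulate_flood(
    spec: DetectorSpec,
    n_events: int,
    field: DistortionField | None = None,
    boundary: BoundaryArtifactModel | None = None,
    gain: GainMap | None = None,
    seed: int = 0,
    energy_window: tuple[float, float] | None = None,
) -> RawProjection:
    """Uniform flood irradiation of the whole detector."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    span_y, span_x = spec.raw_span
    x = rng.uniform(0.0, span_x, n_events)
    y = rng.uniform(0.0, span_y, n_events)
    return _histogram_events(spec, x, y, rng, field, boundary, gain,
                             {"source": "flood"}, energy_window)


def simulate_pencil_beam(
    spec: DetectorSpec,
    position: tuple[float, float],
    n_events: int,
    field: DistortionField | None = None,
    boundary: BoundaryArtifactModel | None = None,
    gain: GainMap | None = None,
    seed: int = 0,
    energy_window: tuple[float, float] | None = None,
) -> RawProjection:
    """Point irradiation at ``position`` = (x, y) in mm."""
    px, py = position
    span_y, span_x = spec.raw_span
    if not (0 <= px < span_x and 0 <= py < span_y):
        raise ValueError(f"pencil-beam position {position} outside the detector")
    rng = np.random.default_rng(seed)
    x = np.full(n_events, float(px))
    y = np.full(n_events, float(py))
    return _histogram_events(spec, x, y, rng, field, boundary, gain,
                             {"source": "pencil", "position": (float(px), float(py))},
                             energy_window)


def simulate_sheet_beam(
    spec: DetectorSpec,
    axis: str,
    position: float,
    beam_width: float,
    n_events: int,
    field: DistortionField | None = None,
    boundary: BoundaryArtifactModel | None = None,
    gain: GainMap | None = None,
    seed: int = 0,
    energy_window: tuple[float, float] | None = None,
) -> RawProjection:
    """One sheet-beam exposure: a uniform band of width ``beam_width``
    centred on the scan line.

    ``axis='x'`` scans along x (the band is a column of constant x,
    the detector response to a preconditioned *column*); ``axis='y'``
    scans along y (a row band).
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if beam_width <= 0:
        raise ValueError("beam_width must be positive")
    rng = np.random.default_rng(seed)
    span_y, span_x = spec.raw_span
    across = rng.uniform(position - beam_width / 2, position + beam_width / 2, n_events)
    if axis == "x":
        x = across
        y = rng.uniform(0.0, span_y, n_events)
    else:
        y = across
        x = rng.uniform(0.0, span_x, n_events)
    return _histogram_events(
        spec, x, y, rng, field, boundary, gain,
        {"source": "sheet", "axis": axis, "position": float(position),
         "beam_width": float(beam_width)},
        energy_window,
    )


def simulate_sheet_beam_scan(
    spec: DetectorSpec,
    axis: str,
    positions: Sequence[float],
    beam_width: float,
    counts_per_position: int,
    field: DistortionField | None = None,
    boundary: BoundaryArtifactModel | None = None,
    gain: GainMap | None = None,
    seed: int = 0,
    energy_window: tuple[float, float] | None = None,
) -> list[RawProjection]:
    """A full scan along one axis: one projection per scan position.

    Per-position seeds are derived from ``seed`` with a spawned
    :class:`numpy.random.SeedSequence`, so the scan is reproducible as
    a whole and each exposure is independent.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("positions must be non-empty")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if beam_width <= 0:
        raise ValueError("beam_width must be positive")
    seeds = np.random.SeedSequence(seed).generate_state(positions.size) % (2**31)
    return [
        simulate_sheet_beam(spec, axis, pos, beam_width, counts_per_position,
                            field, boundary, gain, int(s), energy_window)
        for pos, s in zip(positions, seeds)
    ]
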