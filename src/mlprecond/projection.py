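"""Projection containers: raw and preconditioned count arrays."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .detector import DetectorSpec

__all__ = ["RawProjection", "PrecondProjection", "rebin_raw_to_precond"]


@dataclass
class RawProjection:
    """Counts of gamma-ray interactions on the fine raw grid.

    ``counts[m-1]`` is the image recorded at DOI layer ``m`` (1-based;
    layer 1 at the anode/rear, layer ``n_layers`` at the irradiated
    front).  Counts are integer for measured data but may be real after
    preprocessing (artificial blurring produces real-valued images).
    """

    counts: np.ndarray  # [n_layers, rows, cols]
    spec: DetectorSpec
    energy_window: tuple[float, float] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (self.spec.n_layers, *self.spec.raw_shape)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != expected {expected}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def layer(self, m: int) -> np.ndarray:
        """Image at DOI layer ``m`` (1-based)."""
        if not 1 <= m <= self.spec.n_layers:
            raise ValueError(f"layer {m} outside 1..{self.spec.n_layers}")
        return self.counts[m - 1]

    def layer_summed(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class PrecondProjection:
    """Deconvolved (preconditioned) projection on the coarse grid.

    Carries the MLEM iteration count and the per-layer log-likelihood
    trace so convergence can be inspected after the fact.
    """

    values: np.ndarray  # [n_layers, rows, cols], real, >= 0
    spec: DetectorSpec
    n_iter: int = 0
    loglik: list[np.ndarray] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.spec.n_layers, *self.spec.precond_shape)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != expected {expected}")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")

    def layer(self, m: int) -> np.ndarray:
        if not 1 <= m <= self.spec.n_layers:
            raise ValueError(f"layer {m} outside 1..{self.spec.n_layers}")
        return self.values[m - 1]

    def layer_summed(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.values.sum())


def rebin_raw_to_precond(raw: RawProjection) -> PrecondProjection:
    """Plain coordinate rebinning of a raw projection onto the
    precondition grid (no deconvolution) — the baseline the
    preconditioned result is compared against.

    Each raw bin's counts are assigned to the precondition bin
    containing the raw bin centre; raw bins outside the precondition
    span are dropped.
    """
    spec = raw.spec
    ry = spec.raw_centers(0)
    rx = spec.raw_centers(1)
    iy = np.floor(ry / spec.precond_pitch).astype(int)
    ix = np.floor(rx / spec.precond_pitch).astype(int)
    ok_y = (iy >= 0) & (iy < spec.precond_grid[0])
    ok_x = (ix >= 0) & (ix < spec.precond_grid[1])
    out = np.zeros((spec.n_layers, *spec.precond_shape), dtype=float)
    sub = raw.counts[:, ok_y][:, :, ok_x].astype(float)
    iy, ix = iy[ok_y], ix[ok_x]
    for li in range(spec.n_layers):
        np.add.at(out[li], (iy[:, None], ix[None, :]), sub[li])
    return PrecondProjection(values=out, spec=spec, n_iter=0, meta={"method": "rebin"})
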