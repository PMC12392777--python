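"""Exponential-attenuation depth model shared by the simulator, the
uniformity correction and the system-response builder.

Photons enter the crystal at the cathode (front) surface and interact
photoelectrically with depth density proportional to
``mu_pe * exp(-mu_total * x)``, ``x`` measured from the front surface.
DOI layer ``m`` (1-based, layer 1 at the anode/rear) occupies depths
``[(n-m)*t, (n-m+1)*t)``, so the expected counts per layer are

    c(m) = c0 * (mu_pe/mu_total) * (exp(-mu_total*(n-m)*t)
                                    - exp(-mu_total*(n-m+1)*t))

and the per-layer ratio relative to the front layer ``n`` is

    ratio(m) = c(m)/c(n)
             = (exp(-mu_total*(n-m)*t) - exp(-mu_total*(n-m+1)*t))
               / (1 - exp(-mu_total*t))

with ``ratio(n) = 1`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import DetectorSpec

__all__ = [
    "AttenuationModel",
    "layer_count",
    "layer_ratio",
    "layer_fractions",
    "sample_depths",
]


@dataclass(frozen=True)
class AttenuationModel:
    """Depth-attenuation constants of one detector at one energy.

    ``c0`` is the event rate at the front surface in arbitrary units;
    it cancels from every ratio.
    """

    mu_total: float
    mu_pe: float
    t: float
    n: int
    c0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.mu_total >= self.mu_pe > 0):
            raise ValueError("require mu_total >= mu_pe > 0")
        if self.t <= 0:
            raise ValueError("layer thickness t must be positive")
        if self.n < 1:
            raise ValueError("layer count n must be >= 1")

    @classmethod
    def from_spec(cls, spec: DetectorSpec, c0: float = 1.0) -> "AttenuationModel":
        return cls(mu_total=spec.mu_total, mu_pe=spec.mu_pe,
                   t=spec.layer_thickness, n=spec.n_layers, c0=c0)


def _check_m(model: AttenuationModel, m: int) -> None:
    if not 1 <= m <= model.n:
        raise ValueError(f"layer index m={m} outside 1..{model.n}")


def layer_count(model: AttenuationModel, m: int) -> float:
    """Expected counts at DOI layer ``m`` (closed form of the depth
    integral over that layer)."""
    _check_m(model, m)
    mu, t, n = model.mu_total, model.t, model.n
    return (
        model.c0
        * (model.mu_pe / mu)
        * (np.exp(-mu * (n - m) * t) - np.exp(-mu * (n - m + 1) * t))
    )


def layer_ratio(model: AttenuationModel, m: int) -> float:
    """c(m)/c(n): layer counts relative to the front (cathode) layer."""
    _check_m(model, m)
    mu, t, n = model.mu_total, model.t, model.n
    return float(
        (np.exp(-mu * (n - m) * t) - np.exp(-mu * (n - m + 1) * t))
        / (1.0 - np.exp(-mu * t))
    )


def layer_fractions(model: AttenuationModel) -> np.ndarray:
    """Normalized per-layer interaction probabilities, indexed
    ``[m-1]`` for layer ``m`` — i.e. the depth distribution of detected
    events conditioned on detection."""
    c = np.array([layer_count(model, m) for m in range(1, model.n + 1)])
    return c / c.sum()


def sample_depths(model: AttenuationModel, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample interaction depths (mm from the front surface) from the
    truncated exponential over the crystal thickness by inverse CDF."""
    mu = model.mu_total
    total_depth = model.n * model.t
    u = rng.random(size)
    return -np.log1p(-u * (1.0 - np.exp(-mu * total_depth))) / mu


def depth_to_layer_index(model: AttenuationModel, depth: np.ndarray) -> np.ndarray:
    """Map depth from the front surface to the 0-based layer array
    index ``m-1`` (front layer m=n first in depth)."""
    k = np.floor(depth / model.t).astype(int)
    k = np.clip(k, 0, model.n - 1)
    return model.n - 1 - k
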