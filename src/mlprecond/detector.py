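"""Detector geometry description.

A 3-D position-sensitive gamma-ray imaging detector is described by two
planar grids sharing one coordinate frame plus a depth discretization:

* the *raw* grid — the fine grid on which the detector's subpixel
  positioning algorithm histograms events (default 440 x 440 bins of
  0.095 mm), carrying all positioning artifacts;
* the *preconditioned* grid — the coarser grid on which deconvolved
  projections are defined (default 88 x 88 bins of 0.5 mm);
* ``n_layers`` depth-of-interaction (DOI) layers of equal thickness,
  layer 1 at the anode (rear) side and layer ``n_layers`` at the
  cathode (irradiated front) side.

Coordinates are in millimetres with the origin at the lower-left corner
of the precondition grid, which coincides with the lower-left corner of
the raw grid.  Bins are half-open ``[k*w, (k+1)*w)``; arrays are indexed
``[layer, row, col]`` (row ~ y, col ~ x), row-major and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["DetectorSpec"]


@dataclass(frozen=True)
class DetectorSpec:
    """Geometry and attenuation constants of one detector unit.

    Parameters
    ----------
    raw_grid : (int, int)
        Raw-grid bins per axis (rows, cols).
    raw_bin_pitch : float
        Raw bin size in mm.
    precond_grid : (int, int)
        Preconditioned-grid bins per axis.
    precond_pitch : float
        Preconditioned bin size in mm; equals the sheet-beam scan step.
    anode_pitch : float
        Pitch of the coarse anode readout pixels in mm.
    n_layers : int
        Number of DOI layers.
    layer_thickness : float
        Thickness of one DOI layer in mm.
    mu_total, mu_pe : float
        Total and photoelectric linear attenuation coefficients of the
        detector material at the working energy, in 1/mm.
    """

    raw_grid: tuple[int, int] = (440, 440)
    raw_bin_pitch: float = 0.095
    precond_grid: tuple[int, int] = (88, 88)
    precond_pitch: float = 0.5
    anode_pitch: float = 1.9
    n_layers: int = 5
    layer_thickness: float = 2.0
    mu_total: float = 0.23
    mu_pe: float = 0.15

    def __post_init__(self) -> None:
        for name in ("raw_bin_pitch", "precond_pitch", "anode_pitch", "layer_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not (self.mu_total >= self.mu_pe > 0):
            raise ValueError("require mu_total >= mu_pe > 0")
        for name in ("raw_grid", "precond_grid"):
            g = getattr(self, name)
            if len(g) != 2 or any(int(v) != v or v < 1 for v in g):
                raise ValueError(f"{name} must be a pair of positive integers")

    # -- raw grid ----------------------------------------------------
    @property
    def raw_shape(self) -> tuple[int, int]:
        return (int(self.raw_grid[0]), int(self.raw_grid[1]))

    @property
    def raw_span(self) -> tuple[float, float]:
        """(y, x) extent of the raw grid in mm."""
        return (self.raw_grid[0] * self.raw_bin_pitch, self.raw_grid[1] * self.raw_bin_pitch)

    def raw_centers(self, axis: int) -> np.ndarray:
        return (np.arange(self.raw_grid[axis]) + 0.5) * self.raw_bin_pitch

    # -- precondition grid -------------------------------------------
    @property
    def precond_shape(self) -> tuple[int, int]:
        return (int(self.precond_grid[0]), int(self.precond_grid[1]))

    @property
    def precond_span(self) -> tuple[float, float]:
        return (self.precond_grid[0] * self.precond_pitch, self.precond_grid[1] * self.precond_pitch)

    def precond_centers(self, axis: int) -> np.ndarray:
        return (np.arange(self.precond_grid[axis]) + 0.5) * self.precond_pitch

    # -- depth --------------------------------------------------------
    @property
    def thickness(self) -> float:
        """Total crystal thickness in mm."""
        return self.n_layers * self.layer_thickness

    @property
    def subbins_per_anode(self) -> int:
        """Raw bins per anode pixel along one axis (must be integral)."""
        ratio = self.anode_pitch / self.raw_bin_pitch
        n = round(ratio)
        if abs(ratio - n) > 1e-9 * n:
            raise ValueError(
                f"anode_pitch/raw_bin_pitch = {ratio} is not an integer; "
                "the raw grid must tile the anode cell exactly"
            )
        return n

    # -- convenience constructors ------------------------------------
    @classmethod
    def toy(
        cls,
        precond_n: int = 24,
        raw_bin_pitch: float = 0.1,
        precond_pitch: float = 0.5,
        **kwargs,
    ) -> "DetectorSpec":
        """A scaled-down detector with matched raw/precond spans.

        The default gives a 12 mm x 12 mm unit: 24 x 24 precondition
        bins of 0.5 mm over 120 x 120 raw bins of 0.1 mm, spanning
        about 6.3 anode pixels of 1.9 mm — enough to exhibit every
        artifact while keeping simulations cheap.
        """
        span = precond_n * precond_pitch
        raw_n = int(round(span / raw_bin_pitch))
        if abs(raw_n * raw_bin_pitch - span) > 1e-9:
            raise ValueError("raw_bin_pitch must divide the precondition span")
        return cls(
            raw_grid=(raw_n, raw_n),
            raw_bin_pitch=raw_bin_pitch,
            precond_grid=(precond_n, precond_n),
            precond_pitch=precond_pitch,
            **kwargs,
        )

    def with_(self, **kwargs) -> "DetectorSpec":
        return replace(self, **kwargs)
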