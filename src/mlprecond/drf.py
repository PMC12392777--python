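"""Detector response function (DRF) from sheet-beam scans.

The DRF is the sparse matrix ``P`` of shape (M raw bins, N precond
pixels): column ``l`` is the raw-grid response to gamma rays entering
preconditioned pixel ``l``.  Measuring it with a pencil beam needs one
exposure per pixel; the sheet-beam shortcut measures one response per
precondition *row* (``R_a``) and per *column* (``C_b``) and
approximates the pencil response at pixel ``(a, b)`` by the
element-wise product ``R_a ∘ C_b``.  Columns are stored un-normalized;
the flood-based uniformity correction absorbs the global scale.
Per-bin values below ``sparsity_threshold`` times the column maximum
are zeroed.  The sensitivity ``s_l`` is the column sum of the stored
(sparsified) matrix; pixels with ``s_l = 0`` are flagged inactive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

from .detector import DetectorSpec
from .projection import RawProjection

__all__ = [
    "SheetBeamScanSet",
    "DRFMatrix",
    "outer_product_response",
    "build_drf",
    "compute_sensitivity",
    "SheetBeamDRF",
]


@dataclass
class SheetBeamScanSet:
    """Layer-summed raw images of a two-axis sheet-beam scan.

    ``row_images[a]`` is the response to the beam centred on
    precondition row ``a`` (a y-scan band); ``col_images[b]`` to the
    beam on precondition column ``b`` (an x-scan band).  Scans pool DOI
    layers for statistics.
    """

    row_images: np.ndarray  # [n_rows, H, W]
    col_images: np.ndarray  # [n_cols, H, W]
    row_positions: np.ndarray
    col_positions: np.ndarray
    beam_width: float
    spec: DetectorSpec | None = None

    def __post_init__(self) -> None:
        self.row_images = np.asarray(self.row_images, dtype=float)
        self.col_images = np.asarray(self.col_images, dtype=float)
        if np.any(self.row_images < 0) or np.any(self.col_images < 0):
            raise ValueError("scan images must be non-negative")
        if self.row_images.shape[1:] != self.col_images.shape[1:]:
            raise ValueError("row and column scan images must share the raw grid shape")

    @classmethod
    def from_projections(
        cls,
        row_scans: Sequence[RawProjection],
        col_scans: Sequence[RawProjection],
        beam_width: float,
    ) -> "SheetBeamScanSet":
        """Assemble a scan set from simulator (or converted) exposures,
        checking that every precondition row/column has its scan at the
        expected centre position."""
        spec = row_scans[0].spec
        for name, scans, axis in (("row", row_scans, 0), ("column", col_scans, 1)):
            need = spec.precond_grid[axis]
            if len(scans) != need:
                raise ValueError(f"need {need} {name} scans, got {len(scans)}")
            centers = spec.precond_centers(axis)
            for k, (scan, c) in enumerate(zip(scans, centers)):
                pos = scan.meta.get("position")
                if pos is not None and abs(pos - c) > spec.precond_pitch / 4:
                    raise ValueError(
                        f"missing/misplaced {name} scan {k}: expected centre "
                        f"{c:.3f} mm, got {pos:.3f} mm"
                    )
        return cls(
            row_images=np.stack([s.layer_summed() for s in row_scans]),
            col_images=np.stack([s.layer_summed() for s in col_scans]),
            row_positions=spec.precond_centers(0),
            col_positions=spec.precond_centers(1),
            beam_width=float(beam_width),
            spec=spec,
        )


@dataclass
class DRFMatrix:
    """Sparse detector response ``P`` (M x N) with sensitivity ``s``."""

    P: sparse.csc_matrix
    s: np.ndarray
    raw_shape: tuple[int, int]
    precond_shape: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.P = sparse.csc_matrix(self.P)
        if self.P.nnz and self.P.data.min() < 0:
            raise ValueError("DRF entries must be non-negative")
        M = self.raw_shape[0] * self.raw_shape[1]
        N = self.precond_shape[0] * self.precond_shape[1]
        if self.P.shape != (M, N):
            raise ValueError(f"P shape {self.P.shape} != ({M}, {N})")
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (N,):
            raise ValueError("sensitivity length mismatch")

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of preconditioned pixels with nonzero sensitivity."""
        return self.s > 0

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def outer_product_response(R_a: np.ndarray, C_b: np.ndarray) -> np.ndarray:
    """Approximate pencil-beam response at the row/column intersection:
    element-wise product of the two sheet-beam responses."""
    R_a = np.asarray(R_a, dtype=float)
    C_b = np.asarray(C_b, dtype=float)
    if R_a.shape != C_b.shape:
        raise ValueError(f"shape mismatch: {R_a.shape} vs {C_b.shape}")
    return R_a * C_b


def compute_sensitivity(P: sparse.spmatrix) -> np.ndarray:
    """Column sums of the response matrix."""
    return np.asarray(sparse.csc_matrix(P).sum(axis=0)).ravel()


def build_drf(
    scans: SheetBeamScanSet,
    spec: DetectorSpec | None = None,
    sparsity_threshold: float = 1e-3,
) -> DRFMatrix:
    """Assemble the sparse DRF from a complete two-axis scan set.

    Precondition pixel ``l = a * n_cols + b`` (row-major) gets column
    ``flatten(R_a ∘ C_b)`` with entries below ``sparsity_threshold``
    times the column maximum zeroed.
    """
    spec = spec or scans.spec
    if spec is None:
        raise ValueError("a DetectorSpec is required (none attached to the scan set)")
    n_rows, n_cols = spec.precond_shape
    if scans.row_images.shape[0] != n_rows or scans.col_images.shape[0] != n_cols:
        raise ValueError(
            f"scan set has {scans.row_images.shape[0]} rows / "
            f"{scans.col_images.shape[0]} cols, spec wants {n_rows} x {n_cols}"
        )
    H, W = scans.row_images.shape[1:]
    if (H, W) != spec.raw_shape:
        raise ValueError(f"scan raw grid {(H, W)} != spec raw grid {spec.raw_shape}")

    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    retained = np.ones(n_rows * n_cols)
    for a in range(n_rows):
        Ra = scans.row_images[a]
        for b in range(n_cols):
            col = (Ra * scans.col_images[b]).ravel()
            total = col.sum()
            if total <= 0:
                continue
            keep = (col >= sparsity_threshold * col.max()) & (col > 0)
            l = a * n_cols + b
            nz = np.nonzero(keep)[0]
            rows_idx.append(nz)
            cols_idx.append(np.full(nz.size, l))
            vals.append(col[nz])
            retained[l] = col[nz].sum() / total
    M = H * W
    N = n_rows * n_cols
    if rows_idx:
        P = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
            shape=(M, N),
        ).tocsc()
    else:
        P = sparse.csc_matrix((M, N))
    s = compute_sensitivity(P)
    return DRFMatrix(
        P=P, s=s, raw_shape=(H, W), precond_shape=(n_rows, n_cols),
        meta={
            "sparsity_threshold": float(sparsity_threshold),
            "retained_mass_min": float(retained.min()),
            "retained_mass": retained,
        },
    )


class SheetBeamDRF(BaseEstimator):
    """Estimator wrapper: fit the detector response from a scan set.

    Parameters
    ----------
    spec : DetectorSpec, optional
        Overrides the spec attached to the scan set.
    sparsity_threshold : float
        Per-column relative threshold below which DRF entries are
        dropped.

    Attributes
    ----------
    drf_ : DRFMatrix
    P_ : scipy.sparse.csc_matrix
    s_ : ndarray
    retained_mass_ : ndarray
        Per-column fraction of response mass kept after sparsification.
    """

    def __init__(self, spec: DetectorSpec | None = None, sparsity_threshold: float = 1e-3):
        self.spec = spec
        self.sparsity_threshold = sparsity_threshold

    def fit(self, X: SheetBeamScanSet, y=None) -> "SheetBeamDRF":
        self.drf_ = build_drf(X, self.spec, self.sparsity_threshold)
        self.P_ = self.drf_.P
        self.s_ = self.drf_.s
        self.retained_mass_ = self.drf_.meta["retained_mass"]
        return self
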