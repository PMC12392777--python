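"""Geometric model and calibration of the single-pinhole tomograph.

The prototype consists of a point source mounted on a rotation stage
(offset ~6 mm from the axis), a pinhole treated as a single point, and
the detector plane.  The setup is described by a 19-component
parameter vector:

====================  ===  =========================================
detector origin         3  position of the precondition-grid corner
detector orientation    3  z-y-x Euler angles (degrees)
pinhole position        3
rotation-axis tilt      2  axis direction = normalize((tx, ty, 1))
axis point              1  stage-plane height along the axis
rotation radius         1  source distance from the axis
translation vector      3  global displacement per commanded mm
reserved                3  lateral axis offsets (2) + stage phase (1)
====================  ===  =========================================

The global frame is anchored to the rotation stage: the axis passes
laterally through the origin and the source sits on +x at angle zero,
so the three reserved components and the axis tilt/height are gauge
(or only weakly identifiable) and stay fixed during calibration by
default.  The 13 remaining parameters form the default free set.

Angles are degrees in every public interface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .detector import DetectorSpec

__all__ = [
    "GeometryParams",
    "CalibrationAcquisition",
    "weighting_center",
    "forward_centers",
    "GeometryCalibrator",
    "calibrate",
    "DEFAULT_FREE",
]

PARAM_NAMES = (
    "det_origin_x", "det_origin_y", "det_origin_z",
    "det_rot_z", "det_rot_y", "det_rot_x",
    "pinhole_x", "pinhole_y", "pinhole_z",
    "axis_tilt_x", "axis_tilt_y",
    "axis_z",
    "radius",
    "trans_x", "trans_y", "trans_z",
    "axis_off_x", "axis_off_y", "phase",
)

# The identifiable set: a single point source cannot separate the
# pinhole-to-axis distance (pinhole_y) and the detector tilt toward the
# axis (det_rot_x) from the axial positions and magnification, so those
# two come from the mechanical design and stay fixed by default.
DEFAULT_FREE = (
    "det_origin_x", "det_origin_y", "det_origin_z",
    "det_rot_z", "det_rot_y",
    "pinhole_x", "pinhole_z",
    "radius",
    "trans_x", "trans_y", "trans_z",
)

_ANGULAR = {"det_rot_z", "det_rot_y", "det_rot_x", "phase"}


def _rot_zyx(angles_deg: np.ndarray) -> np.ndarray:
    gz, gy, gx = np.deg2rad(angles_deg)
    cz, sz = np.cos(gz), np.sin(gz)
    cy, sy = np.cos(gy), np.sin(gy)
    cx, sx = np.cos(gx), np.sin(gx)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class GeometryParams:
    """Named view of the 19-component parameter vector."""

    det_origin: tuple[float, float, float]
    det_angles: tuple[float, float, float]  # degrees, z-y-x
    pinhole: tuple[float, float, float]
    axis_tilt: tuple[float, float] = (0.0, 0.0)
    axis_z: float = 0.0
    radius: float = 6.0
    trans_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    axis_offset: tuple[float, float] = (0.0, 0.0)
    phase: float = 0.0  # degrees

    # -- vector round trip -------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([
            *self.det_origin, *self.det_angles, *self.pinhole,
            *self.axis_tilt, self.axis_z, self.radius, *self.trans_axis,
            *self.axis_offset, self.phase,
        ])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "GeometryParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (19,):
            raise ValueError(f"parameter vector must have 19 components, got {v.shape}")
        return cls(
            det_origin=tuple(v[0:3]), det_angles=tuple(v[3:6]),
            pinhole=tuple(v[6:9]), axis_tilt=tuple(v[9:11]),
            axis_z=float(v[11]), radius=float(v[12]),
            trans_axis=tuple(v[13:16]), axis_offset=tuple(v[16:18]),
            phase=float(v[18]),
        )

    def replace_named(self, **kwargs) -> "GeometryParams":
        return replace(self, **kwargs)

    # -- frames -------------------------------------------------------
    def detector_frame(self):
        """(origin, e_u, e_v, e_w): in-plane axes and plane normal."""
        R = _rot_zyx(np.asarray(self.det_angles))
        e_u = R @ np.array([1.0, 0.0, 0.0])
        e_v = R @ np.array([0.0, 0.0, 1.0])
        e_w = R @ np.array([0.0, 1.0, 0.0])
        return np.asarray(self.det_origin, dtype=float), e_u, e_v, e_w

    def stage_frame(self):
        """(centre, e1, e2, axis direction n)."""
        tx, ty = self.axis_tilt
        n = np.array([tx, ty, 1.0])
        n /= np.linalg.norm(n)
        e1 = np.array([1.0, 0.0, 0.0])
        e1 = e1 - (e1 @ n) * n
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        c = np.array([self.axis_offset[0], self.axis_offset[1], self.axis_z])
        return c, e1, e2, n

    # -- convenience --------------------------------------------------
    @classmethod
    def default_prototype(cls, spec: DetectorSpec, pinhole_to_axis: float = 90.0,
                          detector_to_pinhole: float = 90.0,
                          radius: float = 6.0) -> "GeometryParams":
        """Symmetric prototype: pinhole on +y at ``pinhole_to_axis`` mm
        from the rotation axis, detector plane a further
        ``detector_to_pinhole`` mm back, centred on the optical axis
        (unit magnification when the distances are equal)."""
        span_y, span_x = spec.precond_span
        d = pinhole_to_axis + detector_to_pinhole
        return cls(
            det_origin=(-span_x / 2.0, d, -span_y / 2.0),
            det_angles=(0.0, 0.0, 0.0),
            pinhole=(0.0, pinhole_to_axis, 0.0),
            radius=radius,
        )


@dataclass
class CalibrationAcquisition:
    """Measured weighting centres with their known stage settings."""

    centers: np.ndarray        # (V, 2) mm on the precondition plane
    angles_deg: np.ndarray     # (V,)
    translations: np.ndarray   # (V,) commanded mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.angles_deg = np.mod(np.asarray(self.angles_deg, dtype=float), 360.0)
        self.translations = np.asarray(self.translations, dtype=float)
        V = self.centers.shape[0]
        if self.centers.shape != (V, 2):
            raise ValueError("centers must be (V, 2)")
        if self.angles_deg.shape != (V,) or self.translations.shape != (V,):
            raise ValueError("one angle and one translation per view required")

    @property
    def n_views(self) -> int:
        return self.centers.shape[0]


def weighting_center(image: np.ndarray, pitch: float = 1.0,
                     origin: tuple[float, float] = (0.0, 0.0)) -> tuple[float, float]:
    """Intensity-weighted centroid of a (layer-summed) projection in mm,
    returned as (u, v) = (x, y)."""
    img = np.asarray(image, dtype=float)
    tot = img.sum()
    if tot <= 0:
        raise ValueError("cannot take the weighting centre of a zero image")
    ys = origin[0] + (np.arange(img.shape[0]) + 0.5) * pitch
    xs = origin[1] + (np.arange(img.shape[1]) + 0.5) * pitch
    v = float((img.sum(axis=1) @ ys) / tot)
    u = float((img.sum(axis=0) @ xs) / tot)
    return u, v


def source_positions(alpha: GeometryParams, angles_deg: np.ndarray,
                     translations: np.ndarray,
                     source_offset: float = 0.0) -> np.ndarray:
    """Global source positions for each (angle, translation) view."""
    c, e1, e2, n = alpha.stage_frame()
    th = np.deg2rad(np.asarray(angles_deg, dtype=float) + alpha.phase)
    rho = alpha.radius + source_offset
    t = np.asarray(alpha.trans_axis, dtype=float)
    d = np.asarray(translations, dtype=float)[:, None]
    return (c[None, :]
            + rho * (np.cos(th)[:, None] * e1[None, :] + np.sin(th)[:, None] * e2[None, :])
            + d * t[None, :])


def project_points(alpha: GeometryParams, points: np.ndarray) -> np.ndarray:
    """Project global points through the pinhole onto the detector
    plane; returns (u, v) detector-plane coordinates in mm."""
    o, e_u, e_v, e_w = alpha.detector_frame()
    p = np.asarray(alpha.pinhole, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ray = p[None, :] - points
    denom = ray @ e_w
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("ray parallel to the detector plane")
    tau = ((o - p) @ e_w) / denom
    if np.any(tau <= 0):
        raise ValueError("source projects to the wrong side of the pinhole")
    x = p[None, :] + tau[:, None] * ray
    rel = x - o[None, :]
    return np.column_stack([rel @ e_u, rel @ e_v])


def forward_centers(alpha: GeometryParams, angles_deg, translations,
                    source_offset: float = 0.0) -> np.ndarray:
    """Predicted weighting centres (V, 2) of the point source for the
    given stage settings under the idealized point-pinhole model."""
    s = source_positions(alpha, np.asarray(angles_deg, dtype=float),
                         np.asarray(translations, dtype=float), source_offset)
    return project_points(alpha, s)


class GeometryCalibrator(BaseEstimator):
    """Constrained least-squares estimation of the system geometry from
    point-source weighting centres.

    Gaussian measurement noise on the centres makes the negative
    log-probability of the observed centres a sum of squared residuals,
    minimized with bounded least squares and multi-start restarts
    (perturbed copies of the initial guess).

    Parameters
    ----------
    free : sequence of str
        Parameter names optimized; the rest stay at the initial value.
    bound_width : float
        Half-width of the box around the initial value, mm for lengths
        and degrees for angles.
    n_restarts : int
        Seeded perturbed restarts; best final cost wins, ties broken by
        the smaller parameter-vector norm.

    Attributes
    ----------
    alpha_ : GeometryParams
    cost_ : float, final sum of squared residuals
    per_view_residuals_ : ndarray (V,), Euclidean residual per view
    report_ : dict with convergence diagnostics
    """

    def __init__(self, free=DEFAULT_FREE, bound_width: float = 30.0,
                 n_restarts: int = 8, perturb: float = 1.0, seed: int = 0):
        self.free = free
        self.bound_width = bound_width
        self.n_restarts = n_restarts
        self.perturb = perturb
        self.seed = seed

    def fit(self, acq: CalibrationAcquisition, init: GeometryParams,
            source_offset: float = 0.0) -> "GeometryCalibrator":
        free = list(self.free)
        unknown = set(free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        if np.unique(np.round(acq.translations, 6)).size < 2:
            raise ValueError("acquisition must span >= 2 axial positions")
        if np.unique(np.round(acq.angles_deg, 6)).size < 3:
            raise ValueError("acquisition must span >= 3 rotation angles")
        if acq.n_views * 2 < len(free):
            raise ValueError(
                f"{acq.n_views} views provide {acq.n_views * 2} measurements "
                f"for {len(free)} free parameters"
            )

        idx = np.array([PARAM_NAMES.index(n) for n in free])
        x_full0 = init.to_vector()
        x0 = x_full0[idx]
        lo = x0 - self.bound_width
        hi = x0 + self.bound_width

        target = acq.centers

        def residuals(x: np.ndarray) -> np.ndarray:
            v = x_full0.copy()
            v[idx] = x
            pred = forward_centers(GeometryParams.from_vector(v),
                                   acq.angles_deg, acq.translations,
                                   source_offset)
            return (pred - target).ravel()

        rng = np.random.default_rng(self.seed)
        best = None
        for k in range(max(1, self.n_restarts)):
            xk = x0 if k == 0 else np.clip(
                x0 + rng.normal(0.0, self.perturb, x0.size), lo, hi)
            try:
                res = optimize.least_squares(residuals, xk, bounds=(lo, hi),
                                             method="trf", xtol=1e-12,
                                             ftol=1e-12, gtol=1e-12)
            except ValueError:
                continue
            key = (res.cost, np.linalg.norm(res.x))
            if best is None or key < (best.cost, np.linalg.norm(best.x)):
                best = res
        if best is None:
            raise RuntimeError("calibration failed: no restart produced a "
                               "valid forward projection")

        v = x_full0.copy()
        v[idx] = best.x
        self.alpha_ = GeometryParams.from_vector(v)
        r = best.fun.reshape(-1, 2)
        self.per_view_residuals_ = np.linalg.norm(r, axis=1)
        self.cost_ = float(2.0 * best.cost)  # sum of squares
        at_bounds = (np.abs(best.x - lo) < 1e-9) | (np.abs(best.x - hi) < 1e-9)
        self.report_ = {
            "success": bool(best.success),
            "optimality": float(best.optimality),
            "n_free": len(free),
            "active_bounds": [n for n, a in zip(free, at_bounds) if a],
            "rms_residual": float(np.sqrt(np.mean(self.per_view_residuals_**2))),
        }
        if not best.success:
            raise RuntimeError(
                "calibration did not converge: final gradient norm "
                f"{best.optimality:.3e}, active bounds {self.report_['active_bounds']}"
            )
        return self


def calibrate(acq: CalibrationAcquisition, init: GeometryParams,
              **kwargs) -> tuple[GeometryParams, dict]:
    """Functional wrapper over :class:`GeometryCalibrator`."""
    est = GeometryCalibrator(**kwargs)
    est.fit(acq, init)
    return est.alpha_, est.report_
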