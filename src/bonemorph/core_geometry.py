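"""Primitive geometric fitting and angle arithmetic.

Every clinical measurement in this package reduces to a handful of
primitives: an algebraic least-squares sphere fit (femoral head, acetabula),
a nonlinear least-squares cylinder fit (femoral neck, shaft and condyles,
tibial condyles), plane projection (transverse / frontal plane angles) and
angle arithmetic with an explicit sign convention.

Units: lengths in cm, angles in degrees throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class GeometryError(ValueError):
    """Base class for geometric failures."""


class DegenerateGeometryError(GeometryError):
    """Input configuration does not determine the requested primitive."""


class DegenerateProjectionError(GeometryError):
    """Vector is (numerically) parallel to the projection plane normal."""


class FitConvergenceError(GeometryError):
    """Iterative fit failed to converge; carries the last residual."""

    def __init__(self, message: str, last_residual: float):
        super().__init__(f"{message} (last rms residual {last_residual:.3g})")
        self.last_residual = last_residual


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit norm; raise on (near-)zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("cannot normalise a zero-length vector")
    return v / n


@dataclass(frozen=True)
class SphereFit:
    """Algebraic least-squares sphere.

    ``center`` is the fitted centre (cm), ``radius`` the fitted radius (cm)
    and ``rms_residual`` the RMS of the *geometric* distances
    ``| |p - c| - r |`` over the input points.
    """

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class CylinderFit:
    """Least-squares circular cylinder.

    ``axis_point`` is the orthogonal projection of the input centroid onto
    the fitted axis (the "centre" of the fitted cylinder), ``axis_direction``
    a unit vector with a deterministic sign (largest-magnitude component
    positive).
    """

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    rms_residual: float
    n_points: int


def _as_points(points, min_points: int, what: str) -> np.ndarray:
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"{what}: expected an (n, 3) array of points, got {P.shape}")
    if len(P) < min_points:
        raise ValueError(f"{what}: need at least {min_points} points, got {len(P)}")
    if not np.all(np.isfinite(P)):
        raise ValueError(f"{what}: points contain non-finite values")
    return P


def fit_sphere(points) -> SphereFit:
    """Fit a sphere by the analytic (Kasa-style) linearised least squares.

    Solves the linear system minimising ``sum((|p - c|^2 - r^2)^2)``, which is
    exact for points lying on a sphere and requires no initialisation. The
    reported residual is nevertheless the geometric one,
    ``rms(|p - c| - r)``.

    Raises
    ------
    ValueError
        Fewer than 4 points.
    DegenerateGeometryError
        Coplanar or otherwise rank-deficient point set.
    """
    P = _as_points(points, 4, "fit_sphere")
    A = np.column_stack([2.0 * P, np.ones(len(P))])
    b = np.einsum("ij,ij->i", P, P)
    # Coplanar points make [x, y, z, 1] affinely dependent -> rank < 4.
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError(
            "sphere fit is rank-deficient (points coplanar or degenerate)"
        )
    center = sol[:3]
    r_sq = sol[3] + center @ center
    if r_sq <= 0:
        raise DegenerateGeometryError("sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r_sq))
    d = np.linalg.norm(P - center, axis=1) - radius
    return SphereFit(
        center=center,
        radius=radius,
        rms_residual=float(np.sqrt(np.mean(d**2))),
        n_points=len(P),
    )


def _plane_basis(d: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane orthogonal to ``d``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(d, ref))
    e2 = np.cross(d, e1)
    return np.vstack([e1, e2])


def _circle_kasa_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic circle fit in 2D; returns (centre, radius)."""
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = np.einsum("ij,ij->i", xy, xy)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateGeometryError("circle fit rank-deficient")
    c = sol[:2]
    r_sq = sol[2] + c @ c
    if r_sq <= 0:
        raise DegenerateGeometryError("circle fit produced non-positive radius")
    return c, float(np.sqrt(r_sq))


def _cylinder_residuals_for_direction(P: np.ndarray, d: np.ndarray):
    """Geometric residuals dist(p, axis) - r with the optimal circle for axis
    direction ``d`` (variable-projection trick: centre and radius are solved
    analytically per direction)."""
    B = _plane_basis(d)
    xy = P @ B.T
    c2, r = _circle_kasa_2d(xy)
    res = np.linalg.norm(xy - c2, axis=1) - r
    return res, c2, r, B


def fit_cylinder(points, init_direction=None, max_iter: int = 200) -> CylinderFit:
    """Nonlinear least-squares circular cylinder fit.

    The axis direction is parameterised by two angular coordinates (a
    tangent-plane chart around the initial direction, avoiding gauge
    redundancy); for each trial direction the axis position and radius
    are recovered analytically by a circle fit of the projected points, so
    the outer optimisation minimises ``sum((dist(p, axis) - r)^2)`` over the
    two angles only. Initialised from ``init_direction`` when given, else
    from the dominant principal axis of the centred point cloud.
    """
    P = _as_points(points, 6, "fit_cylinder")
    centroid = P.mean(axis=0)
    Q = P - centroid

    # Collinearity check: a line has a single non-trivial singular value.
    sv = np.linalg.svd(Q, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("cylinder fit: points are collinear")

    if init_direction is not None:
        d0 = unit(init_direction)
    else:
        _, _, Vt = np.linalg.svd(Q, full_matrices=False)
        d0 = Vt[0]

    # Two angular parameters as a tangent-plane chart around the initial
    # direction: d(a, b) = unit(d0 + a e1 + b e2). Unlike global spherical
    # angles this chart has no pole singularity near the solution, so the
    # optimiser's accuracy does not depend on the cloud's orientation.
    E = _plane_basis(d0)

    def fun(x):
        d = unit(d0 + x[0] * E[0] + x[1] * E[1])
        try:
            res, _, _, _ = _cylinder_residuals_for_direction(Q, d)
        except DegenerateGeometryError:
            return np.full(len(Q), 1e6)
        return res

    sol = least_squares(
        fun, np.zeros(2), method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=max_iter * 10,
    )
    last_rms = float(np.sqrt(np.mean(sol.fun**2)))
    if not sol.success:
        raise FitConvergenceError("cylinder fit did not converge", last_rms)

    d = unit(d0 + sol.x[0] * E[0] + sol.x[1] * E[1])
    res, c2, r, B = _cylinder_residuals_for_direction(Q, d)
    # Deterministic sign: largest-|component| positive.
    k = int(np.argmax(np.abs(d)))
    if d[k] < 0:
        d = -d
    # Axis point: lift the 2D circle centre back to 3D, then take the
    # projection of the centroid onto the axis line (centroid is the origin
    # of Q, so its projection is the in-plane part of the axis).
    axis_point = centroid + c2 @ B
    rms = float(np.sqrt(np.mean(res**2)))
    return CylinderFit(
        axis_point=axis_point, axis_direction=d, radius=r,
        rms_residual=rms, n_points=len(P),
    )


def project_onto_plane(v, normal) -> np.ndarray:
    """Project ``v`` onto the plane with unit normal ``normal``, renormalised.

    Raises :class:`DegenerateProjectionError` when ``v`` is parallel to the
    normal (projection norm < 1e-9 relative to |v|).
    """
    v = np.asarray(v, dtype=float)
    n = unit(normal)
    w = v - (v @ n) * n
    norm_w = np.linalg.norm(w)
    if norm_w < 1e-9 * max(np.linalg.norm(v), 1e-30):
        raise DegenerateProjectionError(
            "vector is parallel to the plane normal; in-plane direction undefined"
        )
    return w / norm_w


def angle_between(u, v, mode: str = "full", signed_about=None) -> float:
    """Angle between two vectors, in degrees.

    mode='full' returns the angle in [0, 180]; mode='acute' folds it to
    [0, 90] (for undirected joint-line axes). With ``signed_about=n`` the
    result is the signed angle in (-180, 180] carrying ``u`` onto ``v`` by a
    right-handed rotation about ``n``:  atan2(n . (u x v), u . v).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("angle_between: zero-length input vector")
    if signed_about is not None:
        n = unit(signed_about)
        ang = np.degrees(np.arctan2(n @ np.cross(u, v), u @ v))
        if ang <= -180.0:
            ang += 360.0
        return float(ang)
    c = np.clip((u @ v) / (nu * nv), -1.0, 1.0)
    ang = float(np.degrees(np.arccos(c)))
    if mode == "acute" and ang > 90.0:
        ang = 180.0 - ang
    elif mode not in ("full", "acute"):
        raise ValueError(f"unknown mode {mode!r}")
    return ang
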