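"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the implementation paths they check: the sphere
oracle is an iterative *geometric* least squares (the package uses the
algebraic solve), the cylinder oracle is a brute-force direction-grid
search, and the ANOVA oracle is the textbook balanced-design mean
decomposition.
"""

import numpy as np
from scipy.optimize import least_squares


def geometric_sphere_fit(points):
    """Iterative least squares minimising sum((|p-c| - r)^2).

    Returns (centre, radius). Initialised from the centroid and mean
    distance, i.e. independent of the algebraic solve under test.
    """
    P = np.asarray(points, float)
    c0 = P.mean(axis=0)
    r0 = np.linalg.norm(P - c0, axis=1).mean()

    def resid(x):
        return np.linalg.norm(P - x[:3], axis=1) - x[3]

    sol = least_squares(resid, np.r_[c0, r0], xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return sol.x[:3], sol.x[3]


def _circle_residuals(P2):
    A = np.column_stack([2.0 * P2, np.ones(len(P2))])
    b = (P2 ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:2]
    r = np.sqrt(max(sol[2] + c @ c, 0.0))
    return np.linalg.norm(P2 - c, axis=1) - r


def _rms_for_direction(P, d):
    d = d / np.linalg.norm(d)
    ref = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0.0, 1, 0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    res = _circle_residuals(P @ np.vstack([e1, e2]).T)
    return float(np.sqrt(np.mean(res ** 2)))


def grid_cylinder_axis(points, coarse_step_deg: float = 2.0):
    """Brute-force cylinder axis: scan directions on a hemisphere grid
    (coarse_step_deg spacing), then refine locally with Nelder-Mead.

    Returns a unit axis direction (sign arbitrary).
    """
    P = np.asarray(points, float)
    P = P - P.mean(axis=0)
    best, best_rms = None, np.inf
    step = np.radians(coarse_step_deg)
    for theta in np.arange(0.0, np.pi / 2 + step / 2, step):
        n_phi = max(1, int(round(2 * np.pi * np.sin(theta) / step))) if theta > 0 else 1
        for phi in np.arange(0.0, np.pi, np.pi / n_phi):
            d = np.array([np.sin(theta) * np.cos(phi),
                          np.sin(theta) * np.sin(phi),
                          np.cos(theta)])
            rms = _rms_for_direction(P, d)
            if rms < best_rms:
                best, best_rms = (theta, phi), rms

    from scipy.optimize import minimize

    def f(x):
        th, ph = x
        d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        return _rms_for_direction(P, d)

    res = minimize(f, np.array(best), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    th, ph = res.x
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def axis_angle_deg(u, v) -> float:
    """Angle between two undirected axes, in degrees (folded to [0, 90])."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    return float(np.degrees(np.arccos(min(abs(u @ v), 1.0))))


def balanced_two_way_ss(y, a_levels, b_levels):
    """Classical two-way ANOVA sums of squares for a balanced design.

    ``y[i, j, k]``: replicate k of cell (a_i, b_j). Returns dict with
    ss_a, ss_b, ss_ab, ss_resid.
    """
    y = np.asarray(y, float)
    a, b, n = y.shape
    grand = y.mean()
    mi = y.mean(axis=(1, 2))
    mj = y.mean(axis=(0, 2))
    mij = y.mean(axis=2)
    ss_a = b * n * ((mi - grand) ** 2).sum()
    ss_b = a * n * ((mj - grand) ** 2).sum()
    ss_ab = n * ((mij - mi[:, None] - mj[None, :] + grand) ** 2).sum()
    ss_resid = ((y - mij[:, :, None]) ** 2).sum()
    return {"ss_a": ss_a, "ss_b": ss_b, "ss_ab": ss_ab, "ss_resid": ss_resid}


def sample_cylinder_patch(rng, axis, radius, half_length, n, arc_deg=180.0,
                          noise_sd=0.0, center=None):
    """Random points on a (half-)cylinder patch, for fit testing."""
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    ref = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1, 0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    phi = rng.uniform(0.0, np.radians(arc_deg), n)
    z = rng.uniform(-half_length, half_length, n)
    pts = (radius * np.cos(phi)[:, None] * e1
           + radius * np.sin(phi)[:, None] * e2
           + z[:, None] * axis)
    if center is not None:
        pts = pts + np.asarray(center, float)
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return pts
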