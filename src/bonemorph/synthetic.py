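"""Parametric synthetic bones and cohorts with exact ground truth.

The generators build stylised primitive assemblies (spheres, cylinders,
point landmarks) — not anatomically realistic shapes. That is deliberate:
every clinical measurement in this package is *defined* through landmarks
and primitive fits, so a bone assembled from those same primitives with
prescribed angles and lengths has exactly known ground truth, and the whole
pipeline can be validated closed-loop without any imaging data.

Geometry conventions (right-side canonical pose): x anterior, y superior,
z lateral; condylar midpoint at the origin; the bone's anatomical frame as
recovered by :func:`bonemorph.anatomy.build_frame` is the identity for the
femur and pelvis, and the torsion-twisted (y-preserving) frame for the
tibia. All tilts and torsions are imposed *in that recovered frame*, so the
construction parameter is the measured quantity by definition.

Noise model: isotropic Gaussian displacement of surface vertices
(``noise_sd`` cm per coordinate). Named single-vertex landmarks receive
attenuated noise (``noise_sd * landmark_noise_factor``), a stylised proxy
for the spatial averaging inherent in template-correspondence landmarking,
where a landmark node's position is constrained by its whole neighbourhood
rather than by one independent surface sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import LandmarkRegistry, TriangleMesh
from .core_geometry import unit
from .measurements import MeasurementRecord


class SpecError(ValueError):
    """Geometrically or statistically infeasible generator specification."""


#: Clearance (cm) by which condylar prominence vertices dominate the
#: surrounding condylar cylinder surface in their extremal direction.
_PROMINENCE_MARGIN = 0.3


# ---------------------------------------------------------------------------
# Primitive surface patches (parametric grids with triangulation)
# ---------------------------------------------------------------------------

def _grid_faces(n_u: int, n_v: int, wrap_v: bool, offset: int) -> np.ndarray:
    """Triangulate an n_u x n_v vertex grid (vertex id = iu * n_v + iv)."""
    faces = []
    nv_eff = n_v if wrap_v else n_v - 1
    for iu in range(n_u - 1):
        for iv in range(nv_eff):
            a = iu * n_v + iv
            b = iu * n_v + (iv + 1) % n_v
            c = (iu + 1) * n_v + iv
            d = (iu + 1) * n_v + (iv + 1) % n_v
            faces.append([a + offset, b + offset, c + offset])
            faces.append([b + offset, d + offset, c + offset])
    return np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def _cylinder_patch_local(radius: float, half_length: float,
                          n_axial: int, n_angle: int) -> tuple[np.ndarray, np.ndarray]:
    """Full-circumference cylinder patch in local coords (axis = +z),
    including both end rims (the grid's first/last axial rows sit exactly at
    z = -h and z = +h so extremal points land on the rims)."""
    z = np.linspace(-half_length, half_length, n_axial)
    phi = np.arange(n_angle) * (2.0 * np.pi / n_angle)
    Z, PHI = np.meshgrid(z, phi, indexing="ij")
    verts = np.column_stack([
        radius * np.cos(PHI).ravel(),
        radius * np.sin(PHI).ravel(),
        Z.ravel(),
    ])
    faces = _grid_faces(n_axial, n_angle, wrap_v=True, offset=0)
    return verts, faces


def _orient(local: np.ndarray, axis: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Map local coords (z along +z) onto the given axis at the centre."""
    a = unit(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(a, ref))
    e2 = np.cross(a, e1)
    R = np.column_stack([e1, e2, a])
    return local @ R.T + center


def _sphere_patch(center: np.ndarray, radius: float, n_theta: int, n_phi: int,
                  theta_max: float = np.pi * 0.92,
                  theta_min: float = np.pi * 0.08,
                  axis=None) -> tuple[np.ndarray, np.ndarray]:
    """UV sphere patch (poles excluded to avoid degenerate triangles).
    ``axis`` tilts the polar axis (default +z); ``theta_max`` < pi truncates
    the patch (e.g. an acetabular cup)."""
    th = np.linspace(theta_min, theta_max, n_theta)
    ph = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    local = radius * np.column_stack([
        (np.sin(TH) * np.cos(PH)).ravel(),
        (np.sin(TH) * np.sin(PH)).ravel(),
        np.cos(TH).ravel(),
    ])
    faces = _grid_faces(n_theta, n_phi, wrap_v=True, offset=0)
    if axis is not None:
        return _orient(local, axis, center), faces
    return local + center, faces


def _grid_dims(resolution: int) -> tuple[int, int]:
    """Axial x angular grid dimensions totalling ~resolution points."""
    n_ax = max(4, int(round(np.sqrt(resolution / 2.0))))
    n_ang = max(8, int(round(resolution / n_ax)))
    return n_ax, n_ang


def _rot_x(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


class _MeshBuilder:
    """Accumulates region patches and landmark vertices into one mesh plus
    its landmark registry."""

    def __init__(self, bone: str):
        self.bone = bone
        self._verts: list[np.ndarray] = []
        self._faces: list[np.ndarray] = []
        self._n = 0
        self.points: dict[str, int] = {}
        self.regions: dict[str, list[int]] = {}
        self._region_mask: list[bool] = []

    def add_region(self, name: str, verts: np.ndarray, faces: np.ndarray):
        idx = list(range(self._n, self._n + len(verts)))
        self.regions[name] = idx
        self._faces.append(faces + self._n)
        self._verts.append(verts)
        self._region_mask.extend([True] * len(verts))
        self._n += len(verts)

    def add_point(self, name: str, p) -> None:
        self.points[name] = self._n
        self._verts.append(np.asarray(p, float).reshape(1, 3))
        self._region_mask.append(False)
        self._n += 1

    def add_region_vertex(self, region: str, p, landmark_like: bool = True) -> None:
        """Append one vertex to an existing region; ``landmark_like`` vertices
        (anatomical prominences) receive attenuated noise like named
        landmarks."""
        self.regions[region].append(self._n)
        self._verts.append(np.asarray(p, float).reshape(1, 3))
        self._region_mask.append(not landmark_like)
        self._n += 1

    def build(self, rng: np.random.Generator, noise_sd: float,
              landmark_noise_factor: float, side: str
              ) -> tuple[TriangleMesh, LandmarkRegistry]:
        verts = np.vstack(self._verts)
        faces = (np.vstack(self._faces) if self._faces
                 else np.empty((0, 3), dtype=np.int64))
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, size=verts.shape)
            mask = np.asarray(self._region_mask)
            noise[~mask] *= landmark_noise_factor
            verts = verts + noise
        if side == "L":
            verts = verts @ np.diag([1.0, 1.0, -1.0])
            faces = faces[:, ::-1].copy() if len(faces) else faces
        mesh = TriangleMesh(vertices=verts, faces=faces)
        registry = LandmarkRegistry(bone=self.bone, template_vertex_count=len(verts),
                                    points=self.points, regions=self.regions)
        return mesh, registry


# ---------------------------------------------------------------------------
# Bone specifications
# ---------------------------------------------------------------------------

@dataclass
class FemurSpec:
    """Construction parameters of a synthetic femur (angles deg, lengths cm).

    ``joint_line_tilt`` is the lateral-distal tilt of the knee joint line in
    the frontal plane; the implied ground-truth mLDFA is ``90 - tilt``.
    """

    anteversion: float = 15.0
    neck_shaft: float = 135.0
    bicondylar: float = 8.0
    joint_line_tilt: float = 3.0
    femoral_length: float = 30.0
    epicondylar_width: float = 6.0
    head_radius: float = 1.5
    neck_radius: float = 1.0
    shaft_radius: float = 1.2
    neck_length: float | None = None  # default 2.2 * head_radius
    mesh_resolution: int = 400
    noise_sd: float = 0.0
    landmark_noise_factor: float = 0.2
    seed: int = 0
    side: str = "R"

    def __post_init__(self):
        for name in ("femoral_length", "epicondylar_width", "head_radius",
                     "neck_radius", "shaft_radius"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if not 90.0 < self.neck_shaft < 180.0:
            raise SpecError("neck_shaft angle must lie in (90, 180)")
        if self.mesh_resolution < 50:
            raise SpecError("mesh_resolution must be >= 50 points per region")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.side not in ("L", "R"):
            raise SpecError("side must be 'L' or 'R'")
        neck_len = self.neck_length if self.neck_length is not None else 2.2 * self.head_radius
        if neck_len <= self.head_radius:
            raise SpecError("neck is shorter than the head radius (infeasible)")
        if self.femoral_length < 4.0 * self.epicondylar_width / 3.0:
            raise SpecError("femoral_length too small for the distal geometry")


@dataclass
class TibiaSpec:
    """Construction parameters of a synthetic tibia/fibula composite.

    ``mpta_tilt`` is the medial-distal (varus) tilt of the tibial joint line
    in the bone's frontal plane; the implied ground-truth mMPTA is
    ``90 - tilt``. The requested ``condylar_width`` is realised exactly by a
    pair of condylar prominence vertices (the in-frame medial/lateral
    extremal points of the condylar regions).
    """

    torsion: float = 30.0
    mpta_tilt: float = 2.0
    tibial_length: float = 26.0
    condylar_width: float = 5.5
    malleolar_width: float = 4.5
    condyle_radius: float | None = None  # default 0.2 * condylar_width
    mesh_resolution: int = 400
    noise_sd: float = 0.0
    landmark_noise_factor: float = 0.2
    seed: int = 0
    side: str = "R"

    def __post_init__(self):
        for name in ("tibial_length", "condylar_width", "malleolar_width"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if abs(self.mpta_tilt) > 10.0:
            raise SpecError("|mpta_tilt| must be <= 10 deg")
        if self.mesh_resolution < 50:
            raise SpecError("mesh_resolution must be >= 50 points per region")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.side not in ("L", "R"):
            raise SpecError("side must be 'L' or 'R'")
        r = self.condyle_radius if self.condyle_radius is not None else 0.2 * self.condylar_width
        if r <= 0:
            raise SpecError("condyle_radius must be positive")
        h = 0.6 * r
        w_inner = self.condylar_width - 2 * _PROMINENCE_MARGIN
        if w_inner ** 2 <= 4 * r * r or np.sqrt(w_inner ** 2 - 4 * r * r) <= 2 * h:
            raise SpecError("condylar_width too small for the condyle cylinders")
        if self.tibial_length < 2.0 * self.condylar_width:
            raise SpecError("tibial_length too small relative to condylar_width")


@dataclass
class PelvisSpec:
    """Construction parameters of a synthetic pelvis."""

    asis_width: float = 16.0
    psis_width: float = 7.0
    depth: float = 9.0
    hip_centre_distance: float = 10.0
    acetab_radius: float = 2.0
    mesh_resolution: int = 400
    noise_sd: float = 0.0
    landmark_noise_factor: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("asis_width", "psis_width", "depth", "hip_centre_distance",
                     "acetab_radius"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if self.mesh_resolution < 50:
            raise SpecError("mesh_resolution must be >= 50 points per region")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.hip_centre_distance <= 2.0 * self.acetab_radius:
            raise SpecError("acetabula overlap: hip_centre_distance must exceed "
                            "twice the acetabular radius")


# ---------------------------------------------------------------------------
# Bone generators
# ---------------------------------------------------------------------------

def make_femur(spec: FemurSpec, case_id: str = "synthetic_femur"
               ) -> tuple[TriangleMesh, LandmarkRegistry, MeasurementRecord]:
    """Synthetic right-convention femur realising the spec's angles exactly.

    Deterministic given the seed. Returns the mesh, its landmark registry and
    the implied ground-truth measurement record.
    """
    rng = np.random.default_rng(spec.seed)
    tau, beta = spec.joint_line_tilt, spec.bicondylar
    alpha, nu = spec.anteversion, spec.neck_shaft
    w_e = spec.epicondylar_width
    L_mech = 0.92 * spec.femoral_length

    # Knee joint line (lateral, distally tilted by tau) and shaft direction
    # (proximal, leaning medially so the bicondylar angle is beta).
    j_hat = _rot_x(tau) @ np.array([0.0, 0.0, 1.0])            # (0, -sin, cos)
    s_hat = _rot_x(tau - beta) @ np.array([0.0, 1.0, 0.0])

    # Neck direction: transverse azimuth fixed by the anteversion, elevation
    # solved so the angle to the distal shaft equals the neck-shaft angle.
    from scipy.optimize import brentq

    def nsa_of(elev_deg):
        e = np.radians(elev_deg)
        a = np.radians(alpha)
        n = np.array([np.cos(e) * np.sin(a), np.sin(e), -np.cos(e) * np.cos(a)])
        return np.degrees(np.arccos(np.clip(n @ (-s_hat), -1, 1))) - nu

    try:
        elev = brentq(nsa_of, 0.05, 89.95, xtol=1e-12)
    except ValueError as exc:
        raise SpecError(f"neck-shaft angle {nu} deg unreachable with anteversion "
                        f"{alpha} deg and bicondylar {beta} deg") from exc
    e, a = np.radians(elev), np.radians(alpha)
    n_hat = np.array([np.cos(e) * np.sin(a), np.sin(e), -np.cos(e) * np.cos(a)])

    head_centre = np.array([0.0, L_mech, 0.0])
    neck_len = spec.neck_length if spec.neck_length is not None else 2.2 * spec.head_radius
    neck_centre = head_centre - neck_len * n_hat
    shaft_centre = 0.55 * L_mech * s_hat

    b = _MeshBuilder("femur")
    n_ax, n_ang = _grid_dims(spec.mesh_resolution)

    hv, hf = _sphere_patch(head_centre, spec.head_radius, n_ax + 2, n_ang)
    b.add_region("head_region", hv, hf)

    lv, lf = _cylinder_patch_local(spec.neck_radius, 0.8 * spec.head_radius, n_ax, n_ang)
    b.add_region("neck_region", _orient(lv, n_hat, neck_centre), lf)

    lv, lf = _cylinder_patch_local(spec.shaft_radius, 0.22 * L_mech, n_ax, n_ang)
    b.add_region("shaft_region", _orient(lv, s_hat, shaft_centre), lf)

    # Congruent condylar cylinders: one local template reused for both sides
    # so noise-free extremal landmarks differ by an exact joint-line vector.
    r_c, h_c, d_c = 0.2 * w_e, 0.14 * w_e, 0.3 * w_e
    lv, lf = _cylinder_patch_local(r_c, h_c, n_ax, n_ang)
    cond_local = _orient(lv, j_hat, np.zeros(3))
    b.add_region("condyle_region_med", cond_local - d_c * j_hat, lf)
    b.add_region("condyle_region_lat", cond_local + d_c * j_hat, lf)
    # Distal condylar prominences: one strictly most-distal vertex per
    # condyle (identical offsets, so the knee axis they span is exactly the
    # joint line). They dominate the cylinder surfaces by a >=0.3 cm margin
    # and are landmark-class for noise. Each is balanced by a counter-vertex
    # reflected through its cylinder's centre so the pair perturbs the
    # cylinder fit symmetrically (axis and centre stay exact).
    drop = (r_c + h_c * abs(np.sin(np.radians(tau))) + 0.3) * np.array([0.0, 1.0, 0.0])
    for name, centre in (("condyle_region_med", -d_c * j_hat),
                         ("condyle_region_lat", +d_c * j_hat)):
        b.add_region_vertex(name, centre - drop)
        b.add_region_vertex(name, centre + drop)

    # Point landmarks.
    b.add_point("epicondyle_med", [0.0, 0.0, -0.5 * w_e])
    b.add_point("epicondyle_lat", [0.0, 0.0, +0.5 * w_e])
    b.add_point("condyle_post_med", [-0.3 * w_e, -0.1 * w_e, -0.35 * w_e])
    b.add_point("condyle_post_lat", [-0.3 * w_e, -0.1 * w_e, +0.35 * w_e])
    # Greater trochanter: placed so |GT - lateral epicondyle| is exact.
    e_lat = np.array([0.0, 0.0, 0.5 * w_e])
    target = np.array([0.0, 0.95 * L_mech, 0.18 * L_mech])
    b.add_point("greater_trochanter",
                e_lat + spec.femoral_length * unit(target - e_lat))

    mesh, registry = b.build(rng, spec.noise_sd, spec.landmark_noise_factor, spec.side)
    truth = MeasurementRecord(
        case_id=case_id, bone="femur", side=spec.side,
        values={
            "anteversion_angle": alpha,
            "neck_shaft_angle": nu,
            "mldfa": 90.0 - tau,
            "bicondylar_angle": beta,
            "femoral_head_diameter": 2.0 * spec.head_radius,
            "femoral_length": spec.femoral_length,
            "epicondylar_width": w_e,
        })
    return mesh, registry, truth


def make_tibia(spec: TibiaSpec, case_id: str = "synthetic_tibia"
               ) -> tuple[TriangleMesh, LandmarkRegistry, MeasurementRecord]:
    """Synthetic right-convention tibia/fibula realising torsion and joint
    tilt exactly.

    The recovered anatomical frame has its lateral axis along the malleolar
    axis (rotated by the torsion about +y); the proximal joint-line tilt is
    imposed in that frame, so mMPTA and condylar width are exact in-frame
    quantities.
    """
    rng = np.random.default_rng(spec.seed)
    t, m = spec.torsion, spec.mpta_tilt
    W = spec.condylar_width
    z_frame = _rot_y(t) @ np.array([0.0, 0.0, 1.0])     # frame lateral axis
    y_hat = np.array([0.0, 1.0, 0.0])
    # Joint line: lateral side raised by the varus tilt, in the y/z_frame plane.
    j_hat = np.cos(np.radians(m)) * z_frame + np.sin(np.radians(m)) * y_hat

    r_c = spec.condyle_radius if spec.condyle_radius is not None else 0.2 * W
    h_c = 0.6 * r_c
    # Centre separation solved so the cylinder surfaces stay clear of the
    # condylar prominences by the prominence margin:
    # (extremal cylinder width)^2 = (2d + 2h)^2 + 4 r^2.
    w_inner = W - 2 * _PROMINENCE_MARGIN
    d_c = 0.5 * (np.sqrt(w_inner * w_inner - 4 * r_c * r_c) - 2 * h_c)

    L_im = 0.88 * spec.tibial_length
    im_mid = np.array([0.0, -L_im, 0.0])
    mall_med = im_mid - 0.5 * spec.malleolar_width * z_frame
    mall_lat = im_mid + 0.5 * spec.malleolar_width * z_frame

    b = _MeshBuilder("tibia_fibula")
    n_ax, n_ang = _grid_dims(spec.mesh_resolution)
    lv, lf = _cylinder_patch_local(r_c, h_c, n_ax, n_ang)
    cond_local = _orient(lv, j_hat, np.zeros(3))
    b.add_region("condyle_region_med", cond_local - d_c * j_hat, lf)
    b.add_region("condyle_region_lat", cond_local + d_c * j_hat, lf)
    # Condylar prominences: the strictly medial-most / lateral-most vertices
    # (in-frame), realising the requested condylar width exactly; each is
    # balanced by its reflection through the cylinder centre so the pair
    # leaves the condylar cylinder fits unbiased.
    for name, centre, prom in (
            ("condyle_region_med", -d_c * j_hat, -0.5 * W * z_frame),
            ("condyle_region_lat", +d_c * j_hat, +0.5 * W * z_frame)):
        b.add_region_vertex(name, prom)
        b.add_region_vertex(name, 2.0 * centre - prom)

    b.add_point("condyle_post_med", [-0.35 * W, -0.15 * W, -0.4 * W])
    b.add_point("condyle_post_lat", [-0.35 * W, -0.15 * W, +0.4 * W])
    b.add_point("malleolus_med", mall_med)
    b.add_point("malleolus_lat", mall_lat)
    # Lateral condyle landmark placed so |condyle_lat - malleolus_lat| is exact.
    target = np.array([0.0, 0.6, 0.0]) + 0.55 * W * z_frame
    b.add_point("condyle_lat",
                mall_lat + spec.tibial_length * unit(target - mall_lat))

    mesh, registry = b.build(rng, spec.noise_sd, spec.landmark_noise_factor, spec.side)
    truth = MeasurementRecord(
        case_id=case_id, bone="tibia_fibula", side=spec.side,
        values={
            "tibial_torsion": t,
            "mmpta": 90.0 - m,
            "condylar_width": W,
            "tibial_length": spec.tibial_length,
            "malleolar_width": spec.malleolar_width,
        })
    return mesh, registry, truth


def make_pelvis(spec: PelvisSpec, case_id: str = "synthetic_pelvis"
                ) -> tuple[TriangleMesh, LandmarkRegistry, MeasurementRecord]:
    """Synthetic pelvis realising the four pelvic linear measurements and the
    acetabular sphere geometry exactly."""
    rng = np.random.default_rng(spec.seed)
    x_a = 0.0
    asis_l = np.array([x_a, 0.0, -0.5 * spec.asis_width])
    asis_r = np.array([x_a, 0.0, +0.5 * spec.asis_width])
    psis_l = np.array([x_a - spec.depth, 0.0, -0.5 * spec.psis_width])
    psis_r = np.array([x_a - spec.depth, 0.0, +0.5 * spec.psis_width])
    acet_c = np.array([x_a - 0.35 * spec.depth, -0.25 * spec.asis_width, 0.0])

    b = _MeshBuilder("pelvis")
    n_ax, n_ang = _grid_dims(spec.mesh_resolution)
    for side_name, sgn in (("acetabulum_region_L", -1.0), ("acetabulum_region_R", +1.0)):
        centre = acet_c + np.array([0.0, 0.0, sgn * 0.5 * spec.hip_centre_distance])
        # Acetabular cup: a spherical cap opening laterally.
        pv, pf = _sphere_patch(centre, spec.acetab_radius, n_ax + 2, n_ang,
                               theta_min=np.pi * 0.08, theta_max=np.pi * 0.55,
                               axis=np.array([0.0, 0.0, -sgn]))
        b.add_region(side_name, pv, pf)
    b.add_point("ASIS_L", asis_l)
    b.add_point("ASIS_R", asis_r)
    b.add_point("PSIS_L", psis_l)
    b.add_point("PSIS_R", psis_r)

    mesh, registry = b.build(rng, spec.noise_sd, spec.landmark_noise_factor, "R")
    truth = MeasurementRecord(
        case_id=case_id, bone="pelvis", side="R",
        values={
            "asis_width": spec.asis_width,
            "psis_width": spec.psis_width,
            "pelvis_depth": spec.depth,
            "hip_joint_centre_distance": spec.hip_centre_distance,
            "hip_joint_diameter": 2.0 * spec.acetab_radius,
        })
    return mesh, registry, truth


def make_bone(spec, case_id: str = "synthetic"):
    """Dispatch on the spec type."""
    if isinstance(spec, FemurSpec):
        return make_femur(spec, case_id)
    if isinstance(spec, TibiaSpec):
        return make_tibia(spec, case_id)
    if isinstance(spec, PelvisSpec):
        return make_pelvis(spec, case_id)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass
class MeasurementModel:
    """Age-linear model of one measurement across the cohort.

    value = intercept + slope * age + sex_offset * 1[male] * 1[age >= divergence]
            + N(0, sd); the (value_at_4, value_at_18) pair parameterises the
    line on the cohort's age span.
    """

    value_at_4: float
    value_at_18: float
    sd: float
    sex_offset: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise SpecError("residual sd must be >= 0")

    @property
    def slope(self) -> float:
        return (self.value_at_18 - self.value_at_4) / 14.0

    @property
    def intercept(self) -> float:
        return self.value_at_4 - 4.0 * self.slope


def default_measurement_models() -> dict[str, MeasurementModel]:
    """Cohort models emulating the reported paediatric growth structure:
    torsions/angles drift weakly with age and carry no sex effect; linear
    measurements grow strongly and diverge by sex from the divergence age
    (males larger, except PSIS width and pelvis depth where females are
    larger for the same age)."""
    return {
        "anteversion_angle": MeasurementModel(22.0, 8.8, 9.0),
        "neck_shaft_angle": MeasurementModel(138.6, 132.1, 6.0),
        "mldfa": MeasurementModel(88.0, 86.5, 2.5),
        "bicondylar_angle": MeasurementModel(8.0, 9.7, 2.0),
        "tibial_torsion": MeasurementModel(32.0, 41.1, 9.0),
        "mmpta": MeasurementModel(90.1, 87.8, 3.0),
        "asis_width": MeasurementModel(14.6, 21.8, 1.5, sex_offset=+0.8),
        "psis_width": MeasurementModel(6.1, 9.2, 0.7, sex_offset=-0.35),
        "pelvis_depth": MeasurementModel(7.5, 14.2, 0.8, sex_offset=-0.4),
        "hip_joint_centre_distance": MeasurementModel(8.6, 13.8, 0.6, sex_offset=+0.3),
        "hip_joint_diameter": MeasurementModel(4.2, 6.6, 0.3, sex_offset=+0.15),
        "femoral_head_diameter": MeasurementModel(2.7, 4.5, 0.25, sex_offset=+0.25),
        "femoral_length": MeasurementModel(22.6, 40.3, 2.0, sex_offset=+2.0),
        "epicondylar_width": MeasurementModel(5.2, 8.1, 0.5, sex_offset=+0.5),
        "condylar_width": MeasurementModel(4.2, 7.5, 0.45, sex_offset=+0.45),
        "tibial_length": MeasurementModel(20.1, 36.2, 2.2, sex_offset=+2.2),
        "malleolar_width": MeasurementModel(4.1, 6.5, 0.4, sex_offset=+0.4),
    }


@dataclass
class CohortSpec:
    """Specification of a synthetic measurement cohort.

    With ``cases_per_sex_per_age`` set, ages are enumerated with a balanced
    number of cases of each sex per integer year (for calibration studies);
    otherwise ``n_cases`` cases are drawn with uniform integer ages and
    Bernoulli(0.5) sex.
    """

    n_cases: int = 300
    age_range: tuple[int, int] = (4, 18)
    divergence_age: int = 13
    measurements: dict[str, MeasurementModel] = field(
        default_factory=default_measurement_models)
    cases_per_sex_per_age: int | None = None
    height_intercept: float = 85.0
    height_slope: float = 5.0
    height_sd: float = 6.0
    height_sex_offset: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 2:
            raise SpecError("n_cases must be >= 2")
        lo, hi = self.age_range
        if not (4 <= lo <= hi <= 18):
            raise SpecError("age_range must lie within [4, 18]")


def simulate_cohort(spec: CohortSpec):
    """Simulate a cohort measurement table with known statistical structure.

    Emits per-bone rows like the mesh pipeline (one pelvis, femur L/R and
    tibia L/R row per case); left/right values are independent draws from
    the same case-level model. The rotational profile on each tibia row is
    computed as TT - AA of the same case and side, never drawn
    independently, so the RP identity holds in every simulated table.

    Returns a pandas DataFrame in the measurement-CSV schema.
    """
    import pandas as pd

    from .measurements import BONE_MEASUREMENTS, MEASUREMENT_NAMES

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    if spec.cases_per_sex_per_age is not None:
        ages = np.repeat(np.arange(lo, hi + 1), 2 * spec.cases_per_sex_per_age)
        sexes = np.tile(
            np.repeat(np.array(["F", "M"]), spec.cases_per_sex_per_age),
            hi - lo + 1)
    else:
        ages = rng.integers(lo, hi + 1, size=spec.n_cases)
        sexes = np.where(rng.random(spec.n_cases) < 0.5, "F", "M")
    n = len(ages)
    male = sexes == "M"
    post = ages >= spec.divergence_age
    heights = (spec.height_intercept + spec.height_slope * ages
               + spec.height_sex_offset * (male & post)
               + rng.normal(0.0, spec.height_sd, n))
    heights = np.clip(heights, 95.0, 194.9)

    def draw(name: str) -> np.ndarray:
        mm = spec.measurements[name]
        return (mm.intercept + mm.slope * ages
                + mm.sex_offset * (male & post)
                + rng.normal(0.0, mm.sd, n))

    per_bone_side = [("pelvis", ["R"]), ("femur", ["L", "R"]),
                     ("tibia_fibula", ["L", "R"])]
    draws: dict[tuple[str, str, str], np.ndarray] = {}
    for bone, sides in per_bone_side:
        for side in sides:
            for name in BONE_MEASUREMENTS[bone]:
                if name in spec.measurements:
                    draws[(bone, side, name)] = draw(name)

    rows = []
    for bone, sides in per_bone_side:
        for side in sides:
            block = {
                "case_id": [f"case{i:04d}" for i in range(n)],
                "bone": bone, "side": side, "sex": sexes,
                "age_years": ages, "height_cm": np.round(heights, 1),
            }
            for name in MEASUREMENT_NAMES:
                key = (bone, side, name)
                block[name] = draws[key] if key in draws else np.nan
            df = pd.DataFrame(block)
            aa_key = ("femur", side, "anteversion_angle")
            if (bone == "tibia_fibula" and aa_key in draws
                    and (bone, side, "tibial_torsion") in draws):
                df["rotational_profile"] = (
                    df["tibial_torsion"].to_numpy() - draws[aa_key])
            rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values(["case_id", "bone", "side"], kind="stable",
                          ignore_index=True)
    return out
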