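"""Landmark resolution, anatomical frames and side normalisation.

Meshes are assumed to be in nodal correspondence with a per-bone template:
a landmark registry maps anatomical names to template node indices, so
"automatic landmarking" is a pure index lookup on any corresponded mesh.

The per-bone anatomical frame follows the spirit of the International
Society of Biomechanics recommendations with the axis naming used
throughout this package: x anterior, y superior, z lateral (towards the
subject's right). The transverse plane has normal y, the frontal plane
normal x. Left-side bones are mirrored across the sagittal (x-y) plane
before measurement so a single sign convention covers both sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core_geometry import CylinderFit, SphereFit, unit

BONES = ("pelvis", "femur", "tibia_fibula")

#: Landmark / region names each bone's measurement set requires.
REQUIRED_POINTS = {
    "pelvis": ("ASIS_L", "ASIS_R", "PSIS_L", "PSIS_R"),
    "femur": (
        "greater_trochanter", "epicondyle_med", "epicondyle_lat",
        "condyle_post_med", "condyle_post_lat",
    ),
    "tibia_fibula": (
        "condyle_post_med", "condyle_post_lat", "condyle_lat",
        "malleolus_med", "malleolus_lat",
    ),
}
REQUIRED_REGIONS = {
    "pelvis": ("acetabulum_region_L", "acetabulum_region_R"),
    "femur": (
        "head_region", "neck_region", "shaft_region",
        "condyle_region_med", "condyle_region_lat",
    ),
    "tibia_fibula": ("condyle_region_med", "condyle_region_lat"),
}


class CorrespondenceError(ValueError):
    """Mesh is not in nodal correspondence with the registry's template."""


class RegistryError(ValueError):
    """Registry is missing required names or has out-of-range indices."""


class DegenerateFrameError(ValueError):
    """Frame-defining landmarks are collinear / coincident."""


@dataclass
class TriangleMesh:
    """A triangle surface mesh of one bone.

    ``vertices`` is (n, 3) float (cm); ``faces`` is (m, 3) int and may be
    empty (landmark-only point sets are legal). Isolated vertices (named
    landmarks not part of any triangle) are permitted and preserved by the
    package's mesh I/O.
    """

    vertices: np.ndarray
    faces: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if len(self.vertices) < 4:
            raise ValueError("a mesh needs at least 4 vertices")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class LandmarkRegistry:
    """Named anatomical points and node regions on a bone template.

    JSON schema: ``{"bone": ..., "template_vertex_count": N,
    "points": {name: index}, "regions": {name: [indices]}}``.
    """

    bone: str
    template_vertex_count: int
    points: dict[str, int]
    regions: dict[str, list[int]]

    def __post_init__(self):
        if self.bone not in BONES:
            raise RegistryError(f"unknown bone {self.bone!r}; expected one of {BONES}")
        missing = [n for n in REQUIRED_POINTS[self.bone] if n not in self.points]
        missing += [n for n in REQUIRED_REGIONS[self.bone] if n not in self.regions]
        if missing:
            raise RegistryError(f"registry for {self.bone} missing names: {missing}")
        n = self.template_vertex_count
        for name, idx in self.points.items():
            if not (0 <= int(idx) < n):
                raise RegistryError(f"point {name!r}: index {idx} out of range for {n} vertices")
        for name, idxs in self.regions.items():
            a = np.asarray(idxs, dtype=np.int64)
            if len(a) == 0:
                raise RegistryError(f"region {name!r} is empty")
            if a.min() < 0 or a.max() >= n:
                raise RegistryError(f"region {name!r}: indices out of range for {n} vertices")

    def to_json(self, path) -> None:
        obj = {
            "bone": self.bone,
            "template_vertex_count": int(self.template_vertex_count),
            "points": {k: int(v) for k, v in self.points.items()},
            "regions": {k: [int(i) for i in v] for k, v in self.regions.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LandmarkRegistry":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            bone=obj["bone"],
            template_vertex_count=int(obj["template_vertex_count"]),
            points=obj["points"],
            regions=obj["regions"],
        )


@dataclass
class LandmarkSet:
    """Resolved landmarks: named points (3-vectors) and regions ((k, 3) clouds).

    ``region_indices`` keeps each region's template node indices in the order
    its rows appear, so extremal-point tie-breaking by lowest node index is
    well defined.
    """

    bone: str
    points: dict[str, np.ndarray]
    regions: dict[str, np.ndarray]
    region_indices: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin plus right-handed orthonormal axes (x anterior, y superior,
    z lateral-to-subject's-right)."""

    origin: np.ndarray
    x_anterior: np.ndarray
    y_superior: np.ndarray
    z_lateral: np.ndarray

    def __post_init__(self):
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise DegenerateFrameError("frame axes are not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise DegenerateFrameError("frame is not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """Columns are (x_anterior, y_superior, z_lateral)."""
        return np.column_stack([self.x_anterior, self.y_superior, self.z_lateral])


def resolve_landmarks(mesh: TriangleMesh, registry: LandmarkRegistry) -> LandmarkSet:
    """Resolve a registry against a corresponded mesh (pure index lookup)."""
    if mesh.n_vertices != registry.template_vertex_count:
        raise CorrespondenceError(
            f"mesh has {mesh.n_vertices} vertices but registry expects "
            f"{registry.template_vertex_count}"
        )
    points = {name: mesh.vertices[int(i)].copy() for name, i in registry.points.items()}
    regions, region_indices = {}, {}
    for name, idxs in registry.regions.items():
        a = np.asarray(idxs, dtype=np.int64)
        regions[name] = mesh.vertices[a].copy()
        region_indices[name] = a
    return LandmarkSet(bone=registry.bone, points=points, regions=regions,
                       region_indices=region_indices)


def extremal_point(points, direction, indices=None) -> np.ndarray:
    """Point of a cloud maximising the dot product with ``direction``.

    Ties are broken by the lowest node index: rows are assumed ordered by
    index (as produced by :func:`resolve_landmarks`), and ``argmax`` returns
    the first maximiser.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P.reshape(1, 3)
    if len(P) == 0:
        raise ValueError("extremal_point: empty point cloud")
    d = unit(direction)
    proj = P @ d
    if indices is not None:
        order = np.argsort(indices, kind="stable")
        k = order[int(np.argmax(proj[order]))]
    else:
        k = int(np.argmax(proj))
    return P[k].copy()


def _orthonormal_frame(origin, y_raw, z_raw) -> AnatomicalFrame:
    """Frame from a superior axis and a provisional lateral axis."""
    ny, nz = np.linalg.norm(y_raw), np.linalg.norm(z_raw)
    if ny < 1e-9 or nz < 1e-9:
        raise DegenerateFrameError("frame-defining landmarks coincide")
    y = y_raw / ny
    z = z_raw - (z_raw @ y) * y
    if np.linalg.norm(z) < 1e-9 * nz:
        raise DegenerateFrameError("frame-defining landmarks are collinear")
    z = unit(z)
    x = np.cross(y, z)
    return AnatomicalFrame(origin=np.asarray(origin, float), x_anterior=x,
                           y_superior=y, z_lateral=z)


def build_frame(bone: str, landmarks: LandmarkSet, fits: dict | None = None) -> AnatomicalFrame:
    """Anatomical frame for one bone.

    pelvis: z along ASIS_L->ASIS_R, x from PSIS-midpoint->ASIS-midpoint
    (orthogonalised), origin at the ASIS midpoint.

    femur: y along condylar-cylinder-midpoint -> femoral head centre (the
    mechanical axis), provisional z from the epicondyles, origin at the
    condylar midpoint. Requires ``fits`` with 'head_sphere' (SphereFit) and
    'condyle_cyl_med'/'condyle_cyl_lat' (CylinderFit).

    tibia_fibula: y along inter-malleolar midpoint -> condylar-cylinder
    midpoint, provisional z from the malleoli, origin at the condylar
    midpoint. Requires 'condyle_cyl_med'/'condyle_cyl_lat' fits.
    """
    lm = landmarks.points
    if bone == "pelvis":
        asis_mid = 0.5 * (lm["ASIS_L"] + lm["ASIS_R"])
        psis_mid = 0.5 * (lm["PSIS_L"] + lm["PSIS_R"])
        z_raw = lm["ASIS_R"] - lm["ASIS_L"]
        x_raw = asis_mid - psis_mid
        nz, nx = np.linalg.norm(z_raw), np.linalg.norm(x_raw)
        if nz < 1e-9 or nx < 1e-9:
            raise DegenerateFrameError("pelvic frame landmarks coincide")
        z = z_raw / nz
        x = x_raw - (x_raw @ z) * z
        if np.linalg.norm(x) < 1e-9 * nx:
            raise DegenerateFrameError("pelvic frame landmarks are collinear")
        x = unit(x)
        y = np.cross(z, x)
        return AnatomicalFrame(origin=asis_mid, x_anterior=x, y_superior=y, z_lateral=z)

    if fits is None:
        raise ValueError(f"build_frame({bone!r}) requires primitive fits")

    if bone == "femur":
        head: SphereFit = fits["head_sphere"]
        cm: CylinderFit = fits["condyle_cyl_med"]
        cl: CylinderFit = fits["condyle_cyl_lat"]
        cond_mid = 0.5 * (cm.axis_point + cl.axis_point)
        y_raw = head.center - cond_mid
        z_raw = lm["epicondyle_lat"] - lm["epicondyle_med"]
        return _orthonormal_frame(cond_mid, y_raw, z_raw)

    if bone == "tibia_fibula":
        cm = fits["condyle_cyl_med"]
        cl = fits["condyle_cyl_lat"]
        cond_mid = 0.5 * (cm.axis_point + cl.axis_point)
        im_mid = 0.5 * (lm["malleolus_med"] + lm["malleolus_lat"])
        y_raw = cond_mid - im_mid
        z_raw = lm["malleolus_lat"] - lm["malleolus_med"]
        return _orthonormal_frame(cond_mid, y_raw, z_raw)

    raise ValueError(f"unknown bone {bone!r}")


def _swap_side_name(name: str) -> str:
    if name.endswith("_L"):
        return name[:-2] + "_R"
    if name.endswith("_R"):
        return name[:-2] + "_L"
    return name


def mirror_to_right(obj):
    """Reflect a left-side mesh or landmark set across the sagittal plane.

    Vertices map (x, y, z) -> (x, y, -z); triangle winding is flipped so
    outward normals are preserved; paired ``*_L``/``*_R`` landmark names are
    swapped (medial/lateral names are side-neutral and kept). Applying it
    twice is the identity.
    """
    M = np.diag([1.0, 1.0, -1.0])
    if isinstance(obj, TriangleMesh):
        return TriangleMesh(vertices=obj.vertices @ M,
                            faces=obj.faces[:, ::-1].copy() if len(obj.faces) else obj.faces)
    if isinstance(obj, LandmarkSet):
        return LandmarkSet(
            bone=obj.bone,
            points={_swap_side_name(k): v @ M for k, v in obj.points.items()},
            regions={_swap_side_name(k): v @ M for k, v in obj.regions.items()},
            region_indices={_swap_side_name(k): v.copy()
                            for k, v in obj.region_indices.items()},
        )
    if isinstance(obj, np.ndarray):
        return obj @ M
    raise TypeError(f"cannot mirror object of type {type(obj).__name__}")
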