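"""Clinical torsional, angular and linear bone measurements.

Seven angles and eleven lengths are computed per bone instance from the
resolved landmarks, primitive fits and the bone's anatomical frame:

angular (degrees)
    anteversion_angle (AA)   transverse-plane angle of the femoral neck axis
                             relative to the posterior condylar axis;
                             positive = anteversion (neck anterior).
    neck_shaft_angle (NSA)   full 3D angle between neck axis and the distal
                             femoral shaft direction (~120-160).
    mldfa                    frontal-plane lateral angle between the femoral
                             mechanical axis and the knee joint line (~84-90).
    bicondylar_angle (BA)    frontal-plane angle between the perpendicular of
                             the knee axis and the shaft axis (~6-12).
    tibial_torsion (TT)      transverse-plane angle carrying the posterior
                             tibial condylar axis onto the malleolar axis
                             about +y; positive = external torsion (~20-50).
    mmpta                    frontal-plane medial angle between the tibial
                             mechanical axis and the tibial knee axis (~85-92).
    rotational_profile (RP)  TT - AA of the same limb, exactly.

linear (cm)
    asis_width, psis_width, pelvis_depth, hip_joint_centre_distance,
    hip_joint_diameter, femoral_head_diameter, femoral_length,
    epicondylar_width, condylar_width, tibial_length, malleolar_width.

Torsional angles are signed transverse-plane projections about the superior
axis; NSA is a full 3D angle; mLDFA, BA and mMPTA are frontal-plane angles.
Left bones are mirrored to the right-side convention before measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import (
    AnatomicalFrame,
    LandmarkRegistry,
    LandmarkSet,
    TriangleMesh,
    build_frame,
    extremal_point,
    mirror_to_right,
    resolve_landmarks,
)
from .core_geometry import (
    CylinderFit,
    SphereFit,
    angle_between,
    fit_cylinder,
    fit_sphere,
    project_onto_plane,
    unit,
)

ANGULAR_MEASUREMENTS = (
    "anteversion_angle", "neck_shaft_angle", "mldfa", "bicondylar_angle",
    "tibial_torsion", "mmpta", "rotational_profile",
)
LINEAR_MEASUREMENTS = (
    "asis_width", "psis_width", "pelvis_depth", "hip_joint_centre_distance",
    "hip_joint_diameter", "femoral_head_diameter", "femoral_length",
    "epicondylar_width", "condylar_width", "tibial_length", "malleolar_width",
)
#: Fixed column order of the measurement vocabulary.
MEASUREMENT_NAMES = ANGULAR_MEASUREMENTS + LINEAR_MEASUREMENTS

#: Measurements applicable to each bone (RP is limb-level, carried on the
#: tibia row once paired with the same-side femur).
BONE_MEASUREMENTS = {
    "pelvis": ("asis_width", "psis_width", "pelvis_depth",
               "hip_joint_centre_distance", "hip_joint_diameter"),
    "femur": ("anteversion_angle", "neck_shaft_angle", "mldfa",
              "bicondylar_angle", "femoral_head_diameter", "femoral_length",
              "epicondylar_width"),
    "tibia_fibula": ("tibial_torsion", "mmpta", "condylar_width",
                     "tibial_length", "malleolar_width"),
}


class PairingError(ValueError):
    """TT and AA come from different cases or limb sides."""


@dataclass
class MeasurementRecord:
    """All measurements for one bone instance plus demographics."""

    case_id: str
    bone: str
    side: str = "R"
    sex: str | None = None
    age_years: int | None = None
    height_cm: float | None = None
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        unknown = set(self.values) - set(MEASUREMENT_NAMES)
        if unknown:
            raise ValueError(f"unknown measurement names: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Angular / torsional operations
# ---------------------------------------------------------------------------

def anteversion_angle(head_fit: SphereFit, neck_fit: CylinderFit,
                      condyle_post_med, condyle_post_lat,
                      frame: AnatomicalFrame) -> float:
    """Femoral anteversion: signed transverse-plane angle of the neck axis.

    The neck axis runs from the neck cylinder centre to the head sphere
    centre; the reference is the posterior condylar axis. Both are projected
    onto the transverse plane; the result is the signed angle about the
    superior axis carrying the projected neck axis onto the medially
    directed condylar axis, positive when the neck lies anterior
    (anteversion), negative for retroversion.
    """
    y = frame.y_superior
    neck = np.asarray(head_fit.center) - np.asarray(neck_fit.axis_point)
    medial = np.asarray(condyle_post_med) - np.asarray(condyle_post_lat)
    n_p = project_onto_plane(neck, y)
    m_p = project_onto_plane(medial, y)
    return angle_between(n_p, m_p, signed_about=y)


def neck_shaft_angle(neck_axis, shaft_axis_distal) -> float:
    """Full 3D angle between the neck axis (pointing toward the head) and
    the shaft axis pointing distally (shaft cylinder centre -> condylar
    midpoint); reported in [0, 180], clinically ~120-160."""
    return angle_between(neck_axis, shaft_axis_distal, mode="full")


def mechanical_ldfa(knee_axis_lat, mech_axis_prox, frame: AnatomicalFrame) -> float:
    """mLDFA: frontal-plane angle on the lateral side between the mechanical
    axis and the knee joint line (between the distal mechanical-axis
    direction and the lateral joint-line direction)."""
    x = frame.x_anterior
    k = project_onto_plane(knee_axis_lat, x)
    m = project_onto_plane(np.asarray(mech_axis_prox, float), x)
    return angle_between(-m, k, mode="full")


def bicondylar_angle(knee_axis, shaft_axis_prox, frame: AnatomicalFrame) -> float:
    """Frontal-plane obliquity of the shaft relative to the perpendicular of
    the knee joint line (0 when the shaft is exactly perpendicular)."""
    x = frame.x_anterior
    k = project_onto_plane(knee_axis, x)
    s = project_onto_plane(shaft_axis_prox, x)
    perp = np.cross(x, k)  # in-plane perpendicular of the joint line
    return angle_between(perp, s, mode="acute")


def tibial_torsion(condyle_post_med, condyle_post_lat,
                   malleolus_med, malleolus_lat, frame: AnatomicalFrame) -> float:
    """Tibial torsion: signed transverse-plane angle carrying the posterior
    condylar axis onto the malleolar axis about the superior axis; positive
    = external torsion."""
    y = frame.y_superior
    cond = np.asarray(condyle_post_lat) - np.asarray(condyle_post_med)
    mall = np.asarray(malleolus_lat) - np.asarray(malleolus_med)
    c_p = project_onto_plane(cond, y)
    m_p = project_onto_plane(mall, y)
    return angle_between(c_p, m_p, signed_about=y)


def mechanical_mpta(knee_axis_lat, mech_axis_prox, frame: AnatomicalFrame) -> float:
    """mMPTA: frontal-plane angle on the medial side between the tibial
    mechanical axis and the tibial knee axis (condylar cylinder centres)."""
    x = frame.x_anterior
    k = project_onto_plane(knee_axis_lat, x)
    m = project_onto_plane(np.asarray(mech_axis_prox, float), x)
    return angle_between(-m, -k, mode="full")


def rotational_profile(tt: float, aa: float) -> float:
    """Rotational profile angle: tibial torsion minus anteversion angle."""
    return tt - aa


def rotational_profile_from_records(femur: MeasurementRecord,
                                    tibia: MeasurementRecord) -> float:
    """RP for one limb, checking the two records belong together."""
    if femur.case_id != tibia.case_id or femur.side != tibia.side:
        raise PairingError(
            f"cannot pair femur ({femur.case_id}/{femur.side}) with "
            f"tibia ({tibia.case_id}/{tibia.side})"
        )
    return rotational_profile(tibia.values["tibial_torsion"],
                              femur.values["anteversion_angle"])


# ---------------------------------------------------------------------------
# Primitive fits per bone
# ---------------------------------------------------------------------------

def fit_femur_primitives(landmarks: LandmarkSet) -> dict:
    """Sphere/cylinder fits for the femoral regions.

    The neck cylinder is initialised along head-region-centroid minus
    neck-region-centroid; the condylar cylinders along the epicondylar axis.
    """
    reg = landmarks.regions
    head = fit_sphere(reg["head_region"])
    neck_init = reg["head_region"].mean(axis=0) - reg["neck_region"].mean(axis=0)
    neck = fit_cylinder(reg["neck_region"], init_direction=neck_init)
    shaft = fit_cylinder(reg["shaft_region"])
    epi_axis = landmarks["epicondyle_lat"] - landmarks["epicondyle_med"]
    return {
        "head_sphere": head,
        "neck_cyl": neck,
        "shaft_cyl": shaft,
        "condyle_cyl_med": fit_cylinder(reg["condyle_region_med"], init_direction=epi_axis),
        "condyle_cyl_lat": fit_cylinder(reg["condyle_region_lat"], init_direction=epi_axis),
    }


def fit_tibia_primitives(landmarks: LandmarkSet) -> dict:
    cond_axis = landmarks["condyle_post_lat"] - landmarks["condyle_post_med"]
    reg = landmarks.regions
    return {
        "condyle_cyl_med": fit_cylinder(reg["condyle_region_med"], init_direction=cond_axis),
        "condyle_cyl_lat": fit_cylinder(reg["condyle_region_lat"], init_direction=cond_axis),
    }


def fit_pelvis_primitives(landmarks: LandmarkSet) -> dict:
    reg = landmarks.regions
    return {
        "acetab_sphere_L": fit_sphere(reg["acetabulum_region_L"]),
        "acetab_sphere_R": fit_sphere(reg["acetabulum_region_R"]),
    }


# ---------------------------------------------------------------------------
# Per-bone measurement sets
# ---------------------------------------------------------------------------

def measure_pelvis(landmarks: LandmarkSet, fits: dict,
                   frame: AnatomicalFrame | None = None) -> dict[str, float]:
    """Pelvic linear measurements (frame-independent distances)."""
    lm = landmarks.points
    asis_mid = 0.5 * (lm["ASIS_L"] + lm["ASIS_R"])
    psis_mid = 0.5 * (lm["PSIS_L"] + lm["PSIS_R"])
    cl: SphereFit = fits["acetab_sphere_L"]
    cr: SphereFit = fits["acetab_sphere_R"]
    return {
        "asis_width": float(np.linalg.norm(lm["ASIS_L"] - lm["ASIS_R"])),
        "psis_width": float(np.linalg.norm(lm["PSIS_L"] - lm["PSIS_R"])),
        "pelvis_depth": float(np.linalg.norm(asis_mid - psis_mid)),
        "hip_joint_centre_distance": float(np.linalg.norm(cl.center - cr.center)),
        "hip_joint_diameter": float(cl.diameter + cr.diameter) / 2.0,
    }


def measure_femur(landmarks: LandmarkSet, fits: dict,
                  frame: AnatomicalFrame) -> dict[str, float]:
    """All femoral measurements (4 angles + 3 lengths) on a right-convention
    femur."""
    lm = landmarks.points
    head: SphereFit = fits["head_sphere"]
    neck: CylinderFit = fits["neck_cyl"]
    shaft: CylinderFit = fits["shaft_cyl"]
    cond_mid = 0.5 * (fits["condyle_cyl_med"].axis_point
                      + fits["condyle_cyl_lat"].axis_point)

    neck_axis = head.center - neck.axis_point
    shaft_prox = shaft.axis_point - cond_mid
    mech_prox = head.center - cond_mid

    # Knee joint line: most distal points of the condylar regions, in-frame.
    distal = -frame.y_superior
    p_med = extremal_point(landmarks.regions["condyle_region_med"], distal,
                           indices=landmarks.region_indices.get("condyle_region_med"))
    p_lat = extremal_point(landmarks.regions["condyle_region_lat"], distal,
                           indices=landmarks.region_indices.get("condyle_region_lat"))
    knee_axis_lat = p_lat - p_med

    return {
        "anteversion_angle": anteversion_angle(
            head, neck, lm["condyle_post_med"], lm["condyle_post_lat"], frame),
        "neck_shaft_angle": neck_shaft_angle(neck_axis, -shaft_prox),
        "mldfa": mechanical_ldfa(knee_axis_lat, mech_prox, frame),
        "bicondylar_angle": bicondylar_angle(knee_axis_lat, shaft_prox, frame),
        "femoral_head_diameter": head.diameter,
        "femoral_length": float(np.linalg.norm(
            lm["greater_trochanter"] - lm["epicondyle_lat"])),
        "epicondylar_width": float(np.linalg.norm(
            lm["epicondyle_med"] - lm["epicondyle_lat"])),
    }


def measure_tibia(landmarks: LandmarkSet, fits: dict,
                  frame: AnatomicalFrame) -> dict[str, float]:
    """All tibial measurements (2 angles + 3 lengths) on a right-convention
    tibia/fibula."""
    lm = landmarks.points
    cm: CylinderFit = fits["condyle_cyl_med"]
    cl: CylinderFit = fits["condyle_cyl_lat"]
    cond_mid = 0.5 * (cm.axis_point + cl.axis_point)
    im_mid = 0.5 * (lm["malleolus_med"] + lm["malleolus_lat"])
    knee_axis_lat = cl.axis_point - cm.axis_point
    mech_prox = cond_mid - im_mid

    p_med = extremal_point(landmarks.regions["condyle_region_med"], -frame.z_lateral,
                           indices=landmarks.region_indices.get("condyle_region_med"))
    p_lat = extremal_point(landmarks.regions["condyle_region_lat"], frame.z_lateral,
                           indices=landmarks.region_indices.get("condyle_region_lat"))

    return {
        "tibial_torsion": tibial_torsion(
            lm["condyle_post_med"], lm["condyle_post_lat"],
            lm["malleolus_med"], lm["malleolus_lat"], frame),
        "mmpta": mechanical_mpta(knee_axis_lat, mech_prox, frame),
        "condylar_width": float(np.linalg.norm(p_lat - p_med)),
        "tibial_length": float(np.linalg.norm(
            lm["condyle_lat"] - lm["malleolus_lat"])),
        "malleolar_width": float(np.linalg.norm(
            lm["malleolus_med"] - lm["malleolus_lat"])),
    }


# ---------------------------------------------------------------------------
# One-call pipeline for a single bone instance
# ---------------------------------------------------------------------------

def measure_bone(mesh: TriangleMesh, registry: LandmarkRegistry, *,
                 case_id: str = "case", side: str = "R", sex: str | None = None,
                 age_years: int | None = None, height_cm: float | None = None,
                 mirror_left: bool = True) -> MeasurementRecord:
    """Resolve landmarks, fit primitives, build the frame and measure.

    Left femora/tibiae are mirrored to the right-side convention first (the
    pelvis is a midline structure and is never mirrored), so torsion and
    version signs are comparable across sides.
    """
    landmarks = resolve_landmarks(mesh, registry)
    bone = registry.bone
    if side == "L" and mirror_left and bone != "pelvis":
        landmarks = mirror_to_right(landmarks)

    if bone == "pelvis":
        fits = fit_pelvis_primitives(landmarks)
        frame = build_frame("pelvis", landmarks)
        values = measure_pelvis(landmarks, fits, frame)
    elif bone == "femur":
        fits = fit_femur_primitives(landmarks)
        frame = build_frame("femur", landmarks, fits)
        values = measure_femur(landmarks, fits, frame)
    elif bone == "tibia_fibula":
        fits = fit_tibia_primitives(landmarks)
        frame = build_frame("tibia_fibula", landmarks, fits)
        values = measure_tibia(landmarks, fits, frame)
    else:  # pragma: no cover - registry validation forbids this
        raise ValueError(f"unknown bone {bone!r}")

    return MeasurementRecord(case_id=case_id, bone=bone, side=side, sex=sex,
                             age_years=age_years, height_cm=height_cm,
                             values=values)
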