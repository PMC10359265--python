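"""Clinical measurements: conventions, closed-loop recovery, invariances."""

import numpy as np
import pytest

from bonemorph.anatomy import AnatomicalFrame, TriangleMesh
from bonemorph.measurements import (
    ANGULAR_MEASUREMENTS,
    LINEAR_MEASUREMENTS,
    MEASUREMENT_NAMES,
    MeasurementRecord,
    PairingError,
    bicondylar_angle,
    measure_bone,
    mechanical_ldfa,
    mechanical_mpta,
    neck_shaft_angle,
    rotational_profile,
    rotational_profile_from_records,
    tibial_torsion,
)
from bonemorph.synthetic import FemurSpec, TibiaSpec, make_bone
from conftest import random_rotation

IDENTITY = AnatomicalFrame(origin=np.zeros(3),
                           x_anterior=np.array([1.0, 0, 0]),
                           y_superior=np.array([0.0, 1, 0]),
                           z_lateral=np.array([0.0, 0, 1]))


def transformed(mesh, R, t):
    return TriangleMesh(vertices=mesh.vertices @ R.T + t, faces=mesh.faces)


class TestToyVectorConventions:
    def test_perpendicular_neck_and_shaft(self):
        assert neck_shaft_angle((0, 0, 1), (0, 1, 0)) == pytest.approx(90.0)

    def test_mldfa_is_90_when_joint_line_perpendicular(self):
        assert mechanical_ldfa((0, 0, 1), (0, 1, 0), IDENTITY) == pytest.approx(90.0)

    def test_mmpta_is_90_when_joint_line_perpendicular(self):
        assert mechanical_mpta((0, 0, 1), (0, 1, 0), IDENTITY) == pytest.approx(90.0)

    def test_bicondylar_zero_when_shaft_perpendicular_to_knee_axis(self):
        assert bicondylar_angle((0, 0, 1), (0, 1, 0), IDENTITY) == pytest.approx(0.0)

    def test_torsion_of_rotated_malleolar_axis(self):
        """A malleolar axis that is the condylar axis rotated +35 deg about
        the superior axis reads as exactly 35 deg of torsion."""
        r = np.radians(35.0)
        cond = (np.zeros(3), np.array([0.0, 0, 1]))
        mall = np.array([np.sin(r), 0, np.cos(r)])
        tt = tibial_torsion(-cond[1], cond[1], -mall, mall, IDENTITY)
        assert tt == pytest.approx(35.0, abs=1e-9)

    @pytest.mark.parametrize("tt,aa,expected", [
        (30.0, 10.0, 20.0),
        (32.0, 22.0, 10.0),
        (17.5, 17.5, 0.0),
    ])
    def test_rotational_profile_definition(self, tt, aa, expected):
        assert rotational_profile(tt, aa) == expected

    def test_rotational_profile_pairing_error(self):
        fem = MeasurementRecord("c1", "femur", "R",
                                values={"anteversion_angle": 10.0})
        tib = MeasurementRecord("c1", "tibia_fibula", "L",
                                values={"tibial_torsion": 30.0})
        with pytest.raises(PairingError):
            rotational_profile_from_records(fem, tib)
        tib_r = MeasurementRecord("c1", "tibia_fibula", "R",
                                  values={"tibial_torsion": 30.0})
        assert rotational_profile_from_records(fem, tib_r) == 20.0


class TestClosedLoopRecovery:
    @pytest.mark.parametrize("anteversion", [-10.0, 0.0, 20.0])
    def test_anteversion_sign_and_value(self, anteversion):
        mesh, reg, truth = make_bone(FemurSpec(anteversion=anteversion, seed=1))
        rec = measure_bone(mesh, reg)
        assert rec.values["anteversion_angle"] == pytest.approx(anteversion, abs=0.5)

    @pytest.mark.parametrize("nsa", [120.0, 130.0, 140.0, 150.0])
    def test_neck_shaft_angle_sweep_monotone(self, nsa):
        mesh, reg, _ = make_bone(FemurSpec(neck_shaft=nsa, seed=2))
        rec = measure_bone(mesh, reg)
        assert rec.values["neck_shaft_angle"] == pytest.approx(nsa, abs=1.0)

    def test_joint_line_tilt_drives_mldfa(self):
        mesh, reg, _ = make_bone(FemurSpec(joint_line_tilt=3.0, seed=3))
        rec = measure_bone(mesh, reg)
        assert rec.values["mldfa"] == pytest.approx(87.0, abs=0.5)

    def test_shaft_obliquity_drives_bicondylar(self):
        mesh, reg, _ = make_bone(FemurSpec(bicondylar=9.0, seed=4))
        rec = measure_bone(mesh, reg)
        assert rec.values["bicondylar_angle"] == pytest.approx(9.0, abs=0.5)

    def test_noisy_tibial_torsion(self):
        mesh, reg, _ = make_bone(TibiaSpec(torsion=40.0, noise_sd=0.05, seed=5))
        rec = measure_bone(mesh, reg)
        assert rec.values["tibial_torsion"] == pytest.approx(40.0, abs=1.0)

    def test_varus_tilt_drives_mmpta(self):
        mesh, reg, _ = make_bone(TibiaSpec(mpta_tilt=2.0, seed=6))
        rec = measure_bone(mesh, reg)
        assert rec.values["mmpta"] == pytest.approx(88.0, abs=0.5)

    @pytest.mark.parametrize("bundle,rel", [
        ("femur_bundle", 0.01), ("tibia_bundle", 0.01), ("pelvis_bundle", 0.01),
    ])
    def test_linear_ground_truth(self, bundle, rel, request):
        mesh, reg, truth = request.getfixturevalue(bundle)
        rec = measure_bone(mesh, reg)
        for name, v in truth.values.items():
            if name in LINEAR_MEASUREMENTS:
                assert rec.values[name] == pytest.approx(v, rel=rel), name


class TestInvariances:
    @pytest.mark.parametrize("bundle", ["femur_bundle", "tibia_bundle",
                                        "pelvis_bundle"])
    def test_rigid_invariance(self, bundle, request):
        """Every measurement is unchanged under random rigid transforms of
        the mesh (20 transforms per bone)."""
        mesh, reg, _ = request.getfixturevalue(bundle)
        base = measure_bone(mesh, reg).values
        rng = np.random.default_rng(99)
        for _ in range(20):
            R, t = random_rotation(rng), rng.normal(0, 20, 3)
            moved = measure_bone(transformed(mesh, R, t), reg).values
            for name, v in base.items():
                assert moved[name] == pytest.approx(v, abs=1e-6), name

    def test_mirror_consistency(self):
        """A left bone, mirrored and measured, matches its exact right-side
        twin."""
        for spec_l, spec_r in [
            (FemurSpec(anteversion=20.0, side="L"), FemurSpec(anteversion=20.0)),
            (TibiaSpec(torsion=35.0, side="L"), TibiaSpec(torsion=35.0)),
        ]:
            mesh_l, reg_l, _ = make_bone(spec_l)
            mesh_r, reg_r, _ = make_bone(spec_r)
            rec_l = measure_bone(mesh_l, reg_l, side="L")
            rec_r = measure_bone(mesh_r, reg_r, side="R")
            for name, v in rec_r.values.items():
                assert rec_l.values[name] == pytest.approx(v, abs=1e-6), name

    @pytest.mark.parametrize("bundle", ["femur_bundle", "tibia_bundle",
                                        "pelvis_bundle"])
    def test_scale_covariance(self, bundle, request):
        """Isotropic scaling multiplies lengths by s and leaves angles
        unchanged."""
        mesh, reg, _ = request.getfixturevalue(bundle)
        s = 1.3
        base = measure_bone(mesh, reg).values
        scaled = measure_bone(
            TriangleMesh(vertices=mesh.vertices * s, faces=mesh.faces), reg).values
        for name, v in base.items():
            if name in ANGULAR_MEASUREMENTS:
                assert scaled[name] == pytest.approx(v, abs=1e-6), name
            else:
                assert scaled[name] == pytest.approx(v * s, rel=1e-9), name


class TestMeasurementRecord:
    def test_unknown_measurement_rejected(self):
        with pytest.raises(ValueError):
            MeasurementRecord("c", "femur", values={"femoral_girth": 1.0})

    def test_vocabulary_is_complete(self):
        assert len(MEASUREMENT_NAMES) == len(ANGULAR_MEASUREMENTS) + \
            len(LINEAR_MEASUREMENTS)
        assert len(set(MEASUREMENT_NAMES)) == len(MEASUREMENT_NAMES)
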