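"""Shared fixtures: noise-free synthetic bones and reusable oracles."""

import numpy as np
import pytest

from bonemorph.synthetic import FemurSpec, PelvisSpec, TibiaSpec, make_bone


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def femur_bundle():
    """Noise-free femur with 20 deg anteversion / NSA 135: (mesh, registry, truth)."""
    return make_bone(FemurSpec(anteversion=20.0, neck_shaft=135.0,
                               bicondylar=9.0, joint_line_tilt=3.0, seed=11))


@pytest.fixture(scope="session")
def tibia_bundle():
    """Noise-free tibia with 35 deg torsion / 2 deg varus tilt."""
    return make_bone(TibiaSpec(torsion=35.0, mpta_tilt=2.0, seed=12))


@pytest.fixture(scope="session")
def pelvis_bundle():
    """Noise-free pelvis with 12 cm hip-centre distance / 2.4 cm acetabula."""
    return make_bone(PelvisSpec(hip_centre_distance=12.0, acetab_radius=2.4,
                                seed=13))
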