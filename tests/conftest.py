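import numpy as np
import pytest
import trimesh

from craniometrics.core_frame import LandmarkSet
from craniometrics.synthetic_heads import load_preset, generate_head


@pytest.fixture(scope="session")
def sphere_fixture():
    """Icosphere of radius 8 cm centred 2 cm above the base plane, with
    mirror-symmetric landmarks that make the reference frame the identity."""
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=8.0)
    mesh.apply_translation([0.0, 0.0, 2.0])
    landmarks = LandmarkSet(
        {
            "tragus_r": [7.0, 0.0, 0.0],
            "tragus_l": [-7.0, 0.0, 0.0],
            "canthus_lat_r": [4.5, 8.0, 0.0],
            "canthus_lat_l": [-4.5, 8.0, 0.0],
            "subnasale": [0.0, 9.0, -1.0],
        }
    )
    return mesh, landmarks


@pytest.fixture(scope="session")
def preset_heads():
    """Frozen exemplar presets with their generated meshes and landmarks."""
    out = {}
    for name in ("control", "scaphocephaly", "trigonocephaly", "anterior_plagiocephaly"):
        preset = load_preset(name)
        mesh, landmarks = generate_head(preset, seed=0)
        out[name] = (preset, mesh, landmarks)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
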