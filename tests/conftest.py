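import numpy as np
import pytest
import trimesh

from boneatlas.geometry import ScalarVolume, soft_occupancy, voxelize
from boneatlas.population import PopulationSpec, make_base_shape, make_population

# Desk-scale study conditions used throughout the suite: a half-scale bone
# with proportionally scaled variability (relative geometry matches the
# full-scale defaults).
TEST_LENGTH = 150.0
TEST_AMPLITUDES = (2.5, 2.0, 1.5, 1.25, 1.0)


def small_spec(n_subjects, n_modes=5, seed=0, **kw):
    defaults = dict(
        mode_amplitudes=TEST_AMPLITUDES[:max(n_modes, 1)] or (1.0,),
        pose_rotation_sd=2.0, pose_translation_sd=1.0, vertex_noise_sd=0.025)
    defaults.update(kw)
    return PopulationSpec(n_subjects=n_subjects, n_modes=n_modes, seed=seed,
                          **defaults)


@pytest.fixture(scope="session")
def base_shape():
    return make_base_shape(2, length=TEST_LENGTH)


@pytest.fixture(scope="session")
def base_mesh(base_shape):
    return base_shape[0]


@pytest.fixture(scope="session")
def base_landmarks(base_shape):
    return base_shape[1]


@pytest.fixture(scope="session")
def tiny_population(base_shape):
    mesh, lm = base_shape
    return make_population(mesh, lm, small_spec(4, seed=1))


@pytest.fixture(scope="session")
def unit_cube():
    return trimesh.creation.box(extents=(10.0, 10.0, 10.0))


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=20.0)


@pytest.fixture(scope="session")
def sphere_volume(icosphere):
    return voxelize(icosphere, spacing=1.0, padding=4)


def blob_volume(center, radius=6.0, dims=(32, 32, 32), spacing=1.0):
    """Soft ellipsoidal blob on a regular grid (registration test substrate).

    ``radius`` may be a scalar (sphere) or per-axis radii; a triaxial blob
    constrains rotation, which a sphere cannot.
    """
    vol = ScalarVolume(np.zeros(3), np.full(3, float(spacing)),
                       np.zeros(dims))
    coords = vol.grid_world_coords()
    radii = np.broadcast_to(np.asarray(radius, float), (3,))
    d = np.linalg.norm((coords - np.asarray(center, float)) / radii, axis=-1)
    vol.values = np.clip(1.0 - d ** 2, 0.0, 1.0)
    return vol


def textured_blob(center, radius=10.0, dims=(32, 32, 32), spacing=1.0):
    """Blob with smooth interior texture: intensity gradients everywhere
    inside, so dense registration is well-posed over the full foreground."""
    vol = blob_volume(center, radius, dims, spacing)
    coords = vol.grid_world_coords()
    tex = (0.7 + 0.3 * np.sin(0.55 * coords[..., 0])
           * np.sin(0.45 * coords[..., 1]) * np.sin(0.65 * coords[..., 2]))
    vol.values = vol.values * tex
    return vol
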