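import numpy as np
import pytest
import trimesh

from sononav.contact import (
    CONTACT,
    NO_CONTACT,
    extract_features,
    train_contact_model,
)
from sononav.geometry import ProbeCalibration, RigidTransform
from sononav.phantom import (
    PhantomConfig,
    render_contact_image,
    render_no_contact_image,
)


@pytest.fixture(scope="session")
def identity_calib() -> ProbeCalibration:
    return ProbeCalibration(ms_t_us=RigidTransform.identity(), pixel_spacing=(1.0, 1.0))


@pytest.fixture(scope="session")
def fine_calib() -> ProbeCalibration:
    return ProbeCalibration(ms_t_us=RigidTransform.identity(), pixel_spacing=(0.2, 0.2))


@pytest.fixture(scope="session")
def phantom_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def contact_model(phantom_config):
    """Contact SVM trained once on rendered phantom frames (both classes)."""
    rng = np.random.default_rng(20_001)
    shape = (120, 160)
    feats, labels = [], []
    for _ in range(80):
        feats.append(extract_features(render_contact_image(shape, rng, phantom_config)))
        labels.append(CONTACT)
        feats.append(extract_features(render_no_contact_image(shape, rng, phantom_config)))
        labels.append(NO_CONTACT)
    return train_contact_model(feats, labels)


def make_flat_mesh(half_extent: float = 80.0, n: int = 81, z: float = 0.0) -> trimesh.Trimesh:
    """Flat z-plane grid mesh with upward normals."""
    xs = np.linspace(-half_extent, half_extent, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])
    mesh = trimesh.Trimesh(verts, faces, process=False)
    flip = mesh.face_normals[:, 2] < 0
    f = mesh.faces.copy()
    f[flip] = f[flip][:, ::-1]
    return trimesh.Trimesh(verts, f, process=False)


@pytest.fixture(scope="session")
def flat_mesh() -> trimesh.Trimesh:
    return make_flat_mesh()


def random_rigid(rng: np.random.Generator, translation_scale: float = 50.0) -> RigidTransform:
    """Uniform random rotation (QR of a Gaussian matrix) plus random translation."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-translation_scale, translation_scale, 3)
    return RigidTransform.from_rotation_translation(q, t)
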