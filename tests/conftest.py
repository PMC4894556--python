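"""Shared geometric fixtures: all meshes are generated programmatically."""

import numpy as np
import pytest
import trimesh

from arcmorph.mesh_core import TriangleSurface, clean_surface


def make_sphere(radius: float = 10.0, subdivisions: int = 3) -> TriangleSurface:
    m = trimesh.creation.icosphere(subdivisions, radius)
    return clean_surface(TriangleSurface(np.asarray(m.vertices), np.asarray(m.faces)))


def make_cube(extent: float = 1.0) -> TriangleSurface:
    m = trimesh.creation.box(extents=(extent,) * 3)
    return clean_surface(TriangleSurface(np.asarray(m.vertices), np.asarray(m.faces)))


def make_open_cylinder(radius: float = 10.0, length: float = 100.0,
                       n_around: int = 24, n_along: int = 40) -> TriangleSurface:
    z = np.linspace(0.0, length, n_along)
    phi = np.linspace(0.0, 2 * np.pi, n_around, endpoint=False)
    verts = np.array([[radius * np.cos(a), radius * np.sin(a), zz]
                      for zz in z for a in phi])
    faces = []
    for i in range(n_along - 1):
        for j in range(n_around):
            a0 = i * n_around + j
            a1 = i * n_around + (j + 1) % n_around
            b0 = (i + 1) * n_around + j
            b1 = (i + 1) * n_around + (j + 1) % n_around
            faces.extend([[a0, b0, a1], [a1, b0, b1]])
    return clean_surface(TriangleSurface(verts, np.asarray(faces)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


@pytest.fixture(scope="session")
def sphere10() -> TriangleSurface:
    return make_sphere(10.0, 3)


@pytest.fixture(scope="session")
def cube() -> TriangleSurface:
    return make_cube()


@pytest.fixture(scope="session")
def cylinder() -> TriangleSurface:
    return make_open_cylinder()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
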