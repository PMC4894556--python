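"""Centreline extraction and the morphometric descriptor set."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from arcmorph import morphometry as mo
from arcmorph.mesh_core import MeshError
from arcmorph.morphometry import (Centreline, arch_height_width, cap_boundary_loops,
                                  centreline_descriptors, compute_descriptors,
                                  diameters, extract_centreline)
from arcmorph.synthetic_data import ArchParams, generate_arch

from conftest import make_open_cylinder


pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


@pytest.fixture(scope="module")
def cyl_centreline(cylinder):
    return extract_centreline(cylinder)


def test_cylinder_centreline_on_axis(cylinder, cyl_centreline):
    c = cyl_centreline
    axis_dev = np.linalg.norm(c.points[:, :2], axis=1).max()
    assert axis_dev < 0.2
    L, _, _ = centreline_descriptors(c)
    assert L == pytest.approx(100.0, rel=0.02)


def test_closed_mesh_is_non_tubular(sphere10):
    with pytest.raises(MeshError, match="non-tubular"):
        extract_centreline(sphere10)


def test_straight_segment_descriptors():
    pts = np.stack([np.zeros(50), np.zeros(50), np.linspace(0, 100, 50)], axis=1)
    c = Centreline(pts, np.full(50, 5.0), np.linspace(0, 100, 50))
    L, to, cmed = centreline_descriptors(c)
    assert L == pytest.approx(100.0)
    assert to == pytest.approx(0.0, abs=1e-12)
    assert cmed == pytest.approx(0.0, abs=1e-9)


def test_semicircle_descriptors():
    th = np.linspace(0, np.pi, 200)
    R = 50.0
    pts = np.stack([R * np.cos(th), R * np.sin(th), np.zeros_like(th)], axis=1)
    arc = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    c = Centreline(pts, np.full_like(th, 5.0), arc)
    L, to, cmed = centreline_descriptors(c)
    assert L == pytest.approx(np.pi * R, rel=0.01)
    assert to == pytest.approx(np.pi / 2 - 1, rel=0.01)
    assert cmed == pytest.approx(1 / R, rel=0.02)


def test_half_torus_tube_arc_length():
    # tube bent along a half circle of bend radius 50
    p = ArchParams(base_radius=6.0, arch_height_A=50.0, arch_width_T=100.0,
                   ascending_length=1.0, descending_length=1.0,
                   section_points=16, axial_step=5.0)
    c = extract_centreline(generate_arch(p))
    L, _, _ = centreline_descriptors(c)
    assert L == pytest.approx(np.pi * 50.0, rel=0.02)


def test_descriptor_similarity_scaling():
    th = np.linspace(0, np.pi, 100)
    pts = np.stack([30 * np.cos(th), 30 * np.sin(th), np.zeros_like(th)], axis=1)
    arc = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    c1 = Centreline(pts, np.full_like(th, 5.0), arc)
    c2 = Centreline(2 * pts, np.full_like(th, 10.0), 2 * arc)
    L1, to1, k1 = centreline_descriptors(c1)
    L2, to2, k2 = centreline_descriptors(c2)
    assert L2 == pytest.approx(2 * L1, rel=1e-9)
    assert to2 == pytest.approx(to1, rel=1e-9)
    assert k2 == pytest.approx(k1 / 2, rel=1e-6)


def test_tortuosity_nonnegative(rng):
    pts = np.stack([np.zeros(60), np.zeros(60), np.linspace(0, 80, 60)], axis=1)
    pts[:, 0] += rng.normal(0, 0.5, 60)
    arc = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    c = Centreline(pts, np.full(60, 4.0), arc)
    _, to, _ = centreline_descriptors(c)
    assert to >= 0


def test_constant_tube_diameters(cylinder, cyl_centreline):
    d = diameters(cylinder, cyl_centreline)
    for key in ("D_max", "D_min", "D_med"):
        assert d[key] == pytest.approx(20.0, rel=0.02)


def test_narrowed_tube_d_min_location():
    p = ArchParams(base_radius=10.0, arch_height_A=40.0, arch_width_T=80.0,
                   ascending_length=40.0, descending_length=40.0,
                   narrowings={"mid": (0.6, 0.5, 0.05)},
                   section_points=20, axial_step=4.0)
    s = generate_arch(p)
    c = extract_centreline(s)
    d = diameters(s, c)
    assert d["D_min"] == pytest.approx(2 * 0.6 * 10.0, rel=0.03)
    # narrowing removed -> D_min returns to the base diameter
    p0 = ArchParams(**{**p.__dict__, "narrowings": {}})
    s0 = generate_arch(p0)
    d0 = diameters(s0, extract_centreline(s0))
    assert d0["D_min"] > d["D_min"]
    assert d0["D_min"] == pytest.approx(20.0, rel=0.03)


def test_tapering_tube_level_interpolation():
    # linear taper 20 -> 10 mm diameter: mid-level diameter ~ 15
    n, m = 40, 24
    z = np.linspace(0, 100, n)
    r = np.interp(z, [0, 100], [10.0, 5.0])
    phi = np.linspace(0, 2 * np.pi, m, endpoint=False)
    verts = np.array([[rr * np.cos(a), rr * np.sin(a), zz]
                      for rr, zz in zip(r, z) for a in phi])
    faces = []
    for i in range(n - 1):
        for j in range(m):
            a0, a1 = i * m + j, i * m + (j + 1) % m
            b0, b1 = (i + 1) * m + j, (i + 1) * m + (j + 1) % m
            faces.extend([[a0, b0, a1], [a1, b0, b1]])
    from arcmorph.mesh_core import TriangleSurface, clean_surface
    s = clean_surface(TriangleSurface(verts, np.asarray(faces)))
    c = extract_centreline(s)
    d = diameters(s, c, level_fractions={"mid": 0.5})
    assert d["D_mid"] == pytest.approx(15.0, rel=0.03)


def test_arch_height_width_generator_truth():
    p = ArchParams(base_radius=8.0, arch_height_A=40.0, arch_width_T=60.0,
                   ascending_length=30.0, descending_length=50.0,
                   section_points=16, axial_step=5.0)
    c = extract_centreline(generate_arch(p))
    A, T = arch_height_width(c)
    assert A == pytest.approx(40.0, rel=0.02)
    assert T == pytest.approx(60.0, rel=0.02)


def test_arch_height_width_rigid_invariant():
    p = ArchParams(base_radius=8.0, arch_height_A=40.0, arch_width_T=60.0,
                   ascending_length=30.0, descending_length=50.0,
                   section_points=16, axial_step=5.0)
    s = generate_arch(p)
    A0, T0 = arch_height_width(extract_centreline(s))
    R = Rotation.from_euler("xyz", [25, -40, 60], degrees=True).as_matrix()
    A1, T1 = arch_height_width(extract_centreline(
        s.transformed(rotation=R, translation=[9, 4, -2])))
    assert A1 == pytest.approx(A0, rel=0.01)
    assert T1 == pytest.approx(T0, rel=0.01)


def test_straight_tube_has_no_apex(cylinder, cyl_centreline):
    with pytest.raises(ValueError, match="no apex"):
        arch_height_width(cyl_centreline)


def test_capped_volume_of_cylinder(cylinder):
    capped = cap_boundary_loops(cylinder)
    assert capped.is_closed()
    # 24-gon prism volume, not pi r^2 L
    poly_area = 0.5 * 24 * 100 * np.sin(2 * np.pi / 24)
    assert capped.volume() == pytest.approx(poly_area * 100, rel=0.01)


def test_compute_descriptors_consistency(cylinder):
    d = compute_descriptors(cylinder, bsa=2.0)
    assert d.ratio_A_surf_V == pytest.approx(d.A_surf / d.V, rel=1e-9)
    assert d.indexed["L_CL"] == pytest.approx(d.L_CL / 2.0, rel=1e-9)
    assert d.D_min <= d.D_med <= d.D_max
    assert d.To_CL >= 0
    assert d.indexed["A_surf"] == pytest.approx(d.A_surf / 2.0, rel=1e-9)
    assert np.isnan(d.arch_height_A)   # straight tube: no arch measurements


def test_descriptors_rigid_invariance_and_scaling():
    p = ArchParams(section_points=14, axial_step=10.0)
    s = generate_arch(p)
    d0 = compute_descriptors(s)
    R = Rotation.from_euler("zyx", [33, 20, -70], degrees=True).as_matrix()
    d1 = compute_descriptors(s.transformed(rotation=R, translation=[10, -5, 3]))
    for name in ("V", "A_surf", "L_CL", "D_med", "To_CL", "arch_height_A"):
        assert getattr(d1, name) == pytest.approx(getattr(d0, name), rel=0.01)
    s2 = type(s)(s.vertices * 2.0, s.faces)
    d2 = compute_descriptors(s2)
    assert d2.L_CL == pytest.approx(2 * d0.L_CL, rel=0.02)
    assert d2.A_surf == pytest.approx(4 * d0.A_surf, rel=0.02)
    assert d2.V == pytest.approx(8 * d0.V, rel=0.02)
    assert d2.D_med == pytest.approx(2 * d0.D_med, rel=0.02)
    assert d2.C_med == pytest.approx(d0.C_med / 2, rel=0.05)
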