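"""Kernel-width estimation, surface matching, template estimation, momenta."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from arcmorph import atlas as at
from arcmorph.currents import currents_distance2, to_currents
from arcmorph.mesh_core import surface_distance
from arcmorph.morphometry import cap_boundary_loops
from arcmorph.synthetic_data import ArchParams, generate_arch

from conftest import make_sphere


@pytest.mark.parametrize("a_min,p_w,p_v,expect", [
    (8825.0, 0.025, 0.25, (15.0, 47.0)),   # the worked rule-of-thumb example
    (100.0, 1.0, 1.0, (10.0, 10.0)),
])
def test_initial_lambdas(a_min, p_w, p_v, expect):
    k = at.estimate_initial_lambdas(a_min, p_w, p_v)
    assert (k.lambda_w, k.lambda_v) == expect


def test_initial_lambda_rounding():
    # sqrt(0.01 * 8825) = 9.39 -> 9 mm
    k = at.estimate_initial_lambdas(8825.0, 0.01, 0.25)
    assert k.lambda_w == 9.0
    # stiffness below resolution is legal but warned about
    with pytest.warns(UserWarning, match="lambda_v < lambda_w"):
        at.estimate_initial_lambdas(8825.0, 0.025, 0.005)


def test_initial_lambdas_validation():
    with pytest.raises(ValueError):
        at.estimate_initial_lambdas(-1.0, 0.1, 0.2)
    with pytest.raises(ValueError):
        at.estimate_initial_lambdas(100.0, 0.0, 0.2)


def test_momenta_gradient_finite_difference(rng):
    s = make_sphere(10.0, 2)
    kern = at.KernelParams(8.0, 15.0)
    Q0 = at.select_control_points(s.vertices, kern.lambda_v / 2)
    target = to_currents(s.transformed(translation=[5, 0, 0]), kern.lambda_w)
    alpha = rng.normal(0, 0.5, (len(Q0), 3)).ravel()
    gamma, steps, eps = 1e-4, 10, 1e-5
    _, g, _ = at._match_cost_grad(alpha, s.vertices, s.faces, Q0, target, kern, gamma, steps)
    for i in rng.choice(alpha.size, 10, replace=False):
        a1, a2 = alpha.copy(), alpha.copy()
        a1[i] += eps
        a2[i] -= eps
        J1, _, _ = at._match_cost_grad(a1, s.vertices, s.faces, Q0, target, kern, gamma, steps)
        J2, _, _ = at._match_cost_grad(a2, s.vertices, s.faces, Q0, target, kern, gamma, steps)
        fd = (J1 - J2) / (2 * eps)
        assert abs(fd - g[i]) / max(abs(fd), 1e-12) < 1e-4


def test_match_identity(sphere10):
    kern = at.KernelParams(6.0, 12.0)
    fld, diag = at.match_surfaces(sphere10, sphere10, kern,
                                  options=at.MatchOptions(max_iter=10))
    assert np.abs(fld.initial_momenta).max() == pytest.approx(0.0, abs=1e-9)
    assert diag["cost_final"] <= diag["cost_initial"] + 1e-12


def test_match_recovers_translation():
    s = make_sphere(10.0, 2)
    kern = at.KernelParams(8.0, 15.0)
    target = s.transformed(translation=[5.0, 0, 0])
    fld, diag = at.match_surfaces(s, target, kern, gamma=1e-4)
    deformed = at.apply_deformation(s, fld)
    dmax, _ = surface_distance(deformed, target)
    assert dmax < 0.2
    baseline, _ = surface_distance(s, target)
    assert dmax <= 0.2 * baseline   # error reduced by >= 80 %


def test_match_narrowed_tube_currents_reduction():
    base = ArchParams(base_radius=10.0, arch_height_A=30, arch_width_T=60,
                      ascending_length=20, descending_length=20,
                      section_points=12, axial_step=8)
    narrowed = ArchParams(**{**base.__dict__,
                             "narrowings": {"mid": (0.6, 0.5, 0.08)}})
    s, t = generate_arch(base), generate_arch(narrowed)
    kern = at.KernelParams(8.0, 20.0)
    fld, diag = at.match_surfaces(s, t, kern, gamma=1e-5,
                                  options=at.MatchOptions(max_iter=80))
    assert diag["data_final"] <= 0.2 * diag["data_initial"]


def test_zero_momenta_identity_bit_exact(sphere10):
    fld = at.DeformationField.from_initial(sphere10.vertices[:5],
                                           np.zeros((5, 3)), 10, 12.0)
    out = at.apply_deformation(sphere10, fld)
    assert np.array_equal(out.vertices, sphere10.vertices)


def test_matching_cost_rigid_invariant(rng):
    from conftest import random_rotation
    s = make_sphere(10.0, 1)
    t = make_sphere(12.0, 1)
    kern = at.KernelParams(8.0, 15.0)
    Q0 = at.select_control_points(s.vertices, kern.lambda_v / 2)
    alpha = np.zeros(3 * len(Q0))
    J0, _, _ = at._match_cost_grad(alpha, s.vertices, s.faces, Q0,
                                   to_currents(t, kern.lambda_w), kern, 1e-4, 10)
    R = random_rotation(rng)
    tr = rng.normal(0, 20, 3)
    sR, tR = s.transformed(rotation=R, translation=tr), t.transformed(rotation=R, translation=tr)
    QR = Q0 @ R.T + tr
    J1, _, _ = at._match_cost_grad(alpha, sR.vertices, sR.faces, QR,
                                   to_currents(tR, kern.lambda_w), kern, 1e-4, 10)
    assert J1 == pytest.approx(J0, rel=1e-8)


def test_gamma_monotonicity():
    s = make_sphere(10.0, 1)
    target = s.transformed(translation=[4.0, 0, 0])
    kern = at.KernelParams(8.0, 15.0)
    datas = []
    for gamma in (1e-3, 1e-5):
        _, diag = at.match_surfaces(s, target, kern, gamma=gamma,
                                    options=at.MatchOptions(max_iter=60))
        datas.append(diag["data_final"])
    assert datas[1] <= datas[0] + 1e-9   # weaker regularisation fits no worse


def test_template_identical_cohort(sphere10):
    kern = at.KernelParams(6.0, 12.0)
    cohort = [sphere10.copy() for _ in range(4)]
    tpl = at.compute_template(cohort, kern, init=sphere10, max_outer=2)
    dmax, _ = surface_distance(tpl.surface, sphere10)
    assert dmax < 0.1
    for fld in tpl.deformations:
        assert np.abs(fld.initial_momenta).max() < 1e-6


def test_template_two_spheres_midpoint():
    kern = at.KernelParams(6.0, 12.0)
    tpl = at.compute_template([make_sphere(8.0, 2), make_sphere(12.0, 2)], kern,
                              init=make_sphere(10.0, 2), max_outer=4)
    radii = np.linalg.norm(tpl.surface.vertices - tpl.surface.vertices.mean(0), axis=1)
    d_med = 2 * np.median(radii)
    assert d_med == pytest.approx(20.0, rel=0.05)


def test_template_cost_trace_non_increasing(sphere10):
    kern = at.KernelParams(6.0, 12.0)
    cohort = [make_sphere(9.0, 2), make_sphere(11.0, 2)]
    tpl = at.compute_template(cohort, kern, init=make_sphere(10.0, 2), max_outer=3)
    trace = tpl.cost_trace
    assert all(trace[i + 1] <= trace[i] + 1e-9 * abs(trace[i]) for i in range(len(trace) - 1))


def test_moment_matrix_properties(rng):
    kern = at.KernelParams(6.0, 12.0)
    cohort = [make_sphere(9.0, 2), make_sphere(10.0, 2), make_sphere(11.0, 2)]
    tpl = at.compute_template(cohort, kern, init=cohort[1], max_outer=2,
                              options=at.MatchOptions(max_iter=15))
    mm = at.moment_matrix(tpl)
    K_ctrl = len(mm.control_points)
    assert mm.rows.shape == (3, 3 * K_ctrl)
    # row inner products reproduce the kernel double sum
    K = np.exp(-cdist(mm.control_points, mm.control_points, "sqeuclidean") / kern.lambda_v**2)
    for i, j in [(0, 1), (0, 2), (2, 2)]:
        a, b = tpl.deformations[i].initial_momenta, tpl.deformations[j].initial_momenta
        oracle = sum(float(a[:, ax] @ K @ b[:, ax]) for ax in range(3))
        assert mm.rows[i] @ mm.rows[j] == pytest.approx(oracle, rel=1e-8, abs=1e-12)
    # unwhitening inverts the whitening
    assert np.allclose(mm.unwhiten(mm.rows[0]), tpl.deformations[0].initial_momenta)


def test_moment_matrix_zero_row_for_identity():
    kern = at.KernelParams(6.0, 12.0)
    s = make_sphere(10.0, 1)
    cohort = [s.copy(), s.copy()]
    tpl = at.compute_template(cohort, kern, init=s, max_outer=1,
                              options=at.MatchOptions(max_iter=5))
    mm = at.moment_matrix(tpl)
    assert np.abs(mm.rows).max() < 1e-6


def test_refine_lambdas_degenerate_pass(sphere10):
    init = at.KernelParams(8.0, 15.0)
    out = at.refine_lambdas(sphere10, sphere10.copy(), init, lambda_v_floor=10.0)
    assert (out.lambda_w, out.lambda_v) == (init.lambda_w, init.lambda_v)


def test_refine_lambdas_prioritises_high_lambda_w():
    # a target reachable at the initial widths: the first (highest) pair wins
    s = make_sphere(10.0, 2)
    t = s.transformed(translation=[2.0, 0, 0])
    init = at.KernelParams(8.0, 15.0)
    out = at.refine_lambdas(s, t, init, reduction_target=0.8, lambda_v_floor=13.0,
                            options=at.MatchOptions(max_iter=40))
    assert out.lambda_w == init.lambda_w
    assert out.lambda_v == init.lambda_v


def test_refine_lambdas_floor_validation(sphere10):
    init = at.KernelParams(8.0, 15.0)
    with pytest.raises(ValueError):
        at.refine_lambdas(sphere10, sphere10, init, lambda_v_floor=15.0)
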