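"""PLS shape modes, residualization, Cook screening and correlation gating."""

import numpy as np
import pytest

from arcmorph import pls_stats as ps
from arcmorph.pls_stats import (cooks_flag, correlate, pls_fit, residualize,
                                shape_vector)


@pytest.fixture()
def random_xy(rng):
    X = rng.normal(size=(6, 4))
    y = rng.normal(size=6)
    return X, y


def test_rank1_exact_recovery(rng):
    x = rng.normal(size=(8, 1))
    y = 2.0 * x.ravel()
    model = pls_fit(x, y, 1)
    r = np.corrcoef(model.x_scores[:, 0], y)[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-10)


def test_first_weight_matches_closed_form(random_xy):
    X, y = random_xy
    model = pls_fit(X, y, 1)
    Xc = X - X.mean(0)
    w_oracle = Xc.T @ (y - y.mean())
    w_oracle /= np.linalg.norm(w_oracle)
    assert abs(np.dot(model.x_weights[:, 0], w_oracle)) == pytest.approx(1.0, abs=1e-8)


def test_scores_positively_associated_with_response(random_xy):
    X, y = random_xy
    model = pls_fit(X, y, 2)
    for c in range(2):
        assert np.dot(model.x_scores[:, c], y - y.mean()) >= 0


def test_explained_variability_sums_to_one(random_xy):
    X, y = random_xy
    rank = np.linalg.matrix_rank(X - X.mean(0))
    model = pls_fit(X, y, rank)
    assert model.explained_shape_variability.sum() == pytest.approx(1.0, abs=1e-8)
    assert np.all(model.explained_shape_variability >= 0)


def test_score_orthogonality(random_xy):
    X, y = random_xy
    model = pls_fit(X, y, 3)
    G = model.x_scores.T @ model.x_scores
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()


def test_pls_fit_validations(rng):
    X = rng.normal(size=(6, 3))
    with pytest.raises(ValueError, match="constant"):
        pls_fit(X, np.ones(6))
    with pytest.raises(ValueError, match="rank"):
        pls_fit(X, rng.normal(size=6), n_components=5)
    with pytest.raises(ValueError, match="3 subjects"):
        pls_fit(X[:2], np.array([1.0, 2.0]))


def test_shape_vector_in_sample_equals_scores(random_xy):
    X, y = random_xy
    model = pls_fit(X, y, 2)
    sv = shape_vector(model, X, component=1)
    assert np.allclose(sv.values, model.x_scores[:, 0])
    sv2 = shape_vector(model, X, component=2)
    assert np.allclose(sv2.values, model.x_scores[:, 1])


def test_shape_vector_mean_subject_is_zero(random_xy):
    X, y = random_xy
    model = pls_fit(X, y, 1)
    val = shape_vector(model, X.mean(0, keepdims=True)).values
    assert val[0] == pytest.approx(0.0, abs=1e-10)


def test_residualize_orthogonality_and_shrinkage(rng):
    X = rng.normal(size=(10, 6))
    y = X[:, 0] + 0.3 * rng.normal(size=10)
    model = pls_fit(X, y, 1)
    Xr = residualize(X, model)
    assert np.abs(model.x_scores[:, 0] @ (Xr - Xr.mean(0))).max() < 1e-8
    Xc = X - X.mean(0)
    assert np.sum((Xr - Xr.mean(0))**2) < np.sum(Xc**2)
    # refitting the same response on the residuals explains almost nothing
    # along the deflated direction
    refit = pls_fit(Xr, y, 1)
    proj = np.abs(np.dot(refit.x_weights[:, 0], model.x_loadings[:, 0]))
    assert proj < 0.6   # deflated direction no longer dominates


def test_residualize_commutes_with_projection(rng):
    X = rng.normal(size=(9, 5))
    y = X @ rng.normal(size=5) + 0.1 * rng.normal(size=9)
    model = pls_fit(X, y, 1)
    Xr = residualize(X, model)
    # residual rows equal centered rows projected off the score direction
    Xc = X - X.mean(0)
    t = model.x_scores[:, :1]
    P = Xc - t @ (t.T @ Xc) / float((t.T @ t)[0, 0])
    assert np.allclose(Xr - Xr.mean(0), P, atol=1e-6)


def independent_cooks(X, y, n_components=1):
    """Plain-loop leave-one-out oracle following the printed definition."""
    n = len(X)
    full = pls_fit(X, y, n_components)
    yhat = full.predict(X)
    mse = np.mean((y - yhat)**2)
    p = n_components + 1
    D = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = pls_fit(X[keep], y[keep], n_components)
        D[i] = np.sum((yhat - sub.predict(X))**2) / (p * mse)
    return D


def test_cooks_matches_independent_loo_oracle(rng):
    X = rng.normal(size=(9, 4))
    y = X[:, 0] + 0.5 * rng.normal(size=9)
    rep = cooks_flag(X, y)
    assert np.allclose(rep.distances, independent_cooks(X, y))
    assert rep.threshold == pytest.approx(4 * rep.distances.mean())


def test_cooks_flags_planted_outlier(rng):
    X = rng.normal(size=(10, 3))
    y = X[:, 0] + 0.05 * rng.normal(size=10)
    y[4] += 10 * y.std()
    rep = cooks_flag(X, y)
    assert rep.flagged == [4]


def test_cooks_no_flags_for_exact_linear(rng):
    # with enough components the fit is exact; all distances collapse to ~0
    X = rng.normal(size=(8, 3))
    y = X @ np.array([1.0, -2.0, 0.5])
    rep = cooks_flag(X, y, n_components=3)
    assert rep.flagged == []
    assert np.abs(rep.distances).max() < 1e-6


def test_cooks_invariant_to_response_scaling_and_shift(rng):
    X = rng.normal(size=(10, 3))
    y = X[:, 0] + 0.2 * rng.normal(size=10)
    y[2] += 8 * y.std()
    base = cooks_flag(X, y)
    assert cooks_flag(X, 3.0 * y).flagged == base.flagged
    assert cooks_flag(X, y + 42.0).flagged == base.flagged


def test_correlate_linear_pearson(rng):
    a = rng.normal(size=20)
    rep = correlate(a, 2 * a + 1)
    assert rep.method == "pearson"
    assert rep.coefficient == pytest.approx(1.0)


def test_correlate_monotone_heavy_tail_kendall(rng):
    a = rng.standard_t(df=1, size=30)   # heavy-tailed
    rep = correlate(a, np.exp(np.clip(a, -20, 20)))
    assert rep.method == "kendall"
    assert rep.coefficient == pytest.approx(1.0)


def test_correlate_constant_errors():
    with pytest.raises(ValueError):
        correlate(np.ones(5), np.arange(5.0))


def test_mode_sequence_t0_is_template():
    from arcmorph import atlas as at
    from conftest import make_sphere

    kern = at.KernelParams(6.0, 12.0)
    cohort = [make_sphere(9.0, 1), make_sphere(10.0, 1), make_sphere(11.0, 1)]
    tpl = at.compute_template(cohort, kern, init=cohort[1], max_outer=2,
                              options=at.MatchOptions(max_iter=15))
    mm = at.moment_matrix(tpl)
    y = np.array([9.0, 10.0, 11.0])
    model = pls_fit(mm, y, 1)
    seq = ps.mode_deform_sequence(tpl, model, [0.0])
    assert np.array_equal(seq[0].vertices, tpl.surface.vertices)
    # +/- t gives approximately mirror-symmetric size changes in the linear regime
    lo, hi = ps.mode_deform_sequence(tpl, model, [-0.5, 0.5])
    d_lo = tpl.surface.area() - lo.area()
    d_hi = hi.area() - tpl.surface.area()
    assert np.sign(d_lo) == np.sign(d_hi)
    assert d_hi == pytest.approx(d_lo, rel=0.3)
    # size mode: area grows monotonically with t
    areas = [m.area() for m in ps.mode_deform_sequence(tpl, model, [-1.0, 0.0, 1.0])]
    assert areas[0] < areas[1] < areas[2]
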