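"""Shape-mode extraction and response statistics on the moment matrix.

Partial least squares (PLS, NIPALS) extracts *shape modes*: directions in
deformation space most correlated with a response (body surface area,
ejection fraction, ...).  Projecting each subject's deformation onto a mode
yields its *shape vector* entry X_S, a scalar 3D-shape biomarker.  Size
confounding is removed by deflating the size-related rank-one structure
from the predictors (X_resid = X_orig - XS * XL'); influential subjects are
screened with leave-one-out Cook's distances; correlations follow a
Shapiro-Wilk gate between Pearson's r and Kendall's tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .atlas import DeformationField, MomentMatrix, Template, apply_deformation
from .mesh_core import TriangleSurface

__all__ = [
    "PLSModel",
    "ShapeVector",
    "CookReport",
    "CorrelationReport",
    "pls_fit",
    "shape_vector",
    "residualize",
    "cooks_flag",
    "correlate",
    "mode_deform_sequence",
]


@dataclass
class PLSModel:
    """Fitted PLS regression of a response on moment-space predictors."""

    x_weights: np.ndarray           # (P, C)
    x_loadings: np.ndarray          # (P, C)
    x_scores: np.ndarray            # (N, C)
    x_rotations: np.ndarray         # (P, C)
    y_loadings: np.ndarray          # (1, C)
    x_mean: np.ndarray              # (P,)
    y_mean: float
    coef: np.ndarray                # (P,) regression coefficients on centered X
    n_components: int
    explained_shape_variability: np.ndarray   # fraction of ||X_centered||_F^2 per component
    response_name: str = "response"
    moments: MomentMatrix | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return (X - self.x_mean) @ self.coef + self.y_mean

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project rows onto the component score space (x-scores for in-sample rows)."""
        return (np.atleast_2d(X) - self.x_mean) @ self.x_rotations


@dataclass
class ShapeVector:
    """Per-subject scalar projections X_S onto one shape mode."""

    values: np.ndarray
    response_name: str
    component: int = 1
    subject_ids: list[str] = field(default_factory=list)


@dataclass
class CookReport:
    """Leave-one-out influence screen: D_i > 4 * mean(D) flags a subject."""

    distances: np.ndarray
    threshold: float
    flagged: list[int]
    mse: float
    p: int
    n: int
    subject_ids: list[str] = field(default_factory=list)

    @property
    def flagged_ids(self) -> list[str]:
        return [self.subject_ids[i] for i in self.flagged] if self.subject_ids else []


@dataclass
class CorrelationReport:
    """Bivariate association with a normality-gated choice of coefficient."""

    coefficient: float
    p_value: float
    method: str                      # "pearson" | "kendall"
    normality_p: tuple[float, float]
    pearson_r: float
    pearson_p: float
    kendall_tau: float
    kendall_p: float


def _as_rows(X) -> np.ndarray:
    return X.rows if isinstance(X, MomentMatrix) else np.asarray(X, dtype=float)


def pls_fit(X: "MomentMatrix | np.ndarray", y: np.ndarray, n_components: int = 1,
            response_name: str = "response") -> PLSModel:
    """Fit a NIPALS PLS regression of ``y`` on the (internally centered) moment rows.

    The explained shape variability of component c is
    ``||xs_c xl_c'||_F^2 / ||X_centered||_F^2``.
    """
    rows = _as_rows(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(rows) < 3:
        raise ValueError("need at least 3 subjects")
    if len(y) != len(rows):
        raise ValueError("response length mismatch")
    if not np.all(np.isfinite(y)):
        raise ValueError("response must be finite")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    rank = np.linalg.matrix_rank(rows - rows.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds predictor rank {rank}")
    est = PLSRegression(n_components=n_components, scale=False).fit(rows, y)
    # canonical mode sign: scores correlate non-negatively with the response
    for c in range(n_components):
        if np.dot(est.x_scores_[:, c], y - y.mean()) < 0:
            for arr in (est.x_scores_, est.x_weights_, est.x_rotations_,
                        est.x_loadings_):
                arr[:, c] *= -1.0
            est.y_loadings_[:, c] *= -1.0
    Xc = rows - rows.mean(axis=0)
    total = float(np.sum(Xc**2))
    expl = np.array([
        float(np.sum(np.outer(est.x_scores_[:, c], est.x_loadings_[:, c])**2)) / total
        for c in range(n_components)
    ])
    return PLSModel(
        x_weights=est.x_weights_, x_loadings=est.x_loadings_,
        x_scores=est.x_scores_, x_rotations=est.x_rotations_,
        y_loadings=est.y_loadings_, x_mean=est._x_mean,
        y_mean=float(np.mean(y)), coef=est.coef_.ravel(),
        n_components=n_components, explained_shape_variability=expl,
        response_name=response_name,
        moments=X if isinstance(X, MomentMatrix) else None,
    )


def shape_vector(model: PLSModel, X: "MomentMatrix | np.ndarray",
                 component: int = 1) -> ShapeVector:
    """Project moment rows onto a fitted mode (1-based component index).

    For the training rows this returns the model's x-scores exactly; new rows
    are centered with the stored mean and projected with the stored rotations.
    """
    if not 1 <= component <= model.n_components:
        raise ValueError("component out of range")
    rows = _as_rows(X)
    if rows.shape[1] != len(model.x_mean):
        raise ValueError("dimension mismatch between model and moment matrix")
    vals = model.transform(rows)[:, component - 1]
    ids = list(X.subject_ids) if isinstance(X, MomentMatrix) else []
    return ShapeVector(vals, model.response_name, component, ids)


def residualize(X_orig: MomentMatrix, first_fit: PLSModel) -> MomentMatrix:
    """Deflate the first fit's rank-one structure: X_resid = X_orig - XS XL'.

    Removes the shape features most related to the first response (size/BSA)
    before further mode extraction; the scores of the first fit are orthogonal
    to the residual rows.
    """
    rows = _as_rows(X_orig)
    if len(rows) != len(first_fit.x_scores):
        raise ValueError("model was not fitted on this moment matrix")
    resid = rows - first_fit.x_scores @ first_fit.x_loadings.T
    if isinstance(X_orig, MomentMatrix):
        return MomentMatrix(resid, list(X_orig.subject_ids), X_orig.metric,
                            X_orig.control_points, X_orig.whitener)
    return resid


def cooks_flag(X: "MomentMatrix | np.ndarray", y: np.ndarray,
               n_components: int = 1, p: int | None = None) -> CookReport:
    """Cook's distances from leave-one-out PLS refits.

    ``D_i = sum_j (yhat_j - yhat_j(i))^2 / (p * MSE)`` with ``yhat`` the
    full-data fitted values, ``yhat(i)`` the fitted values of the model
    trained without subject i, ``MSE = (1/n) sum (y - yhat)^2`` and
    ``p = n_components + 1`` coefficients by default.  Subjects with
    ``D_i > 4 * mean(D)`` are flagged.
    """
    rows = _as_rows(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(rows)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    p_eff = p if p is not None else n_components + 1
    full = pls_fit(rows, y, n_components)
    yhat = full.predict(rows)
    # floored so a perfectly fitting model (zero residual) yields zero
    # distances instead of 0/0 noise
    mse = max(float(np.mean((y - yhat)**2)), 1e-12 * float(np.var(y)))
    D = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            sub = pls_fit(rows[mask], y[mask], n_components)
            yhat_i = sub.predict(rows)
            D[i] = float(np.sum((yhat - yhat_i)**2)) / (p_eff * mse)
        except Exception:
            D[i] = np.inf
    threshold = 4.0 * float(np.mean(D[np.isfinite(D)]))
    flagged = [int(i) for i in np.nonzero((D > threshold) | ~np.isfinite(D))[0]]
    ids = list(X.subject_ids) if isinstance(X, MomentMatrix) else []
    return CookReport(D, threshold, flagged, mse, p_eff, n, ids)


def correlate(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> CorrelationReport:
    """Pearson's r, or Kendall's tau when a Shapiro-Wilk test rejects normality.

    Non-normality is assumed if the Shapiro-Wilk test is significant
    (p < ``alpha``) for either variable; p-values are two-tailed and
    unadjusted for multiplicity.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    sw_a = float(stats.shapiro(a).pvalue)
    sw_b = float(stats.shapiro(b).pvalue)
    pr = stats.pearsonr(a, b)
    kt = stats.kendalltau(a, b)
    if sw_a < alpha or sw_b < alpha:
        method, coef, pval = "kendall", float(kt.statistic), float(kt.pvalue)
    else:
        method, coef, pval = "pearson", float(pr.statistic), float(pr.pvalue)
    return CorrelationReport(coef, pval, method, (sw_a, sw_b),
                             float(pr.statistic), float(pr.pvalue),
                             float(kt.statistic), float(kt.pvalue))


def mode_deform_sequence(template: Template, model: PLSModel,
                         t_values: np.ndarray,
                         t_range: tuple[float, float] = (-3.0, 3.0)) -> list[TriangleSurface]:
    """Deform the template along a shape mode.

    For each t, the template flows under momenta ``t * sigma_scores *
    unwhiten(mode loading direction)`` — the deviation from the mean
    deformation along the mode, so t = 0 returns the template itself and
    ``t`` is in units of score standard deviations.
    """
    if model.moments is None:
        raise ValueError("model must be fitted on a MomentMatrix")
    if model.moments.control_points.shape != template.deformations[0].control_points.shape:
        raise ValueError("model and template control points differ")
    sigma = float(np.std(model.x_scores[:, 0]))
    alpha_dir = model.moments.unwhiten(model.x_loadings[:, 0])
    ref = template.deformations[0]
    out = []
    for t in np.asarray(t_values, dtype=float).ravel():
        if not t_range[0] <= t <= t_range[1]:
            warnings.warn(f"t={t} outside configured range {t_range}", stacklevel=2)
        fld = DeformationField.from_initial(ref.control_points,
                                            t * sigma * alpha_dir,
                                            ref.n_time_steps, ref.lambda_v)
        out.append(apply_deformation(template.surface, fld))
    return out
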