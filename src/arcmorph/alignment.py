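"""Rigid alignment of the input cohort.

Two-step scheme: every mesh is first rigidly registered (translation +
rotation only, no scaling — size is deliberately retained and handled later
by size residualization) to an initial reference subject chosen by gross
geometry, then a Generalised-Procrustes-style loop re-aligns the cohort to
successively recomputed templates until the model compactness stops
decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import atlas as _atlas
from .mesh_core import TriangleSurface, point_triangle_distances

__all__ = [
    "RigidTransform",
    "icp_rigid",
    "pick_initial_reference",
    "model_compactness",
    "gpa_align",
    "align_to_reference",
]


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (det R = +1, no scaling or shear)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def quaternion(self) -> np.ndarray:
        """Unit quaternion (w, x, y, z) of the rotation."""
        from scipy.spatial.transform import Rotation
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        return np.array([w, x, y, z])


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cd - R @ cs)


def icp_rigid(moving: TriangleSurface, fixed: TriangleSurface,
              max_iter: int = 50, tol: float = 1e-4) -> tuple[RigidTransform, float]:
    """Iterative closest point: vertex-to-nearest-triangle correspondence + SVD solve.

    Returns the accumulated rigid transform and the final RMS vertex-to-surface
    distance [mm].  RMS never increases between accepted iterations.
    """
    if moving.n_vertices == 0 or fixed.n_vertices == 0:
        raise ValueError("empty mesh")
    pts = moving.vertices.copy()
    total = RigidTransform.identity()
    d, closest = point_triangle_distances(pts, fixed, return_closest=True)
    rms = float(np.sqrt(np.mean(d**2)))
    for _ in range(max_iter):
        if np.allclose(closest.std(axis=0), 0) and len(closest) > 1:
            raise ValueError("degenerate correspondence: all closest points coincide")
        step = _kabsch(pts, closest)
        pts_new = step.apply(pts)
        d, closest_new = point_triangle_distances(pts_new, fixed, return_closest=True)
        rms_new = float(np.sqrt(np.mean(d**2)))
        if rms_new > rms + 1e-12:
            break
        pts, closest = pts_new, closest_new
        total = step.compose(total)
        if rms - rms_new < tol:
            rms = rms_new
            break
        rms = rms_new
    return total, rms


def pick_initial_reference(descriptors: np.ndarray,
                           names: tuple[str, ...] = ("V", "A_surf", "L_CL", "D_med")) -> int:
    """Subject closest to the population centre in z-scored gross-descriptor space.

    ``descriptors`` is (n_subjects, 4) for (V, A_surf, L_CL, D_med).  Columns
    with zero variance are dropped with a warning; ties break to the lowest
    index.
    """
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need >= 2 subjects with descriptor rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptors must be finite")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [names[i] if i < len(names) else str(i)
                   for i in np.nonzero(~keep)[0]]
        warnings.warn(f"zero-variance descriptor(s) dropped: {dropped}", stacklevel=2)
    if not keep.any():
        return 0
    z = (X[:, keep] - mu[keep]) / sd[keep]
    dist = np.linalg.norm(z, axis=1)
    return int(np.argmin(dist))   # argmin returns the first (lowest) index on ties


def model_compactness(X: "_atlas.MomentMatrix | np.ndarray") -> float:
    """Total variance of the deformation model.

    Sum of eigenvalues of the subject covariance of the moment rows —
    equivalently the mean squared deviation of rows from their mean.
    """
    rows = X.rows if hasattr(X, "rows") else np.asarray(X, dtype=float)
    if len(rows) < 2:
        raise ValueError("need >= 2 subjects")
    centered = rows - rows.mean(axis=0)
    return float(np.mean(np.sum(centered**2, axis=1)))


def align_to_reference(surfaces: list[TriangleSurface], reference_index: int,
                       max_iter: int = 50, tol: float = 1e-4):
    """ICP-align every surface to the chosen reference subject."""
    ref = surfaces[reference_index]
    aligned, transforms = [], []
    for i, s in enumerate(surfaces):
        if i == reference_index:
            aligned.append(s.copy())
            transforms.append(RigidTransform.identity())
            continue
        tf, _ = icp_rigid(s, ref, max_iter=max_iter, tol=tol)
        aligned.append(TriangleSurface(tf.apply(s.vertices), s.faces.copy(), s.subject_id))
        transforms.append(tf)
    return aligned, transforms


def gpa_align(surfaces: list[TriangleSurface], atlas_config: dict | None = None,
              max_iter: int = 5, icp_max_iter: int = 30, icp_tol: float = 1e-3):
    """Generalised-Procrustes loop: re-align to successive templates.

    Each round ICP-aligns all meshes to the current template, recomputes the
    template, and evaluates the model compactness; rounds are accepted while
    compactness decreases.  Returns ``(aligned_surfaces, log)`` for the last
    accepted configuration, where ``log`` holds the compactness trace and the
    accepted template.
    """
    if len(surfaces) < 2:
        raise ValueError("need >= 2 surfaces")
    cfg = dict(atlas_config or {})
    kernel = cfg.pop("kernel", None)
    if kernel is None:
        a_min = min(s.area() for s in surfaces)
        kernel = _atlas.estimate_initial_lambdas(a_min, 0.025, 0.25)

    current = [s.copy() for s in surfaces]
    tpl = _atlas.compute_template(current, kernel, **cfg)
    comp = model_compactness(_atlas.moment_matrix(tpl))
    trace = [comp]
    best = (current, tpl)
    for _ in range(max_iter):
        realigned = []
        for s in current:
            tf, _ = icp_rigid(s, tpl.surface, max_iter=icp_max_iter, tol=icp_tol)
            realigned.append(TriangleSurface(tf.apply(s.vertices), s.faces.copy(), s.subject_id))
        tpl_new = _atlas.compute_template(realigned, kernel, **cfg)
        comp_new = model_compactness(_atlas.moment_matrix(tpl_new))
        if comp_new >= comp - 1e-12 * max(abs(comp), 1.0):
            break
        current, tpl, comp = realigned, tpl_new, comp_new
        best = (current, tpl)
        trace.append(comp)
    log = {"compactness_trace": trace, "template": best[1], "n_iterations": len(trace) - 1}
    return best[0], log
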