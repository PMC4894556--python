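"""Seeded generator of aortic-arch-like cohorts with analytic ground truth.

Each synthetic subject is a tube swept along a planar arch centreline: a
straight ascending limb, a semi-elliptic arch of height A and width T, and
a straight descending limb, with circular cross sections whose radius is
modulated by Gaussian "narrowing" bumps (dilated root, transverse and
isthmus narrowings — the hallmarks of repaired aortic coarctation).  At the
population level, overall scale follows a body-surface-area (BSA) covariate
and arch taper/roundness follow an ejection-fraction (EF) covariate through
linear couplings with additive noise, so the statistical structure that the
shape-mode analysis assumes is present by construction and every descriptor
has a known generative value.

Cross sections are deliberately circular: realism is traded for closed-form
ground truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .mesh_core import TriangleSurface, clean_surface, write_surface

__all__ = ["ArchParams", "PopulationSpec", "SubjectRecord",
           "generate_arch", "generate_population"]


@dataclass
class ArchParams:
    """Geometry of one synthetic arch (all lengths mm)."""

    base_radius: float = 9.0
    arch_height_A: float = 45.0
    arch_width_T: float = 60.0
    ascending_length: float = 35.0
    descending_length: float = 80.0
    # name -> (multiplier, arc-length fraction, width fraction of total arc)
    narrowings: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    tortuosity_amplitude: float = 0.0
    section_points: int = 12
    axial_step: float = 12.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (m, pos, w) in self.narrowings.items():
            if not 0 < m <= 1.5:
                raise ValueError(f"narrowing multiplier for {name!r} outside (0, 1.5]")
            if not 0 < pos < 1 or w <= 0:
                raise ValueError(f"invalid narrowing position/width for {name!r}")

    def scaled(self, factor: float) -> "ArchParams":
        return replace(self,
                       base_radius=self.base_radius * factor,
                       arch_height_A=self.arch_height_A * factor,
                       arch_width_T=self.arch_width_T * factor,
                       ascending_length=self.ascending_length * factor,
                       descending_length=self.descending_length * factor)


#: the default pathology pattern: slightly dilated root, transverse and
#: isthmus narrowings
COA_NARROWINGS = {
    "root": (1.15, 0.06, 0.05),
    "transverse": (0.85, 0.45, 0.06),
    "isthmus": (0.75, 0.58, 0.05),
}


@dataclass
class PopulationSpec:
    """Statistical structure of a synthetic cohort."""

    n: int = 12
    bsa_mean: float = 1.6          # m^2
    bsa_sd: float = 0.2
    scale_slope: float = 0.35      # global scale per m^2 of BSA above the mean
    ef_mean: float = 60.0          # %
    ef_sd: float = 8.0
    ef_taper_coeff: float = 0.12   # descending-diameter taper per EF z-score
    ef_roundness_coeff: float = 0.10   # A/T roundness change per EF z-score
    coupling_noise_sd: float = 0.03    # sd of noise added to the couplings
    vertex_noise_sigma: float = 0.15   # mm
    base: ArchParams = field(default_factory=lambda: ArchParams(
        narrowings=dict(COA_NARROWINGS), tortuosity_amplitude=2.0))
    planted_outlier: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 subjects")


@dataclass
class SubjectRecord:
    """One generated subject: mesh, covariates and ground-truth geometry."""

    subject_id: str
    mesh_path: Path | None
    bsa: float
    ef: float
    age: float
    height: float
    params: ArchParams
    surface: TriangleSurface


# ---------------------------------------------------------------------------


def _centreline(p: ArchParams, n_fine: int = 800):
    """Fine centreline polyline and the radius profile along it."""
    a, b = p.arch_width_T / 2.0, p.arch_height_A
    # approximate arc lengths to budget samples
    arch_len = np.pi / 2.0 * (a + b)
    total = p.ascending_length + arch_len + p.descending_length
    n_asc = max(int(n_fine * p.ascending_length / total), 8)
    n_arch = max(int(n_fine * arch_len / total), 16)
    n_desc = max(int(n_fine * p.descending_length / total), 8)
    za = np.linspace(-p.ascending_length, 0.0, n_asc, endpoint=False)
    asc = np.stack([np.full_like(za, -a), np.zeros_like(za), za], axis=1)
    th = np.linspace(0.0, np.pi, n_arch, endpoint=False)
    arch = np.stack([-a * np.cos(th), np.zeros_like(th), b * np.sin(th)], axis=1)
    zd = np.linspace(0.0, -p.descending_length, n_desc + 1)
    desc = np.stack([np.full_like(zd, a), np.zeros_like(zd), zd], axis=1)
    pts = np.vstack([asc, arch, desc])
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    L = arc[-1]
    if p.tortuosity_amplitude > 0:
        # out-of-plane sinusoid, windowed to keep the endpoints in plane
        s = arc / L
        pts[:, 1] += p.tortuosity_amplitude * np.sin(2.5 * np.pi * s) * np.sin(np.pi * s)
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        L = arc[-1]
    radius = np.full(len(pts), p.base_radius)
    for mult, pos, width in p.narrowings.values():
        s = arc / L
        radius *= 1.0 + (mult - 1.0) * np.exp(-0.5 * ((s - pos) / width)**2)
    return pts, radius, arc


def generate_arch(p: ArchParams) -> TriangleSurface:
    """Sweep circular cross sections along the arch centreline.

    Returns an open strip-triangulated tube with exactly two boundary loops;
    the same parameters (including ``seed``) reproduce the mesh bit-exactly.
    """
    pts, radius, arc = _centreline(p)
    n_rings = max(int(round(arc[-1] / p.axial_step)) + 1, 6)
    s_rings = np.linspace(0.0, arc[-1], n_rings)
    C = np.stack([np.interp(s_rings, arc, pts[:, k]) for k in range(3)], axis=1)
    R = np.interp(s_rings, arc, radius)
    # parallel-transport frames
    tangents = np.gradient(C, s_rings, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n0 = np.array([0.0, 1.0, 0.0])
    n0 = n0 - np.dot(n0, tangents[0]) * tangents[0]
    n0 /= np.linalg.norm(n0)
    normals = [n0]
    for i in range(1, n_rings):
        n_prev = normals[-1]
        n_new = n_prev - np.dot(n_prev, tangents[i]) * tangents[i]
        norm = np.linalg.norm(n_new)
        if norm < 1e-9:
            n_new = np.cross(tangents[i], [1.0, 0.0, 0.0])
            norm = np.linalg.norm(n_new)
        normals.append(n_new / norm)
    normals = np.asarray(normals)
    binormals = np.cross(tangents, normals)
    phi = np.linspace(0.0, 2.0 * np.pi, p.section_points, endpoint=False)
    rings = (C[:, None, :]
             + R[:, None, None] * (np.cos(phi)[None, :, None] * normals[:, None, :]
                                   + np.sin(phi)[None, :, None] * binormals[:, None, :]))
    verts = rings.reshape(-1, 3)
    m = p.section_points
    faces = []
    for i in range(n_rings - 1):
        for j in range(m):
            a0 = i * m + j
            a1 = i * m + (j + 1) % m
            b0 = (i + 1) * m + j
            b1 = (i + 1) * m + (j + 1) % m
            faces.append([a0, b0, a1])
            faces.append([a1, b0, b1])
    faces = np.asarray(faces, dtype=np.int64)
    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        verts = verts + rng.normal(0.0, p.noise_sigma, verts.shape)
    return clean_surface(TriangleSurface(verts, faces))


def generate_population(spec: PopulationSpec, out_dir: str | Path | None = None,
                        mesh_format: str = "vtk") -> list[SubjectRecord]:
    """Draw covariates, couple them to geometry, and build the cohort.

    BSA drives a global scale factor; EF (as a z-score) drives the
    descending-aorta taper and the arch A/T roundness.  When ``out_dir`` is
    given, meshes and a ``manifest.csv`` (subject_id, mesh_path, BSA, EF,
    age, height + gt_* ground-truth columns) are written there.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(spec.n):
        bsa = float(rng.normal(spec.bsa_mean, spec.bsa_sd))
        ef = float(rng.normal(spec.ef_mean, spec.ef_sd))
        z_ef = (ef - spec.ef_mean) / spec.ef_sd
        noise = rng.normal(0.0, spec.coupling_noise_sd, size=3) if spec.coupling_noise_sd > 0 else np.zeros(3)
        scale = 1.0 + spec.scale_slope * (bsa - spec.bsa_mean) + noise[0]
        p = spec.base.scaled(max(scale, 0.3))
        # high EF -> rounded arch (lower A, wider T) and descending taper
        p = replace(p,
                    arch_height_A=p.arch_height_A * (1.0 - spec.ef_roundness_coeff * z_ef + noise[1]),
                    arch_width_T=p.arch_width_T * (1.0 + spec.ef_roundness_coeff * z_ef - noise[1]),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    noise_sigma=spec.vertex_noise_sigma)
        narrowings = dict(p.narrowings)
        desc_mult = 1.0 - spec.ef_taper_coeff * z_ef + noise[2]
        narrowings["descending"] = (float(np.clip(desc_mult, 0.4, 1.5)), 0.85, 0.12)
        p = replace(p, narrowings=narrowings)
        outlier = spec.planted_outlier and i == spec.n - 1
        if outlier:
            # overly large, highly gothic arch with poor function
            p = p.scaled(1.45)
            p = replace(p, arch_height_A=p.arch_height_A * 1.5,
                        arch_width_T=p.arch_width_T * 0.7)
            ef = spec.ef_mean - 5.0 * spec.ef_sd
        surf = generate_arch(p)
        sid = f"S{i + 1:02d}"
        surf.subject_id = sid
        height = float(1000.0 * (0.6 + 0.65 * bsa) + rng.normal(0, 20))
        age = float(np.clip(11.0 + 9.0 * (bsa - spec.bsa_mean + spec.bsa_sd) /
                            (2 * spec.bsa_sd) + rng.normal(0, 1.0), 8.0, 25.0))
        path = None
        if out_dir is not None:
            path = write_surface(surf, out_dir / f"{sid}.{mesh_format}")
        records.append(SubjectRecord(sid, path, bsa, ef, age, height, p, surf))
    if out_dir is not None:
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "mesh_path", "BSA", "EF", "age", "height",
                        "gt_base_radius", "gt_arch_height_A", "gt_arch_width_T",
                        "gt_ascending_length", "gt_descending_length"])
            for r in records:
                w.writerow([r.subject_id, r.mesh_path.name if r.mesh_path else "",
                            f"{r.bsa:.4f}", f"{r.ef:.2f}", f"{r.age:.1f}", f"{r.height:.0f}",
                            f"{r.params.base_radius:.4f}", f"{r.params.arch_height_A:.4f}",
                            f"{r.params.arch_width_T:.4f}", f"{r.params.ascending_length:.4f}",
                            f"{r.params.descending_length:.4f}"])
    return records
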