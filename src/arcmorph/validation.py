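"""Template validation: descriptor deviations and k-fold stability.

A template is accepted as a good mean-shape approximation when the average
absolute deviation of its gross descriptors (V, A_surf, L_CL, D_med) from
the population means stays below 5 %.  K-fold cross-validation re-estimates
the template with subsets left out and measures how far the fold templates
drift from the full-cohort one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import atlas as _atlas
from .mesh_core import TriangleSurface, surface_distance
from .morphometry import GeometricDescriptors

__all__ = ["DeviationReport", "CrossValReport", "template_deviation", "kfold_validate",
           "DEVIATION_PARAMETERS"]

DEVIATION_PARAMETERS = ("V", "A_surf", "L_CL", "D_med")


@dataclass
class DeviationReport:
    """Signed per-parameter deviations of a template from population means [%]."""

    deviations: dict[str, float]          # signed, %
    total: float                          # mean of absolute deviations, %
    passed: bool
    threshold: float = 5.0

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Magnitudes at display precision."""
        out = {k: round(abs(v), ndigits) for k, v in self.deviations.items()}
        out["total"] = round(self.total, ndigits)
        return out


@dataclass
class CrossValReport:
    k: int
    seed: int
    folds: list[list[int]]
    max_distances: list[float]            # fold template vs full template [mm]
    mean_distances: list[float]
    deviation_totals: list[float]         # fold template descriptors vs full [%]
    failed_folds: list[int] = field(default_factory=list)


def _value(desc, name: str) -> float:
    if isinstance(desc, GeometricDescriptors):
        return float(getattr(desc, name))
    return float(desc[name])


def template_deviation(template_desc, population_desc,
                       parameters: tuple[str, ...] = DEVIATION_PARAMETERS,
                       threshold: float = 5.0) -> DeviationReport:
    """Per-parameter deviation (x - xbar)/xbar * 100 % of the template.

    ``population_desc`` is a list of per-subject descriptor sets; the overall
    deviation is the mean of absolute per-parameter values, compared against
    the pass threshold (default 5 %).
    """
    if not population_desc:
        raise ValueError("empty population")
    devs: dict[str, float] = {}
    for name in parameters:
        xbar = float(np.mean([_value(d, name) for d in population_desc]))
        if xbar == 0:
            raise ZeroDivisionError(f"zero population mean for {name}")
        x = _value(template_desc, name)
        devs[name] = (x - xbar) / xbar * 100.0
    total = float(np.mean([abs(v) for v in devs.values()]))
    return DeviationReport(devs, total, total < threshold, threshold)


def make_folds(n: int, k: int, seed: int) -> list[list[int]]:
    """Seeded random partition into k folds with sizes differing by <= 1."""
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [sorted(int(i) for i in fold) for fold in np.array_split(perm, k)]


def kfold_validate(surfaces: list[TriangleSurface], kernel: "_atlas.KernelParams",
                   k: int = 10, seed: int = 0,
                   full_template: "_atlas.Template | None" = None,
                   descriptor_fn=None,
                   atlas_config: dict | None = None) -> CrossValReport:
    """Leave-a-subset-out stability of the template.

    The cohort is partitioned into ``k`` seeded random folds (``k = n`` is
    leave-one-out); each fold's subjects are removed, the template is
    re-estimated with the same kernel/config, and its surface distance to the
    full-cohort template is recorded.  When ``descriptor_fn`` (surface ->
    GeometricDescriptors-like) is given, fold-vs-full descriptor deviation
    totals are reported as well.  Alignment is reused from the input surfaces;
    folds that fail to converge are marked and skipped.
    """
    n = len(surfaces)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    cfg = dict(atlas_config or {})
    folds = make_folds(n, k, seed)
    if full_template is None:
        full_template = _atlas.compute_template(surfaces, kernel, **cfg)
    full_desc = descriptor_fn(full_template.surface) if descriptor_fn else None
    max_d, mean_d, dev_tot, failed = [], [], [], []
    for fi, fold in enumerate(folds):
        keep = [s for i, s in enumerate(surfaces) if i not in fold]
        try:
            tpl = _atlas.compute_template(keep, kernel, init=full_template.surface, **cfg)
        except Exception:
            failed.append(fi)
            max_d.append(float("nan"))
            mean_d.append(float("nan"))
            dev_tot.append(float("nan"))
            continue
        dmax, dmean = surface_distance(tpl.surface, full_template.surface)
        max_d.append(dmax)
        mean_d.append(dmean)
        if descriptor_fn is not None:
            rep = template_deviation(descriptor_fn(tpl.surface), [full_desc])
            dev_tot.append(rep.total)
        else:
            dev_tot.append(float("nan"))
    return CrossValReport(k, seed, folds, max_d, mean_d, dev_tot, failed)
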