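"""Axial morphological variation metrics within an imaging slab.

Three metrics quantify how much a component (lumen or LRNC) changes along
the slice-select direction inside a slab of a given thickness:

* relative area difference between the slab's top and bottom cross-sections,
* relative non-overlapping area between those same sections, and
* maximum in-plane centroid shift (LRNC only — the models are aligned on the
  luminal centroid, so the lumen shift is zero by construction).

Relative quantities are normalised by the mean of the two areas, which makes
both pairwise metrics symmetric in top/bottom and bounded by [0, 2].
Undefined cases (both areas zero, component absent) return NaN with a
warning rather than raising.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import CrossSection, PlaqueModel3D


def _component_region(cs: CrossSection, component: str):
    if component == "lumen":
        return cs.lumen.polygon
    if component == "lrnc":
        return cs.lrnc_region()
    raise ValueError(f"axial metrics are defined for lumen/lrnc, not {component!r}")


def relative_area_difference(top: CrossSection, bottom: CrossSection,
                             component: str) -> float:
    """|A_top - A_bottom| / mean(A_top, A_bottom)."""
    a, b = _component_region(top, component).area, _component_region(bottom, component).area
    mean = 0.5 * (a + b)
    if mean == 0:
        warnings.warn(f"{component} absent in both sections; metric undefined")
        return float("nan")
    return min(abs(a - b) / mean, 2.0)   # clamp float overshoot at the bound


def relative_nonoverlap(top: CrossSection, bottom: CrossSection,
                        component: str) -> float:
    """(area(union) - area(intersection)) / mean(A_top, A_bottom).

    Computed by exact polygon clipping; equals 2 for disjoint regions.
    """
    pa, pb = _component_region(top, component), _component_region(bottom, component)
    mean = 0.5 * (pa.area + pb.area)
    if mean == 0:
        warnings.warn(f"{component} absent in both sections; metric undefined")
        return float("nan")
    sym = pa.union(pb).area - pa.intersection(pb).area
    return min(sym / mean, 2.0)          # clamp float overshoot at the bound


def max_cog_shift(model: PlaqueModel3D, component: str = "lrnc",
                  z0: float = None, z1: float = None, n_samples: int = 21,
                  endpoints_only: bool = False) -> float:
    """Maximum in-plane centroid shift of the component within the slab.

    Maximised over all sampled z-pairs by default; ``endpoints_only``
    restricts the comparison to the slab top and bottom.
    """
    z0 = model.zmin if z0 is None else z0
    z1 = model.zmax if z1 is None else z1
    zs = np.linspace(z0, z1, n_samples)
    cogs = []
    for z in zs:
        region = _component_region(model.cross_section_at(z), component)
        if region.is_empty or region.area <= 0:
            warnings.warn(f"{component} absent at z={z:.3f}; metric undefined")
            return float("nan")
        c = region.centroid
        cogs.append((c.x, c.y))
    cogs = np.asarray(cogs)
    if endpoints_only:
        return float(np.linalg.norm(cogs[-1] - cogs[0]))
    d = cogs[:, None, :] - cogs[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def axial_variation_report(cohort, slabs=((0.0, 2.0), (0.5, 1.5), (0.75, 1.25)),
                           components=("lumen", "lrnc")) -> pd.DataFrame:
    """Long-format table of the three metrics per model, component and slab."""
    rows = []
    for mid, model in enumerate(cohort):
        for z0, z1 in slabs:
            top = model.cross_section_at(z1)
            bottom = model.cross_section_at(z0)
            for comp in components:
                rows.append((mid, comp, z1 - z0, "rel_area_diff",
                             relative_area_difference(top, bottom, comp)))
                rows.append((mid, comp, z1 - z0, "rel_nonoverlap",
                             relative_nonoverlap(top, bottom, comp)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append((mid, "lrnc", z1 - z0, "max_cog_shift",
                             max_cog_shift(model, "lrnc", z0, z1)))
                rows.append((mid, "lrnc", z1 - z0, "cog_shift_endpoints",
                             max_cog_shift(model, "lrnc", z0, z1, endpoints_only=True)))
    return pd.DataFrame(rows, columns=["model", "component", "slab_mm",
                                       "metric", "value"])
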