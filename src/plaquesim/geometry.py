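"""Synthetic 3D carotid plaque geometries.

A plaque model is a stack of three segmented cross-sections at 1 mm axial
spacing (lumen, outer wall, one or more lipid-rich necrotic cores, LRNC),
aligned on the luminal centroid and interpolated axially with natural cubic
splines of matched contour vertices.  The generator emulates histology-derived
reconstructions: population statistics default to slice-averaged areas of
13.4 mm^2 (lumen), 38.6 mm^2 (vessel wall) and 15.8 mm^2 (LRNC) with a
minimum fibrous-cap thickness of 0.27 mm.

Units are mm throughout; contours are counter-clockwise simple polygons with
the lumen centroid at the in-plane origin of each base section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.stats import truncnorm
from shapely.geometry import Polygon
from shapely.ops import unary_union


class GeometryError(ValueError):
    """Invalid or degenerate plaque geometry."""


class InfeasibleSpecError(GeometryError):
    """Rejection sampling exhausted its attempt budget."""


# --------------------------------------------------------------------------
# Contours
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Contour:
    """Closed planar polygon, counter-clockwise, coordinates in mm."""

    vertices: np.ndarray  # (n, 2)
    closed: bool = True

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("contour needs an (n>=3, 2) vertex array")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def centroid(self) -> np.ndarray:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * np.sum(cross)
        if abs(a) < 1e-14:
            return self.vertices.mean(axis=0)
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def translated(self, dxy) -> "Contour":
        return Contour(self.vertices + np.asarray(dxy, dtype=float))

    def validate(self, min_vertices: int = 16) -> None:
        if len(self.vertices) < min_vertices:
            raise GeometryError(f"contour has {len(self.vertices)} < {min_vertices} vertices")
        if self.area <= 0:
            raise GeometryError("contour is not counter-clockwise / has non-positive area")
        p = Polygon(self.vertices)
        if not p.is_valid or not p.is_simple:
            raise GeometryError("contour is self-intersecting")

    def resampled(self, n: int) -> "Contour":
        return Contour(resample_closed_curve(self.vertices, n))


def resample_closed_curve(vertices: np.ndarray, n: int) -> np.ndarray:
    """Equal-arc-length resampling of a closed polyline to ``n`` vertices."""
    v = np.asarray(vertices, dtype=float)
    pts = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("degenerate contour (zero perimeter)")
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, pts[:, 0])
    y = np.interp(t, s, pts[:, 1])
    return np.column_stack([x, y])


def match_contours(contours: list[Contour], n_vertices: int = 96) -> list[Contour]:
    """Vertex-match a sequence of contours for axial interpolation.

    Each contour is resampled to ``n_vertices`` by equal arc length and then
    cyclically rotated to minimise total squared vertex displacement relative
    to the previous contour in the sequence.
    """
    out = []
    ref = None
    for c in contours:
        v = resample_closed_curve(c.vertices, n_vertices)
        if ref is not None:
            best, best_cost = 0, np.inf
            for k in range(n_vertices):
                cost = np.sum((np.roll(v, -k, axis=0) - ref) ** 2)
                if cost < best_cost:
                    best, best_cost = k, cost
            v = np.roll(v, -best, axis=0)
        ref = v
        out.append(Contour(v))
    return out


# --------------------------------------------------------------------------
# Cross-sections
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSection:
    """One axial cut: lumen, outer wall and LRNC contours at height ``z``."""

    z: float
    lumen: Contour
    outer_wall: Contour
    lrncs: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "lrncs", tuple(self.lrncs))

    @property
    def lumen_area(self) -> float:
        return self.lumen.area

    @property
    def wall_area(self) -> float:
        """Vessel wall area: outer-wall area minus lumen area (annulus)."""
        return self.outer_wall.area - self.lumen.area

    @property
    def lrnc_area(self) -> float:
        if not self.lrncs:
            return 0.0
        return float(unary_union([c.polygon for c in self.lrncs]).area)

    def lrnc_region(self):
        return unary_union([c.polygon for c in self.lrncs]) if self.lrncs else Polygon()

    def min_cap_gap(self) -> float:
        """Shortest lumen-to-LRNC distance (the minimum fibrous-cap thickness)."""
        if not self.lrncs:
            return math.inf
        lum = self.lumen.polygon
        return min(lum.distance(c.polygon) for c in self.lrncs)

    def component_area(self, component: str) -> float:
        if component == "lumen":
            return self.lumen_area
        if component == "wall":
            return self.wall_area
        if component == "lrnc":
            return self.lrnc_area
        raise ValueError(f"unknown component {component!r}")

    def validate(self, min_gap: float = 0.0) -> None:
        self.lumen.validate()
        self.outer_wall.validate()
        lum, out = self.lumen.polygon, self.outer_wall.polygon
        if not lum.within(out) or lum.exterior.distance(out.exterior) <= 0:
            raise GeometryError("lumen not strictly inside outer wall")
        ring = out.difference(lum)
        for i, c in enumerate(self.lrncs):
            c.validate()
            p = c.polygon
            if not p.within(out.buffer(1e-9)):
                raise GeometryError(f"LRNC {i} not inside outer wall")
            if p.intersection(lum).area > 1e-12:
                raise GeometryError(f"LRNC {i} overlaps the lumen")
            gap = lum.distance(p)
            if gap <= min_gap:
                raise GeometryError(f"LRNC {i} cap gap {gap:.4f} mm not > {min_gap}")
        for i in range(len(self.lrncs)):
            for j in range(i + 1, len(self.lrncs)):
                inter = self.lrncs[i].polygon.intersection(self.lrncs[j].polygon).area
                if inter > 1e-12:
                    raise GeometryError(f"LRNCs {i} and {j} overlap")
        del ring

    def translated(self, dxy) -> "CrossSection":
        return CrossSection(
            self.z,
            self.lumen.translated(dxy),
            self.outer_wall.translated(dxy),
            tuple(c.translated(dxy) for c in self.lrncs),
        )


# --------------------------------------------------------------------------
# Cohort specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Population statistics for the synthetic plaque cohort.

    Defaults are calibrated to the histology-based cohort the pipeline
    emulates: per-component slice-averaged areas (mean, sd, range) and the
    minimum fibrous-cap thickness distribution.
    """

    n_models: int = 8
    lumen_area: tuple = (13.4, 6.6, 5.8, 24.9)     # mean, sd, lo, hi (mm^2)
    wall_area: tuple = (38.6, 11.5, 25.2, 57.4)
    lrnc_area: tuple = (15.8, 9.7, 6.0, 34.6)
    min_fc_thickness: tuple = (0.27, 0.20, 0.10, 0.67)  # mm
    lrnc_count_probs: tuple = ((1, 0.5), (2, 0.5))
    roughness: float = 0.08          # harmonic perturbation amplitude (fraction of radius)
    n_harmonics: int = 8             # highest harmonic order of the perturbation
    axial_area_jitter: float = 0.10  # fractional per-knot area jitter
    lrnc_angle_drift: float = 0.25   # rad sd of per-knot LRNC angular drift
    fc_axial_jitter: float = 0.4     # fractional per-knot widening of the cap gap
    n_vertices: int = 96
    max_attempts: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in ("lumen_area", "wall_area", "lrnc_area"):
            mean, sd, lo, hi = getattr(self, name)
            if mean <= 0 or sd < 0 or not (0 < lo <= hi):
                raise ValueError(f"invalid {name} targets")
        mean, sd, lo, hi = self.min_fc_thickness
        if lo <= 0.05 or mean <= 0.05:
            raise ValueError("min FC thickness targets must exceed 0.05 mm")
        if self.n_models < 0 or self.max_attempts < 1:
            raise ValueError("invalid counts")


def _trunc_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


# --------------------------------------------------------------------------
# Section construction from a parameter set
# --------------------------------------------------------------------------

def _harmonic(theta, coefs, phases):
    out = np.zeros_like(theta)
    for k, (a, p) in enumerate(zip(coefs, phases), start=2):
        out += a * np.cos(k * theta + p)
    m = np.max(np.abs(out))
    return out / m if m > 0 else out


def _sample_section_params(spec: CohortSpec, rng) -> dict:
    """Draw the parameter set that fully determines one cross-section."""
    nh = max(0, spec.n_harmonics - 1)
    counts, probs = zip(*spec.lrnc_count_probs)
    n_lrnc = int(rng.choice(counts, p=np.asarray(probs) / np.sum(probs)))
    wall = _trunc_normal(rng, *spec.wall_area)
    # large cores cannot fit into a thin wall ring; resample the pair jointly
    for _ in range(100):
        lrnc = _trunc_normal(rng, *spec.lrnc_area)
        if lrnc <= 0.55 * wall:
            break
    theta_c = rng.uniform(0, 2 * np.pi)
    params = {
        "lumen_area": _trunc_normal(rng, *spec.lumen_area),
        "wall_area": wall,
        "lrnc_area": lrnc,
        "fc_gap": _trunc_normal(rng, *spec.min_fc_thickness),
        "lumen_aspect": rng.uniform(0.75, 1.0),
        "lumen_rot": rng.uniform(0, 2 * np.pi),
        "lumen_harm": rng.normal(0, 1, nh) * spec.roughness,
        "lumen_phase": rng.uniform(0, 2 * np.pi, nh),
        "wall_ecc": rng.uniform(0.3, 0.6),
        "wall_theta": theta_c,
        "wall_harm": rng.normal(0, 1, nh) * spec.roughness,
        "wall_phase": rng.uniform(0, 2 * np.pi, nh),
        "n_lrnc": n_lrnc,
        "lrnc_theta": theta_c + rng.normal(0, 0.3),
        "lrnc2_gap_extra": rng.uniform(0.2, 0.5),
        "lrnc2_frac": rng.uniform(0.10, 0.20),
        "lrnc2_knots": int(rng.integers(0, 2)),  # 0: all knots, 1: tapered
        "taper_scale": 1.0,
    }
    if n_lrnc > 1:
        hw1 = rng.uniform(1.2, 1.7)
        hw2 = rng.uniform(0.6, 0.9)
        # keep the two angular windows disjoint, including widening headroom
        offset = (hw1 + 0.3) + (hw2 + 0.2) + 0.25 + rng.uniform(0, 0.3)
        params["lrnc2_offset"] = offset * rng.choice([-1.0, 1.0])
        params["lrnc2_halfwidth"] = hw2
        params["lrnc_halfwidth"] = hw1
        params["lrnc_halfwidth_max"] = hw1 + 0.3
        params["lrnc2_halfwidth_max"] = hw2 + 0.2
    else:
        params["lrnc_halfwidth"] = rng.uniform(1.5, 2.2)
        params["lrnc_halfwidth_max"] = 2.8
        params["lrnc2_offset"] = 0.0
        params["lrnc2_halfwidth"] = 0.0
        params["lrnc2_halfwidth_max"] = 0.0
    return params


def _radial_contour(theta, r) -> Contour:
    return Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


def _scale_to_area(theta, shape, target):
    poly = np.column_stack([shape * np.cos(theta), shape * np.sin(theta)])
    a0 = Contour(poly).area
    return shape * math.sqrt(target / a0)


def _crescent(theta_grid_unused, r_l, theta_fn_r, params, theta_c, halfw, gap, area_target,
              rim=0.4, m=48, thickness_scale=None):
    """Build a crescent-shaped LRNC in the wall ring.

    The core occupies the angular window ``theta_c ± halfw``; its inner edge
    sits ``gap`` outside the lumen at the window centre (so the minimum cap
    thickness is controlled), opening up towards the shoulders.
    """
    u = np.linspace(-1.0, 1.0, m)
    # plateau window: full thickness over the central 70% of the angular
    # span, cosine-tapered shoulders (keeps the crescent simple and smooth)
    w = np.where(np.abs(u) <= 0.7, 1.0,
                 np.cos(np.pi * (np.abs(u) - 0.7) / 0.6) ** 2)
    w = 0.02 + 0.98 * w
    th = theta_c + u * halfw
    rl = theta_fn_r["lumen"](th)
    ro = theta_fn_r["outer"](th)
    band = ro - rim - rl - gap
    if np.any(band <= 0.02):
        return None, 0.0
    gap_th = gap + (1.0 - w) * 0.15 * band
    r_in = rl + gap_th
    avail = ro - rim - r_in

    def build(s):
        d = s * w * avail
        r_out = r_in + d
        pts = np.vstack([
            np.column_stack([r_in * np.cos(th), r_in * np.sin(th)]),
            np.column_stack([r_out[::-1] * np.cos(th[::-1]), r_out[::-1] * np.sin(th[::-1])]),
        ])
        c = Contour(pts) if Contour(pts).area > 0 else Contour(pts[::-1])
        return c

    if thickness_scale is not None:
        return build(thickness_scale), thickness_scale
    a_max = build(1.0).polygon.area
    if a_max < area_target:
        return None, 0.0
    s = brentq(lambda s_: build(s_).polygon.area - area_target, 1e-4, 1.0, xtol=1e-10)
    return build(s), s


def _build_section(spec: CohortSpec, params: dict, z: float) -> CrossSection:
    n = spec.n_vertices
    theta = 2 * np.pi * np.arange(n) / n

    # lumen: perturbed ellipse scaled to the exact target area
    e = params["lumen_aspect"]
    er = 1.0 / np.sqrt(
        (np.cos(theta - params["lumen_rot"]) / 1.0) ** 2
        + (np.sin(theta - params["lumen_rot"]) / e) ** 2
    )
    pert = _harmonic(theta, params["lumen_harm"], params["lumen_phase"])
    shape_l = er * (1.0 + spec.roughness * pert) if len(params["lumen_harm"]) else er
    r_l = _scale_to_area(theta, shape_l, params["lumen_area"])

    # wall ring: eccentric thickness (plaque burden on one side), scaled so the
    # annulus area matches the target
    tshape = (1.0 + params["wall_ecc"] * np.cos(theta - params["wall_theta"]))
    pert_w = _harmonic(theta, params["wall_harm"], params["wall_phase"])
    tshape = tshape * (1.0 + 0.5 * spec.roughness * pert_w) if len(params["wall_harm"]) else tshape
    tshape = np.maximum(tshape, 0.1)

    def ring_area(s):
        return Contour(np.column_stack(
            [(r_l + s * tshape) * np.cos(theta), (r_l + s * tshape) * np.sin(theta)]
        )).area - params["lumen_area"]

    s_hi = 1.0
    while ring_area(s_hi) < params["wall_area"]:
        s_hi *= 2.0
    s_t = brentq(lambda s: ring_area(s) - params["wall_area"], 1e-6, s_hi, xtol=1e-12)
    r_o = r_l + s_t * tshape

    lumen = _radial_contour(theta, r_l)
    outer = _radial_contour(theta, r_o)

    # radial lookup functions (periodic linear interpolation)
    th_ext = np.concatenate([theta, [2 * np.pi]])
    fns = {
        "lumen": lambda t: np.interp(np.mod(t, 2 * np.pi), th_ext, np.append(r_l, r_l[0])),
        "outer": lambda t: np.interp(np.mod(t, 2 * np.pi), th_ext, np.append(r_o, r_o[0])),
    }

    def fit_crescent(theta_c, halfw, halfw_max, gap, target):
        """Build a crescent of the target area, widening the window if needed."""
        hw = halfw
        while True:
            c, _ = _crescent(theta, r_l, fns, params, theta_c, hw, gap, target)
            if c is not None:
                return c
            hw *= 1.12
            if hw > halfw_max:
                return None

    lrncs = []
    frac2 = params["lrnc2_frac"] if params["n_lrnc"] > 1 else 0.0
    main = fit_crescent(params["lrnc_theta"], params["lrnc_halfwidth"],
                        params["lrnc_halfwidth_max"], params["fc_gap"],
                        params["lrnc_area"] * (1.0 - frac2))
    if main is None:
        raise GeometryError("main LRNC does not fit in the wall ring")
    lrncs.append(main)
    if params["n_lrnc"] > 1:
        gap2 = params["fc_gap"] + params["lrnc2_gap_extra"]
        theta2 = params["lrnc_theta"] + params["lrnc2_offset"]
        target2 = params["lrnc_area"] * frac2 * params["taper_scale"]
        sec = fit_crescent(theta2, params["lrnc2_halfwidth"],
                           params["lrnc2_halfwidth_max"], gap2, target2)
        if sec is None and params["taper_scale"] < 1.0:
            # fall back to a directly scaled thin crescent for the taper knot
            sec, _ = _crescent(theta, r_l, fns, params, theta2,
                               params["lrnc2_halfwidth"], gap2, 0.0,
                               thickness_scale=0.02)
        if sec is None:
            raise GeometryError("secondary LRNC does not fit")
        lrncs.append(sec)

    cs = CrossSection(z, lumen, outer, tuple(lrncs))
    cs = cs.translated(-cs.lumen.centroid)
    return cs


def generate_cross_section(spec: CohortSpec, seed: int) -> CrossSection:
    """Generate one valid cross-section from the cohort distributions."""
    spec.validate()
    rng = np.random.default_rng(seed)
    for _ in range(spec.max_attempts):
        try:
            params = _sample_section_params(spec, rng)
            cs = _build_section(spec, params, z=0.0)
            cs.validate()
            return cs
        except GeometryError:
            continue
    raise InfeasibleSpecError(
        f"no valid cross-section after {spec.max_attempts} attempts")


# --------------------------------------------------------------------------
# 3D model
# --------------------------------------------------------------------------

@dataclass
class PlaqueModel3D:
    """Axially interpolated plaque geometry over ``z in [zmin, zmax]`` mm."""

    base_sections: list
    zmin: float = 0.0
    zmax: float = 2.0
    _splines: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_sections(cls, sections, match: bool = False,
                      n_vertices: int = 96) -> "PlaqueModel3D":
        sections = sorted(sections, key=lambda s: s.z)
        if len(sections) < 2:
            raise GeometryError("need at least two sections to interpolate")
        n_lrnc = {len(s.lrncs) for s in sections}
        if len(n_lrnc) != 1:
            raise GeometryError(
                "sections have differing LRNC counts; taper absent cores to "
                "near-zero area before interpolation")
        if match:
            for role in ("lumen", "outer_wall"):
                matched = match_contours([getattr(s, role) for s in sections], n_vertices)
                sections = [replace(s, **{role: m}) for s, m in zip(sections, matched)]
            k = n_lrnc.pop()
            for i in range(k):
                matched = match_contours([s.lrncs[i] for s in sections], n_vertices)
                sections = [replace(s, lrncs=tuple(
                    m if j == i else c for j, c in enumerate(s.lrncs)))
                    for s, m in zip(sections, matched)]
        model = cls(list(sections), sections[0].z, sections[-1].z)
        model._build_splines()
        return model

    def _build_splines(self):
        zs = np.array([s.z for s in self.base_sections])
        self._splines = {}
        for role in ("lumen", "outer_wall"):
            verts = np.stack([getattr(s, role).vertices for s in self.base_sections])
            self._splines[role] = CubicSpline(zs, verts, axis=0, bc_type="natural")
        for i in range(len(self.base_sections[0].lrncs)):
            verts = np.stack([s.lrncs[i].vertices for s in self.base_sections])
            self._splines[("lrnc", i)] = CubicSpline(zs, verts, axis=0, bc_type="natural")

    def cross_section_at(self, z: float) -> CrossSection:
        if not (self.zmin - 1e-9 <= z <= self.zmax + 1e-9):
            raise GeometryError(f"z={z} outside model domain [{self.zmin}, {self.zmax}]")
        z = float(np.clip(z, self.zmin, self.zmax))
        lum = Contour(self._splines["lumen"](z))
        out = Contour(self._splines["outer_wall"](z))
        lrncs = tuple(
            Contour(self._splines[("lrnc", i)](z))
            for i in range(len(self.base_sections[0].lrncs))
        )
        return CrossSection(z, lum, out, lrncs)

    def extract_slab(self, z0: float, z1: float) -> "PlaqueModel3D":
        if not (self.zmin - 1e-9 <= z0 < z1 <= self.zmax + 1e-9):
            raise GeometryError(f"invalid slab bounds ({z0}, {z1})")
        slab = PlaqueModel3D(self.base_sections, max(z0, self.zmin), min(z1, self.zmax))
        slab._splines = self._splines
        return slab

    def slice_averaged_area(self, component: str, z0: float = None,
                            z1: float = None, rtol: float = 1e-4) -> float:
        """Component volume in the slab divided by slab thickness.

        Composite-Simpson quadrature in z, refined by interval doubling until
        the relative change drops below ``rtol``.
        """
        z0 = self.zmin if z0 is None else z0
        z1 = self.zmax if z1 is None else z1
        if not (self.zmin - 1e-9 <= z0 < z1 <= self.zmax + 1e-9):
            raise GeometryError(f"invalid slab bounds ({z0}, {z1})")

        def f(z):
            return self.cross_section_at(z).component_area(component)

        n = 8
        prev = None
        while n <= 1024:
            zs = np.linspace(z0, z1, n + 1)
            vals = np.array([f(z) for z in zs])
            h = (z1 - z0) / n
            integral = h / 3 * (vals[0] + vals[-1] + 4 * vals[1:-1:2].sum()
                                + 2 * vals[2:-1:2].sum())
            avg = integral / (z1 - z0)
            if prev is not None and abs(avg - prev) <= rtol * max(abs(avg), 1e-12):
                return avg
            prev = avg
            n *= 2
        return prev

    def min_fc_thickness(self, z0: float = None, z1: float = None,
                         n_samples: int = 21) -> float:
        """Slab-minimum cap gap over ``n_samples`` equispaced sections."""
        z0 = self.zmin if z0 is None else z0
        z1 = self.zmax if z1 is None else z1
        gaps = [self.cross_section_at(z).min_cap_gap()
                for z in np.linspace(z0, z1, n_samples)]
        return min(gaps)

    def validate(self, n_samples: int = 41) -> None:
        for z in np.linspace(self.zmin, self.zmax, n_samples):
            self.cross_section_at(z).validate()


def generate_plaque_model(spec: CohortSpec, seed: int) -> PlaqueModel3D:
    """Generate one 3D plaque model: three correlated sections, interpolated.

    The middle section (z = 1 mm) carries the sampled cohort parameters; the
    outer knots are bounded jitters of it, so at least one LRNC (the main
    core) persists across the whole axial domain.
    """
    spec.validate()
    master = np.random.default_rng(seed)
    for _ in range(200):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        try:
            mid = _sample_section_params(spec, rng)
            sections = []
            for z in (0.0, 1.0, 2.0):
                p = dict(mid)
                if z != 1.0:
                    jit = 1.0 + np.clip(rng.normal(0, spec.axial_area_jitter), -0.3, 0.3)
                    p["lumen_area"] = mid["lumen_area"] * jit
                    jit = 1.0 + np.clip(rng.normal(0, spec.axial_area_jitter), -0.3, 0.3)
                    p["wall_area"] = mid["wall_area"] * jit
                    jit = 1.0 + np.clip(rng.normal(0, 1.5 * spec.axial_area_jitter), -0.4, 0.4)
                    p["lrnc_area"] = mid["lrnc_area"] * jit
                    p["lrnc_theta"] = mid["lrnc_theta"] + rng.normal(0, spec.lrnc_angle_drift)
                    p["lumen_rot"] = mid["lumen_rot"] + rng.normal(
                        0, 0.4 * spec.lrnc_angle_drift)
                    p["wall_theta"] = mid["wall_theta"] + rng.normal(
                        0, 0.4 * spec.lrnc_angle_drift)
                    # cap gap can only widen away from the mid knot: the sampled
                    # minimum FC thickness is attained within the slab
                    p["fc_gap"] = mid["fc_gap"] * (1.0 + abs(rng.normal(0, spec.fc_axial_jitter)))
                    if mid["n_lrnc"] > 1 and mid["lrnc2_knots"] == 1:
                        p["taper_scale"] = 0.02  # secondary core fades out axially
                sections.append(_build_section(spec, p, z))
            for s in sections:
                s.validate()
            model = PlaqueModel3D.from_sections(sections)
            model.validate()
            # the axial interpolant can undershoot the knot cap gaps; keep
            # the whole model inside the stated cap-thickness range
            if model.min_fc_thickness() < 0.95 * spec.min_fc_thickness[2]:
                raise GeometryError("interpolated cap dips below the "
                                    "population minimum")
            return model
        except GeometryError:
            continue
    raise InfeasibleSpecError("no valid plaque model after 200 attempts")


def generate_cohort(spec: CohortSpec, seed: int = None) -> list:
    """Generate ``spec.n_models`` models with seeds split from the master seed."""
    seed = spec.seed if seed is None else seed
    children = np.random.SeedSequence(seed).spawn(spec.n_models)
    return [generate_plaque_model(spec, int(c.generate_state(1)[0] % (2**31 - 1)))
            for c in children]
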