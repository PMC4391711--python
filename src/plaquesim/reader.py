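"""Automated reader surrogate: threshold segmentation of simulated images.

Stands in for the blinded human reader of the emulated study.  Tissue classes
are separated at midpoint thresholds between the known noiseless class
signals, contours are extracted with subvoxel bilinear iso-contouring
(marching squares) and lightly smoothed.  The surrogate is deterministic, so
error *trends* across protocols are reproducible; absolute error magnitudes
differ from a human reader by construction.

Lipid cores whose fibrous cap is too thin to resolve merge with the lumen
shadow at the LRNC threshold; such cores are recovered by excluding a
one-acquired-voxel guard band around the detected lumen, which is the main
mechanism by which the surrogate overestimates thin caps (as readers do).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import find_contours
from shapely.geometry import Point, Polygon

from .geometry import Contour
from .mri import MRImage, SequenceProtocol, TissueParams, spin_echo_signal


class SegmentationError(RuntimeError):
    """The surrogate could not find the expected structures."""


@dataclass(frozen=True)
class SegParams:
    min_lrnc_voxels: float = 2.0      # minimum core size, in reconstructed voxels
    smooth_window: int = 5            # moving-average window for contours
    presmooth_voxels: float = 0.75    # Gaussian pre-filter sigma, in recon voxels
                                      # (the reader's visual smoothing scales
                                      # with the displayed pixel size)
    lumen_guard_voxels: float = 1.0   # guard band around the lumen, acquired voxels
    n_vertices: int = 96


@dataclass
class Segmentation:
    lumen: Contour
    outer_wall: Contour
    lrncs: list
    protocol: SequenceProtocol | None = None
    seg_params: SegParams | None = None


@dataclass(frozen=True)
class Measurements:
    lumen_area: float
    wall_area: float
    lrnc_area: float
    min_fc_thickness: float  # NaN when no LRNC was found


def _smooth_closed(vertices: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return vertices
    n = len(vertices)
    k = window // 2
    idx = (np.arange(n)[:, None] + np.arange(-k, k + 1)[None, :]) % n
    return vertices[idx].mean(axis=1)


def _contours_at(im: np.ndarray, level: float, fov: float):
    """Closed marching-squares contours at a level, in mm coordinates."""
    n = im.shape[0]
    dx = fov / n
    out = []
    for c in find_contours(im, level):
        if len(c) < 8 or not np.allclose(c[0], c[-1]):
            continue
        xy = np.column_stack([-fov / 2 + c[:-1, 1] * dx, -fov / 2 + c[:-1, 0] * dx])
        poly = Polygon(xy)
        if not poly.is_valid or poly.area <= 0:
            poly = poly.buffer(0)
            if poly.is_empty or poly.geom_type != "Polygon":
                continue
            xy = np.asarray(poly.exterior.coords[:-1])
        out.append((xy, poly))
    return out


def _interior_value(im: np.ndarray, xy: np.ndarray, fov: float) -> float:
    """Mean image value over the polygon's filled pixels (robust to holes
    of other structures nested inside the iso-polygon)."""
    from skimage.draw import polygon as draw_polygon
    n = im.shape[0]
    dx = fov / n
    rr, cc = draw_polygon((xy[:, 1] + fov / 2) / dx, (xy[:, 0] + fov / 2) / dx,
                          shape=im.shape)
    if len(rr) == 0:
        return float("inf")
    return float(im[rr, cc].mean())


def _finalize(poly: Polygon, params: SegParams) -> Contour:
    xy = np.asarray(poly.exterior.coords[:-1])
    from .geometry import resample_closed_curve
    xy = resample_closed_curve(xy, params.n_vertices)
    xy = _smooth_closed(xy, params.smooth_window)
    c = Contour(xy)
    return c if c.area > 0 else Contour(xy[::-1])


def segment_image(image: MRImage, params: TissueParams,
                  protocol: SequenceProtocol,
                  seg_params: SegParams = SegParams()) -> Segmentation:
    """Three-class threshold segmentation with subvoxel iso-contouring."""
    s_fib = spin_echo_signal("fibrous", params, protocol)
    s_lrnc = spin_echo_signal("lrnc", params, protocol)
    s_bg = spin_echo_signal("background", params, protocol)
    t_lumen = 0.5 * s_lrnc              # blood (0) | darkest tissue class
    t_outer = 0.5 * (s_bg + s_fib)      # background muscle | fibrous wall
    t_lrnc = 0.5 * (s_lrnc + s_fib)     # core | fibrous

    sigma_px = seg_params.presmooth_voxels
    im = gaussian_filter(image.data, sigma_px) if sigma_px > 0 else image.data
    fov = image.fov

    # lumen: dark region nearest the image centre (models are lumen-centred)
    dark = [(xy, p) for xy, p in _contours_at(im, t_lumen, fov)
            if _interior_value(im, xy, fov) < t_lumen
            and p.area >= 2 * image.voxel_size ** 2]
    if not dark:
        raise SegmentationError("no lumen-class region found")
    lumen_poly = min(dark, key=lambda t: t[1].centroid.distance(Point(0, 0)))[1]

    # outer wall: largest contour at the wall/background level that encloses
    # the lumen (the iso-polygon spans the whole vessel, lumen included, so
    # interior brightness cannot be probed at a single point)
    bright = [(xy, p) for xy, p in _contours_at(im, t_outer, fov)
              if p.contains(lumen_poly.centroid)
              and p.area > 1.05 * lumen_poly.area]
    if not bright:
        # a core close to the outer boundary can break the bright ring at
        # this threshold; bridge the gap morphologically, as a reader closing
        # the wall outline through the core would
        from scipy.ndimage import binary_closing, binary_fill_holes, \
            binary_opening
        from skimage.morphology import disk
        r_px = max(2, int(round(2.0 * protocol.acquired_voxel / image.voxel_size)))

        def masked_candidates(mask, pre_open=False):
            if pre_open:               # strip isolated noise speckle first
                mask = binary_opening(mask, disk(1))
            mask = binary_fill_holes(binary_closing(mask, disk(r_px)))
            smoothed = gaussian_filter(mask.astype(float), 1.0)
            return [(xy, p) for xy, p in _contours_at(smoothed, 0.5, fov)
                    if p.contains(lumen_poly.centroid)
                    and p.area > 1.05 * lumen_poly.area]

        bright = masked_candidates(im > t_outer)
        if not bright:
            # a wide superficial core erases the bright ring over its whole
            # arc: fall back to the faint core|background contrast, the way
            # a reader traces a barely-visible rim; the tightest enclosing
            # contour is the vessel (larger ones are merged background)
            faint = [c for c in masked_candidates(im > 0.5 * (s_bg + s_lrnc),
                                                  pre_open=True)
                     if c[1].area < 150.0]   # anatomical plausibility bound
            if faint:
                bright = [min(faint, key=lambda t: t[1].area)]
    if not bright:
        raise SegmentationError("no vessel wall region found")
    outer_poly = max(bright, key=lambda t: t[1].area)[1]

    lumen = _finalize(lumen_poly, seg_params)
    outer = _finalize(outer_poly, seg_params)
    lumen_poly, outer_poly = lumen.polygon, outer.polygon
    annulus = outer_poly.difference(lumen_poly)
    guard = seg_params.lumen_guard_voxels * protocol.acquired_voxel
    lumen_guarded = lumen_poly.buffer(guard)
    min_area = seg_params.min_lrnc_voxels * image.voxel_size ** 2

    # cores are searched only inside the wall: everything outside the annulus
    # (background, lumen interior) is painted fibrous-bright first, so the
    # remaining dark blobs at the core|fibrous level are LRNC candidates
    from skimage.draw import polygon as fill_polygon
    n = im.shape[0]
    dx = fov / n
    annulus_mask = np.zeros_like(im, dtype=bool)
    ov = outer_poly.exterior.coords
    rr, cc = fill_polygon((np.array(ov)[:, 1] + fov / 2) / dx,
                          (np.array(ov)[:, 0] + fov / 2) / dx, shape=im.shape)
    annulus_mask[rr, cc] = True
    lv = lumen_poly.exterior.coords
    rr, cc = fill_polygon((np.array(lv)[:, 1] + fov / 2) / dx,
                          (np.array(lv)[:, 0] + fov / 2) / dx, shape=im.shape)
    annulus_mask[rr, cc] = False
    im_wall = np.where(annulus_mask, im, s_fib)

    lrncs = []
    for xy, p in _contours_at(im_wall, t_lrnc, fov):
        # darkness probed over the wall part only: merged candidates are
        # rings around the (bright-painted) lumen interior
        rr, cc = fill_polygon((xy[:, 1] + fov / 2) / dx, (xy[:, 0] + fov / 2) / dx,
                              shape=im.shape)
        inside = annulus_mask[rr, cc]
        if not np.any(inside) or im_wall[rr[inside], cc[inside]].mean() >= t_lrnc:
            continue
        region = p.intersection(annulus)
        if region.distance(lumen_poly) < 0.5 * guard:
            # thin-cap core fused with the lumen shadow: keep what lies
            # outside a one-voxel guard band around the detected lumen
            region = region.difference(lumen_guarded)
        pieces = [region] if region.geom_type == "Polygon" else list(
            getattr(region, "geoms", []))
        for piece in pieces:
            if piece.geom_type != "Polygon" or piece.area < min_area:
                continue
            lrncs.append(_finalize(piece, seg_params))
    lrncs.sort(key=lambda c: -c.area)

    return Segmentation(lumen, outer, lrncs, protocol, seg_params)


def measure(seg: Segmentation) -> Measurements:
    """Areas (shoelace) and minimum lumen-to-core distance from a segmentation."""
    lumen_area = abs(seg.lumen.area)
    wall_area = abs(seg.outer_wall.area) - lumen_area
    if not seg.lrncs:
        return Measurements(lumen_area, wall_area, 0.0, float("nan"))
    from shapely.ops import unary_union
    union = unary_union([c.polygon for c in seg.lrncs])
    lum = seg.lumen.polygon
    min_fc = min(lum.distance(c.polygon) for c in seg.lrncs)
    return Measurements(lumen_area, wall_area, float(union.area), float(min_fc))


def relative_error(measured: float, truth: float) -> float:
    """Signed relative error (measured - truth) / truth; NaN if truth is 0."""
    if truth == 0 or not np.isfinite(truth):
        return float("nan")
    return (measured - truth) / truth
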