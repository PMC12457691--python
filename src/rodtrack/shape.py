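"""Rod-cell morphology descriptors.

From a cell outline the module extracts a medial axis (centerline plus
perpendicular width profile) and computes the curvature-sensitive
descriptors used to compare strains: solidity (area / convex-hull area),
lateral and longitudinal asymmetry (overlap ratio between the two cell
halves on either side of the medial axis, or of the perpendicular at the
cell middle; 1 = perfect symmetry), width variation (SD of the width
profile) and the basic width/length statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.ops import split as shapely_split
from shapely.ops import unary_union
from skimage import measure

from rodtrack.errors import ShapeExtractionError


@dataclass
class CellContour:
    polygon: Polygon
    cell_id: int = 0
    pixel_size: float | None = None


@dataclass
class MedialAxis:
    """Centerline polyline with its perpendicular width profile.

    ``points`` runs pole to pole (first/last rows are the poles); ``widths``
    holds the perpendicular chord length at each interior centerline sample
    (NaN at the poles themselves).
    """

    points: np.ndarray
    widths: np.ndarray
    step_um: float

    @property
    def poles(self) -> np.ndarray:
        return self.points[[0, -1]]

    @property
    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])


@dataclass
class ShapeDescriptors:
    cell_id: int
    solidity: float
    lateral_asymmetry: float
    longitudinal_asymmetry: float
    width_variation_um: float
    mean_width_um: float
    length_um: float


def _as_polygon(contour: CellContour | Polygon) -> Polygon:
    poly = contour.polygon if isinstance(contour, CellContour) else contour
    if not isinstance(poly, Polygon) or poly.is_empty or poly.area <= 0:
        raise ShapeExtractionError("contour must be a non-degenerate simple polygon")
    if not poly.is_valid:
        raise ShapeExtractionError("contour polygon is not simple (self-intersecting)")
    return poly


def _principal_axis(poly: Polygon) -> tuple[np.ndarray, np.ndarray]:
    xy = np.asarray(poly.exterior.coords)[:-1]
    c = xy.mean(axis=0)
    cov = (xy - c).T @ (xy - c)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, np.argmax(evals)]
    return c, u


def _chord_through(poly: Polygon, point: np.ndarray, direction: np.ndarray, reach: float):
    """Intersection chord of the line through `point` along `direction`."""
    d = direction / np.linalg.norm(direction)
    line = LineString([point - d * reach, point + d * reach])
    inter = line.intersection(poly)
    if inter.is_empty:
        return None
    pieces = list(getattr(inter, "geoms", [inter]))
    pieces = [g for g in pieces if isinstance(g, LineString)]
    if not pieces:
        return None
    pt = Point(point)
    best = min(pieces, key=lambda g: g.distance(pt))
    coords = np.asarray(best.coords)
    return coords[0], coords[-1]


def _smooth_polyline(pts: np.ndarray, window: int = 5) -> np.ndarray:
    if len(pts) < window:
        return pts
    kernel = np.ones(window) / window
    out = pts.copy()
    for j in (0, 1):
        out[:, j] = np.convolve(np.pad(pts[:, j], window // 2, mode="edge"), kernel, mode="valid")
    return out


def extract_medial_axis(contour: CellContour | Polygon, step_um: float = 0.05) -> MedialAxis:
    """Centerline and width profile of a rod-shaped cell.

    Midpoints of chords perpendicular to the principal axis are sampled
    every ``step_um`` and smoothed to give a first centerline; widths and
    midpoints are then re-measured perpendicular to the local centerline
    tangent (second pass), and the centerline is extended along its end
    tangents to the cell poles.

    Raises :class:`ShapeExtractionError` for non-simple polygons or cells
    with elongation (length/width) below 1.5.
    """
    poly = _as_polygon(contour)
    c, u = _principal_axis(poly)
    v = np.array([-u[1], u[0]])
    bxy = np.asarray(poly.exterior.coords)[:-1]
    s_all = (bxy - c) @ u
    s_min, s_max = float(s_all.min()), float(s_all.max())
    extent = s_max - s_min
    reach = 2.0 * max(extent, 1.0)

    # first pass: chords perpendicular to the principal axis
    margin = 0.05 * extent
    stations = np.arange(s_min + margin, s_max - margin, step_um)
    mids = []
    for s in stations:
        ch = _chord_through(poly, c + s * u, v, reach)
        if ch is None:
            continue
        mids.append(0.5 * (ch[0] + ch[1]))
    if len(mids) < 5:
        raise ShapeExtractionError("could not sample enough perpendicular chords")
    center = _smooth_polyline(np.asarray(mids), window=7)

    # second pass: widths perpendicular to the local tangent
    tangents = np.gradient(center, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
    pts2, widths = [], []
    for p, t in zip(center, tangents):
        nvec = np.array([-t[1], t[0]])
        ch = _chord_through(poly, p, nvec, reach)
        if ch is None:
            continue
        pts2.append(0.5 * (ch[0] + ch[1]))
        widths.append(float(np.linalg.norm(ch[1] - ch[0])))
    center = _smooth_polyline(np.asarray(pts2), window=5)
    widths = np.asarray(widths)
    if len(center) < 5 or np.any(widths <= 0):
        raise ShapeExtractionError("width profile extraction failed")

    # extend to the poles along the end tangents
    def pole(p: np.ndarray, t: np.ndarray) -> np.ndarray:
        ray = LineString([p, p + t * reach])
        inter = ray.intersection(poly.exterior)
        if inter.is_empty:
            return p
        pieces = getattr(inter, "geoms", [inter])
        cands = []
        for g in pieces:
            cands.extend(np.asarray(g.coords))
        cands = np.asarray(cands)
        return cands[np.argmax(np.linalg.norm(cands - p, axis=1))]

    t0 = center[0] - center[min(4, len(center) - 1)]
    t1 = center[-1] - center[-min(5, len(center))]
    t0 /= max(np.linalg.norm(t0), 1e-12)
    t1 /= max(np.linalg.norm(t1), 1e-12)
    p0, p1 = pole(center[0], t0), pole(center[-1], t1)
    points = np.vstack([p0, center, p1])
    widths_full = np.concatenate([[np.nan], widths, [np.nan]])

    axis = MedialAxis(points=points, widths=widths_full, step_um=step_um)
    mean_w = float(np.nanmean(widths_full))
    if axis.length / mean_w < 1.5:
        raise ShapeExtractionError(
            f"cell is not rod-shaped (elongation {axis.length / mean_w:.2f} < 1.5)"
        )
    return axis


def solidity(contour: CellContour | Polygon) -> float:
    """Polygon area divided by convex-hull area (1 for convex shapes)."""
    poly = _as_polygon(contour)
    return float(poly.area / poly.convex_hull.area)


def _halves_by_curve(poly: Polygon, curve: LineString) -> tuple[Polygon, Polygon]:
    """Split a polygon by a (possibly curved) line into its two sides."""
    pieces = list(shapely_split(poly, curve).geoms)
    if len(pieces) < 2:
        raise ShapeExtractionError("splitting axis does not divide the cell")
    sides: dict[float, list[Polygon]] = {-1.0: [], 1.0: []}
    cxy = np.asarray(curve.coords)
    for g in pieces:
        rp = np.asarray(g.representative_point().coords[0])
        i = int(np.argmin(np.linalg.norm(cxy - rp, axis=1)))
        j = min(i, len(cxy) - 2)
        t = cxy[j + 1] - cxy[j]
        d = rp - cxy[j]
        side = float(np.sign(t[0] * d[1] - t[1] * d[0]))
        if side == 0:
            side = 1.0
        sides[side].append(g)
    if not sides[-1.0] or not sides[1.0]:
        raise ShapeExtractionError(
            f"split produced {len(pieces)} pieces but only one side of the axis"
        )
    a = unary_union(sides[1.0])
    b = unary_union(sides[-1.0])
    return a, b


def _reflect_across_line(geom, point: np.ndarray, direction: np.ndarray):
    """Exact affine reflection across the straight line through `point`."""
    d = direction / np.linalg.norm(direction)
    cos2 = d[0] ** 2 - d[1] ** 2
    sin2 = 2 * d[0] * d[1]
    x0, y0 = point
    # translate to origin, reflect, translate back
    a, b, dd, e = cos2, sin2, sin2, -cos2
    xoff = x0 - a * x0 - b * y0
    yoff = y0 - dd * x0 - e * y0
    return shapely.affinity.affine_transform(geom, [a, b, dd, e, xoff, yoff])


def asymmetry(
    contour: CellContour | Polygon,
    axis: str = "lateral",
    medial: MedialAxis | None = None,
) -> float:
    """Overlap ratio between the two halves of the cell (1 = symmetric).

    * ``lateral``: the cell is split along its (curved) medial axis and one
      half is folded across the straight line through the two poles; a
      straight cell folds exactly onto its other half, a bent cell does not,
      with the overlap shrinking as curvature grows.
    * ``longitudinal``: the cell is split by the perpendicular to the
      centerline at its arclength midpoint and one half is mirrored across
      that straight line.

    The overlap ratio is intersection-over-union of the reflected half with
    the other half, so it is symmetric in the two halves and equals 1
    exactly at perfect symmetry.
    """
    poly = _as_polygon(contour)
    if medial is None:
        medial = extract_medial_axis(contour)
    mean_w = float(np.nanmean(medial.widths))

    if axis == "lateral":
        # extend the medial polyline beyond the poles for a clean split
        pts = medial.points
        t0 = pts[0] - pts[1]
        t1 = pts[-1] - pts[-2]
        t0 /= max(np.linalg.norm(t0), 1e-12)
        t1 /= max(np.linalg.norm(t1), 1e-12)
        curve = np.vstack([pts[0] + t0 * mean_w, pts, pts[-1] + t1 * mean_w])
        half_a, half_b = _halves_by_curve(poly, LineString(curve))
        chord = pts[-1] - pts[0]
        refl = _reflect_across_line(half_a, pts[0], chord)
    elif axis == "longitudinal":
        arclen = medial.arclength
        mid_s = arclen[-1] / 2.0
        i = int(np.searchsorted(arclen, mid_s))
        i = min(max(i, 1), len(medial.points) - 1)
        frac = (mid_s - arclen[i - 1]) / max(arclen[i] - arclen[i - 1], 1e-12)
        mid = medial.points[i - 1] + frac * (medial.points[i] - medial.points[i - 1])
        t = medial.points[i] - medial.points[i - 1]
        t /= max(np.linalg.norm(t), 1e-12)
        n = np.array([-t[1], t[0]])
        reach = medial.length + 2 * mean_w
        curve = np.vstack([mid - n * reach, mid + n * reach])
        half_a, half_b = _halves_by_curve(poly, LineString(curve))
        refl = _reflect_across_line(half_a, mid, n)
    else:
        raise ValueError(f"axis must be 'lateral' or 'longitudinal', got {axis!r}")

    inter = refl.intersection(half_b).area
    union = refl.union(half_b).area
    return float(inter / union)


def width_stats(
    medial: MedialAxis, spacing_um: float | None = None
) -> tuple[float, float, float]:
    """(width_variation, mean_width, length) from a width profile.

    Widths are resampled at ``spacing_um`` along the centerline (default:
    the extraction step) excluding the polar caps — samples closer than
    mean_width/2 to either pole understate the cylinder diameter and are
    dropped. ``width_variation`` is the SD of the remaining widths,
    ``length`` the centerline arclength.
    """
    if spacing_um is None:
        spacing_um = medial.step_um
    arclen = medial.arclength
    ok = ~np.isnan(medial.widths)
    s_known = arclen[ok]
    w_known = medial.widths[ok]
    if len(s_known) < 3:
        raise ShapeExtractionError("medial axis has fewer than 3 width samples")
    total = float(arclen[-1])
    mean_w0 = float(np.mean(w_known))
    s_new = np.arange(0.0, total + spacing_um / 2, spacing_um)
    keep = (s_new >= mean_w0 / 2.0) & (s_new <= total - mean_w0 / 2.0)
    s_new = s_new[keep]
    if len(s_new) < 3:
        raise ShapeExtractionError("fewer than 3 width samples remain after cap exclusion")
    w_new = np.interp(s_new, s_known, w_known)
    return float(np.std(w_new, ddof=1)), float(np.mean(w_new)), total


def describe_contour(contour: CellContour | Polygon, spacing_um: float | None = None) -> ShapeDescriptors:
    """All shape descriptors of one cell contour."""
    poly = _as_polygon(contour)
    cell_id = contour.cell_id if isinstance(contour, CellContour) else 0
    if spacing_um is None and isinstance(contour, CellContour) and contour.pixel_size:
        spacing_um = contour.pixel_size
    medial = extract_medial_axis(poly)
    wv, mw, length = width_stats(medial, spacing_um)
    return ShapeDescriptors(
        cell_id=cell_id,
        solidity=solidity(poly),
        lateral_asymmetry=asymmetry(poly, "lateral", medial),
        longitudinal_asymmetry=asymmetry(poly, "longitudinal", medial),
        width_variation_um=wv,
        mean_width_um=mw,
        length_um=length,
    )


def contours_from_labels(
    label_image: np.ndarray, pixel_size: float, smooth_window: int = 5
) -> list[CellContour]:
    """Cell contours from a label-mask image.

    Each label is outlined by marching squares at the 0.5 level, smoothed by
    a fixed-window moving average and scaled to µm.
    """
    out = []
    for lab in np.unique(label_image):
        if lab == 0:
            continue
        mask = (label_image == lab).astype(float)
        cs = measure.find_contours(mask, 0.5)
        if not cs:
            continue
        c = max(cs, key=len)  # (row, col) vertices
        xy = np.column_stack([c[:, 1], c[:, 0]]) * pixel_size
        xy = _smooth_polyline(xy, window=smooth_window)
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if isinstance(poly, MultiPolygon):
            poly = max(poly.geoms, key=lambda g: g.area)
        out.append(CellContour(polygon=poly, cell_id=int(lab), pixel_size=pixel_size))
    return out


def descriptors_table(contours: list[CellContour], spacing_um: float | None = None) -> pd.DataFrame:
    """Descriptor rows for a list of contours (failures skipped with NaN-free output)."""
    rows = []
    for c in contours:
        d = describe_contour(c, spacing_um)
        rows.append(
            (
                d.cell_id,
                d.solidity,
                d.lateral_asymmetry,
                d.longitudinal_asymmetry,
                d.width_variation_um,
                d.mean_width_um,
                d.length_um,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "solidity",
            "lateral_asymmetry",
            "longitudinal_asymmetry",
            "width_variation_um",
            "mean_width_um",
            "length_um",
        ],
    )
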