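"""Per-point cross-sectional lumen morphometry.

At each centerline point the luminal surface is cut by the plane normal
to the local tangent; the closed intersection loop enclosing the point
is the lumen contour there.  From the contour come the planar metrics:

- area (shoelace), perimeter (edge-length sum)
- minimal / maximal diameter: min and max Feret (caliper) widths of the
  contour's convex hull, by rotating calipers
- min/max diameter ratio
- circularity 4*pi*A / P^2, the isoperimetric ratio (1 for a circle)

Combined with the maximal-inscribed-sphere radius carried by the
centerline and the Frenet curvature/torsion, these make up the nine
per-point morphological features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon

from .centerline import Centerline, branch_tangents, frenet_features
from .segmentation import SurfaceMesh

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "area_mm2", "misr_mm", "min_diameter_mm", "max_diameter_mm",
    "min_max_ratio", "curvature_per_mm", "torsion_per_mm",
    "perimeter_mm", "circularity",
]


class ContourError(ValueError):
    """Raised when no valid lumen contour exists at a point."""


def cross_section_contour(mesh: SurfaceMesh, point, tangent) -> np.ndarray:
    """Planar lumen contour at ``point`` with plane normal ``tangent``.

    Intersects the surface with the plane, keeps the closed loop that
    encloses the point, and returns its vertices counterclockwise in
    in-plane 2D coordinates (mm) centered on the plane origin's
    projection.

    Raises :class:`ContourError` when the plane misses the mesh, the
    intersection is open, or no loop encloses the point.
    """
    point = np.asarray(point, dtype=float)
    tangent = np.asarray(tangent, dtype=float)
    norm = np.linalg.norm(tangent)
    if norm == 0:
        raise ValueError("tangent must be nonzero")
    tangent = tangent / norm

    tm = mesh.as_trimesh()
    section = tm.section(plane_origin=point, plane_normal=tangent)
    if section is None or len(section.entities) == 0:
        raise ContourError("plane does not intersect the surface")

    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tangent)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(tangent, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tangent, e1)

    best = None
    for poly3d in section.discrete:
        closed = np.allclose(poly3d[0], poly3d[-1], atol=1e-9)
        pts2d = np.column_stack([(poly3d - point) @ e1, (poly3d - point) @ e2])
        if closed:
            pts2d = pts2d[:-1]
        if len(pts2d) < 3:
            continue
        if not closed:
            continue
        poly = Polygon(pts2d)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.is_empty or poly.geom_type != "Polygon":
                continue
        if poly.contains(Point(0.0, 0.0)):
            best = pts2d
            break
    if best is None:
        any_open = any(not np.allclose(p[0], p[-1], atol=1e-9) for p in section.discrete)
        if any_open:
            raise ContourError("intersection contour is open (boundary-touching surface)")
        raise ContourError("no intersection loop encloses the point (outside lumen)")

    # enforce counterclockwise orientation
    if _signed_area(best) < 0:
        best = best[::-1]
    return best


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _feret_widths(hull_pts: np.ndarray) -> tuple[float, float]:
    """Min and max caliper widths of a convex polygon (rotating calipers).

    Min Feret is attained with one caliper flush on a hull edge; max
    Feret is the hull diameter (max pairwise vertex distance).
    """
    n = len(hull_pts)
    edges = np.roll(hull_pts, -1, axis=0) - hull_pts
    lengths = np.linalg.norm(edges, axis=1)
    ok = lengths > 0
    normals = np.column_stack([-edges[ok, 1], edges[ok, 0]]) / lengths[ok, None]
    proj = hull_pts @ normals.T                        # (n, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    min_feret = float(widths.min())
    d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(-1)
    max_feret = float(np.sqrt(d2.max()))
    return min_feret, max_feret


def contour_metrics(polygon: np.ndarray) -> dict[str, float]:
    """Planar metrics of a simple closed polygon (vertices, no repeat).

    Returns area, perimeter, min/max Feret diameter, their ratio, and
    circularity 4*pi*A/P^2.  Raises for self-intersecting or degenerate
    polygons.
    """
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[1] != 2 or len(polygon) < 3:
        raise ValueError("polygon must be an (n>=3, 2) vertex array")
    shp = Polygon(polygon)
    if not shp.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    area = abs(_signed_area(polygon))
    if area < 1e-12:
        raise ValueError("polygon area is numerically zero")
    perimeter = float(np.linalg.norm(np.diff(np.vstack([polygon, polygon[:1]]), axis=0),
                                     axis=1).sum())
    hull = ConvexHull(polygon)
    dmin, dmax = _feret_widths(polygon[hull.vertices])
    return {
        "area_mm2": area,
        "perimeter_mm": perimeter,
        "min_diameter_mm": dmin,
        "max_diameter_mm": dmax,
        "min_max_ratio": dmin / dmax,
        "circularity": 4 * np.pi * area / perimeter ** 2,
    }


def _misr_distance_ascent(vertex_tree, mesh: SurfaceMesh, points: np.ndarray,
                          iterations: int = 8, step_frac: float = 0.25) -> np.ndarray:
    """Maximal-inscribed-sphere radius as local max distance to the surface.

    Starting at each centerline point, climb the distance-to-mesh field
    perpendicular to the local tangent; this removes the residual
    sub-voxel offset of the extracted centerline from the true medial
    axis, which would otherwise bias the MISR low by that offset.
    """
    pts = np.asarray(points, dtype=float).copy()
    tan = np.gradient(pts, axis=0)
    tan /= np.maximum(np.linalg.norm(tan, axis=1, keepdims=True), 1e-12)
    d, j = vertex_tree.query(pts)
    step = step_frac * np.median(d) if len(d) else 0.0
    for _ in range(iterations):
        d, j = vertex_tree.query(pts)
        g = pts - np.asarray(mesh.vertices)[j]
        g /= np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-12)
        g -= np.einsum("ij,ij->i", g, tan)[:, None] * tan
        pts += step * g
        step *= 0.8
    d, _ = vertex_tree.query(pts)
    return d


@dataclass
class CrossSectionFeatures:
    """Long-format table of the nine per-point features.

    One row per centerline point: ``branch_id``, ``point_index``,
    ``arclength_mm``, the world coordinates, a ``missing`` flag for
    points where contour extraction failed, then the feature columns.
    """

    table: pd.DataFrame

    def branch(self, branch_id: int) -> pd.DataFrame:
        return self.table[self.table.branch_id == branch_id]

    def valid(self) -> pd.DataFrame:
        return self.table[~self.table.missing]

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def point_features(mesh: SurfaceMesh, cl: Centerline,
                   frenet_window_mm: float = 9.0,
                   max_missing_fraction: float = 0.2,
                   trim_mm: float = 0.0) -> CrossSectionFeatures:
    """Assemble the nine morphological features at every centerline point.

    Contour metrics are measured on the plane normal to the local spline
    tangent; points whose contour extraction fails (e.g. at a bifurcation
    apex, where the cut is non-planar) are recorded with ``missing=True``
    rather than dropped.  A branch with more than ``max_missing_fraction``
    failed points raises a quality error.  ``trim_mm`` ignores (marks
    missing) points within that arclength of either branch end, where the
    tube cap distorts the contour.
    """
    from scipy.spatial import cKDTree

    frenet = frenet_features(cl, window_mm=frenet_window_mm)
    # MISR as distance to the luminal surface (nearest mesh vertex; the
    # vertex lies on the surface so the error is O(edge^2 / 8r)) — consistent
    # with the mesh-derived diameters, unlike the voxel-grid EDT
    vertex_tree = cKDTree(mesh.vertices)
    rows = []
    for b, fr in zip(cl.branches, frenet):
        misr_mesh = _misr_distance_ascent(vertex_tree, mesh, b.points)
        tangents = branch_tangents(b)
        s = b.arclength_mm
        n_missing = 0
        for i in range(len(b)):
            row = {
                "branch_id": b.branch_id, "point_index": i,
                "arclength_mm": s[i],
                "x_mm": b.points[i, 0], "y_mm": b.points[i, 1], "z_mm": b.points[i, 2],
                "misr_mm": misr_mesh[i],
                "curvature_per_mm": fr["curvature_per_mm"][i],
                "torsion_per_mm": fr["torsion_per_mm"][i],
                "missing": False,
            }
            in_trim = trim_mm > 0 and (s[i] < trim_mm or s[-1] - s[i] < trim_mm)
            if in_trim:
                row["missing"] = True
                rows.append(row)
                continue
            try:
                contour = cross_section_contour(mesh, b.points[i], tangents[i])
                row.update(contour_metrics(contour))
            except (ContourError, ValueError) as exc:
                logger.debug("branch %d point %d: %s", b.branch_id, i, exc)
                row["missing"] = True
                n_missing += 1
            rows.append(row)
        n_eval = len(b) - (np.sum((s < trim_mm) | (s[-1] - s < trim_mm)) if trim_mm > 0 else 0)
        if n_eval > 0 and n_missing / n_eval > max_missing_fraction:
            raise ValueError(
                f"branch {b.branch_id}: {n_missing}/{n_eval} contour extractions failed "
                f"(> {max_missing_fraction:.0%}); check segmentation quality")
    table = pd.DataFrame(rows)
    for col in FEATURE_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return CrossSectionFeatures(table=table)
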