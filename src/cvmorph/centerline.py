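"""Branch centerlines: extraction, arc-length resampling, Frenet geometry.

The centerline of a tubular lumen is the locus of centers of maximal
inscribed spheres (MIS).  It is computed here as a minimal-cost path
between user-given endpoints over the foreground voxel graph, with the
step cost inversely weighted by the Euclidean distance transform (EDT):
the cheapest path hugs the ridge of the distance map, i.e. stays
maximally far from the lumen boundary, and the EDT value at each path
point is the maximal-inscribed-sphere radius (MISR).  A gradient ascent
on the smoothed EDT then pulls each path point onto the medial ridge at
sub-voxel precision.

Branches are resampled to a uniform arc-length pitch (default 0.284 mm,
one voxel of a typical high-resolution TOF acquisition) on a cubic-spline
fit, and curvature/torsion come from local-polynomial (Savitzky-Golay)
derivatives of the uniformly sampled curve:
kappa = |r' x r''| / |r'|^3, tau = ((r' x r'') . r''') / |r' x r''|^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .segmentation import SegmentationMask

logger = logging.getLogger(__name__)

DEFAULT_PITCH_MM = 0.284

# 13 half-neighborhood offsets of the 26-connected stencil
_OFFSETS = np.array([(i, j, k)
                     for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                     if (i, j, k) > (0, 0, 0)])


@dataclass
class Branch:
    """One ordered centerline branch with per-point MISR and arclength."""

    points: np.ndarray            # (n, 3) world mm
    misr_mm: np.ndarray           # (n,)
    branch_id: int = 0
    parent: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.misr_mm = np.asarray(self.misr_mm, dtype=float)
        if len(self.points) != len(self.misr_mm):
            raise ValueError("points and misr_mm must have equal length")

    @property
    def arclength_mm(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length_mm(self) -> float:
        return float(self.arclength_mm[-1])

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Centerline:
    """A set of branches forming (part of) the arterial tree."""

    branches: list[Branch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.branches)

    def total_points(self) -> int:
        return sum(len(b) for b in self.branches)

    def all_points(self) -> np.ndarray:
        return np.concatenate([b.points for b in self.branches], axis=0)


# ------------------------------------------------------------- extraction

def _mask_graph(mask: SegmentationMask):
    """Sparse weighted graph over foreground voxels.

    Edge weight = step length / mean boundary distance of the endpoints,
    so minimal-cost paths maximize centeredness per unit length.
    """
    data = mask.data
    spacing = np.asarray(mask.source.spacing_mm)
    dt = ndimage.distance_transform_edt(data, sampling=spacing)

    flat_ids = -np.ones(data.shape, dtype=np.int64)
    coords = np.argwhere(data)
    flat_ids[tuple(coords.T)] = np.arange(len(coords))

    rows, cols, weights = [], [], []
    eps = 0.1 * float(spacing.min())
    for off in _OFFSETS:
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < data.shape), axis=1)
        src = coords[ok]
        dst = shifted[ok]
        dst_id = flat_ids[tuple(dst.T)]
        valid = dst_id >= 0
        src = src[valid]
        dst_id = dst_id[valid]
        src_id = flat_ids[tuple(src.T)]
        step = float(np.linalg.norm(off * spacing))
        d_mean = 0.5 * (dt[tuple(src.T)] + dt[tuple(coords[dst_id].T)])
        w = step / (d_mean + eps)
        rows.append(src_id)
        cols.append(dst_id)
        weights.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    n = len(coords)
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n)).tocsr()
    return graph, coords, flat_ids, dt


def _nearest_mask_voxel(point_mm, mask: SegmentationMask, flat_ids) -> int:
    idx = np.round(mask.source.world_to_index(point_mm)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
        raise ValueError(f"endpoint {np.asarray(point_mm)} lies outside the volume")
    if not mask.data[tuple(idx)]:
        # allow snapping within a 1-voxel shell
        for off in np.concatenate([[(0, 0, 0)], _OFFSETS, -_OFFSETS]):
            j = idx + off
            if np.all(j >= 0) and np.all(j < np.asarray(mask.shape)) and mask.data[tuple(j)]:
                idx = j
                break
        else:
            raise ValueError(f"endpoint {np.asarray(point_mm)} is not inside the mask")
    return int(flat_ids[tuple(idx)])


def _ridge_ascent(points_idx: np.ndarray, dt: np.ndarray,
                  sigma_vox: float = 1.5, iterations: int = 24,
                  step_vox: float = 0.25) -> np.ndarray:
    """Sub-voxel recentering: climb the ridge of the smoothed EDT.

    Each path point moves along the EDT gradient projected perpendicular
    to the local path tangent, so points slide onto the medial ridge
    without drifting along the vessel.  The EDT is Gaussian-smoothed so
    its gradient is well defined across the one-voxel-wide ridge plateau
    of a discrete distance map.
    """
    dts = ndimage.gaussian_filter(dt, sigma_vox)
    grads = np.gradient(dts)
    pts = points_idx.astype(float).copy()
    for _ in range(iterations):
        tan = np.gradient(pts, axis=0)
        tan /= np.maximum(np.linalg.norm(tan, axis=1, keepdims=True), 1e-12)
        g = np.column_stack([ndimage.map_coordinates(gr, pts.T, order=1)
                             for gr in grads])
        g -= np.einsum("ij,ij->i", g, tan)[:, None] * tan
        gmax = np.abs(g).max()
        if gmax < 1e-12:
            break
        pts += step_vox * g / gmax
    return pts


def compute_centerline(mask: SegmentationMask,
                       endpoints: list[tuple[np.ndarray, np.ndarray]]) -> Centerline:
    """Extract one centerline branch per (source, target) world-mm pair.

    The path maximizes distance from the lumen boundary (EDT-weighted
    shortest path); ``misr_mm`` is the EDT value along the path.

    Raises ``ValueError`` for endpoints outside the mask, coincident
    endpoints, or disconnected endpoint pairs.
    """
    if mask.count() == 0:
        raise ValueError("mask is empty")
    graph, coords, flat_ids, dt = _mask_graph(mask)
    spacing = np.asarray(mask.source.spacing_mm)

    node_of = {}
    for k, (src_mm, dst_mm) in enumerate(endpoints):
        if np.allclose(np.asarray(src_mm, float), np.asarray(dst_mm, float)):
            raise ValueError(f"endpoint pair {k}: source and target coincide "
                             "(degenerate single-point branch)")
        node_of[k] = (_nearest_mask_voxel(src_mm, mask, flat_ids),
                      _nearest_mask_voxel(dst_mm, mask, flat_ids))

    branches = []
    by_source: dict[int, list[int]] = {}
    for k, (s, _) in node_of.items():
        by_source.setdefault(s, []).append(k)

    for s, ks in by_source.items():
        dist, pred = dijkstra(graph, directed=False, indices=s, return_predecessors=True)
        for k in ks:
            t = node_of[k][1]
            if not np.isfinite(dist[t]):
                raise ValueError(f"endpoint pair {k}: target not reachable from source "
                                 "(disconnected mask)")
            chain = [t]
            while chain[-1] != s:
                chain.append(int(pred[chain[-1]]))
            chain.reverse()
            vox = coords[chain]
            vox_c = _ridge_ascent(vox, dt)
            pts = mask.source.index_to_world(vox_c)
            misr = ndimage.map_coordinates(dt, vox_c.T, order=1)
            branches.append(Branch(points=pts, misr_mm=misr, branch_id=k))
    branches.sort(key=lambda b: b.branch_id)
    return Centerline(branches=branches)


# ------------------------------------------------------------- resampling

def _branch_spline(branch: Branch, smoothing_mm: float = 0.0, k: int = 3):
    """Arc-length parameterized spline fit of a branch.

    Returns (tck, total_arclength).  ``smoothing_mm`` is the RMS residual
    the fit may leave per point (0 interpolates).
    """
    pts = branch.points
    n = len(pts)
    if n < 2:
        raise ValueError("branch needs at least 2 points")
    s = branch.arclength_mm
    if s[-1] <= 0:
        raise ValueError("branch has zero length")
    u = s / s[-1]
    # collapse duplicate parameters
    keep = np.concatenate([[True], np.diff(u) > 1e-12])
    pts, u = pts[keep], u[keep]
    kk = min(k, len(pts) - 1)
    smooth = len(pts) * smoothing_mm ** 2
    tck, _ = interpolate.splprep(pts.T, u=u, s=smooth, k=kk)
    return tck, float(s[-1])


def resample_centerline(cl: Centerline, pitch_mm: float = DEFAULT_PITCH_MM,
                        smoothing_mm: float = 0.08) -> Centerline:
    """Resample every branch to uniform arc-length pitch on a cubic spline.

    Points sit at exact multiples of ``pitch_mm`` from the branch start,
    so consecutive spacing equals the pitch; a sub-pitch tail beyond the
    last multiple is dropped (the far endpoint is retained only when the
    branch length is an integer number of pitches).  Branches shorter
    than two pitches are dropped with a logged warning.  MISR values are
    re-interpolated at the new arclengths.  ``smoothing_mm`` is the RMS
    residual budget of the spline fit (a small sub-voxel default absorbs
    voxel-path jitter; 0 interpolates exactly).
    """
    if pitch_mm <= 0:
        raise ValueError("pitch_mm must be positive")
    out = []
    for b in cl.branches:
        if b.length_mm < 2 * pitch_mm:
            logger.warning("dropping branch %d: length %.3f mm < 2 x pitch %.3f mm",
                           b.branch_id, b.length_mm, pitch_mm)
            continue
        tck, _ = _branch_spline(b, smoothing_mm=smoothing_mm)
        # accurate arclength via dense sampling of the spline
        u_dense = np.linspace(0, 1, max(20 * len(b), 1000))
        dense = np.column_stack(interpolate.splev(u_dense, tck))
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        s_dense = np.concatenate([[0.0], np.cumsum(seg)])
        total = s_dense[-1]
        n_steps = int(np.floor(total / pitch_mm + 1e-9))
        s_new = np.arange(n_steps + 1) * pitch_mm
        u_new = np.interp(s_new, s_dense, u_dense)
        pts = np.column_stack(interpolate.splev(u_new, tck))
        misr = np.interp(s_new, b.arclength_mm, b.misr_mm)
        out.append(Branch(points=pts, misr_mm=misr, branch_id=b.branch_id,
                          parent=b.parent))
    return Centerline(branches=out)


# ------------------------------------------------------------- Frenet

def frenet_features(cl: Centerline, window_mm: float = 9.0,
                    straight_tol: float = 1e-8):
    """Per-point curvature and torsion by local-polynomial derivatives.

    Each branch must be resampled to uniform pitch (>= 5 points).  A
    quintic Savitzky-Golay filter over a ``window_mm`` arclength window
    supplies the first three derivatives; at the ends the filter's
    polynomial extrapolation acts as a one-sided stencil.  The window
    default recovers 1/R on a noiseless voxelized circle of radius 10 mm
    to well within 1% while suppressing voxel-scale jitter; it should
    stay a few times shorter than the tightest bend of interest.

    Where the curve is locally straight (|r' x r''| below tolerance
    relative to |r'|^3) torsion is reported as 0 and flagged — torsion
    is mathematically undefined at zero curvature.

    Returns a list over branches of dicts with keys ``curvature_per_mm``,
    ``torsion_per_mm`` and ``straight_flag``.
    """
    from scipy.signal import savgol_filter

    results = []
    for b in cl.branches:
        n = len(b)
        if n < 5:
            raise ValueError(f"branch {b.branch_id} has {n} < 5 points; "
                             "resample before computing Frenet features")
        seg = np.diff(b.arclength_mm)
        pitch = float(seg.mean())
        if seg.max() - seg.min() > 0.2 * pitch:
            raise ValueError(f"branch {b.branch_id} is not uniformly sampled; "
                             "run resample_centerline first")
        w = int(round(window_mm / pitch))
        w = min(w if w % 2 else w + 1, n if n % 2 else n - 1)
        w = max(w, 5)
        poly = min(5, w - 1)

        def deriv(order: int) -> np.ndarray:
            return np.column_stack([
                savgol_filter(b.points[:, d], w, poly, deriv=order,
                              delta=pitch, mode="interp")
                for d in range(3)])

        d1, d2, d3 = deriv(1), deriv(2), deriv(3)
        cross = np.cross(d1, d2)
        cross_norm = np.linalg.norm(cross, axis=1)
        speed = np.linalg.norm(d1, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            kappa = cross_norm / speed ** 3
            tau = np.einsum("ij,ij->i", cross, d3) / cross_norm ** 2
        straight = cross_norm < straight_tol * speed ** 3 + 1e-300
        kappa = np.where(np.isfinite(kappa), kappa, 0.0)
        tau = np.where(straight | ~np.isfinite(tau), 0.0, tau)
        results.append({
            "curvature_per_mm": kappa,
            "torsion_per_mm": tau,
            "straight_flag": straight,
        })
    return results


def branch_tangents(branch: Branch) -> np.ndarray:
    """Unit tangents along a branch from an interpolating cubic spline."""
    tck, _ = _branch_spline(branch, smoothing_mm=0.0)
    u = branch.arclength_mm / branch.length_mm
    d1 = np.column_stack(interpolate.splev(u, tck, der=1))
    return d1 / np.linalg.norm(d1, axis=1, keepdims=True)
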