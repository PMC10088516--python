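"""Shared phantom fixtures.

The canonical phantoms (cylinder, torus arc, helix, bifurcation) are run
once per session through the full measurement chain and shared across
test modules; each case bundles the volume, ground truth, mask, surface,
resampled centerline and feature table.
"""

from __future__ import annotations

import numpy as np
import pytest

from cvmorph.centerline import compute_centerline, resample_centerline
from cvmorph.features import point_features
from cvmorph.phantom import TubeSpec, make_tube_phantom
from cvmorph.segmentation import extract_surface, region_grow

SPACING = 0.284


def run_phantom_case(spec: TubeSpec, spacing: float = SPACING, trim_mm: float = 3.0,
                     max_missing_fraction: float = 0.35):
    vol, gt = make_tube_phantom(spec, spacing_mm=spacing)
    mid = gt.centerline_points[len(gt.centerline_points) // 2]
    seed_vox = tuple(np.round(vol.world_to_index(mid)).astype(int))
    mask = region_grow(vol, [seed_vox], lower=50)
    mesh = extract_surface(mask, smoothing_iterations=20)
    if spec.kind == "bifurcation":
        b0 = gt.branch_points(0)
        pairs = [(b0[0], gt.branch_points(1)[-1]), (b0[0], gt.branch_points(2)[-1])]
    else:
        pts = gt.centerline_points
        pairs = [(pts[0], pts[-1])]
    cl_raw = compute_centerline(mask, pairs)
    cl = resample_centerline(cl_raw)
    feats = point_features(mesh, cl, trim_mm=trim_mm,
                           max_missing_fraction=max_missing_fraction)
    return {"spec": spec, "vol": vol, "gt": gt, "mask": mask, "mesh": mesh,
            "cl_raw": cl_raw, "cl": cl, "feats": feats}


@pytest.fixture(scope="session")
def cylinder_case():
    return run_phantom_case(TubeSpec(kind="cylinder", radius_mm=2.0, length_mm=40.0))


@pytest.fixture(scope="session")
def torus_case():
    return run_phantom_case(TubeSpec(kind="torus_arc", radius_mm=2.0,
                                     bend_radius_mm=10.0, arc_angle_rad=np.pi))


@pytest.fixture(scope="session")
def helix_case():
    return run_phantom_case(TubeSpec(kind="helix", radius_mm=1.5, coil_radius_mm=5.0,
                                     pitch_mm=2.0, turns=1.5))


@pytest.fixture(scope="session")
def bifurcation_case():
    return run_phantom_case(TubeSpec(kind="bifurcation", radius_mm=(2.0, 1.5, 1.5),
                                     length_mm=15.0, daughter_length_mm=12.0))


def mid_slice(values: np.ndarray, frac: float = 0.25) -> np.ndarray:
    """Central portion of a per-point array (away from branch ends)."""
    n = len(values)
    return values[int(n * frac): int(n * (1 - frac))]
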