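"""Arterial territory atlas: branch naming, chunk grouping, chunk means.

Centerline points are allocated to named arterial branches (up to 74 in
the shipped atlas) which are grouped into 19 anatomically motivated
"chunks" — e.g. the basilar artery, left/right basal and pial ACA / MCA /
PCA territories, cerebellar and vertebral groups, and the intracranial
ICAs.  Feature means are computed per chunk over all member centerline
points (point-wise, not branch-wise, averaging: a chunk mean is the mean
over the bundle of fine segments it contains).

Branch labeling is semi-automatic: the user marks one seed point per
anatomical branch, and labels propagate to every centerline point along
the centerline connectivity graph (nearest labeled seed by on-tree
distance, ties to the lower branch id).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .centerline import Centerline
from .features import FEATURE_COLUMNS, CrossSectionFeatures

N_CHUNKS_DEFAULT = 19
MAX_BRANCHES = 74


@dataclass
class Atlas:
    """Branch -> chunk partition.

    ``branches``: DataFrame with columns branch_id, branch_name,
    chunk_id, chunk_name.  Every branch belongs to exactly one chunk.
    """

    branches: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.branches
        required = {"branch_id", "branch_name", "chunk_id", "chunk_name"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"atlas table is missing columns {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("atlas table is empty")
        dup = df.branch_id[df.branch_id.duplicated()]
        if len(dup):
            rows = df.index[df.branch_id.isin(dup)].tolist()
            raise ValueError(f"branch_id values {sorted(set(dup))} appear in more than "
                             f"one row (rows {rows}); each branch must map to one chunk")
        if df.branch_name.duplicated().any() or (
                df.groupby("chunk_id").chunk_name.nunique() > 1).any():
            raise ValueError("branch names must be unique and each chunk_id must have "
                             "a single chunk_name")
        by_name = df.groupby("chunk_name").chunk_id.nunique()
        if (by_name > 1).any():
            raise ValueError(f"chunk names reused across ids: "
                             f"{by_name[by_name > 1].index.tolist()}")
        if len(df) > MAX_BRANCHES:
            raise ValueError(f"atlas has {len(df)} branches; at most {MAX_BRANCHES} allowed")

    @property
    def n_chunks(self) -> int:
        return int(self.branches.chunk_id.nunique())

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def chunk_of(self, branch_id: int) -> int:
        row = self.branches[self.branches.branch_id == branch_id]
        if row.empty:
            raise KeyError(f"unknown branch_id {branch_id}")
        return int(row.chunk_id.iloc[0])

    def chunks(self) -> pd.DataFrame:
        return (self.branches.groupby(["chunk_id", "chunk_name"])
                .branch_id.apply(list).reset_index()
                .rename(columns={"branch_id": "member_branch_ids"}))


def load_atlas(path, expected_chunks: int | None = None) -> Atlas:
    """Load and validate an atlas table (CSV with the four required columns).

    Validation failures report offending values and rows.  Pass
    ``expected_chunks`` to additionally require an exact chunk count.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"atlas file {path} is empty") from exc
    atlas = Atlas(branches=df)
    if expected_chunks is not None and atlas.n_chunks != expected_chunks:
        raise ValueError(f"atlas defines {atlas.n_chunks} chunks; "
                         f"expected {expected_chunks}")
    return atlas


def default_atlas() -> Atlas:
    """The shipped 74-branch, 19-chunk atlas (editable CSV in package data)."""
    with importlib.resources.as_file(
            importlib.resources.files("cvmorph.data") / "default_atlas.csv") as p:
        return load_atlas(p, expected_chunks=N_CHUNKS_DEFAULT)


# ----------------------------------------------------------- branch labeling

@dataclass
class BranchAssignment:
    """Per-centerline-branch arrays of atlas branch ids (-1 = unlabeled)."""

    labels: list[np.ndarray]
    unlabeled_points: int = 0

    def flat(self) -> np.ndarray:
        return np.concatenate(self.labels) if self.labels else np.empty(0, int)


def assign_branches(cl: Centerline, seed_labels: list[tuple[int, np.ndarray]],
                    junction_tol_mm: float = 0.5) -> BranchAssignment:
    """Propagate per-branch seed labels to every centerline point.

    ``seed_labels`` holds (atlas branch_id, world-mm seed point) pairs.
    Each seed must lie within the MISR of some centerline point
    (otherwise an error names the seed).  Every point then takes the
    label of the topologically nearest seed: labels spread along the
    centerline graph (consecutive points connected; points of different
    centerline branches within ``junction_tol_mm`` joined, which links
    branches at shared junctions) by geodesic distance, ties to the
    lower branch_id.  Points in islands not reachable from any seed stay
    at -1 and are counted in ``unlabeled_points``.
    """
    if not seed_labels:
        raise ValueError("at least one seed label is required")
    G = nx.Graph()
    nodes = []
    for bi, b in enumerate(cl.branches):
        for i in range(len(b)):
            G.add_node((bi, i))
            nodes.append((bi, i))
        seg = np.linalg.norm(np.diff(b.points, axis=0), axis=1)
        for i in range(len(b) - 1):
            G.add_edge((bi, i), (bi, i + 1), weight=float(seg[i]))
    # join branches at coincident / near-coincident points (junctions)
    all_pts = [(bi, i, cl.branches[bi].points[i]) for bi, i in nodes]
    from scipy.spatial import cKDTree

    coords = np.array([p for _, _, p in all_pts])
    tree = cKDTree(coords)
    for a, bpair in tree.query_pairs(junction_tol_mm):
        na, nb = all_pts[a][:2], all_pts[bpair][:2]
        if na[0] != nb[0]:
            d = float(np.linalg.norm(coords[a] - coords[bpair]))
            G.add_edge(na, nb, weight=d)

    # seeds -> nearest centerline point, must be within that point's MISR
    seed_nodes: dict[tuple[int, int], int] = {}
    for label_id, seed_pt in seed_labels:
        seed_pt = np.asarray(seed_pt, dtype=float)
        d, j = tree.query(seed_pt)
        bi, i = all_pts[j][:2]
        misr = cl.branches[bi].misr_mm[i]
        if d > max(misr, junction_tol_mm):
            raise ValueError(
                f"seed for branch {label_id} at {seed_pt.round(2)} is {d:.2f} mm from "
                f"the nearest centerline point (MISR {misr:.2f} mm); no vessel there")
        node = (bi, i)
        if node in seed_nodes:
            seed_nodes[node] = min(seed_nodes[node], int(label_id))
        else:
            seed_nodes[node] = int(label_id)

    # multi-source Dijkstra; ties broken to the lower branch_id by sorting
    best_dist: dict[tuple[int, int], float] = {}
    best_label: dict[tuple[int, int], int] = {}
    for node, label in sorted(seed_nodes.items(), key=lambda kv: kv[1]):
        dist = nx.single_source_dijkstra_path_length(G, node)
        for n, d in dist.items():
            if n not in best_dist or d < best_dist[n] - 1e-12:
                best_dist[n] = d
                best_label[n] = label

    labels = []
    unlabeled = 0
    for bi, b in enumerate(cl.branches):
        arr = np.full(len(b), -1, dtype=int)
        for i in range(len(b)):
            lab = best_label.get((bi, i), -1)
            arr[i] = lab
            if lab < 0:
                unlabeled += 1

        labels.append(arr)
    return BranchAssignment(labels=labels, unlabeled_points=unlabeled)


def apply_labels(features: CrossSectionFeatures,
                 assignment: BranchAssignment,
                 cl: Centerline) -> pd.DataFrame:
    """Attach an ``atlas_branch_id`` column to a feature table."""
    table = features.table.copy()
    label_of = {}
    for bi, b in enumerate(cl.branches):
        for i, lab in enumerate(assignment.labels[bi]):
            label_of[(b.branch_id, i)] = int(lab)
    table["atlas_branch_id"] = [
        label_of.get((bid, pi), -1)
        for bid, pi in zip(table.branch_id, table.point_index)
    ]
    return table


# ----------------------------------------------------------- chunk summaries

def chunk_means(feature_table: pd.DataFrame, atlas: Atlas,
                exclusions: set[int] | None = None) -> pd.DataFrame:
    """Per-chunk unweighted point means of every feature.

    ``feature_table`` must carry ``atlas_branch_id`` (see
    :func:`apply_labels`).  Points that are missing, unlabeled, or whose
    branch is in ``exclusions`` (e.g. the symptomatic segment) are left
    out of the means.  Chunks with no remaining points are emitted with
    NaN means and point_count 0, never dropped.
    """
    exclusions = set(exclusions or ())
    unknown = exclusions - set(atlas.branches.branch_id)
    if unknown:
        raise ValueError(f"exclusions reference unknown branch ids {sorted(unknown)}")
    if "atlas_branch_id" not in feature_table.columns:
        raise ValueError("feature table has no atlas_branch_id column; "
                         "run apply_labels first")
    usable = feature_table[
        (~feature_table.missing)
        & (feature_table.atlas_branch_id >= 0)
        & (~feature_table.atlas_branch_id.isin(exclusions))
    ]
    merged = usable.merge(atlas.branches[["branch_id", "chunk_id"]],
                          left_on="atlas_branch_id", right_on="branch_id",
                          how="left", suffixes=("", "_atlas"))

    rows = []
    for _, chunk in atlas.chunks().iterrows():
        sub = merged[merged.chunk_id == chunk.chunk_id]
        row = {"chunk_id": int(chunk.chunk_id), "chunk_name": chunk.chunk_name,
               "point_count": int(len(sub)),
               "branch_count": int(sub.atlas_branch_id.nunique())}
        for col in FEATURE_COLUMNS:
            row[col] = float(sub[col].mean()) if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values("chunk_id").reset_index(drop=True)
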