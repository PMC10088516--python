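"""File I/O: NIfTI volumes, DICOM series conversion, VTK-XML polydata, CSV.

NIfTI goes through nibabel; DICOM through pydicom.  Polydata (surface
meshes and centerlines) is written as ASCII ``.vtp`` — the XML flavour of
VTK polydata — which any VTK-based viewer (ParaView, 3D Slicer) opens.
"""

from __future__ import annotations

import os
from typing import Sequence
from xml.sax.saxutils import escape

import nibabel as nib
import numpy as np

from .volume import Volume3D


# ---------------------------------------------------------------- NIfTI

def read_nifti(path: str) -> Volume3D:
    """Load a NIfTI file into a :class:`Volume3D`.

    The affine is decomposed into spacing, origin and an orthonormal
    direction matrix (shear, if any, is discarded with a warning-free
    polar decomposition — TOF-MRA affines are shear-free in practice).
    """
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    aff = img.affine
    M = aff[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    direction = M / spacing
    # nearest orthonormal matrix (polar factor)
    u, _, vt = np.linalg.svd(direction)
    direction = u @ vt
    return Volume3D(data, tuple(spacing), tuple(aff[:3, 3]), direction)


def write_nifti(vol: Volume3D, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(vol.intensities, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, path)


def write_nifti_mask(mask: np.ndarray, like: Volume3D, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), like.affine)
    nib.save(img, path)


# ---------------------------------------------------------------- DICOM

def dicom_series_to_volume(directory: str) -> Volume3D:
    """Stack a single-series directory of 2D DICOM slices into a volume.

    Slices are ordered by ImagePositionPatient along the slice normal;
    spacing is taken from PixelSpacing and inter-slice distance.
    """
    import pydicom

    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {directory}")

    first = slices[0]
    orient = np.asarray(getattr(first, "ImageOrientationPatient",
                                [1, 0, 0, 0, 1, 0]), dtype=float)
    row, col = orient[:3], orient[3:]
    normal = np.cross(row, col)
    slices.sort(key=lambda s: float(
        np.dot(np.asarray(getattr(s, "ImagePositionPatient", [0, 0, 0]), float), normal)))

    arrs = [s.pixel_array.astype(np.float64) for s in slices]
    data = np.stack(arrs, axis=-1)  # (rows, cols, nslices)
    # reorder to (x=col, y=row, z=slice) so axis i follows `row` direction
    data = np.transpose(data, (1, 0, 2))

    ps = [float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0])]
    if len(slices) > 1:
        p0 = np.asarray(slices[0].ImagePositionPatient, float)
        p1 = np.asarray(slices[1].ImagePositionPatient, float)
        dz = float(abs(np.dot(p1 - p0, normal)))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    origin = tuple(np.asarray(getattr(first, "ImagePositionPatient", [0, 0, 0]), float))
    direction = np.column_stack([col, row, normal])
    # spacing order matches axes (col, row, slice)
    return Volume3D(data, (ps[1], ps[0], dz), origin, direction)


def convert_dicom_to_nifti(directory: str, out_path: str) -> Volume3D:
    vol = dicom_series_to_volume(directory)
    write_nifti(vol, out_path)
    return vol


# ---------------------------------------------------------------- VTP

def _fmt(a: np.ndarray) -> str:
    return " ".join(f"{v:.9g}" for v in np.asarray(a).ravel())


def write_vtp_mesh(vertices: np.ndarray, triangles: np.ndarray, path: str,
                   point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a triangle mesh as ASCII VTK-XML PolyData (.vtp)."""
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    n_pts, n_tri = len(vertices), len(triangles)
    offsets = 3 * (np.arange(n_tri) + 1)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "  <PolyData>",
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfVerts="0" NumberOfLines="0" '
        f'NumberOfStrips="0" NumberOfPolys="{n_tri}">',
        _point_data_block(point_data),
        "      <Points>",
        f'        <DataArray type="Float64" NumberOfComponents="3" format="ascii">{_fmt(vertices)}</DataArray>',
        "      </Points>",
        "      <Polys>",
        f'        <DataArray type="Int64" Name="connectivity" format="ascii">{_fmt(triangles)}</DataArray>',
        f'        <DataArray type="Int64" Name="offsets" format="ascii">{_fmt(offsets)}</DataArray>',
        "      </Polys>",
        "    </Piece>",
        "  </PolyData>",
        "</VTKFile>",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_vtp_polylines(branches: Sequence[np.ndarray], path: str,
                        point_data: dict[str, Sequence[np.ndarray]] | None = None) -> None:
    """Write polylines (e.g. centerline branches) as ASCII .vtp.

    ``point_data`` maps array names to one per-point array per branch.
    """
    pts = np.concatenate([np.asarray(b, float) for b in branches], axis=0)
    conn, offsets, start = [], [], 0
    for b in branches:
        n = len(b)
        conn.extend(range(start, start + n))
        start += n
        offsets.append(start)
    pd = None
    if point_data:
        pd = {k: np.concatenate([np.asarray(a, float) for a in v])
              for k, v in point_data.items()}
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "  <PolyData>",
        f'    <Piece NumberOfPoints="{len(pts)}" NumberOfVerts="0" '
        f'NumberOfLines="{len(branches)}" NumberOfStrips="0" NumberOfPolys="0">',
        _point_data_block(pd),
        "      <Points>",
        f'        <DataArray type="Float64" NumberOfComponents="3" format="ascii">{_fmt(pts)}</DataArray>',
        "      </Points>",
        "      <Lines>",
        f'        <DataArray type="Int64" Name="connectivity" format="ascii">{_fmt(np.asarray(conn))}</DataArray>',
        f'        <DataArray type="Int64" Name="offsets" format="ascii">{_fmt(np.asarray(offsets))}</DataArray>',
        "      </Lines>",
        "    </Piece>",
        "  </PolyData>",
        "</VTKFile>",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtp(path: str):
    """Read an ASCII .vtp written by this package.

    Returns ``(points, polys, lines, point_data)`` where ``polys`` is an
    (n, 3) triangle array or None, ``lines`` a list of per-polyline point
    index arrays or None, and ``point_data`` a name -> array dict.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path} is not a VTK-XML PolyData file")

    def arr(parent, name=None):
        for da in parent.findall("DataArray"):
            if name is None or da.get("Name") == name:
                text = (da.text or "").split()
                return np.asarray(text, dtype=float)
        return None

    pts = arr(piece.find("Points")).reshape(-1, 3)
    polys = lines = None
    pel = piece.find("Polys")
    if pel is not None and arr(pel, "connectivity") is not None \
            and len(arr(pel, "connectivity")):
        conn = arr(pel, "connectivity").astype(np.int64)
        offs = arr(pel, "offsets").astype(np.int64)
        polys = np.stack([conn[o - 3:o] for o in offs]) if len(offs) else None
    lel = piece.find("Lines")
    if lel is not None and arr(lel, "connectivity") is not None \
            and len(arr(lel, "connectivity")):
        conn = arr(lel, "connectivity").astype(np.int64)
        offs = arr(lel, "offsets").astype(np.int64)
        lines, start = [], 0
        for o in offs:
            lines.append(conn[start:o])
            start = int(o)
    point_data = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for da in pd_el.findall("DataArray"):
            point_data[da.get("Name")] = np.asarray((da.text or "").split(), dtype=float)
    return pts, polys, lines, point_data


def _point_data_block(point_data: dict[str, np.ndarray] | None) -> str:
    if not point_data:
        return "      <PointData></PointData>"
    rows = ["      <PointData>"]
    for name, arr in point_data.items():
        rows.append(
            f'        <DataArray type="Float64" Name="{escape(name)}" '
            f'format="ascii">{_fmt(np.asarray(arr, float))}</DataArray>')
    rows.append("      </PointData>")
    return "\n".join(rows)
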