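"""VTK polydata I/O for medial surfaces.

Reads and writes triangle meshes with per-vertex scalar arrays in two VTK
dialects: legacy ASCII (``.vtk``) and serial XML PolyData with ascii-encoded
appended-free data (``.vtp``).  Only the subset needed for tract surfaces is
supported: POINTS, POLYGONS/triangle connectivity, and named POINT_DATA
scalar arrays (``radius`` on input; ``fa_mean``, ``rate``, ``plateau_age``,
``sig_model`` etc. on output).  Coordinates are world millimetres.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .surface import MedialSurface

__all__ = ["read_polydata", "write_polydata", "read_surface", "write_surface"]


def read_polydata(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read a VTK polydata file (legacy ASCII or XML .vtp).

    Returns ``(points, triangles, point_data)`` where ``point_data`` maps
    array names to per-vertex float arrays.
    """
    path = Path(path)
    head = path.read_bytes()[:64].lstrip()
    if head.startswith(b"<"):
        return _read_vtp(path)
    return _read_legacy(path)


def _read_legacy(path: Path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    tokens = path.read_text().split()
    pos = 0

    def peek() -> str:
        return tokens[pos].upper()

    points = None
    triangles = None
    point_data: dict[str, np.ndarray] = {}
    n_points = 0
    while pos < len(tokens):
        tok = peek()
        if tok == "POINTS":
            n_points = int(tokens[pos + 1])
            start = pos + 3  # skip dtype token
            flat = np.array(tokens[start : start + 3 * n_points], dtype=float)
            points = flat.reshape(n_points, 3)
            pos = start + 3 * n_points
        elif tok == "POLYGONS":
            n_cells = int(tokens[pos + 1])
            n_ints = int(tokens[pos + 2])
            flat = np.array(tokens[pos + 3 : pos + 3 + n_ints], dtype=np.int64)
            cells, i = [], 0
            while i < n_ints:
                k = flat[i]
                if k != 3:
                    raise ValueError("only triangle polygons are supported")
                cells.append(flat[i + 1 : i + 4])
                i += k + 1
            if len(cells) != n_cells:
                raise ValueError("POLYGONS cell count mismatch")
            triangles = np.array(cells, dtype=np.int64)
            pos += 3 + n_ints
        elif tok == "POINT_DATA":
            pos += 2
        elif tok == "SCALARS":
            name = tokens[pos + 1]
            pos += 4  # SCALARS name dtype [ncomp]; assume 1 component
            if tokens[pos - 1].upper() == "LOOKUP_TABLE":
                pos -= 1  # ncomp was omitted
            if tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            point_data[name] = np.array(tokens[pos : pos + n_points], dtype=float)
            pos += n_points
        elif tok == "FIELD":
            n_arrays = int(tokens[pos + 2])
            pos += 3
            for _ in range(n_arrays):
                name = tokens[pos]
                n_comp, n_tuples = int(tokens[pos + 1]), int(tokens[pos + 2])
                pos += 4
                vals = np.array(tokens[pos : pos + n_comp * n_tuples], dtype=float)
                point_data[name] = vals if n_comp == 1 else vals.reshape(n_tuples, n_comp)
                pos += n_comp * n_tuples
        else:
            pos += 1
    if points is None or triangles is None:
        raise ValueError(f"{path}: no POINTS/POLYGONS found")
    return points, triangles, point_data


def _floats(text: str) -> np.ndarray:
    return np.array((text or "").split(), dtype=float)


def _read_vtp(path: Path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise ValueError(f"{path}: no PolyData Piece")
    pts_el = piece.find("Points/DataArray")
    points = _floats(pts_el.text).reshape(-1, 3)
    conn = _floats(piece.find("Polys/DataArray[@Name='connectivity']").text).astype(np.int64)
    offsets = _floats(piece.find("Polys/DataArray[@Name='offsets']").text).astype(np.int64)
    if not np.all(np.diff(np.concatenate([[0], offsets])) == 3):
        raise ValueError("only triangle polys are supported")
    triangles = conn.reshape(-1, 3)
    point_data = {}
    pd = piece.find("PointData")
    if pd is not None:
        for arr in pd.findall("DataArray"):
            point_data[arr.get("Name")] = _floats(arr.text)
    return points, triangles, point_data


def write_polydata(
    path: str | Path,
    points: np.ndarray,
    triangles: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a triangle mesh with named per-vertex arrays.

    The format is chosen from the suffix: ``.vtp`` → XML, anything else →
    legacy ASCII.  NaN values are written literally (``nan``); VTK readers
    and this module round-trip them.
    """
    path = Path(path)
    points = np.asarray(points, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    point_data = point_data or {}
    if path.suffix == ".vtp":
        _write_vtp(path, points, triangles, point_data)
    else:
        _write_legacy(path, points, triangles, point_data)


def _write_legacy(path, points, triangles, point_data) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "tractmat surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} float",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in points]
    lines.append(f"POLYGONS {len(triangles)} {4 * len(triangles)}")
    lines += ["3 " + " ".join(str(i) for i in t) for t in triangles]
    if point_data:
        lines.append(f"POINT_DATA {len(points)}")
        for name, vals in point_data.items():
            vals = np.asarray(vals, dtype=float)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in vals]
    path.write_text("\n".join(lines) + "\n")


def _write_vtp(path, points, triangles, point_data) -> None:
    root = ET.Element("VTKFile", type="PolyData", version="0.1", byte_order="LittleEndian")
    pd_el = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        pd_el,
        "Piece",
        NumberOfPoints=str(len(points)),
        NumberOfPolys=str(len(triangles)),
    )
    if point_data:
        pdata = ET.SubElement(piece, "PointData")
        for name, vals in point_data.items():
            arr = ET.SubElement(
                pdata, "DataArray", type="Float64", Name=name, format="ascii"
            )
            arr.text = " ".join(f"{v:.9g}" for v in np.asarray(vals, dtype=float))
    pts = ET.SubElement(piece, "Points")
    arr = ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    arr.text = " ".join(f"{v:.9g}" for v in points.ravel())
    polys = ET.SubElement(piece, "Polys")
    conn = ET.SubElement(polys, "DataArray", type="Int64", Name="connectivity", format="ascii")
    conn.text = " ".join(str(i) for i in triangles.ravel())
    offs = ET.SubElement(polys, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = " ".join(str(3 * (i + 1)) for i in range(len(triangles)))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_surface(path: str | Path, tract_name: str = "tract", hemisphere: str = "midline") -> MedialSurface:
    """Load a medial surface; requires a per-vertex ``radius`` array."""
    points, triangles, point_data = read_polydata(path)
    if "radius" not in point_data:
        raise ValueError(f"{path}: missing per-vertex 'radius' array")
    return MedialSurface(points, triangles, point_data["radius"], tract_name, hemisphere)


def write_surface(path: str | Path, surface: MedialSurface, extra: dict[str, np.ndarray] | None = None) -> None:
    """Save a medial surface with its radius field plus optional result arrays."""
    data = {"radius": surface.radius}
    if extra:
        data.update(extra)
    write_polydata(path, surface.vertices, surface.triangles, data)
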