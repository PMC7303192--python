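"""Mesh and result file I/O.

Triangulated surfaces travel as STL (geometry only, via trimesh) or legacy
ASCII VTK PolyData (geometry plus integer/float cell and point data fields —
region labels, material ids, strain fields).  Stent frames are written as
VTK line-element PolyData.  The small legacy-VTK reader/writer lives here so
label fields survive a round trip without any binary dependencies.
"""

from __future__ import annotations

import os

import numpy as np
import trimesh

__all__ = [
    "write_vtk_polydata",
    "read_vtk_polydata",
    "write_anatomy",
    "read_surface",
    "write_stent_vtk",
    "MeshIOError",
]

LABEL_FIELD = "region"  # documented cell-data field name for region labels


class MeshIOError(RuntimeError):
    pass


def write_vtk_polydata(
    path,
    vertices: np.ndarray,
    faces: np.ndarray | None = None,
    lines: np.ndarray | None = None,
    cell_data: dict | None = None,
    point_data: dict | None = None,
    comment: str = "tavisim surface",
) -> None:
    """Legacy ASCII VTK PolyData with optional cell/point data fields."""
    v = np.asarray(vertices, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment[:254] + "\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        np.savetxt(fh, v, fmt="%.9g")
        ncells = 0
        if faces is not None and len(faces):
            f = np.asarray(faces, dtype=np.int64)
            fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
            np.savetxt(fh, np.column_stack([np.full(len(f), 3), f]), fmt="%d")
            ncells = len(f)
        if lines is not None and len(lines):
            l = np.asarray(lines, dtype=np.int64)
            fh.write(f"LINES {len(l)} {3 * len(l)}\n")
            np.savetxt(fh, np.column_stack([np.full(len(l), 2), l]), fmt="%d")
            ncells += len(l)
        if cell_data:
            fh.write(f"CELL_DATA {ncells}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                typ = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
                fh.write(f"SCALARS {name} {typ} 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr.reshape(-1, 1), fmt="%d" if typ == "int" else "%.9g")
        if point_data:
            fh.write(f"POINT_DATA {len(v)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                typ = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
                fh.write(f"SCALARS {name} {typ} 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr.reshape(-1, 1), fmt="%d" if typ == "int" else "%.9g")


def read_vtk_polydata(path) -> dict:
    """Read a legacy ASCII VTK PolyData file written by this package.

    Returns a dict with ``vertices``, ``faces``, ``lines``, ``cell_data``
    and ``point_data``.
    """
    if not os.path.exists(path):
        raise MeshIOError(f"no such file: {path}")
    with open(path) as fh:
        tokens = fh.read().split()
    out = {"vertices": None, "faces": None, "lines": None, "cell_data": {}, "point_data": {}}
    i = 0
    n = len(tokens)

    def take(count):
        nonlocal i
        vals = tokens[i : i + count]
        i += count
        return vals

    try:
        while i < n:
            t = tokens[i].upper()
            if t == "POINTS":
                cnt = int(tokens[i + 1])
                i += 3
                vals = np.array(take(3 * cnt), dtype=float)
                out["vertices"] = vals.reshape(cnt, 3)
            elif t in ("POLYGONS", "LINES"):
                cnt = int(tokens[i + 1])
                total = int(tokens[i + 2])
                i += 3
                vals = np.array(take(total), dtype=np.int64)
                conn = []
                j = 0
                for _ in range(cnt):
                    k = vals[j]
                    conn.append(vals[j + 1 : j + 1 + k])
                    j += 1 + k
                key = "faces" if t == "POLYGONS" else "lines"
                out[key] = np.vstack(conn)
            elif t in ("CELL_DATA", "POINT_DATA"):
                cnt = int(tokens[i + 1])
                i += 2
                bucket = "cell_data" if t == "CELL_DATA" else "point_data"
                while i < n and tokens[i].upper() == "SCALARS":
                    name = tokens[i + 1]
                    typ = tokens[i + 2].lower()
                    i += 3
                    if i + 1 < n and tokens[i].upper() == "1":
                        i += 1  # components
                    if tokens[i].upper() == "LOOKUP_TABLE":
                        i += 2
                    arr = np.array(take(cnt), dtype=int if typ.startswith("int") else float)
                    out[bucket][name] = arr
            else:
                i += 1
    except (ValueError, IndexError) as exc:
        raise MeshIOError(f"corrupt or unsupported VTK file {path}: {exc}") from exc
    if out["vertices"] is None:
        raise MeshIOError(f"corrupt or unsupported VTK file {path}: no POINTS block")
    return out


def write_anatomy(model, path, fmt: str | None = None, logger=None) -> None:
    """Write an anatomy wall surface to STL or labelled VTK.

    STL keeps geometry only (a warning is logged that the region labels are
    dropped); VTK carries the per-element ``region`` field.
    """
    fmt = fmt or ("stl" if str(path).lower().endswith(".stl") else "vtk")
    if fmt == "stl":
        if logger is not None:
            logger.warning("STL is geometry-only: region labels dropped for %s", path)
        mesh = trimesh.Trimesh(
            vertices=model.wall_vertices, faces=model.wall_faces, process=False
        )
        mesh.export(path)
    elif fmt == "vtk":
        write_vtk_polydata(
            path,
            model.wall_vertices,
            faces=model.wall_faces,
            cell_data={LABEL_FIELD: model.wall_regions},
            comment="implantation-site wall with region labels",
        )
    else:
        raise MeshIOError(f"unknown format {fmt!r} (use stl or vtk)")


def read_surface(path, label_field: str = LABEL_FIELD):
    """Read a triangulated surface from STL or legacy VTK.

    Returns (vertices, faces, labels-or-None).
    """
    p = str(path)
    if not os.path.exists(p):
        raise MeshIOError(f"no such file: {p}")
    if p.lower().endswith(".stl"):
        mesh = trimesh.load(p, force="mesh")
        return np.asarray(mesh.vertices), np.asarray(mesh.faces), None
    if p.lower().endswith(".vtk"):
        data = read_vtk_polydata(p)
        labels = data["cell_data"].get(label_field)
        return data["vertices"], data["faces"], labels
    raise MeshIOError(f"unsupported mesh format: {p} (use .stl or .vtk)")


def write_stent_vtk(stent, path, positions: np.ndarray | None = None) -> None:
    """Stent frame as VTK line elements with a per-beam material id."""
    pos = stent.nodes if positions is None else positions
    write_vtk_polydata(
        path,
        pos,
        lines=stent.beams,
        cell_data={"material": np.zeros(len(stent.beams), dtype=np.int64)},
        comment=f"{stent.spec.family} frame, nominal {stent.spec.nominal_size} mm",
    )
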