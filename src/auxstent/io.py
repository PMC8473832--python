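"""Exports: legacy-VTK fields, binary-STL design extrusions, design tables.

The VTK writer/reader speak the legacy ASCII unstructured-grid dialect
(points, hexahedron/quad cells, named point and cell arrays), enough for
ParaView and for round-trip tests.  The STL exporter extrudes the zero
level set of a design to a watertight triangulated solid: marching-squares
polygons per grid cell form the caps, the contour chords and the outer
domain boundary form the side walls.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .levelset import KnotGrid, LevelSetDesign, evaluate_level_set, grid_points

__all__ = [
    "write_vtk",
    "read_vtk",
    "export_fields_vtk",
    "export_plane_vtk",
    "serialize_design",
    "load_design",
    "export_design_stl",
]

_VTK_CELL_TYPES = {8: 12, 4: 9}  # nodes-per-cell -> VTK hexahedron / quad


def write_vtk(path, points, cells, point_data=None, cell_data=None, title="auxstent fields"):
    """Write a legacy ASCII VTK unstructured grid.

    ``points`` is (n, 3); ``cells`` (m, 4) quads or (m, 8) hexahedra;
    data dicts map names to per-point / per-cell arrays (scalars or
    3-vectors).
    """
    points = np.asarray(points, float)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    cells = np.asarray(cells, int)
    ctype = _VTK_CELL_TYPES[cells.shape[1]]
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(points)} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in p) for p in points]
    npc = cells.shape[1]
    lines.append(f"CELLS {len(cells)} {len(cells) * (npc + 1)}")
    lines += [f"{npc} " + " ".join(map(str, c)) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += [str(ctype)] * len(cells)

    def _data_block(tag, n, data):
        out = [f"{tag} {n}"]
        for name, arr in data.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 2 and arr.shape[1] in (2, 3):
                if arr.shape[1] == 2:
                    arr = np.column_stack([arr, np.zeros(len(arr))])
                out.append(f"VECTORS {name} double")
                out += [" ".join(f"{v:.10g}" for v in row) for row in arr]
            else:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out += [f"{v:.10g}" for v in arr.ravel()]
        return out

    if point_data:
        lines += _data_block("POINT_DATA", len(points), point_data)
    if cell_data:
        lines += _data_block("CELL_DATA", len(cells), cell_data)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Minimal legacy-VTK reader for files written by :func:`write_vtk`."""
    tokens = Path(path).read_text().split("\n")
    i = 0
    out = {"point_data": {}, "cell_data": {}}
    section = None
    while i < len(tokens):
        line = tokens[i].strip()
        parts = line.split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals += [float(v) for v in tokens[i].split()]
                i += 1
            out["points"] = np.array(vals).reshape(n, 3)
            continue
        if key == "CELLS":
            m = int(parts[1])
            cells = []
            i += 1
            for _ in range(m):
                row = [int(v) for v in tokens[i].split()]
                cells.append(row[1:])
                i += 1
            out["cells"] = np.array(cells)
            continue
        if key == "POINT_DATA":
            section = "point_data"
            out["_n"] = int(parts[1])
            i += 1
            continue
        if key == "CELL_DATA":
            section = "cell_data"
            out["_n"] = int(parts[1])
            i += 1
            continue
        if key in ("SCALARS", "VECTORS"):
            name = parts[1]
            n = out["_n"]
            ncomp = 3 if key == "VECTORS" else 1
            i += 1
            if key == "SCALARS":
                i += 1  # LOOKUP_TABLE line
            vals = []
            while len(vals) < ncomp * n:
                vals += [float(v) for v in tokens[i].split()]
                i += 1
            arr = np.array(vals)
            out[section][name] = arr.reshape(n, 3) if ncomp == 3 else arr
            continue
        i += 1
    out.pop("_n", None)
    return out


def export_fields_vtk(sol, domain, path):
    """3D velocity/pressure point fields plus the element fluid fraction."""
    write_vtk(
        path,
        domain.node_coords(),
        domain.connectivity(),
        point_data={"velocity": sol.u, "pressure": sol.p},
        cell_data={"fluid_fraction": domain.Hf, "region": domain.region.astype(float)},
    )


def export_plane_vtk(w2d, nx, path, name="velocity_2d"):
    """Design-plane in-plane velocity on the unit-cell grid."""
    pts = grid_points(nx, nx)
    ex, ey = np.meshgrid(np.arange(nx), np.arange(nx), indexing="ij")
    stride = nx + 1
    n00 = (ex * stride + ey).ravel()
    cells = np.column_stack([n00, n00 + stride, n00 + stride + 1, n00 + 1])
    write_vtk(path, pts, cells, point_data={name: np.asarray(w2d)})


def serialize_design(design: LevelSetDesign, path):
    """Plain-text design table: 2 header lines, then knot x, knot y, alpha."""
    lo, hi = design.alpha_bounds
    header = (
        f"# auxstent level-set design: N={design.knots.count} "
        f"support_radius={design.knots.support_radius!r} bounds=({lo!r},{hi!r})\n"
        "# knot_x knot_y alpha\n"
    )
    body = "\n".join(
        f"{x:.17g} {y:.17g} {a:.17g}"
        for (x, y), a in zip(design.knots.positions, design.alpha)
    )
    Path(path).write_text(header + body + "\n")


def load_design(path) -> LevelSetDesign:
    lines = Path(path).read_text().splitlines()
    head = lines[0]
    support = float(head.split("support_radius=")[1].split()[0])
    bounds = head.split("bounds=(")[1].rstrip(")").split(",")
    lo, hi = float(bounds[0]), float(bounds[1].rstrip(")"))
    data = np.array([[float(v) for v in ln.split()] for ln in lines[2:] if ln.strip()])
    knots = KnotGrid(data[:, :2], support)
    return LevelSetDesign(knots=knots, alpha=data[:, 2], alpha_bounds=(lo, hi))


# ---------------------------------------------------------------------------
# STL export


def _cell_polygons(phi):
    """Marching-squares solid polygons for one grid cell.

    ``phi`` holds the four corner values in CCW order c00, c10, c11, c01;
    returns a list of CCW polygons in unit-cell-of-one coordinates.
    """
    eps = 1e-12
    v = np.where(np.abs(phi) < eps, eps, phi)
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    inside = v > 0
    if inside.all():
        return [corners.tolist()]
    if not inside.any():
        return []
    # saddle: opposite corners solid -> split on the (bilinear) center value
    if inside.tolist() in ([True, False, True, False], [False, True, False, True]):
        if v.mean() <= 0:
            polys = []
            for k in range(4):
                if inside[k]:
                    prev_e = (k + 3) % 4
                    a = _edge_cross(corners, v, prev_e)
                    b = _edge_cross(corners, v, k)
                    polys.append([a, corners[k].tolist(), b])
            # fix orientation: walk corner-centred triangles CCW
            return [p if _area(p) > 0 else p[::-1] for p in polys]
    poly = []
    for k in range(4):
        if inside[k]:
            poly.append(corners[k].tolist())
        if inside[k] != inside[(k + 1) % 4]:
            poly.append(_edge_cross(corners, v, k))
    return [poly]


def _edge_cross(corners, v, k):
    a, b = corners[k], corners[(k + 1) % 4]
    t = v[k] / (v[k] - v[(k + 1) % 4])
    return (a + t * (b - a)).tolist()


def _area(poly):
    p = np.asarray(poly)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ear_clip(poly):
    """Triangulate a simple CCW polygon by ear clipping; returns index triples."""
    n = len(poly)
    if n < 3:
        return []
    idx = list(range(n))
    pts = np.asarray(poly)
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n:
        guard += 1
        m = len(idx)
        for pos in range(m):
            i0, i1, i2 = idx[pos - 1], idx[pos], idx[(pos + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-14:
                continue
            ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                if _in_triangle(pts[j], a, b, c):
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(pos)
                break
        else:
            break
    if len(idx) == 3:
        tris.append(tuple(idx))
    return tris


def _in_triangle(p, a, b, c):
    def s(u, v, w):
        return (v[0] - u[0]) * (w[1] - u[1]) - (v[1] - u[1]) * (w[0] - u[0])

    d1, d2, d3 = s(a, b, p), s(b, c, p), s(c, a, p)
    neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (neg and pos)


def write_stl(path, triangles):
    """Binary STL from an (n, 3, 3) array of triangle vertices."""
    tris = np.asarray(triangles, float)
    with open(path, "wb") as f:
        f.write(b"auxstent binary STL".ljust(80, b" "))
        f.write(struct.pack("<I", len(tris)))
        for t in tris:
            n = np.cross(t[1] - t[0], t[2] - t[0])
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            f.write(struct.pack("<3f", *n))
            for v in t:
                f.write(struct.pack("<3f", *v))
            f.write(struct.pack("<H", 0))


def export_design_stl(design: LevelSetDesign, thickness: float, path, resolution: int = 64):
    """Extrude the solid phase of the design to a watertight binary STL.

    The zero contour is sampled on a ``resolution``-cell grid; every grid
    cell contributes its marching-squares polygon to the top and bottom
    caps and its contour chords to the side walls, plus the outer unit-cell
    boundary where the solid reaches it.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    nodes = grid_points(resolution, resolution)
    phi = evaluate_level_set(design, nodes).reshape(resolution + 1, resolution + 1)
    if not (phi > 0).any():
        raise ValueError("design has an empty solid phase; nothing to export")
    h = 1.0 / resolution
    tris = []
    z0, z1 = 0.0, thickness

    if (phi > 0).all():
        # fully solid cell: a plain 12-triangle box
        quads = _box_quads(z0, z1)
        for q in quads:
            tris.append([q[0], q[1], q[2]])
            tris.append([q[0], q[2], q[3]])
        write_stl(path, np.array(tris))
        return np.array(tris)

    for ix in range(resolution):
        for iy in range(resolution):
            v = np.array(
                [phi[ix, iy], phi[ix + 1, iy], phi[ix + 1, iy + 1], phi[ix, iy + 1]]
            )
            for poly in _cell_polygons(v):
                pts = (np.asarray(poly) * h + [ix * h, iy * h]).tolist()
                for i0, i1, i2 in _ear_clip(pts):
                    a, b, c = pts[i0], pts[i1], pts[i2]
                    tris.append([[*a, z1], [*b, z1], [*c, z1]])  # top cap, +z
                    tris.append([[*a, z0], [*c, z0], [*b, z0]])  # bottom, -z
                m = len(pts)
                for k in range(m):
                    p, q = pts[k], pts[(k + 1) % m]
                    if _is_wall_edge(p, q, ix, iy, h, resolution):
                        # outward normal to the right of p->q (solid on the left)
                        tris.append([[*p, z0], [*q, z0], [*q, z1]])
                        tris.append([[*p, z0], [*q, z1], [*p, z1]])
    tris = np.array(tris)
    write_stl(path, tris)
    return tris


def _is_wall_edge(p, q, ix, iy, h, resolution):
    """Wall if the polygon edge is a contour chord or on the domain boundary."""
    tol = 1e-9
    for coord, lo_cell, n_cells in ((0, ix, resolution), (1, iy, resolution)):
        for side in (lo_cell * h, (lo_cell + 1) * h):
            if abs(p[coord] - side) < tol and abs(q[coord] - side) < tol:
                # grid-line edge: wall only on the outer domain boundary
                return abs(side) < tol or abs(side - 1.0) < tol
    return True  # interior chord


def _box_quads(z0, z1):
    c = [(0, 0), (1, 0), (1, 1), (0, 1)]
    top = [[x, y, z1] for x, y in c]
    bot = [[x, y, z0] for x, y in c]
    quads = [top, bot[::-1]]
    for k in range(4):
        p, q = c[k], c[(k + 1) % 4]
        quads.append([[*p, z0], [*q, z0], [*q, z1], [*p, z1]])
    return quads
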