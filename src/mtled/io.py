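"""Geometry and field I/O: legacy ASCII VTK unstructured grids and STL surfaces.

The VTK legacy format is written/parsed directly (it is a simple line-oriented
text format); STL surfaces go through :mod:`trimesh`.  An STL surface carries
no interior, so reading one returns only a triangulated boundary — use
:func:`grid_from_surface` to fill the interior with nodes and background cells
before simulating.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

from .grids import Grid, GridGenerationError, _build_from_points, _tet_volumes

__all__ = [
    "write_vtk", "read_vtk", "write_stl", "read_stl_surface",
    "grid_from_surface", "write_geometry", "read_geometry",
]


class ParseError(ValueError):
    """Malformed geometry file; the message carries line/record context."""


def write_vtk(grid: Grid, path, point_data: dict | None = None) -> None:
    """Write a grid (and optional per-node vector/scalar fields) as legacy VTK.

    Coordinates are converted mm -> m on output, matching the convention of
    the downstream visualization tooling; fields are written as-is with their
    units in the array name.
    """
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0",
             "mtled grid (coordinates in m; source units mm)",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {grid.n_nodes} double"]
    for p in grid.nodes * 1e-3:
        lines.append(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}")
    lines.append(f"CELLS {grid.n_cells} {5 * grid.n_cells}")
    for c in grid.cells:
        lines.append("4 " + " ".join(str(int(i)) for i in c))
    lines.append(f"CELL_TYPES {grid.n_cells}")
    lines.extend(["10"] * grid.n_cells)  # VTK_TETRA
    lines.append(f"CELL_DATA {grid.n_cells}")
    lines.append("SCALARS material_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(m)) for m in grid.material_id)
    if point_data:
        lines.append(f"POINT_DATA {grid.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                for v in arr:
                    lines.append(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9e}" for v in arr.ravel())
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path) -> Grid:
    """Read a legacy ASCII VTK unstructured tetrahedral grid written in metres."""
    path = Path(path)
    tokens: list[str] = []
    line_of: list[int] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if ln <= 4:  # header lines
            continue
        for tok in line.split():
            tokens.append(tok)
            line_of.append(ln)
    pos = 0

    def expect(kw: str):
        nonlocal pos
        if pos >= len(tokens):
            raise ParseError(f"{path}: truncated file, expected {kw!r}")
        if tokens[pos].upper() != kw:
            raise ParseError(
                f"{path}:{line_of[pos]}: expected {kw!r}, found {tokens[pos]!r}")
        pos += 1

    def take(n: int, cast):
        nonlocal pos
        if pos + n > len(tokens):
            raise ParseError(
                f"{path}: truncated near line {line_of[min(pos, len(tokens) - 1)]}")
        out = [cast(t) for t in tokens[pos:pos + n]]
        pos += n
        return out

    expect("POINTS")
    npts = take(1, int)[0]
    take(1, str)  # dtype
    nodes = np.array(take(3 * npts, float)).reshape(npts, 3) * 1e3  # m -> mm
    expect("CELLS")
    ncell = take(1, int)[0]
    total = take(1, int)[0]
    raw = np.array(take(total, int))
    cells = []
    i = 0
    for _ in range(ncell):
        k = raw[i]
        if k != 4:
            raise ParseError(f"{path}: non-tetrahedral cell of size {k}")
        cells.append(raw[i + 1:i + 5])
        i += 5
    cells = np.array(cells, dtype=np.int64)
    expect("CELL_TYPES")
    take(1, int)
    take(ncell, int)
    mat = np.zeros(ncell, dtype=np.int64)
    if pos < len(tokens) and tokens[pos].upper() == "CELL_DATA":
        pos += 5  # CELL_DATA n SCALARS name type
        take(1, str)
        expect("LOOKUP_TABLE")
        take(1, str)
        mat = np.array(take(ncell, int), dtype=np.int64)
    vols = _tet_volumes(nodes, cells)
    flip = vols < 0
    cells[flip] = cells[flip][:, [0, 1, 3, 2]]
    vols = np.abs(vols)
    grid = Grid(nodes=nodes, cells=cells, cell_volumes=vols,
                quad_points=nodes[cells].mean(axis=1), material_id=mat,
                boundary_sets={})
    grid.validate()
    return grid


def _surface_mesh(grid: Grid) -> trimesh.Trimesh:
    """Boundary triangulation of the background tessellation (faces used once).

    Dropped sliver cells can leave pinholes and tiny detached face patches in
    the raw once-used face set; the largest connected component is kept and
    its holes filled so the exported surface is closed.
    """
    faces = grid.cells[:, [[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inv] == 1]
    mesh = trimesh.Trimesh(vertices=grid.nodes, faces=boundary, process=True)
    if not mesh.is_watertight:
        parts = mesh.split(only_watertight=False)
        if len(parts):
            mesh = max(parts, key=lambda m: m.area)
        trimesh.repair.fill_holes(mesh)
    return mesh


def write_stl(grid: Grid, path) -> None:
    """Write the boundary surface of a grid as ASCII STL (mm)."""
    _surface_mesh(grid).export(str(path), file_type="stl_ascii")


def read_stl_surface(path) -> trimesh.Trimesh:
    try:
        mesh = trimesh.load(str(path), file_type="stl", force="mesh")
    except Exception as exc:
        raise ParseError(f"{path}: STL parse failure: {exc}") from exc
    if mesh.vertices.size == 0:
        raise ParseError(f"{path}: STL file contains no facets")
    return mesh


def _points_in_surface(mesh: trimesh.Trimesh, points: np.ndarray,
                       batch: int = 2048) -> np.ndarray:
    """Even-odd ray-casting containment test (rays along +z), vectorized.

    A tiny deterministic ray tilt avoids edge/vertex grazing degeneracies.
    """
    tri = np.asarray(mesh.triangles, dtype=float)  # (m, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    d = np.array([1.23456789e-4, 7.654321e-5, 1.0])
    d /= np.linalg.norm(d)
    h = np.cross(d, e2)                      # (m, 3)
    a = np.einsum("mj,mj->m", e1, h)
    ok = np.abs(a) > 1e-14
    inside = np.zeros(len(points), dtype=bool)
    for lo in range(0, len(points), batch):
        p = points[lo:lo + batch]
        s = p[:, None, :] - v0[None, :, :]   # (b, m, 3)
        u = np.einsum("bmj,mj->bm", s, h) / a
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("bmj,j->bm", q, d) / a
        t = np.einsum("bmj,mj->bm", q, e2) / a
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
        inside[lo:lo + batch] = hit.sum(axis=1) % 2 == 1
    return inside


def grid_from_surface(mesh: trimesh.Trimesh, target_nodes: int, seed: int) -> Grid:
    """Fill a closed surface with interior nodes + background cells.

    Interior nodes come from a jittered lattice filtered by the surface's
    signed distance; the surface vertices themselves are kept so the hull of
    the node set tracks the input geometry.
    """
    if not mesh.is_watertight:
        raise GridGenerationError("surface is not closed; cannot fill interior")
    rng = np.random.default_rng(seed)
    lo, hi = mesh.bounds
    vol = float(mesh.volume)
    h = (vol / max(target_nodes, 1)) ** (1.0 / 3.0)
    axes = [np.arange(lo[d] + 0.5 * h, hi[d], h) for d in range(3)]
    lattice = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    lattice = lattice + rng.uniform(-0.2 * h, 0.2 * h, size=lattice.shape)
    inside = _points_in_surface(mesh, lattice)
    interior = lattice[inside]
    # keep only interior points clear of the surface to avoid slivers
    from scipy.spatial import cKDTree
    d, _ = cKDTree(mesh.vertices).query(interior)
    interior = interior[d > 0.4 * h]
    pts = np.vstack([np.asarray(mesh.vertices, dtype=float), interior])
    cells, vols, centroids = _build_from_points(pts)
    # Delaunay fills the convex hull; discard cells whose centroid is outside
    keep = _points_in_surface(mesh, centroids)
    cells, vols, centroids = cells[keep], vols[keep], centroids[keep]
    grid = Grid(nodes=pts, cells=cells, cell_volumes=vols, quad_points=centroids,
                material_id=np.zeros(len(cells), dtype=np.int64), boundary_sets={})
    grid.validate()
    return grid


def write_geometry(grid: Grid, path, fmt: str | None = None) -> None:
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt == "vtk":
        write_vtk(grid, path)
    elif fmt == "stl":
        write_stl(grid, path)
    else:
        raise ValueError(f"unsupported geometry format {fmt!r}")


def read_geometry(path, fmt: str | None = None, *, target_nodes: int = 5000,
                  seed: int = 0) -> Grid:
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt == "vtk":
        return read_vtk(path)
    if fmt == "stl":
        return grid_from_surface(read_stl_surface(path), target_nodes, seed)
    raise ValueError(f"unsupported geometry format {fmt!r}")
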