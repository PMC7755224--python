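"""Meshless discretizations: node clouds plus tetrahedral background integration cells.

A :class:`Grid` is not a finite-element mesh.  Nodes carry the kinematic
unknowns; the tetrahedra are only a background tessellation used for one-point
numerical quadrature (one Gauss point, at the centroid, per cell) and need not
satisfy any mesh-quality criteria.  Generators produce the synthetic gel-sample
geometries used throughout: a homogeneous cylinder, a layered cylinder with a
different material per layer, and marker (bead) sets embedded between layers.

Coordinates are millimetres, right-handed, origin at the sample base centre,
z pointing up.  The needle is inserted along -z from the top surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "Grid",
    "MarkerSet",
    "GridGenerationError",
    "generate_cylinder_grid",
    "generate_layered_cylinder",
    "place_markers",
    "find_containing_cells",
]


class GridGenerationError(ValueError):
    """Raised when a discretization cannot be built from the requested inputs."""


@dataclass
class Grid:
    """Node cloud + background integration cells.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, mm
    cells : (n_cells, 4) int array of node indices
    cell_volumes : (n_cells,) float array, mm^3, all positive
    quad_points : (n_cells, 3) float array, cell centroids, mm
    material_id : (n_cells,) int array
    boundary_sets : dict mapping set name ("top", "bottom", "lateral") to
        sorted int arrays of node indices; sets are pairwise disjoint
    """

    nodes: np.ndarray
    cells: np.ndarray
    cell_volumes: np.ndarray
    quad_points: np.ndarray
    material_id: np.ndarray
    boundary_sets: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_volume(self) -> float:
        return float(self.cell_volumes.sum())

    def nodal_spacing(self) -> np.ndarray:
        """Per-node distance to the nearest other node (mm)."""
        d, _ = cKDTree(self.nodes).query(self.nodes, k=2)
        return d[:, 1]

    def validate(self) -> None:
        if np.any(self.cell_volumes <= 0):
            raise GridGenerationError("non-positive cell volume present")
        if self.cells.max() >= self.n_nodes or self.cells.min() < 0:
            raise GridGenerationError("cell references a non-existent node")
        names = list(self.boundary_sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if np.intersect1d(self.boundary_sets[a], self.boundary_sets[b]).size:
                    raise GridGenerationError(f"boundary sets {a!r} and {b!r} overlap")


@dataclass
class MarkerSet:
    """Embedded material points tracked through a simulation (synthetic beads)."""

    positions: np.ndarray  # (n, 3) mm
    ids: np.ndarray  # (n,) int

    def __len__(self) -> int:
        return len(self.ids)


def _tet_volumes(nodes: np.ndarray, cells: np.ndarray) -> np.ndarray:
    a, b, c, d = (nodes[cells[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def _cylinder_points(radius: float, z_levels: np.ndarray, h: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-uniform cylinder sampling: concentric rings per z level.

    Returns points and a boolean mask of strictly-interior points (eligible
    for jitter).  The outermost ring sits exactly on the lateral surface and
    the first/last z levels on the end faces, so the convex hull tracks the
    analytic cylinder up to circumferential faceting.
    """
    pts = []
    interior = []
    n_rings = max(int(round(radius / h)), 1)
    ring_r = np.linspace(0.0, radius, n_rings + 1)
    z0, z1 = z_levels[0], z_levels[-1]
    for li, z in enumerate(z_levels):
        on_cap = z == z0 or z == z1
        # stagger ring start angle between levels to avoid coplanar degeneracy
        base_ang = 0.5 * np.pi * (li % 4) / max(n_rings, 1)
        for r in ring_r:
            if r == 0.0:
                pts.append((0.0, 0.0, z))
                interior.append(not on_cap)
                continue
            m = max(int(round(2.0 * np.pi * r / h)), 6)
            ang = base_ang + 2.0 * np.pi * (np.arange(m) + 0.37 * (li % 3)) / m
            for t in ang:
                pts.append((r * np.cos(t), r * np.sin(t), z))
                interior.append(not on_cap and r < ring_r[-1])
    pts = np.asarray(pts, dtype=float)
    interior = np.asarray(interior, dtype=bool)
    # deterministic jitter of strictly-interior points (xy only; z levels kept
    # exact so layer interfaces stay conforming)
    jit = rng.uniform(-0.18 * h, 0.18 * h, size=(interior.sum(), 2))
    pts[interior, :2] += jit
    # keep jittered points inside the lateral surface
    rr = np.hypot(pts[:, 0], pts[:, 1])
    bad = rr > radius - 0.05 * h
    bad &= interior
    if bad.any():
        scale = (radius - 0.1 * h) / rr[bad]
        pts[bad, :2] *= scale[:, None]
    return pts, interior


def _count_for_spacing(radius: float, height: float, h: float) -> int:
    nz = max(int(round(height / h)) + 1, 2)
    n_rings = max(int(round(radius / h)), 1)
    ring_r = np.linspace(0.0, radius, n_rings + 1)
    per_level = 1 + sum(max(int(round(2 * np.pi * r / h)), 6) for r in ring_r[1:])
    return nz * per_level


def _solve_spacing(radius: float, height: float, target_nodes: int) -> float:
    # bisect on spacing; node count is monotone decreasing in h
    volume = np.pi * radius**2 * height
    h0 = (volume / max(target_nodes, 1)) ** (1.0 / 3.0)
    lo, hi = 0.25 * h0, 4.0 * h0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _count_for_spacing(radius, height, mid) > target_nodes:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _z_levels(heights: list[float], h: float) -> np.ndarray:
    """z levels from the base up, snapped so every layer interface is a level."""
    levels = [0.0]
    z = 0.0
    for hk in heights:
        n = max(int(round(hk / h)), 1)
        levels.extend(z + hk * (np.arange(1, n + 1) / n))
        z += hk
    return np.asarray(levels)


def _classify_boundaries(nodes: np.ndarray, radius: float, height: float) -> dict:
    tol_z = 1e-3 * height
    z = nodes[:, 2]
    r = np.hypot(nodes[:, 0], nodes[:, 1])
    top = np.flatnonzero(np.abs(z - height) < tol_z)
    bottom = np.flatnonzero(np.abs(z) < tol_z)
    lateral = np.flatnonzero(r > radius - 1e-3 * radius)
    lateral = np.setdiff1d(lateral, np.union1d(top, bottom))
    return {"top": top, "bottom": bottom, "lateral": lateral}


def _build_from_points(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        tri = Delaunay(points)
    except Exception as exc:  # qhull failures on degenerate inputs
        raise GridGenerationError(f"tetrahedralization failed: {exc}") from exc
    cells = tri.simplices.astype(np.int64)
    vols = _tet_volumes(points, cells)
    flip = vols < 0
    cells[flip] = cells[flip][:, [0, 1, 3, 2]]
    vols = np.abs(vols)
    # Drop sliver cells: they carry negligible quadrature weight but, being
    # nearly flat, blow up the cell-averaged gradients (face area / volume)
    # and with them the stiffness spectrum.  A flat sliver's face integrals
    # nearly self-cancel, so removing it perturbs the quadrature identities
    # only at O(V_sliver).
    keep = vols > 0.05 * np.median(vols[vols > 0])
    cells, vols = cells[keep], vols[keep]
    centroids = points[cells].mean(axis=1)
    return cells, vols, centroids


def generate_layered_cylinder(radius: float, layer_heights, target_nodes: int,
                              seed: int) -> Grid:
    """Cylinder of stacked layers; each cell's material_id is its centroid's layer.

    Layer heights are listed from the base up.  Interfaces coincide with node
    levels, so no cell straddles an interface by more than the centroid
    assignment tolerance.
    """
    layer_heights = [float(hk) for hk in np.atleast_1d(layer_heights)]
    if len(layer_heights) == 0:
        raise GridGenerationError("layer list is empty")
    if any(hk <= 0 for hk in layer_heights) or radius <= 0:
        raise GridGenerationError("radius and layer heights must be positive")
    if target_nodes < 50:
        raise GridGenerationError(
            f"target_nodes={target_nodes} too small to tetrahedralize reliably")
    height = float(sum(layer_heights))
    h = _solve_spacing(radius, height, target_nodes)
    rng = np.random.default_rng(seed)
    z_levels = _z_levels(layer_heights, h)
    # rebuild the per-level sampling on the snapped levels
    pts, _ = _cylinder_points(radius, z_levels, h, rng)
    n = len(pts)
    if abs(n - target_nodes) > 0.15 * target_nodes:
        # one refinement of the spacing estimate
        h *= (n / target_nodes) ** (1.0 / 3.0)
        rng = np.random.default_rng(seed)
        z_levels = _z_levels(layer_heights, h)
        pts, _ = _cylinder_points(radius, z_levels, h, rng)
    cells, vols, centroids = _build_from_points(pts)
    interfaces = np.concatenate([[0.0], np.cumsum(layer_heights)])
    mat = np.clip(np.searchsorted(interfaces, centroids[:, 2], side="right") - 1,
                  0, len(layer_heights) - 1).astype(np.int64)
    grid = Grid(nodes=pts, cells=cells, cell_volumes=vols, quad_points=centroids,
                material_id=mat, boundary_sets=_classify_boundaries(pts, radius, height))
    grid.validate()
    return grid


def generate_cylinder_grid(radius: float, height: float, target_nodes: int,
                           seed: int) -> Grid:
    """Homogeneous cylinder discretization (single material_id = 0).

    Deterministic for a fixed seed; the node count lands within 15 % of
    ``target_nodes`` and the summed cell volumes approximate pi r^2 h up to
    circumferential faceting of the lateral surface.
    """
    return generate_layered_cylinder(radius, [height], target_nodes, seed)


def find_containing_cells(grid: Grid, points: np.ndarray,
                          tol: float = 1e-9) -> np.ndarray:
    """Index of a cell containing each point (-1 if outside), by barycentric test."""
    points = np.atleast_2d(points)
    tree = cKDTree(grid.quad_points)
    k = min(32, grid.n_cells)
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    out = np.full(len(points), -1, dtype=np.int64)
    for pi, row in enumerate(cand):
        for ci in np.atleast_1d(row):
            verts = grid.nodes[grid.cells[ci]]
            T = (verts[1:] - verts[0]).T
            try:
                lam = np.linalg.solve(T, points[pi] - verts[0])
            except np.linalg.LinAlgError:
                continue
            if lam.min() >= -tol and lam.sum() <= 1 + tol:
                out[pi] = ci
                break
    return out


def place_markers(grid: Grid, layout) -> MarkerSet:
    """Place marker points (synthetic beads) on horizontal planes inside the solid.

    ``layout`` is a sequence of ``(z, count)`` pairs; markers are arranged on
    concentric rings scaled to 80 % of the local cross-section radius.  Every
    marker must fall strictly inside the solid or the placement fails naming
    the offending marker.
    """
    layout = list(layout)
    if not layout:
        return MarkerSet(positions=np.empty((0, 3)), ids=np.empty(0, dtype=np.int64))
    r_surf = np.hypot(grid.nodes[:, 0], grid.nodes[:, 1]).max()
    positions = []
    for z, count in layout:
        pts = _disk_layout(0.8 * r_surf, int(count))
        for x, y in pts:
            positions.append((x, y, float(z)))
    positions = np.asarray(positions)
    inside = find_containing_cells(grid, positions) >= 0
    if not inside.all():
        bad = int(np.flatnonzero(~inside)[0])
        raise GridGenerationError(
            f"marker {bad} at {positions[bad]} lies outside the solid")
    return MarkerSet(positions=positions, ids=np.arange(len(positions)))


def _disk_layout(radius: float, count: int) -> np.ndarray:
    """Sunflower (Vogel spiral) arrangement of ``count`` points in a disk."""
    if count == 0:
        return np.empty((0, 2))
    i = np.arange(count) + 0.5
    r = radius * np.sqrt(i / count)
    th = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(th), r * np.sin(th)])
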