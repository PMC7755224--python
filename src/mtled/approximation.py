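"""Modified moving least squares (MMLS) shape functions over scattered nodes.

The approximation uses a polynomial basis that is linear in the evaluation
coordinates augmented with the six quadratic monomials, whose coefficients are
ridge-penalized toward zero.  The penalty keeps the moment matrix invertible
on nearly degenerate node configurations (the "modification") while leaving
partition of unity and linear completeness exact, because the constant and
linear monomials are never penalized.  Weight function: quartic spline
w(q) = 1 - 6q^2 + 8q^3 - 3q^4 on q in [0, 1].

All shape values and reference-configuration gradients are precomputed once
(total Lagrangian setting) and stored in a :class:`ShapeTable`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SupportDomain", "ShapeTable", "ApproximationError",
    "build_supports", "mmls_shape", "build_shape_table", "evaluate_field",
]

_NBASIS = 10  # 1, x, y, z, x^2, y^2, z^2, xy, yz, zx
_QUAD_SLICE = slice(4, 10)
_INTERP_EPS = 1e-10  # weight regularization of the interpolating variant


class ApproximationError(ValueError):
    pass


@dataclass
class SupportDomain:
    """Nodes supporting the approximation at one evaluation point."""

    eval_point: np.ndarray  # (3,) mm
    neighbor_ids: np.ndarray  # (k,) int
    radius: float  # mm


@dataclass
class ShapeTable:
    """Precomputed MMLS shape values (and optionally gradients) at a point set.

    ``conn`` is padded with index 0 beyond ``counts[i]`` entries; the matching
    ``phi``/``grad`` entries are exactly zero, so padded slots are inert in
    any gather/scatter.
    """

    points: np.ndarray       # (n_pts, 3) mm
    conn: np.ndarray         # (n_pts, kmax) int32
    counts: np.ndarray       # (n_pts,) int32
    phi: np.ndarray          # (n_pts, kmax)
    grad: np.ndarray | None  # (n_pts, kmax, 3), 1/mm

    @property
    def n_points(self) -> int:
        return len(self.points)


def build_supports(node_coords: np.ndarray, eval_points: np.ndarray,
                   min_neighbors: int = 16, dilation: float = 1.1) -> list[SupportDomain]:
    """Support domain per evaluation point.

    The radius is ``dilation`` times the distance to the ``min_neighbors``-th
    nearest node; all nodes inside that radius belong to the support.
    """
    node_coords = np.asarray(node_coords, dtype=float)
    eval_points = np.atleast_2d(np.asarray(eval_points, dtype=float))
    if min_neighbors < 4:
        raise ApproximationError("min_neighbors must be >= 4 (linear basis in 3-D)")
    if len(node_coords) < min_neighbors:
        raise ApproximationError(
            f"only {len(node_coords)} nodes available, need >= {min_neighbors}")
    tree = cKDTree(node_coords)
    dk, _ = tree.query(eval_points, k=min_neighbors)
    radii = dilation * dk[:, -1]
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = int(np.flatnonzero(~np.isfinite(radii) | (radii <= 0))[0])
        raise ApproximationError(f"isolated evaluation point {bad}")
    supports = []
    for p, r in zip(eval_points, radii):
        ids = np.asarray(tree.query_ball_point(p, r * (1 + 1e-12)), dtype=np.int64)
        ids.sort()
        supports.append(SupportDomain(eval_point=p, neighbor_ids=ids, radius=float(r)))
    return supports


def _weight(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quartic spline weight and its derivative w.r.t. q, zero outside q >= 1."""
    q = np.clip(q, 0.0, 1.0)
    w = 1.0 - 6.0 * q**2 + 8.0 * q**3 - 3.0 * q**4
    dw = -12.0 * q + 24.0 * q**2 - 12.0 * q**3
    return w, dw


def _basis(xi: np.ndarray) -> np.ndarray:
    """Monomial basis at scaled local coordinates, shape (..., 10)."""
    x, y, z = xi[..., 0], xi[..., 1], xi[..., 2]
    return np.stack([np.ones_like(x), x, y, z,
                     x * x, y * y, z * z, x * y, y * z, z * x], axis=-1)


def mmls_shape(point: np.ndarray, support: SupportDomain, node_coords: np.ndarray,
               penalty: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
    """Shape values and reference gradients of one support at one point.

    Returns ``(phi, dphi)`` with shapes ``(k,)`` and ``(k, 3)``; gradients are
    with respect to the physical (mm) coordinates.
    """
    phi, grad, _ = _mmls_batch(
        np.asarray(point, float)[None, :],
        np.asarray(node_coords, float),
        support.neighbor_ids[None, :],
        np.array([len(support.neighbor_ids)], dtype=np.int32),
        np.array([support.radius]),
        penalty,
    )
    return phi[0], grad[0]


def _mmls_batch(points, node_coords, conn, counts, radii, penalty,
                interpolating=False):
    """Vectorized MMLS at many points; conn padded with zeros beyond counts.

    With ``interpolating=True`` the spline weight is divided by (q^2 + eps),
    making it near-singular at coincident nodes so nodal values are honored
    (interpolating MLS; used for cross-grid transfer, marker evaluation, and
    wherever essential boundary conditions must bind the displacement field).
    """
    n, kmax = conn.shape
    xi = (node_coords[conn] - points[:, None, :]) / radii[:, None, None]
    mask = np.arange(kmax)[None, :] < counts[:, None]
    dist = np.linalg.norm(node_coords[conn] - points[:, None, :], axis=2)
    q = np.where(mask, dist / radii[:, None], 1.0)
    w, dwdq = _weight(q)
    if interpolating:
        # near-singular regularized weights: w -> w / (q^2 + eps) gives the
        # shape functions a near-delta property at the nodes
        denom = q * q + _INTERP_EPS
        dwdq = (dwdq * denom - 2.0 * q * w) / denom**2
        w = w / denom
    w = np.where(mask, w, 0.0)
    # dw/dx_k (physical coordinates, 1/mm): q = |x0 - xI|/r -> dq/dx0 = (x0-xI)/(|.|r)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = (points[:, None, :] - node_coords[conn]) / dist[..., None]
    direction = np.where(np.isfinite(direction), direction, 0.0)
    dw = (dwdq * mask / radii[:, None])[..., None] * direction  # (n, kmax, 3)

    P = _basis(xi)  # (n, kmax, 10)
    P = np.where(mask[..., None], P, 0.0)
    A = np.einsum("nk,nki,nkj->nij", w, P, P)
    idx = np.arange(_NBASIS)[_QUAD_SLICE]
    A[:, idx, idx] += penalty
    # rhs columns: e1 (shape values), d(p)/dx at local origin (three linear rows)
    rhs = np.zeros((n, _NBASIS, 4))
    rhs[:, 0, 0] = 1.0
    for k in range(3):
        rhs[:, 1 + k, 1 + k] = 1.0 / radii
    # symmetric Jacobi equilibration plus one step of iterative refinement:
    # the moment matrix can be poorly conditioned on thin supports while the
    # partition-of-unity / gradient-sum invariants are asserted to near
    # machine precision
    dscale = np.sqrt(np.einsum("nii->ni", A))
    As = A / (dscale[:, :, None] * dscale[:, None, :])

    def solve_refined(B):
        Bs = B / dscale[..., None]
        try:
            x = np.linalg.solve(As, Bs)
        except np.linalg.LinAlgError as exc:
            raise ApproximationError(f"singular moment matrix: {exc}") from exc
        x = x + np.linalg.solve(As, Bs - As @ x)
        x = x + np.linalg.solve(As, Bs - As @ x)
        return x / dscale[..., None]

    sol = solve_refined(rhs)
    gamma = sol[..., 0]          # (n, 10)
    c = sol[..., 1:]             # (n, 10, 3)
    gp = np.einsum("ni,nki->nk", gamma, P)         # gamma^T p_i
    phi = w * gp
    # dA_k gamma  -> t_k ; e_k = A^{-1} t_k
    t = np.einsum("nkd,nki,nj,nkj->nid", dw, P, gamma, P)
    e = solve_refined(t)         # (n, 10, 3)
    term1 = np.einsum("nk,nid,nki->nkd", w, c - e, P)
    term3 = dw * gp[..., None]
    grad = term1 + term3
    phi = np.where(mask, phi, 0.0)
    grad = np.where(mask[..., None], grad, 0.0)
    return phi, grad, w


def build_shape_table(node_coords: np.ndarray, eval_points: np.ndarray,
                      min_neighbors: int = 16, dilation: float = 1.1,
                      penalty: float = 1e-7, with_gradients: bool = True,
                      interpolating: bool = False, batch: int = 8192) -> ShapeTable:
    """Build the MMLS table (values + reference gradients) for a point set.

    ``interpolating=True`` requests near-singular regularized weights so the
    shape functions are near-delta at the nodes (nodal values honored).
    """
    node_coords = np.asarray(node_coords, dtype=float)
    eval_points = np.atleast_2d(np.asarray(eval_points, dtype=float))
    n_pts = len(eval_points)

    def compute(points, mn, dil):
        supports = build_supports(node_coords, points,
                                  min(mn, len(node_coords)), dil)
        counts = np.array([len(s.neighbor_ids) for s in supports],
                          dtype=np.int32)
        kmax = int(counts.max())
        conn = np.zeros((len(supports), kmax), dtype=np.int64)
        for i, s in enumerate(supports):
            conn[i, :counts[i]] = s.neighbor_ids
        radii = np.array([s.radius for s in supports])
        phi = np.empty((len(supports), kmax))
        grad = np.empty((len(supports), kmax, 3)) if with_gradients else None
        for lo in range(0, len(supports), batch):
            hi = min(lo + batch, len(supports))
            p, g, _ = _mmls_batch(points[lo:hi], node_coords, conn[lo:hi],
                                  counts[lo:hi], radii[lo:hi], penalty,
                                  interpolating=interpolating)
            phi[lo:hi] = p
            if with_gradients:
                grad[lo:hi] = g
        return conn, counts, phi, grad, radii

    # Adaptive support enlargement.  Thin one-sided supports (boundary and
    # corner regions) can leave the penalized moment matrix poorly
    # conditioned, which shows up in two ways: partition-of-unity /
    # gradient-sum residuals above machine level, and oscillatory shape
    # functions (|phi| or |grad|*radius far above O(1)).  Points failing
    # either check get progressively larger supports.
    rounds = [(min_neighbors, dilation),
              (int(1.6 * min_neighbors), dilation + 0.1),
              (int(2.6 * min_neighbors), dilation + 0.2),
              (int(4.0 * min_neighbors), dilation + 0.3)]
    pieces = []
    pending = np.arange(n_pts)
    for r_i, (mn, dil) in enumerate(rounds):
        conn, counts, phi, grad, radii = compute(eval_points[pending], mn, dil)
        resid = np.abs(phi.sum(axis=1) - 1.0)
        smooth = np.abs(phi).max(axis=1) < 1.2
        if with_gradients:
            resid_g = np.abs(grad.sum(axis=1)).max(axis=1)
            smooth &= (np.linalg.norm(grad, axis=2).max(axis=1) * radii) < 4.0
        else:
            resid_g = np.zeros(len(pending))
        ok = (resid < 1e-13) & (resid_g < 1e-11) & smooth
        if r_i == len(rounds) - 1:
            ok[:] = True  # keep the best effort from the largest supports
        pieces.append((pending[ok], conn[ok], counts[ok], phi[ok],
                       grad[ok] if with_gradients else None))
        pending = pending[~ok]
        if pending.size == 0:
            break
    kmax = max(p[1].shape[1] for p in pieces)
    conn = np.zeros((n_pts, kmax), dtype=np.int64)
    counts = np.zeros(n_pts, dtype=np.int32)
    phi = np.zeros((n_pts, kmax))
    grad = np.zeros((n_pts, kmax, 3)) if with_gradients else None
    for idx, cn, ct, ph, gr in pieces:
        k = cn.shape[1]
        conn[idx, :k] = cn
        counts[idx] = ct
        phi[idx, :k] = ph
        if with_gradients:
            grad[idx, :k] = gr
    if interpolating:
        # exact short-circuit: a point sitting on a node takes that node's value
        for i in range(n_pts):
            d = np.linalg.norm(node_coords[conn[i, :counts[i]]] - eval_points[i],
                               axis=1)
            j = int(np.argmin(d))
            if d[j] < 1e-9:
                phi[i] = 0.0
                phi[i, j] = 1.0
    return ShapeTable(points=eval_points, conn=conn.astype(np.int32),
                      counts=counts, phi=phi, grad=grad)


def build_cell_gradient_table(nodes: np.ndarray, cells: np.ndarray,
                              cell_volumes: np.ndarray,
                              quad_points: np.ndarray,
                              min_neighbors: int = 16, dilation: float = 1.1,
                              penalty: float = 1e-7,
                              interpolating: bool = True) -> ShapeTable:
    """Shape table with conforming smoothed gradients for one-point quadrature.

    The reference gradient stored per cell is the cell average of the shape
    gradient, evaluated as a surface integral over the tetrahedron's faces
    (one value point per face):

        grad_i(cell) = (1/V) sum_faces  phi_i(face centroid) * (A n)_outward

    Each interior face is shared with the opposite orientation by its two
    cells, so the quadrature identity sum_c V_c grad_i = boundary-only terms
    holds exactly; in particular the divergence of a constant stress field
    vanishes at every interior node and the linear patch test is passed to
    machine precision.  Shape *values* at the cell centroids (used for mass
    lumping) are carried alongside.
    """
    nodes = np.asarray(nodes, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    cell_volumes = np.asarray(cell_volumes, dtype=float)
    if np.any(cell_volumes <= 0):
        bad = int(np.flatnonzero(cell_volumes <= 0)[0])
        raise ApproximationError(
            f"cell {bad} has non-positive volume; drop degenerate (sliver) "
            "cells before building smoothed gradients")
    n_cells = len(cells)
    # unique faces with the cells they bound
    faces = cells[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    centroids_f = nodes[uniq].mean(axis=1)
    # outward area vectors per (cell, local face)
    v = nodes[cells]  # (nc, 4, 3)
    area = np.empty((n_cells, 4, 3))
    for lf, (i0, i1, i2, iop) in enumerate([(1, 2, 3, 0), (0, 3, 2, 1),
                                            (0, 1, 3, 2), (0, 2, 1, 3)]):
        a = 0.5 * np.cross(v[:, i1] - v[:, i0], v[:, i2] - v[:, i0])
        fc = (v[:, i0] + v[:, i1] + v[:, i2]) / 3.0
        flip = np.einsum("ij,ij->i", a, v[:, iop] - fc) > 0
        a[flip] *= -1.0
        area[:, lf] = a
    face_table = build_shape_table(nodes, centroids_f, min_neighbors, dilation,
                                   penalty, with_gradients=False,
                                   interpolating=interpolating)
    cen_table = build_shape_table(nodes, quad_points, min_neighbors, dilation,
                                  penalty, with_gradients=False,
                                  interpolating=interpolating)
    face_of_cell = inv.reshape(n_cells, 4)
    kf = face_table.conn.shape[1]
    kc = cen_table.conn.shape[1]
    kmax = 4 * kf + kc
    conn = np.zeros((n_cells, kmax), dtype=np.int64)
    grad = np.zeros((n_cells, kmax, 3))
    phi = np.zeros((n_cells, kmax))
    counts = np.zeros(n_cells, dtype=np.int32)
    f_conn = face_table.conn
    f_phi = face_table.phi
    f_counts = face_table.counts
    for c in range(n_cells):
        ids = [cen_table.conn[c, :cen_table.counts[c]]]
        for lf in range(4):
            fid = face_of_cell[c, lf]
            ids.append(f_conn[fid, :f_counts[fid]])
        ids = np.unique(np.concatenate(ids))
        k = len(ids)
        conn[c, :k] = ids
        counts[c] = k
        g = np.zeros((k, 3))
        for lf in range(4):
            fid = face_of_cell[c, lf]
            kk = f_counts[fid]
            pos = np.searchsorted(ids, f_conn[fid, :kk])
            g[pos] += f_phi[fid, :kk, None] * area[c, lf]
        grad[c, :k] = g / cell_volumes[c]
        kk = cen_table.counts[c]
        pos = np.searchsorted(ids, cen_table.conn[c, :kk])
        phi[c, pos] = cen_table.phi[c, :kk]
    kmax = int(counts.max())
    return ShapeTable(points=np.asarray(quad_points, dtype=float),
                      conn=conn[:, :kmax].astype(np.int32), counts=counts,
                      phi=np.ascontiguousarray(phi[:, :kmax]),
                      grad=np.ascontiguousarray(grad[:, :kmax]))


def evaluate_field(table: ShapeTable, nodal_values: np.ndarray) -> np.ndarray:
    """MMLS evaluation of a nodal field at the table's points.

    ``nodal_values`` has shape (n_nodes,) or (n_nodes, m); the result has the
    point count as leading dimension.
    """
    nodal_values = np.asarray(nodal_values, dtype=float)
    gathered = nodal_values[table.conn]  # (n_pts, kmax[, m])
    if gathered.ndim == 2:
        return np.einsum("nk,nk->n", table.phi, gathered)
    return np.einsum("nk,nkm->nm", table.phi, gathered)
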