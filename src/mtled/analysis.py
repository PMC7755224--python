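"""Verification and comparison toolkit for displacement fields.

The central metric is the per-component normalized root-mean-square error

    NRMSE_c = sqrt( (1/N) sum_i (a_i,c - r_i,c)^2 ) / (max_i r_i,c - min_i r_i,c)

between a field ``a`` evaluated at the nodes of a reference (denser) grid and
the reference field ``r`` itself; the normalizer is the reference field's
component range.  Cross-grid comparison transfers the coarse-grid solution to
the refined grid's nodes with interpolating MMLS before computing the NRMSE,
so the comparison is node-by-node on the refined grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .approximation import ShapeTable, build_shape_table, evaluate_field
from .grids import Grid, MarkerSet

__all__ = [
    "ComparisonResult", "AnalysisError",
    "nrmse", "cross_grid_compare", "marker_displacements",
    "difference_histogram", "force_depth_curve", "marker_success_fraction",
]


class AnalysisError(ValueError):
    pass


@dataclass
class ComparisonResult:
    """Per-component NRMSE with the ingredients used to form it."""

    nrmse: np.ndarray          # (3,)
    n: int                     # node count of the reference field
    differences: np.ndarray    # (n, 3), a - ref, mm
    normalizers: np.ndarray    # (3,), component ranges of the reference, mm

    @property
    def max_nrmse(self) -> float:
        return float(self.nrmse.max())


def nrmse(field_a: np.ndarray, field_ref: np.ndarray) -> ComparisonResult:
    """Per-component NRMSE of ``field_a`` against ``field_ref`` (same nodes)."""
    a = np.asarray(field_a, dtype=float)
    r = np.asarray(field_ref, dtype=float)
    if a.shape != r.shape:
        raise AnalysisError(f"field shapes differ: {a.shape} vs {r.shape}")
    if a.ndim == 1:
        a = a[:, None]
        r = r[:, None]
    rng = r.max(axis=0) - r.min(axis=0)
    for c, comp in enumerate("xyz"[: a.shape[1]]):
        if rng[c] <= 0:
            raise AnalysisError(
                f"reference field has zero range in component u_{comp}")
    diff = a - r
    rmse = np.sqrt(np.mean(diff**2, axis=0))
    return ComparisonResult(nrmse=rmse / rng, n=len(r), differences=diff,
                            normalizers=rng)


def cross_grid_compare(coarse_grid: Grid, coarse_field: np.ndarray,
                       refined_grid: Grid, refined_field: np.ndarray,
                       hull_tol: float | None = None) -> ComparisonResult:
    """NRMSE of a coarse-grid solution against a refined-grid solution.

    The coarse field is evaluated at the refined grid's node positions with
    interpolating MMLS.  Refined nodes may sit marginally outside the coarse
    grid's convex hull (the boundary faceting differs between densities);
    such points are accepted and extrapolated as long as they lie within
    ``hull_tol`` of the nearest coarse node (default: one median coarse
    spacing), points further out are an error.
    """
    if hull_tol is None:
        hull_tol = float(np.median(coarse_grid.nodal_spacing()))
    hull = Delaunay(coarse_grid.nodes)
    outside = hull.find_simplex(refined_grid.nodes) < 0
    if outside.any():
        from scipy.spatial import cKDTree
        d, _ = cKDTree(coarse_grid.nodes).query(refined_grid.nodes[outside])
        too_far = np.flatnonzero(outside)[d > hull_tol]
        if too_far.size:
            raise AnalysisError(
                f"{too_far.size} refined-grid nodes lie outside the coarse "
                f"domain hull beyond tolerance, e.g. node {int(too_far[0])}")
    table = build_shape_table(coarse_grid.nodes, refined_grid.nodes,
                              with_gradients=False, interpolating=True)
    transferred = evaluate_field(table, np.asarray(coarse_field, dtype=float))
    return nrmse(transferred, refined_field)


def marker_displacements(nodal_history, markers: MarkerSet,
                         table: ShapeTable) -> np.ndarray:
    """MMLS-evaluated displacement at each marker for each stored snapshot.

    ``nodal_history`` is a (n_nodes, 3) field or a sequence of them; ``table``
    must have been built at the marker positions (interpolating mode
    recommended so markers sitting on nodes take the nodal value).
    """
    if table.n_points != len(markers):
        raise AnalysisError("shape table was not built at the marker positions")
    fields = np.asarray(nodal_history, dtype=float)
    single = fields.ndim == 2
    if single:
        fields = fields[None]
    out = np.stack([evaluate_field(table, f) for f in fields])
    return out[0] if single else out


def difference_histogram(comparison: ComparisonResult,
                         bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Binned counts of per-node differences, per component.

    Returns ``(edges, counts)`` with a symmetric bin range around zero; counts
    sum to the node count in every component.
    """
    if bin_width <= 0:
        raise AnalysisError("bin width must be positive")
    diff = comparison.differences
    if diff.size == 0:
        raise AnalysisError("empty comparison")
    half = max(float(np.abs(diff).max()), bin_width)
    nbins = int(np.ceil(half / bin_width))
    edges = np.arange(-nbins, nbins + 1) * bin_width
    counts = np.stack([np.histogram(diff[:, c], bins=edges)[0]
                       for c in range(diff.shape[1])])
    return edges, counts


def force_depth_curve(result) -> np.ndarray:
    """(depth mm, force N) pairs from a quasi-static run's settled snapshots."""
    if not result.depths:
        raise AnalysisError("run stored no snapshots")
    return np.column_stack([result.depths, result.reaction_forces])


def marker_success_fraction(predicted: np.ndarray, measured: np.ndarray,
                            thresholds=(0.32, 0.32, 0.20)) -> np.ndarray:
    """Per-component fraction of markers within the accuracy thresholds (mm).

    The default thresholds are twice a 0.16/0.16/0.10 mm voxel size, the
    customary image-registration accuracy criterion.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    diff = np.abs(predicted - measured)
    return (diff <= np.asarray(thresholds)).mean(axis=0)
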