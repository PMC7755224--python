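"""End-to-end orchestration: simulate, convergence study, material sensitivity.

These functions are the library face of the command-line interface; each takes
a :class:`~mtled.config.RunConfig` (or pieces of one), runs the meshless
solver and returns in-memory results, optionally writing VTK/CSV artifacts
plus a provenance log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .analysis import cross_grid_compare, nrmse
from .approximation import ShapeTable, build_cell_gradient_table
from .config import ConfigError, RunConfig, provenance_record
from .dynamics import QuasiStaticResult, SolverSettings, run_quasi_static
from .grids import Grid, generate_cylinder_grid, generate_layered_cylinder
from .needle import KinematicParams, NeedleDriver, NeedleSpec

__all__ = ["SimulationBundle", "build_grid", "prepare", "simulate",
           "convergence", "material_sensitivity"]


@dataclass
class SimulationBundle:
    """Everything a needle-insertion run produced."""

    config: RunConfig
    grid: Grid
    table: ShapeTable
    result: QuasiStaticResult

    @property
    def final_displacements(self) -> np.ndarray:
        return self.result.displacements[-1]


def build_grid(config: RunConfig) -> Grid:
    g = config.geometry
    if g.kind == "cylinder":
        return generate_cylinder_grid(g.radius, g.height, g.target_nodes,
                                      config.seed)
    if g.kind == "layered_cylinder":
        return generate_layered_cylinder(g.radius, g.layer_heights,
                                         g.target_nodes, config.seed)
    return io.read_geometry(g.path, target_nodes=g.target_nodes, seed=config.seed)


def prepare(config: RunConfig, grid: Grid | None = None
            ) -> tuple[Grid, ShapeTable, list, NeedleDriver, SolverSettings, list]:
    """Resolve a config into solver-ready pieces (grid reusable across variants)."""
    grid = grid if grid is not None else build_grid(config)
    n_mats = int(grid.material_id.max()) + 1
    mats = [m.build() for m in config.materials]
    if len(mats) == 1 and n_mats > 1:
        mats = mats * n_mats  # homogeneous material over a layered grid
    if len(mats) != n_mats:
        raise ConfigError(
            f"grid has {n_mats} material ids but {len(mats)} materials configured")
    table = build_cell_gradient_table(grid.nodes, grid.cells,
                                      grid.cell_volumes, grid.quad_points)
    nc = config.needle
    entry = (np.asarray(nc.entry_point, dtype=float) if nc.entry_point is not None
             else np.array([0.0, 0.0, float(grid.nodes[:, 2].max())]))
    spec = NeedleSpec(entry_point=entry, axis=np.asarray(nc.axis, float),
                      diameter=nc.diameter, max_depth=nc.depth)
    driver = NeedleDriver(grid, spec, KinematicParams(
        eps_p=nc.eps_p, cd=nc.cd, capture_radius=nc.capture_radius,
        monitor_radius=nc.monitor_radius, fade_steps=nc.fade_steps))
    s = config.solver
    settings = SolverSettings(safety=s.safety, density=s.density,
                              damping_factor=s.damping_factor,
                              ramp_steps=s.ramp_steps,
                              settle_tol=s.settle_tol,
                              max_steps_per_stage=s.max_steps_per_stage)
    depths = s.snapshot_depths if s.snapshot_depths else [nc.depth]
    return grid, table, mats, driver, settings, depths


def simulate(config: RunConfig, grid: Grid | None = None,
             table: ShapeTable | None = None,
             write_outputs: bool | None = None) -> SimulationBundle:
    """Run one needle-insertion simulation described by ``config``.

    The sample base is rigidly fixed.  Pass ``grid``/``table`` to reuse a
    discretization across material variants (they must match the config's
    geometry block).
    """
    grid_r, table_r, mats, driver, settings, depths = prepare(config, grid)
    if table is not None:
        table_r = table
    result = run_quasi_static(grid_r, table_r, mats, driver, depths, settings,
                              fixed_nodes=grid_r.boundary_sets.get("bottom"))
    bundle = SimulationBundle(config=config, grid=grid_r, table=table_r,
                              result=result)
    do_write = (config.outputs.csv or config.outputs.vtk
                if write_outputs is None else write_outputs)
    if do_write:
        _write_bundle(bundle)
    return bundle


def _write_bundle(bundle: SimulationBundle) -> None:
    out = Path(bundle.config.outputs.directory)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(
        json.dumps(provenance_record(bundle.config), indent=2) + "\n")
    if bundle.config.outputs.csv:
        rows = []
        for d, f, diag in zip(bundle.result.depths,
                              bundle.result.reaction_forces,
                              bundle.result.diagnostics):
            rows.append({"depth_mm": d, "force_N": f, **{k: diag[k] for k in
                         ("steps", "KE", "SE", "ratio", "dt", "damping")}})
        pd.DataFrame(rows).to_csv(out / "diagnostics.csv", index=False,
                                  float_format="%.10e")
        for d, u in zip(bundle.result.depths, bundle.result.displacements):
            pd.DataFrame(u, columns=["ux_mm", "uy_mm", "uz_mm"]).to_csv(
                out / f"displacements_depth_{d:g}mm.csv", index=False,
                float_format="%.10e")
    if bundle.config.outputs.vtk:
        for d, u in zip(bundle.result.depths, bundle.result.displacements):
            io.write_vtk(bundle.grid, out / f"field_depth_{d:g}mm.vtk",
                         point_data={"displacement_m": u * 1e-3,
                                     "displacement_magnitude_m":
                                         np.linalg.norm(u, axis=1) * 1e-3})


def convergence(config: RunConfig, node_counts) -> pd.DataFrame:
    """Grid-refinement study: NRMSE of each density against the densest.

    Returns one row per coarser density with per-component NRMSE computed
    node-by-node on the densest grid.
    """
    node_counts = sorted(int(n) for n in node_counts)
    if len(node_counts) < 2:
        raise ConfigError("convergence study needs at least two node counts")
    runs = []
    base = config.model_copy(deep=True)
    for n in node_counts:
        cfg = base.model_copy(deep=True)
        cfg.geometry.target_nodes = n
        cfg.outputs.csv = cfg.outputs.vtk = False
        b = simulate(cfg)
        if base.needle.capture_radius is None:
            # every density must solve the same physical problem: freeze the
            # kinematic geometry at the coarsest grid's resolved values
            base.needle.capture_radius = b.result.driver.capture_radius
            base.needle.monitor_radius = b.result.driver.monitor_radius
        runs.append(b)
    ref = runs[-1]
    rows = []
    for b in runs[:-1]:
        comp = cross_grid_compare(b.grid, b.final_displacements,
                                  ref.grid, ref.final_displacements)
        rows.append({
            "nodes": b.grid.n_nodes, "reference_nodes": ref.grid.n_nodes,
            "nrmse_ux": comp.nrmse[0], "nrmse_uy": comp.nrmse[1],
            "nrmse_uz": comp.nrmse[2]})
    return pd.DataFrame(rows)


def material_sensitivity(config: RunConfig, variants, pairs=None) -> pd.DataFrame:
    """Pairwise NRMSE between material variants on one shared grid.

    ``variants`` is a list of material lists (each a list of
    :class:`~mtled.config.MaterialConfig`); ``pairs`` the index pairs to
    compare (default: every variant against the first).
    """
    if len(variants) < 2:
        raise ConfigError("material sensitivity needs at least two variants")
    grid = build_grid(config)
    table = None
    runs = []
    for mats in variants:
        cfg = config.model_copy(deep=True)
        cfg.materials = list(mats)
        cfg.outputs.csv = cfg.outputs.vtk = False
        b = simulate(cfg, grid=grid, table=table)
        table = b.table
        runs.append(b)
    if pairs is None:
        pairs = [(0, j) for j in range(1, len(variants))]
    rows = []
    for i, j in pairs:
        comp = nrmse(runs[i].final_displacements, runs[j].final_displacements)
        rows.append({"variant_a": i, "variant_b": j,
                     "nrmse_ux": comp.nrmse[0], "nrmse_uy": comp.nrmse[1],
                     "nrmse_uz": comp.nrmse[2]})
    return pd.DataFrame(rows)
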