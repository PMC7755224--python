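"""Total-Lagrangian explicit central-difference solver.

Semi-discrete equations of motion  M u'' + F_int(u) = F_ext  are advanced by
the central-difference update

    u(t+dt) = dt^2 M^-1 (F_ext - F_int) + 2 u(t) - u(t-dt)

with a diagonal (lumped) mass matrix and, for quasi-static problems, a
mass-proportional damping term in dynamic-relaxation style: loading is ramped
smoothly and the transient is damped until the kinetic energy is negligible
against the strain energy, leaving the static equilibrium field.

Unit bookkeeping: geometry and displacements are mm, stresses Pa, density
kg/m^3, time s.  Internal forces from the quadrature kernel come out in
Pa*mm^2 = 1e-6 N; nodal masses are kg; accelerations are converted back to
mm/s^2 inside :func:`step`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import internal_forces_kernel, max_green_strain_kernel
from .approximation import ShapeTable
from .grids import Grid
from .materials import MaterialParams, bulk_modulus

__all__ = [
    "SimState", "BoundaryConditions", "SolverSettings", "QuasiStaticResult",
    "StabilityError", "SettleError",
    "lumped_mass", "internal_forces", "compute_deformation_gradient",
    "critical_time_step", "step", "run_quasi_static", "reaction_force",
]

_FORCE_UNIT = 1e-6  # Pa*mm^2 -> N
_MM = 1e-3          # mm -> m


class StabilityError(RuntimeError):
    """Non-finite displacement detected: the explicit scheme went unstable."""


class SettleError(RuntimeError):
    """Quasi-static relaxation did not reach the energy tolerance."""


def _material_table(materials) -> np.ndarray:
    mats = np.array([[m.a, m.mu, m.D] for m in materials], dtype=np.float64)
    return mats


def lumped_mass(grid: Grid, density: float, table: ShapeTable) -> np.ndarray:
    """Per-node diagonal mass (kg) by per-cell diagonal scaling (HRZ lumping).

    Each cell's mass rho*V_cell is distributed over its supporting nodes in
    proportion to phi_i(centroid)^2.  This conserves every cell's mass (hence
    the total) exactly and stays positive even where the moving-least-squares
    shape values are negative, which plain row-sum lumping does not.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    masses = np.zeros(grid.n_nodes)
    phi2 = table.phi**2
    cell_mass = density * (grid.cell_volumes * 1e-9)  # kg
    contrib = (cell_mass / phi2.sum(axis=1))[:, None] * phi2
    np.add.at(masses, table.conn.ravel(), contrib.ravel())
    if np.any(masses <= 0):
        bad = int(np.flatnonzero(masses <= 0)[0])
        raise ValueError(
            f"non-positive lumped mass at node {bad}: pathological shape values")
    return masses


def relaxation_mass(grid: Grid, table: ShapeTable, materials, dt: float = 1.0,
                    margin: float = 3.0) -> np.ndarray:
    """Fictitious diagonal mass for dynamic relaxation (Gershgorin bound).

    Row sums of the linearized stiffness are bounded cell-wise by
    V_c * (K + 4 mu/3) * |grad phi_i| * sum_j |grad phi_j|; choosing
    m_i = margin * dt^2/4 * (that bound, in solver units) makes the
    central-difference scheme stable at pseudo time step ``dt`` with
    ``margin``-fold headroom for tangent stiffening.  Mass is a free
    parameter of the quasi-static solution; only its distribution affects
    the convergence rate.
    """
    stiff = np.array([bulk_modulus(m) + 4.0 * m.mu / 3.0 for m in materials])
    e_cell = stiff[grid.material_id]                       # Pa
    gnorm = np.linalg.norm(table.grad, axis=2)             # (ncell, kmax), 1/mm
    row = grid.cell_volumes * e_cell * gnorm.sum(axis=1)   # Pa*mm^2 per mm
    khat = np.zeros(grid.n_nodes)
    np.add.at(khat, table.conn.ravel(), (row[:, None] * gnorm).ravel())
    # omega^2 = khat * 1e-3 / m  (solver units);  require dt^2 omega^2 <= 4
    m = margin * 0.25 * dt * dt * 1e-3 * khat
    if np.any(m <= 0):
        bad = int(np.flatnonzero(m <= 0)[0])
        raise ValueError(f"node {bad} carries no stiffness: isolated node")
    return m


def internal_forces(table: ShapeTable, u: np.ndarray, material_id: np.ndarray,
                    materials, cell_volumes: np.ndarray) -> np.ndarray:
    """Nodal internal force vector (N) by one-point quadrature over cells."""
    f = np.zeros((len(u), 3))
    _, bad = internal_forces_kernel(
        table.conn, table.counts, table.grad, cell_volumes,
        material_id.astype(np.int64), _material_table(materials),
        np.ascontiguousarray(u, dtype=np.float64), f)
    if bad >= 0:
        raise FloatingPointError(f"inverted cell {bad} (det F <= 0)")
    return f * _FORCE_UNIT


def compute_deformation_gradient(table: ShapeTable, u: np.ndarray,
                                 cell: int) -> np.ndarray:
    """F = I + sum_i u_i (dphi_i/dX)^T at one quadrature point."""
    k = table.counts[cell]
    ids = table.conn[cell, :k]
    g = table.grad[cell, :k]
    return np.eye(3) + np.einsum("ka,kb->ab", u[ids], g)


def critical_time_step(grid: Grid, materials, density: float,
                       safety: float = 0.5) -> float:
    """dt = safety * h_min / c with c the fastest dilatational wave speed."""
    if safety <= 0:
        raise ValueError("safety factor must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    c = max(math.sqrt((bulk_modulus(m) + 4.0 * m.mu / 3.0) / density)
            for m in materials)
    h_min = float(grid.nodal_spacing().min())
    return safety * (h_min * _MM) / c


def spectral_time_step(table: ShapeTable, grid: Grid, materials, masses: np.ndarray,
                       u: np.ndarray | None = None, iters: int = 30) -> float:
    """Central-difference stability bound 2/omega_max of the tangent system.

    The highest natural frequency of M^-1 K(u) is estimated by power
    iteration with directional finite differences of the internal force
    (deterministic start vector).  This captures what the h/c estimate of
    :func:`critical_time_step` misses: support overlap and the spread of the
    lumped masses.
    """
    n = grid.n_nodes
    mats = list(materials)
    if u is None:
        u = np.zeros((n, 3))
    f0 = internal_forces(table, u, grid.material_id, mats, grid.cell_volumes)
    rng = np.random.default_rng(12345)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v)
    eps = 1e-7 * max(1.0, float(np.abs(u).max()))
    lam = 0.0
    for _ in range(iters):
        f1 = internal_forces(table, u + eps * v, grid.material_id, mats,
                             grid.cell_volumes)
        w = (f1 - f0) / eps / masses[:, None] / _MM  # omega^2 action, 1/s^2
        lam = float(np.linalg.norm(w))
        if lam == 0.0:
            return math.inf
        v = w / lam
    return 2.0 / math.sqrt(lam)


@dataclass
class BoundaryConditions:
    """Fixed (zero-displacement) and driven (prescribed-displacement) node sets."""

    fixed_nodes: np.ndarray
    driven_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    driven_values: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self):
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        self.driven_nodes = np.asarray(self.driven_nodes, dtype=np.int64)
        self.driven_values = np.asarray(self.driven_values, dtype=float).reshape(-1, 3)
        if np.intersect1d(self.fixed_nodes, self.driven_nodes).size:
            raise ValueError("fixed and driven node sets must be disjoint")


@dataclass
class SimState:
    """Explicit-solver state: displacement history, forces, mass, time control."""

    u_t: np.ndarray      # (n, 3) mm
    u_tm1: np.ndarray    # (n, 3) mm
    F_int: np.ndarray    # (n, 3) N
    F_ext: np.ndarray    # (n, 3) N
    M: np.ndarray        # (n,) kg
    t: float             # s
    dt: float            # s
    damping: float = 0.0  # mass-proportional damping coefficient, 1/s
    n_steps: int = 0


def step(state: SimState, bcs: BoundaryConditions) -> SimState:
    """One damped central-difference step; prescribed nodes are overwritten.

    With ``damping`` c the update solves M u'' + c M u' + F_int = F_ext,
    the velocity discretized centrally; c = 0 recovers the plain scheme.
    """
    dt = state.dt
    zeta = 0.5 * state.damping * dt
    accel = (state.F_ext - state.F_int) / state.M[:, None] / _MM  # mm/s^2
    u_next = (dt * dt * accel + 2.0 * state.u_t
              - (1.0 - zeta) * state.u_tm1) / (1.0 + zeta)
    if bcs.fixed_nodes.size:
        u_next[bcs.fixed_nodes] = 0.0
    if bcs.driven_nodes.size:
        u_next[bcs.driven_nodes] = bcs.driven_values
    if not np.all(np.isfinite(u_next)):
        bad = int(np.flatnonzero(~np.isfinite(u_next).all(axis=1))[0])
        raise StabilityError(
            f"non-finite displacement at node {bad}, step {state.n_steps}")
    state.u_tm1 = state.u_t
    state.u_t = u_next
    state.t += dt
    state.n_steps += 1
    return state


@dataclass
class SolverSettings:
    """Quasi-static solution controls (dynamic relaxation).

    The solver uses a fictitious Gershgorin-bound diagonal mass at pseudo
    time step 1, so stability is unconditional up to ``stiffening_margin``
    of tangent-stiffness growth (guarded by periodic spectral re-checks),
    and mass-proportional damping whose coefficient is auto-tuned from a
    Rayleigh-quotient estimate of the dominant residual mode.
    ``settle_tol`` is the kinetic-to-strain-energy ratio accepted as static.
    """

    safety: float = 0.5
    density: float = 1000.0              # kg/m^3 (physical; for reaction recovery)
    damping_factor: float = 1.0          # multiple of the critical 2*omega_1
    ramp_steps: int = 1500               # pseudo-time steps per loading stage
    settle_tol: float = 1e-9
    settle_atol: float = 1e-30           # for zero-load stages
    max_steps_per_stage: int = 60000
    check_every: int = 25
    stiffening_margin: float = 3.0       # mass headroom for tangent stiffening
    dt_recompute_every: int = 1000       # steps between stability re-estimates
    spectral_iters: int = 20


@dataclass
class QuasiStaticResult:
    """Settled snapshots plus per-stage diagnostics."""

    depths: list
    displacements: list          # (n, 3) mm per snapshot
    reaction_forces: list        # N, signed along the drive axis
    diagnostics: list            # dicts: steps, KE, SE, ratio
    state: SimState
    driver: object = None


def _smoothstep(s: float) -> float:
    s = min(max(s, 0.0), 1.0)
    return s * s * (3.0 - 2.0 * s)


def run_quasi_static(grid: Grid, table: ShapeTable, materials, driver,
                     snapshot_depths, settings: SolverSettings | None = None,
                     fixed_nodes=None) -> QuasiStaticResult:
    """Drive the model through a monotone depth schedule and settle each stage.

    ``driver`` supplies the prescribed-displacement boundary conditions as a
    function of depth (see :class:`mtled.needle.NeedleDriver` and the simple
    drivers in :mod:`mtled.drivers`); it must expose
    ``targets(depth, u, strain_fn) -> (node_ids, values)``.
    """
    settings = settings or SolverSettings()
    mats = list(materials)
    # fictitious dynamic-relaxation mass: unconditionally stable at dt = 1
    # up to `stiffening_margin` of tangent-stiffness growth
    dt = 1.0
    masses = relaxation_mass(grid, table, mats, dt=dt,
                             margin=settings.stiffening_margin)
    n = grid.n_nodes
    mats_arr = _material_table(mats)
    mat_id = grid.material_id.astype(np.int64)
    vols = grid.cell_volumes
    conn, counts, grads = table.conn, table.counts, table.grad
    ramp_steps = max(int(settings.ramp_steps), 10)

    fixed = (np.asarray(fixed_nodes, dtype=np.int64)
             if fixed_nodes is not None else np.empty(0, np.int64))
    state = SimState(u_t=np.zeros((n, 3)), u_tm1=np.zeros((n, 3)),
                     F_int=np.zeros((n, 3)), F_ext=np.zeros((n, 3)),
                     M=masses, t=0.0, dt=dt, damping=0.0)
    f_buf = np.zeros((n, 3))

    def strain_fn(cell_ids):
        return max_green_strain_kernel(np.asarray(cell_ids, dtype=np.int64),
                                       conn, counts, grads, state.u_t)

    def eval_internal():
        energy, bad = internal_forces_kernel(conn, counts, grads, vols, mat_id,
                                             mats_arr, state.u_t, f_buf)
        if bad >= 0:
            raise FloatingPointError(
                f"inverted cell {bad} at step {state.n_steps}")
        state.F_int = f_buf * _FORCE_UNIT
        return energy * 1e-9  # Pa*mm^3 -> J

    snapshot_depths = list(snapshot_depths)
    depths_out, fields_out, forces_out, diags = [], [], [], []
    prev_depth = 0.0
    u_prev_for_accel = np.zeros((n, 3))
    last_recompute = 0
    u_mark = state.u_t.copy()
    f_mark = state.F_int.copy()

    def maybe_recompute_dt():
        # the tangent stiffens as strains grow; periodically re-check the
        # stability bound and shrink dt if the stiffening margin is eaten up,
        # rescaling the history so the discrete velocity is preserved
        nonlocal last_recompute
        if state.n_steps - last_recompute < settings.dt_recompute_every:
            return
        last_recompute = state.n_steps
        dt_new = 0.75 * spectral_time_step(
            table, grid, mats, masses, u=state.u_t,
            iters=settings.spectral_iters)
        if dt_new < state.dt:
            v = (state.u_t - state.u_tm1) / state.dt
            state.dt = dt_new
            state.u_tm1 = state.u_t - v * dt_new

    def tune_damping():
        # Rayleigh-quotient (secant) estimate of the dominant residual mode:
        # omega_1^2 ~ du.dF / du.M.du; mass-proportional damping at critical
        nonlocal u_mark, f_mark
        du = state.u_t - u_mark
        dF = state.F_int - f_mark
        num = float(np.sum(du * dF))            # N*mm
        den = float(np.sum(state.M[:, None] * du * du))  # kg*mm^2
        if num > 0 and den > 0:
            omega1 = math.sqrt(num / den / _MM)
            state.damping = min(settings.damping_factor * 2.0 * omega1,
                                2.0 / state.dt)
        u_mark = state.u_t.copy()
        f_mark = state.F_int.copy()

    for target_depth in snapshot_depths:
        # --- ramp stage ---
        stage_ramp = max(ramp_steps, 1)
        for i_r in range(stage_ramp):
            depth = prev_depth + (target_depth - prev_depth) * _smoothstep(
                (i_r + 1) / stage_ramp)
            ids, vals = driver.targets(depth, state.u_t, strain_fn,
                                       step=state.n_steps)
            bcs = BoundaryConditions(fixed_nodes=fixed, driven_nodes=ids,
                                     driven_values=vals)
            eval_internal()
            if (i_r + 1) % settings.check_every == 0:
                tune_damping()
            u_prev_for_accel = state.u_tm1
            step(state, bcs)
            maybe_recompute_dt()
        # --- relaxation stage at constant depth (the driver is re-polled so
        # capture-offset fades complete before the settle check can pass) ---
        depth = target_depth
        settled = False
        ke = se = ratio = float("nan")
        bcs = None
        for i_s in range(settings.max_steps_per_stage):
            if bcs is None or (i_s + 1) % settings.check_every == 0:
                ids, vals = driver.targets(depth, state.u_t, strain_fn,
                                           step=state.n_steps)
                bcs = BoundaryConditions(fixed_nodes=fixed, driven_nodes=ids,
                                         driven_values=vals)
            se = eval_internal()
            if (i_s + 1) % settings.check_every == 0:
                tune_damping()
                v = (state.u_t - state.u_tm1) * (_MM / state.dt)
                ke = 0.5 * float(np.sum(state.M[:, None] * v * v))
                ratio = ke / se if se > 0 else math.inf
                quiescent = not getattr(driver, "pending_fade",
                                        lambda s: False)(state.n_steps)
                if quiescent and (ke < settings.settle_atol
                                  or ratio < settings.settle_tol):
                    settled = True
                    break
            u_prev_for_accel = state.u_tm1
            step(state, bcs)
            maybe_recompute_dt()
        if not settled:
            raise SettleError(
                f"stage at depth {depth} mm did not settle in "
                f"{settings.max_steps_per_stage} steps "
                f"(KE={ke:.3e}, SE={se:.3e} J, ratio={ratio:.3e})")
        axis = getattr(driver, "axis", np.array([0.0, 0.0, -1.0]))
        rf = reaction_force(state, bcs.driven_nodes, axis,
                            u_prev=u_prev_for_accel)
        depths_out.append(depth)
        fields_out.append(state.u_t.copy())
        forces_out.append(rf)
        diags.append({"depth": depth, "steps": state.n_steps, "KE": ke,
                      "SE": se, "ratio": ratio, "dt": state.dt,
                      "damping": state.damping})
        prev_depth = depth
    return QuasiStaticResult(depths=depths_out, displacements=fields_out,
                             reaction_forces=forces_out, diagnostics=diags,
                             state=state, driver=driver)


def reaction_force(state: SimState, driven_nodes, axis,
                   u_prev: np.ndarray | None = None) -> float:
    """Signed projection on ``axis`` of the constraint force at driven nodes (N).

    The constraint force the drive exerts on the tissue is
    M u'' + F_int - F_ext per driven node; its projection on the drive axis is
    returned (the force on the needle is the reaction, equal and opposite).
    Accelerations are recovered by central differences of stored displacements.
    """
    driven_nodes = np.asarray(driven_nodes, dtype=np.int64)
    if driven_nodes.size == 0:
        raise ValueError("empty driven node set")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if u_prev is None:
        u_prev = state.u_tm1
    accel = (state.u_t - 2.0 * state.u_tm1 + u_prev) * (_MM / state.dt**2)
    f = (state.M[driven_nodes, None] * accel[driven_nodes]
         + state.F_int[driven_nodes] - state.F_ext[driven_nodes])
    return float(f.sum(axis=0) @ axis)
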