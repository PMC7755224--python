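"""Explicit solver: lumping, internal forces, stepping, patch tests."""

import numpy as np
import pytest

import mtled
from mtled.approximation import build_cell_gradient_table, build_shape_table
from mtled.drivers import AffineBoundaryDriver
from mtled.dynamics import (BoundaryConditions, SimState, SolverSettings,
                            StabilityError, compute_deformation_gradient,
                            critical_time_step, internal_forces, lumped_mass,
                            reaction_force, relaxation_mass, run_quasi_static,
                            step)
from mtled.materials import neo_hookean


@pytest.fixture(scope="module")
def block():
    """Moderate brick of nodes with its solver shape table (for patch tests)."""
    g = np.linspace(0.0, 10.0, 8)
    nodes = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
    rng = np.random.default_rng(5)
    interior = ((nodes > 0).all(axis=1)) & ((nodes < 10).all(axis=1))
    nodes[interior] += rng.uniform(-0.2, 0.2, size=(interior.sum(), 3))
    from scipy.spatial import Delaunay
    tri = Delaunay(nodes)
    cells = tri.simplices
    a, b, c, d = (nodes[cells[:, i]] for i in range(4))
    vols = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0
    cells[vols < 0] = cells[vols < 0][:, [0, 1, 3, 2]]
    vols = np.abs(vols)
    keep = vols > 1e-8
    from mtled.grids import Grid
    grid = Grid(nodes=nodes, cells=cells[keep], cell_volumes=vols[keep],
                quad_points=nodes[cells[keep]].mean(axis=1),
                material_id=np.zeros(keep.sum(), dtype=np.int64),
                boundary_sets={
                    "top": np.flatnonzero(nodes[:, 2] > 10 - 1e-9),
                    "bottom": np.flatnonzero(nodes[:, 2] < 1e-9),
                })
    table = build_cell_gradient_table(grid.nodes, grid.cells,
                                      grid.cell_volumes, grid.quad_points)
    return grid, table


class TestLumpedMass:
    def test_total_mass_conserved_exactly(self, small_grid, small_table):
        m = lumped_mass(small_grid, 1000.0, small_table)
        expected = 1000.0 * small_grid.total_volume * 1e-9
        assert m.sum() == pytest.approx(expected, rel=1e-12)
        assert (m > 0).all()

    def test_uniform_quarter_shares_for_symmetric_cell(self):
        """A cell whose centroid carries phi = 1/4 per node splits rho*V evenly."""
        from mtled.approximation import ShapeTable
        from mtled.grids import Grid
        nodes = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        cells = np.array([[0, 1, 2, 3]])
        grid = Grid(nodes=nodes, cells=cells, cell_volumes=np.array([1 / 6]),
                    quad_points=nodes.mean(0, keepdims=True),
                    material_id=np.zeros(1, dtype=np.int64))
        table = ShapeTable(points=grid.quad_points,
                           conn=np.array([[0, 1, 2, 3]], dtype=np.int32),
                           counts=np.array([4], dtype=np.int32),
                           phi=np.full((1, 4), 0.25), grad=None)
        m = lumped_mass(grid, 1000.0, table)
        np.testing.assert_allclose(m, 1000.0 * (1 / 6) * 1e-9 / 4)

    def test_invalid_density_rejected(self, small_grid, small_table):
        with pytest.raises(ValueError):
            lumped_mass(small_grid, 0.0, small_table)


class TestInternalForces:
    def test_zero_displacement_gives_zero_force(self, small_grid, small_table,
                                                ogden_gel):
        f = internal_forces(small_table, np.zeros((small_grid.n_nodes, 3)),
                            small_grid.material_id, [ogden_gel],
                            small_grid.cell_volumes)
        assert np.abs(f).max() == 0.0

    def test_rigid_translation_gives_zero_force(self, small_grid, small_table,
                                                ogden_gel):
        # translation and comparison compression have the same displacement
        # scale, so the bound is a genuine relative-roundoff statement
        u = np.broadcast_to([0.1, -0.1, 0.05], (small_grid.n_nodes, 3)).copy()
        f = internal_forces(small_table, u, small_grid.material_id,
                            [ogden_gel], small_grid.cell_volumes)
        uc = np.zeros_like(u)
        uc[:, 2] = -0.01 * small_grid.nodes[:, 2]
        fc = internal_forces(small_table, uc, small_grid.material_id,
                             [ogden_gel], small_grid.cell_volumes)
        assert np.abs(f).max() <= 1e-10 * np.abs(fc).max()

    def test_global_balance(self, small_grid, small_table, ogden_gel):
        # smooth nonlinear field (a random one can invert cells)
        x, y, z = small_grid.nodes.T
        u = np.column_stack([0.3 * np.sin(x / 8.0), 0.4 * np.cos(y / 9.0),
                             -0.02 * z + 0.2 * np.sin(z / 6.0)])
        f = internal_forces(small_table, u, small_grid.material_id,
                            [ogden_gel], small_grid.cell_volumes)
        assert np.abs(f.sum(axis=0)).max() <= 1e-8 * np.abs(f).max()

    def test_inverted_cell_detected(self, small_grid, small_table, ogden_gel):
        u = np.zeros((small_grid.n_nodes, 3))
        u[:, 2] = -1.2 * small_grid.nodes[:, 2]  # lambda_z < 0 everywhere
        with pytest.raises(FloatingPointError, match="inverted"):
            internal_forces(small_table, u, small_grid.material_id,
                            [ogden_gel], small_grid.cell_volumes)


class TestDeformationGradient:
    def test_zero_displacement_is_identity(self, small_table, small_grid):
        F = compute_deformation_gradient(small_table,
                                         np.zeros((small_grid.n_nodes, 3)), 0)
        np.testing.assert_allclose(F, np.eye(3))

    def test_affine_displacement_recovers_gradient(self, small_table,
                                                   small_grid):
        A = np.array([[0.02, 0.01, 0.0], [0.0, -0.03, 0.01], [0.0, 0.0, 0.05]])
        u = small_grid.nodes @ A.T
        for cell in (0, 100, 2000):
            F = compute_deformation_gradient(small_table, u, cell)
            np.testing.assert_allclose(F, np.eye(3) + A, atol=1e-9)

    def test_rigid_rotation_gives_orthogonal_gradient(self, small_table,
                                                      small_grid):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec([0.0, 0.0, 0.2]).as_matrix()
        u = small_grid.nodes @ (R - np.eye(3)).T
        F = compute_deformation_gradient(small_table, u, 500)
        np.testing.assert_allclose(F.T @ F, np.eye(3), atol=1e-8)


class TestTimeStep:
    def test_stiffness_scaling(self, small_grid, ogden_gel):
        base = critical_time_step(small_grid, [ogden_gel], 1000.0)
        stiff = critical_time_step(small_grid, [ogden_gel.scaled(100.0)], 1000.0)
        assert stiff == pytest.approx(base / 10.0, rel=1e-12)

    def test_zero_safety_rejected(self, small_grid, ogden_gel):
        with pytest.raises(ValueError):
            critical_time_step(small_grid, [ogden_gel], 1000.0, safety=0.0)

    def test_spacing_scaling(self, ogden_gel):
        a = mtled.generate_cylinder_grid(15.0, 17.0, 500, seed=1)
        import copy
        b = copy.deepcopy(a)
        b.nodes = 0.5 * b.nodes
        da = critical_time_step(a, [ogden_gel], 1000.0)
        db = critical_time_step(b, [ogden_gel], 1000.0)
        assert db == pytest.approx(da / 2.0, rel=1e-12)


class TestStep:
    def _single_node_state(self, dt=0.1, m=2.0):
        z = np.zeros((1, 3))
        return SimState(u_t=z.copy(), u_tm1=z.copy(), F_int=z.copy(),
                        F_ext=z.copy(), M=np.array([m]), t=0.0, dt=dt)

    def test_single_mass_closed_form_update(self):
        """u(t+dt) = dt^2 * F/m for a node at rest: 0.1^2 * 4/2 = 0.02 m."""
        st = self._single_node_state()
        st.F_ext = np.array([[0.0, 0.0, 4.0]])
        bcs = BoundaryConditions(fixed_nodes=np.empty(0, np.int64))
        step(st, bcs)
        assert st.u_t[0, 2] == pytest.approx(0.02e3)  # solver units are mm

    def test_equilibrium_is_stationary(self):
        st = self._single_node_state()
        st.u_t[:] = st.u_tm1[:] = [[1.0, 2.0, 3.0]]
        st.F_int = np.array([[0.0, 0.0, 4.0]])
        st.F_ext = st.F_int.copy()
        step(st, BoundaryConditions(fixed_nodes=np.empty(0, np.int64)))
        np.testing.assert_allclose(st.u_t, [[1.0, 2.0, 3.0]])

    def test_driven_node_follows_prescription_exactly(self):
        st = self._single_node_state()
        st.F_ext = np.array([[0.0, 0.0, 100.0]])
        bcs = BoundaryConditions(fixed_nodes=np.empty(0, np.int64),
                                 driven_nodes=np.array([0]),
                                 driven_values=np.array([[0.0, 0.0, -0.7]]))
        step(st, bcs)
        assert st.u_t[0, 2] == -0.7

    def test_instability_detected(self):
        st = self._single_node_state()
        st.F_ext = np.array([[0.0, 0.0, np.inf]])
        with pytest.raises(StabilityError):
            step(st, BoundaryConditions(fixed_nodes=np.empty(0, np.int64)))

    def test_disjoint_fixed_and_driven_enforced(self):
        with pytest.raises(ValueError):
            BoundaryConditions(fixed_nodes=np.array([0]),
                               driven_nodes=np.array([0]),
                               driven_values=np.zeros((1, 3)))


class TestQuasiStaticPatch:
    """Confined uniaxial compression of a brick: homogeneous closed form."""

    LAM = 0.9  # stretch in z

    @pytest.fixture(scope="class")
    def settled(self, block):
        grid, table = block
        mat = neo_hookean(1000.0, 0.49)
        boundary = np.flatnonzero(
            (np.abs(grid.nodes - 0.0) < 1e-9).any(axis=1)
            | (np.abs(grid.nodes - 10.0) < 1e-9).any(axis=1))
        A = np.diag([0.0, 0.0, self.LAM - 1.0])
        driver = AffineBoundaryDriver(boundary, grid.nodes, A,
                                      axis=(0.0, 0.0, -1.0))
        res = run_quasi_static(grid, table, [mat], driver, [1.0],
                               SolverSettings(ramp_steps=400))
        return grid, table, mat, res, boundary

    def test_interior_settles_to_homogeneous_field(self, settled):
        grid, _, _, res, _ = settled
        u = res.displacements[-1]
        exact = np.zeros_like(u)
        exact[:, 2] = (self.LAM - 1.0) * grid.nodes[:, 2]
        scale = np.abs(exact[:, 2]).max()
        # field-level agreement within 1%; the max-norm carries an O(1%)
        # boundary layer because interior shape functions do not vanish on
        # the Dirichlet surface (a known property of meshless essential BCs)
        rms = np.sqrt((((u - exact) ** 2).sum(axis=1)).mean())
        assert rms <= 0.01 * scale
        assert np.abs(u - exact).max() <= 0.03 * scale

    def test_reaction_matches_analytic_traction(self, settled):
        grid, _, mat, res, _ = settled
        # independent closed form: P = F S for F = diag(1,1,lam)
        lam = self.LAM
        J = lam
        C = np.diag([1.0, 1.0, lam**2])
        Ci = np.linalg.inv(C)
        S = mat.mu * J ** (-2 / 3) * (np.eye(3) - np.trace(C) / 3 * Ci) \
            + (2 / mat.D) * (J - 1) * J * Ci
        P = np.diag([1.0, 1.0, lam]) @ S
        area = 100.0 * 1e-6  # 10 x 10 mm in m^2
        expected = abs(P[2, 2]) * area
        # the driver prescribes all six faces, so the summed constraint force
        # cancels; measure the top face alone
        measured = abs(reaction_force(res.state, grid.boundary_sets["top"],
                                      (0.0, 0.0, -1.0)))
        assert measured == pytest.approx(expected, rel=0.02)

    def test_material_scaling_leaves_displacements_invariant(self, block):
        grid, table = block
        boundary = np.flatnonzero(
            (np.abs(grid.nodes - 0.0) < 1e-9).any(axis=1)
            | (np.abs(grid.nodes - 10.0) < 1e-9).any(axis=1))
        A = np.diag([0.0, 0.0, -0.05])
        fields = {}
        forces = {}
        for s in (1.0, 100.0):
            mat = neo_hookean(1000.0 * s, 0.49)
            driver = AffineBoundaryDriver(boundary, grid.nodes, A,
                                          axis=(0.0, 0.0, -1.0))
            res = run_quasi_static(grid, table, [mat], driver, [1.0],
                                   SolverSettings(ramp_steps=400))
            fields[s] = res.displacements[-1]
            forces[s] = res.reaction_forces[-1]
        comp = mtled.nrmse(fields[100.0], fields[1.0])
        assert comp.max_nrmse <= 1e-4
        assert forces[100.0] == pytest.approx(100.0 * forces[1.0], rel=1e-3)

    def test_zero_schedule_keeps_zero_field(self, block, ogden_gel):
        grid, table = block
        driver = AffineBoundaryDriver(grid.boundary_sets["top"], grid.nodes,
                                      np.zeros((3, 3)))
        res = run_quasi_static(grid, table, [ogden_gel], driver, [0.0],
                               SolverSettings(ramp_steps=50),
                               fixed_nodes=grid.boundary_sets["bottom"])
        assert np.abs(res.displacements[-1]).max() == 0.0

    def test_reaction_force_empty_driven_set_rejected(self):
        st = SimState(u_t=np.zeros((1, 3)), u_tm1=np.zeros((1, 3)),
                      F_int=np.zeros((1, 3)), F_ext=np.zeros((1, 3)),
                      M=np.ones(1), t=0.0, dt=0.1)
        with pytest.raises(ValueError):
            reaction_force(st, np.empty(0, np.int64), [0, 0, 1])


class TestRelaxationMass:
    def test_positive_and_scales_with_stiffness(self, small_grid, small_table,
                                                ogden_gel):
        m1 = relaxation_mass(small_grid, small_table, [ogden_gel])
        m2 = relaxation_mass(small_grid, small_table, [ogden_gel.scaled(10.0)])
        assert (m1 > 0).all()
        np.testing.assert_allclose(m2, 10.0 * m1, rtol=1e-12)
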