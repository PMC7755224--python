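"""Two-parameter kinematic needle model: phases, capture, prescriptions."""

import numpy as np
import pytest

import mtled
from mtled.needle import (InsertionMeasurement, KinematicParams, NeedleDriver,
                          NeedleModelError, NeedleSpec, PhaseState,
                          check_puncture, estimate_cd, indentation_update,
                          monitored_cells, penetration_update,
                          select_contact_nodes, update_driven_set)


@pytest.fixture(scope="module")
def spec(small_grid):
    return NeedleSpec(entry_point=[0.0, 0.0, 17.0], axis=[0.0, 0.0, -1.0],
                      diameter=1.6, max_depth=15.0)


class TestDeformationCoefficient:
    def test_image_identified_ratio(self):
        """8 mm insertion with 3.2 mm surface deflection identifies C_D = 0.4."""
        assert estimate_cd(InsertionMeasurement(U1=8.0, U2=3.2)) == pytest.approx(0.4)

    def test_no_surface_drag(self):
        assert estimate_cd(InsertionMeasurement(U1=5.0, U2=0.0)) == 0.0

    def test_zero_depth_rejected(self):
        with pytest.raises(NeedleModelError):
            estimate_cd(InsertionMeasurement(U1=0.0, U2=0.0))

    def test_clipped_to_unit_interval(self):
        assert estimate_cd(InsertionMeasurement(U1=1.0, U2=2.0)) == 1.0


class TestContactSelection:
    def test_footprint_nodes_selected(self, small_grid, spec):
        with pytest.warns(UserWarning):
            nodes = select_contact_nodes(small_grid, spec)
        assert len(nodes) >= 1
        d = np.linalg.norm(small_grid.nodes[nodes] - spec.entry_point, axis=1)
        assert (d <= 3.0 * spec.radius).all()
        assert np.isin(nodes, small_grid.boundary_sets["top"]).all()

    def test_fine_grid_gives_multiple_contacts(self):
        grid = mtled.generate_cylinder_grid(15.0, 17.0, 18000, seed=1)
        spec = NeedleSpec(entry_point=[0, 0, 17.0], axis=[0, 0, -1.0],
                          diameter=3.2)
        nodes = select_contact_nodes(grid, spec)
        assert len(nodes) > 1

    def test_zero_diameter_rejected(self):
        with pytest.raises(NeedleModelError):
            NeedleSpec(entry_point=[0, 0, 17.0], axis=[0, 0, -1], diameter=0.0)


class TestPhases:
    def _phase(self, contacts=(0, 1)):
        return PhaseState(contact_nodes=np.asarray(contacts, dtype=np.int64))

    def test_indentation_prescribes_tip_displacement(self, spec):
        ph = self._phase()
        ids, vals = indentation_update(ph, spec, 0.5)
        np.testing.assert_array_equal(ids, [0, 1])
        np.testing.assert_allclose(vals, [[0, 0, -0.5], [0, 0, -0.5]])

    def test_indentation_monotone_with_depth(self, spec):
        ph = self._phase()
        _, v1 = indentation_update(ph, spec, 0.2)
        _, v2 = indentation_update(ph, spec, 0.6)
        assert (np.abs(v2) >= np.abs(v1)).all()

    def test_indentation_rejected_after_puncture(self, spec):
        ph = self._phase()
        ph.to_penetration(0.01)
        with pytest.raises(NeedleModelError):
            indentation_update(ph, spec, 0.5)

    def test_single_transition(self):
        ph = self._phase()
        ph.to_penetration(0.01)
        with pytest.raises(NeedleModelError):
            ph.to_penetration(0.02)
        assert ph.transitions == 1

    def test_contact_nodes_carried_into_driven_set(self):
        ph = self._phase((3, 7))
        ph.to_penetration(0.01)
        assert set(ph.driven_ids) >= {3, 7}


class TestPuncture:
    def test_strain_above_threshold_punctures(self):
        assert check_puncture(2e-5, 1e-5) is True

    def test_zero_strain_no_puncture(self):
        assert check_puncture(0.0, 1e-5) is False

    def test_tie_does_not_puncture(self):
        assert check_puncture(1e-5, 1e-5) is False

    def test_monitored_cells_near_entry(self, small_grid, spec):
        ids = monitored_cells(small_grid, spec, 4.0)
        d = np.linalg.norm(small_grid.quad_points[ids] - spec.entry_point,
                           axis=1)
        assert (d <= 4.0).all()
        with pytest.raises(NeedleModelError):
            monitored_cells(small_grid, spec, 1e-6)


class TestDrivenSet:
    def test_monotone_growth_with_depth(self, small_grid, spec):
        ph = PhaseState(contact_nodes=np.array([0], dtype=np.int64))
        ph.to_penetration(0.0)
        sizes = []
        for depth in (2.0, 6.0, 10.0, 15.0):
            update_driven_set(ph, small_grid, spec, 3.0, depth)
            sizes.append(len(ph.driven_ids))
        assert sizes == sorted(sizes)
        # sleeve membership: perpendicular distance within capture radius
        rel = small_grid.nodes[ph.driven_ids] - spec.entry_point
        s = rel @ spec.axis
        perp = np.linalg.norm(rel - s[:, None] * spec.axis, axis=1)
        mask = ~np.isin(ph.driven_ids, [0])
        assert (perp[mask] <= 3.0 + 1e-9).all()
        assert (s[mask] >= -1e-9).all()
        assert (s[mask] <= 15.0 + 1e-9).all()

    def test_tiny_capture_radius_warns(self, small_grid):
        # entry point off any node, so a vanishing capture radius finds nothing
        off = NeedleSpec(entry_point=[0.37, 0.41, 17.0], axis=[0, 0, -1.0],
                         diameter=1.6)
        ph = PhaseState(contact_nodes=np.empty(0, np.int64))
        ph.to_penetration(0.0)
        with pytest.warns(UserWarning):
            update_driven_set(ph, small_grid, off, 1e-9, 1.0)
        assert len(ph.driven_ids) == 0

    def test_capture_is_continuous_then_purely_geometric(self, small_grid,
                                                         spec):
        """Capture offsets fade: continuous at capture, pure rule afterwards."""
        ph = PhaseState(contact_nodes=np.empty(0, np.int64))
        ph.to_penetration(0.0)
        u = np.zeros((small_grid.n_nodes, 3))
        u[:, 2] = -1.0  # every node already moved 1 mm along the axis
        update_driven_set(ph, small_grid, spec, 3.0, 10.0, u=u, step=100.0)
        # at the instant of capture the prescription equals the free motion
        _, vals = penetration_update(ph, spec, 0.4, 10.0, fade_steps=200,
                                     step=100.0)
        np.testing.assert_allclose(vals[:, 2], -1.0, atol=1e-12)
        # once the fade has elapsed only the pure kinematic rule remains
        _, vals = penetration_update(ph, spec, 0.4, 12.5, fade_steps=200,
                                     step=400.0)
        np.testing.assert_allclose(vals[:, 2], -0.4 * 2.5, atol=1e-12)


class TestPenetration:
    def test_driven_fraction_of_needle_travel(self, spec):
        """C_D = 0.4: nodes move 40% of the needle travel since activation."""
        ph = PhaseState(contact_nodes=np.array([2], dtype=np.int64))
        ph.to_penetration(0.0)
        ids, vals = penetration_update(ph, spec, 0.4, 1.0)
        np.testing.assert_allclose(vals, [[0.0, 0.0, -0.4]])

    @pytest.mark.parametrize("cd,expect", [(0.0, 0.0), (1.0, -2.0)])
    def test_cd_limits(self, spec, cd, expect):
        ph = PhaseState(contact_nodes=np.array([2], dtype=np.int64))
        ph.to_penetration(0.0)
        _, vals = penetration_update(ph, spec, cd, 2.0)
        assert vals[0, 2] == pytest.approx(expect)

    def test_retraction_rejected(self, spec):
        ph = PhaseState(contact_nodes=np.array([2], dtype=np.int64))
        ph.to_penetration(5.0)
        with pytest.raises(NeedleModelError):
            penetration_update(ph, spec, 0.4, 4.0)

    def test_invalid_kinematic_params_rejected(self):
        with pytest.raises(NeedleModelError):
            KinematicParams(cd=1.5)
        with pytest.raises(NeedleModelError):
            KinematicParams(eps_p=-1.0)


class TestDriverIntegration:
    def test_phase_machine_punctures_early_with_small_eps(self, small_grid,
                                                          spec):
        """With eps_p = 1e-5 the indentation stage lasts only a few updates."""
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            driver = NeedleDriver(small_grid, spec, KinematicParams(eps_p=1e-5))
        # mimic the solver: as soon as any monitored strain passes eps_p the
        # driver switches; feed it a growing fake strain
        strains = iter([0.0, 5e-6, 2e-5, 1e-4])

        def strain_fn(cells):
            return next(strains)

        u = np.zeros((small_grid.n_nodes, 3))
        for depth in (0.001, 0.002, 0.003, 0.004):
            driver.targets(depth, u, strain_fn)
        assert driver.phase.phase == "penetration"
        assert driver.phase.puncture_depth <= 0.003
        assert driver.phase.transitions == 1
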