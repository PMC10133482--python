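import numpy as np
import pytest

import squirmtopo as sq
from squirmtopo.errors import AssemblyError


def make_problem(state, n_s=4, N_s=18, eps=1e-3):
    return sq.MobilityProblem.build(state, sq.KernelSpec("reg_stokeslet", eps), n_s, N_s)


class TestNearestNeighbourMatrix:
    def test_identity_when_sets_coincide(self):
        ns = sq.sphere_surface_nodes(3)
        nu = sq.nearest_neighbour_matrix(ns, ns)
        np.testing.assert_array_equal(nu.toarray(), np.eye(ns.count))

    def test_rows_sum_to_one(self):
        coarse = sq.sphere_surface_nodes(4)
        fine = sq.sphere_surface_nodes(18, level="fine")
        nu = sq.nearest_neighbour_matrix(coarse, fine)
        np.testing.assert_array_equal(np.asarray(nu.sum(axis=1)).ravel(), 1.0)

    def test_matches_brute_force_example(self):
        coarse = sq.NodeSet([[0, 0, 0], [1, 0, 0]], [1.0, 1.0], "swimmer", "coarse")
        fine = sq.NodeSet(
            [[0.1, 0, 0], [0.4, 0, 0], [0.9, 0, 0]], [1.0] * 3, "swimmer", "fine"
        )
        nu = sq.nearest_neighbour_matrix(coarse, fine)
        np.testing.assert_array_equal(nu.toarray(), [[1, 0], [1, 0], [0, 1]])

    def test_cross_body_entries_vanish(self):
        sw_c = sq.sphere_surface_nodes(2, centre=[0, 0, 1.5])
        wall_c = sq.NodeSet([[0, 0, 0], [1, 0, 0]], [1.0, 1.0], "wall", "coarse")
        sw_f = sq.sphere_surface_nodes(4, centre=[0, 0, 1.5], level="fine")
        wall_f = sq.NodeSet([[0.2, 0, 0]], [1.0], "wall", "fine")
        coarse = sq.concatenate_node_sets(sw_c, wall_c)
        fine = sq.concatenate_node_sets(sw_f, wall_f)
        nu = sq.nearest_neighbour_matrix(coarse, fine).toarray()
        # wall fine node selects a wall coarse node even though swimmer
        # nodes may be closer in space
        assert nu[-1, -2] == 1
        assert nu[: sw_f.count, sw_c.count :].sum() == 0

    def test_empty_raises(self):
        ns = sq.sphere_surface_nodes(2)
        empty = sq.NodeSet(np.empty((0, 3)), np.empty(0), "swimmer", "fine")
        with pytest.raises(AssemblyError):
            sq.nearest_neighbour_matrix(ns, empty)


class TestAssembly:
    def test_free_space_dimension(self, free_state):
        system = sq.assemble_mobility_system(make_problem(free_state))
        assert system.matrix.shape == (3 * 96 + 6, 3 * 96 + 6)

    def test_wall_dimension(self, free_state):
        prob = sq.MobilityProblem.build(
            sq.SquirmerState(centre=[0, 0, 1.2], orientation=[0, 0, 1]),
            sq.KernelSpec("reg_stokeslet", 1e-3),
            4,
            18,
            wall_spec=sq.WallPatchSpec(8.0, 16, 45),
            topography=sq.Topography("flat", 0.0, 1.0),
        )
        system = sq.assemble_mobility_system(prob)
        assert system.matrix.shape == (3 * (96 + 256) + 6,) * 2

    def test_balance_rows_on_constant_traction(self, free_state):
        # a constant traction integrates to (total area) * g and zero torque
        system = sq.assemble_mobility_system(make_problem(free_state))
        N = system.coarse.count
        g = np.tile([0.3, -0.2, 0.5], N)
        bal = system.matrix[3 * N :, : 3 * N] @ g
        np.testing.assert_allclose(bal[:3], 4 * np.pi * np.array([0.3, -0.2, 0.5]), rtol=1e-10)
        np.testing.assert_allclose(bal[3:], 0.0, atol=1e-12)

    def test_duplicate_collocation_raises(self, free_state, stokeslet_kernel):
        ns = sq.sphere_surface_nodes(3)
        dup = sq.NodeSet(
            np.vstack([ns.positions, ns.positions[:1]]),
            np.append(ns.weights, ns.weights[0]),
            "swimmer",
            "coarse",
        )
        prob = sq.MobilityProblem(
            free_state, stokeslet_kernel, dup, sq.sphere_surface_nodes(8, level="fine")
        )
        with pytest.raises(AssemblyError):
            sq.assemble_mobility_system(prob)


class TestFreeSpaceMobility:
    def test_reference_speed(self, free_state):
        # |U| at eps = 1e-3, (n_s, N_s) = (4, 18): tabulated value 1.0048
        sol = sq.solve_mobility(make_problem(free_state))
        assert np.linalg.norm(sol.U) == pytest.approx(1.0048, rel=5e-3)
        assert np.linalg.norm(sol.Omega) < 1e-6

    def test_velocity_parallel_to_orientation(self):
        state = sq.SquirmerState(orientation=[0.0, 0.0, 1.0], B1=1.5, beta=3.0)
        sol = sq.solve_mobility(make_problem(state))
        cross = np.linalg.norm(np.cross(sol.U, state.orientation))
        assert cross / np.linalg.norm(sol.U) < 1e-6

    def test_speed_independent_of_beta(self, free_state):
        s0 = np.linalg.norm(sq.solve_mobility(make_problem(free_state)).U)
        state7 = sq.SquirmerState(orientation=[0, 0, 1], B1=1.5, beta=7.0)
        s7 = np.linalg.norm(sq.solve_mobility(make_problem(state7)).U)
        assert abs(s7 - s0) < 1e-3

    def test_balance_residuals_small(self, free_state):
        sol = sq.solve_mobility(make_problem(free_state))
        scale = max(1.0, np.abs(sol.tractions).max())
        assert np.abs(sol.force_residual).max() < 1e-8 * scale
        assert np.abs(sol.torque_residual).max() < 1e-8 * scale

    def test_regularisation_convergence(self, free_state):
        # O(eps) regularisation error: 1e-2 -> 1e-3 changes |U| by < 0.5%
        a = np.linalg.norm(sq.solve_mobility(make_problem(free_state, eps=1e-2)).U)
        b = np.linalg.norm(sq.solve_mobility(make_problem(free_state, eps=1e-3)).U)
        assert abs(a - b) / b < 0.005


class TestResistance:
    def test_translation_drag_is_stokes_law(self):
        state = sq.SquirmerState(orientation=[0, 0, 1], B1=0.0)
        F, T = sq.solve_resistance(make_problem(state), [0, 0, 1.0], [0, 0, 0])
        assert np.linalg.norm(F) == pytest.approx(6 * np.pi, rel=0.02)

    def test_rotation_torque(self):
        state = sq.SquirmerState(orientation=[0, 0, 1], B1=0.0)
        F, T = sq.solve_resistance(make_problem(state), [0, 0, 0], [0, 0, 1.0])
        assert np.linalg.norm(T) == pytest.approx(8 * np.pi, rel=0.02)

    def test_zero_motion_zero_loads(self):
        state = sq.SquirmerState(orientation=[0, 0, 1], B1=0.0)
        F, T = sq.solve_resistance(make_problem(state), np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(F, 0.0, atol=1e-12)
        np.testing.assert_allclose(T, 0.0, atol=1e-12)

    def test_requires_passive_sphere(self, free_state):
        with pytest.raises(ValueError):
            sq.solve_resistance(make_problem(free_state), np.zeros(3), np.zeros(3))

    def test_mobility_resistance_reciprocity(self):
        # towing with force F must give U ~ F / (6 pi mu a)
        state = sq.SquirmerState(orientation=[0, 0, 1], B1=0.0)
        F = np.array([0.0, 0.0, 2.0])
        sol = sq.solve_mobility(make_problem(state), external_force=F)
        U_expected = F / (6 * np.pi)
        assert np.linalg.norm(sol.U) == pytest.approx(np.linalg.norm(U_expected), rel=0.02)
        assert np.dot(sol.U, F) > 0


class TestWallVariantAgreement:
    def test_blakelet_vs_rescaled_patch_velocities(self):
        # the image-system kernel and the explicit rescaled wall patch
        # are two discretisations of the same flat-wall problem
        state = sq.SquirmerState.from_angles(
            [0.0, 0.0, 1.2], -0.17 * np.pi, 0.5 * np.pi, B1=1.5, beta=7.0
        )
        blake = sq.solve_mobility(
            sq.MobilityProblem.build(state, sq.KernelSpec("reg_blakelet", 1e-3), 4, 18)
        )
        patch = sq.solve_mobility(
            sq.MobilityProblem.build(
                state,
                sq.KernelSpec("reg_stokeslet", 1e-3),
                4,
                18,
                wall_spec=sq.WallPatchSpec(),
                topography=sq.Topography("flat", 0.0, 1.0),
            )
        )
        speed = np.linalg.norm(blake.U)
        assert np.linalg.norm(patch.U - blake.U) / speed < 0.03
        # Omega is small; compare it on the natural rate scale |U| / a
        assert np.linalg.norm(patch.Omega - blake.Omega) / speed < 0.03


class TestGaugeRobustness:
    def test_normal_traction_does_not_move_the_body(self, free_state):
        # adding c * (outward normal) to the traction is a gauge change:
        # re-substituted through the balance rows it shifts the computed
        # force and torque by far less than c
        prob = make_problem(free_state)
        system = sq.assemble_mobility_system(prob)
        sol = sq.solve_mobility(prob)
        normals = prob.swimmer_coarse.positions - free_state.centre
        c = 1e-6
        g2 = sol.tractions + c * normals
        dF = (system.areas[:, None] * (g2 - sol.tractions)).sum(axis=0)
        dT = np.cross(system.moments, g2 - sol.tractions).sum(axis=0)
        assert np.abs(dF).max() < 1e-8
        assert np.abs(dT).max() < 1e-8
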