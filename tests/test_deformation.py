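"""The improved mass-spring model: constraints, masses, integration, bounds."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import leafsim as ls
from leafsim.deformation import _forces
from leafsim.errors import ConfigurationError, InvalidInputError


def single_triangle_mesh():
    return ls.TriMesh(
        vertices=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        triangles=np.array([[0, 1, 2]]),
        boundary=np.ones(3, bool),
        uv=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
    )


def two_triangle_mesh():
    return ls.TriMesh(
        vertices=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        triangles=np.array([[0, 1, 2], [0, 2, 3]]),
        boundary=np.ones(4, bool),
        uv=np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float),
    )


class TestBuildConstraints:
    def test_single_triangle_has_three_springs(self):
        cons = ls.build_constraints(single_triangle_mesh())
        assert len(cons) == 3

    def test_shared_edge_not_duplicated(self):
        cons = ls.build_constraints(two_triangle_mesh())
        assert len(cons) == 5
        pairs = {tuple(sorted(p)) for p in cons.pairs}
        assert len(pairs) == 5
        assert (0, 2) in pairs  # the diagonal shared by both triangles

    def test_count_matches_unique_edge_set_oracle(self, maple_mesh):
        cons = ls.build_constraints(maple_mesh)
        edges = set()
        for a, b, c in maple_mesh.triangles:
            edges |= {tuple(sorted(e)) for e in ((a, b), (b, c), (c, a))}
        assert len(cons) == len(edges)
        assert {tuple(sorted(p)) for p in cons.pairs} == edges

    def test_rest_lengths_are_edge_lengths(self):
        mesh = two_triangle_mesh()
        cons = ls.build_constraints(mesh)
        P = mesh.vertices3
        expected = np.linalg.norm(P[cons.pairs[:, 0]] - P[cons.pairs[:, 1]], axis=1)
        assert np.array_equal(cons.rest_lengths, expected)


class TestMassFromMask:
    def test_black_pixel_gives_half(self):
        mask = ls.MaskMap(np.zeros((1, 1), dtype=np.uint8))
        mesh = single_triangle_mesh()
        assert np.all(ls.mass_from_mask(mesh, mask) == 0.5)

    @pytest.mark.parametrize("gray,expected", [(1, np.log(2.0)), (255, np.log(256.0))])
    def test_log_mapping(self, gray, expected):
        mask = ls.MaskMap(np.full((1, 1), gray, dtype=np.uint8))
        masses = ls.mass_from_mask(single_triangle_mesh(), mask)
        assert masses == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_gray_over_full_range(self):
        mask = ls.MaskMap(np.arange(256, dtype=np.uint8).reshape(1, 256))
        uv = np.column_stack([(np.arange(256) + 0.5) / 256, np.full(256, 0.5)])
        mesh = ls.TriMesh(
            vertices=np.zeros((256, 2)),
            triangles=np.array([[0, 1, 2]]),
            boundary=np.zeros(256, bool),
            uv=uv,
        )
        masses = ls.mass_from_mask(mesh, mask)
        assert np.all(np.diff(masses) > 0)
        assert masses[0] == 0.5
        assert np.all((masses >= 0.5) & (masses <= np.log(256.0)))

    def test_uv_outside_unit_square_rejected(self):
        mesh = single_triangle_mesh()
        mesh.uv[0] = [1.5, 0.0]
        with pytest.raises(InvalidInputError):
            ls.mass_from_mask(mesh, ls.MaskMap(np.zeros((2, 2), dtype=np.uint8)))


class TestEulerStep:
    def test_zero_forces_zero_velocity_is_fixed_point(self):
        mesh = two_triangle_mesh()
        cons = ls.build_constraints(mesh)
        ps = ls.ParticleSystem.from_mesh(mesh, np.ones(4))
        before = ps.positions.copy()
        ls.euler_step(ps, cons, ls.SimConfig())
        assert np.array_equal(ps.positions, before)

    def test_hand_computed_single_particle_update(self):
        # mu=2, F=(0,0,-4), dt=0.1: a=(0,0,-2), v=(0,0,-0.2), dP=(0,0,-0.02)
        cons = ls.SpringConstraints(
            pairs=np.array([[0, 1]]), rest_lengths=np.array([1.0])
        )
        ps2 = ls.ParticleSystem(
            masses=np.array([2.0, 1.0]),
            positions=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            velocities=np.zeros((2, 3)),
            accelerations=np.zeros((2, 3)),
            fixed=np.array([False, True]),
        )
        config = ls.SimConfig(
            dt=0.1, damping=0.0,
            external_force=ls.constant_force([0.0, 0.0, -4.0]),
        )
        ls.euler_step(ps2, cons, config)
        assert np.allclose(ps2.accelerations[0], [0, 0, -2.0])
        assert np.allclose(ps2.velocities[0], [0, 0, -0.2])
        assert np.allclose(ps2.positions[0], [0.0, 0.0, -0.02])

    def test_fixed_particle_never_moves(self):
        mesh = two_triangle_mesh()
        cons = ls.build_constraints(mesh)
        fixed = np.array([True, False, False, False])
        ps = ls.ParticleSystem.from_mesh(mesh, np.ones(4), fixed)
        config = ls.SimConfig(external_force=ls.constant_force([5.0, 0, -3.0]))
        for _ in range(20):
            ls.euler_step(ps, cons, config)
        assert np.array_equal(ps.positions[0], mesh.vertices3[0])
        assert np.all(ps.velocities[0] == 0)


class TestConstrainVelocities:
    def two_particle(self, fixed=(False, False), v=(0, 0, 0)):
        return ls.ParticleSystem(
            masses=np.ones(2),
            positions=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            velocities=np.array([[0.0, 0, 0], list(v)]),
            accelerations=np.zeros((2, 3)),
            fixed=np.array(fixed),
        )

    def cons(self):
        return ls.SpringConstraints(
            pairs=np.array([[0, 1]]), rest_lengths=np.array([1.0])
        )

    def test_resting_spring_untouched(self):
        ps = self.two_particle(v=(1e-4, 0, 0))
        before = ps.velocities.copy()
        ls.constrain_velocities(ps, self.cons(), ls.SimConfig(dt=0.01, tau_c=0.1))
        assert np.array_equal(ps.velocities, before)

    @pytest.mark.parametrize("tau_c,limit", [(0.1, 1.1), (0.0, 1.0)])
    def test_overstretch_clamped_to_bound(self, tau_c, limit):
        # tentative velocities would stretch the unit spring to 1.25
        config = ls.SimConfig(dt=0.1, tau_c=tau_c)
        ps = self.two_particle(v=(2.5, 0, 0))
        ls.constrain_velocities(ps, self.cons(), config)
        rel = (ps.positions[1] + config.dt * ps.velocities[1]) - (
            ps.positions[0] + config.dt * ps.velocities[0]
        )
        assert np.linalg.norm(rel) <= limit + 1e-9

    def test_fixed_endpoint_absorbs_no_correction(self):
        config = ls.SimConfig(dt=0.1, tau_c=0.1)
        ps = self.two_particle(fixed=(True, False), v=(2.5, 0, 0))
        ls.constrain_velocities(ps, self.cons(), config)
        assert np.all(ps.velocities[0] == 0)
        rel = ps.positions[1] + config.dt * ps.velocities[1] - ps.positions[0]
        assert np.linalg.norm(rel) <= 1.1 + 1e-9

    def test_two_fixed_violating_endpoints_rejected(self):
        config = ls.SimConfig(dt=0.1, tau_c=0.0)
        ps = ls.ParticleSystem(
            masses=np.ones(2),
            positions=np.array([[0.0, 0, 0], [1.5, 0, 0]]),
            velocities=np.zeros((2, 3)),
            accelerations=np.zeros((2, 3)),
            fixed=np.array([True, True]),
        )
        with pytest.raises(ConfigurationError):
            ls.constrain_velocities(ps, self.cons(), config)


class TestSimulate:
    def test_zero_steps_yields_only_initial_snapshot(
        self, maple_mesh, dark_edge_mask, sim_config
    ):
        snaps = ls.simulate(maple_mesh, dark_edge_mask, sim_config, n_steps=0)
        assert len(snaps) == 1
        assert np.array_equal(snaps[0].vertices, maple_mesh.vertices3)

    def test_elongation_bound_holds_every_step(self, maple_mesh, dark_edge_run):
        cons = ls.build_constraints(maple_mesh)
        for snap in dark_edge_run:
            lengths = cons.current_lengths(snap.vertices3)
            assert np.all(
                lengths <= (1.1) * cons.rest_lengths + 1e-9
            )

    def test_darker_regions_move_more(self, maple_mesh, dark_edge_mask, dark_edge_run):
        gray = dark_edge_mask.values_at_uv(maple_mesh.uv)
        disp = np.linalg.norm(
            dark_edge_run[-1].vertices3 - dark_edge_run[0].vertices3, axis=1
        )
        assert disp[gray < 64].mean() > disp[gray > 192].mean()

    def test_symmetric_setup_deforms_symmetrically(self, symmetric_cross_mesh):
        mask = ls.MaskMap(np.full((8, 8), 128, dtype=np.uint8))
        config = ls.SimConfig(external_force=ls.constant_force([0, 0, -1.0]))
        snaps = ls.simulate(
            symmetric_cross_mesh, mask, config, n_steps=50, snapshot_every=50,
            petiole=(0.0, 0.0), anchor_radius=0.1,
        )
        P = snaps[-1].vertices3
        # mirror pairs across the x axis: (0,3) and (1,2)
        for i, j in ((0, 3), (1, 2)):
            assert np.allclose(P[i] * [1, -1, 1], P[j], atol=1e-6)

    def test_anchored_vertices_bit_identical(self, symmetric_cross_mesh):
        mask = ls.MaskMap(np.full((4, 4), 200, dtype=np.uint8))
        config = ls.SimConfig(external_force=ls.constant_force([0, 0, -1.0]))
        snaps = ls.simulate(
            symmetric_cross_mesh, mask, config, n_steps=100, snapshot_every=100,
            petiole=(0.0, 0.0), anchor_radius=0.1,
        )
        assert np.array_equal(snaps[-1].vertices3[4], symmetric_cross_mesh.vertices3[4])

    def test_trajectories_are_deterministic(self, maple_mesh, dark_edge_mask, sim_config):
        a = ls.simulate(maple_mesh, dark_edge_mask, sim_config, 40, snapshot_every=40)
        b = ls.simulate(maple_mesh, dark_edge_mask, sim_config, 40, snapshot_every=40)
        assert np.array_equal(a[-1].vertices, b[-1].vertices)

    def test_kinetic_energy_dissipates_without_forcing(self):
        mesh = two_triangle_mesh()
        cons = ls.build_constraints(mesh)
        ps = ls.ParticleSystem.from_mesh(mesh, np.full(4, 2.0))
        config_on = ls.SimConfig(damping=0.5,
                                 external_force=ls.constant_force([0.5, 0, -1.0]))
        for _ in range(50):  # pump some energy in
            ls.euler_step(ps, cons, config_on)
            ls.constrain_velocities(ps, cons, config_on)
        config_off = ls.SimConfig(damping=0.5, external_force=None)
        ke = [ps.kinetic_energy()]
        for _ in range(200):
            ls.euler_step(ps, cons, config_off)
            ls.constrain_velocities(ps, cons, config_off)
            ke.append(ps.kinetic_energy())
        assert all(b <= a + 1e-12 for a, b in zip(ke, ke[1:]))


@given(g1=st.integers(0, 255), g2=st.integers(0, 255))
def test_mass_mapping_monotone_property(g1, g2):
    """Mass from gray never decreases as the pixel brightens."""
    def mass(g):
        return 0.5 if g == 0 else float(np.log(g + 1.0))

    lo, hi = sorted((g1, g2))
    assert mass(lo) <= mass(hi)
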