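"""Continuous-model MD: potentials, forces, integrator, walls, workflows."""

import numpy as np
import pytest

from saltmix.md import (
    ContinuousPotentialParams,
    MDIntegrator,
    MDSystem,
    WallSpec,
    WALL_ATTRACT_BOTH,
    WALL_ATTRACT_SP1,
    kinetic_temperature,
    largest_cluster_fraction,
    pair_force,
    pair_potential,
    potential_energy,
    random_system,
    run_adsorption_scaled,
    run_nve,
    run_slit,
    step,
    wall_force,
    wall_potential,
)


class TestPairPotential:
    def test_contact_value_like(self):
        # LJ terms cancel at r = 1; only the screened tail remains
        assert pair_potential(1.0, 1, 1) == pytest.approx(1.8 * np.exp(-0.5))

    def test_zero_beyond_cutoff(self):
        for r in (6.75, 6.76, 7.0, 20.0):
            assert pair_potential(r, 1, 1) == 0.0
            assert pair_potential(r, 1, 2) == 0.0
            assert pair_force(r, 2, 2) == 0.0

    def test_unlike_attractive_at_long_range(self):
        assert pair_potential(4.0, 1, 2) < 0

    def test_unlike_repulsive_at_contact(self):
        assert pair_potential(1.0, 1, 2) > 0

    def test_species2_scaling(self):
        p = ContinuousPotentialParams(q=0.5)
        r = np.linspace(0.9, 6.0, 40)
        np.testing.assert_allclose(pair_potential(r, 2, 2, p),
                                   pair_potential(r, 1, 1, p) * 4.0)
        np.testing.assert_allclose(pair_potential(r, 1, 2, p),
                                   pair_potential(r, 1, 2) * 2.0)

    def test_invalid_r(self):
        with pytest.raises(ValueError):
            pair_potential(0.0, 1, 1)


class TestWalls:
    def test_repulsive_value(self):
        assert wall_potential(1.0, 1, WallSpec(), Lz=800.0) \
            == pytest.approx(2.0, rel=1e-9)

    def test_attractive_minimum(self):
        z = 2 ** (1 / 6)
        w = WallSpec(WALL_ATTRACT_BOTH)
        assert wall_potential(z, 1, w, Lz=800.0) == pytest.approx(-1.0, rel=1e-6)
        assert wall_force(z, 1, w, Lz=800.0) == pytest.approx(0.0, abs=1e-9)

    def test_selective_wall_repels_species_2(self):
        w = WallSpec(WALL_ATTRACT_SP1)
        assert wall_potential(1.5, 2, w, Lz=800.0) > 0
        assert wall_potential(1.12, 1, w, Lz=800.0) < 0

    def test_outside_slab_rejected(self):
        with pytest.raises(ValueError):
            wall_potential(-0.1, 1, WallSpec(), Lz=4.0)


class TestForceConsistency:
    def test_analytic_pair_force_matches_numeric(self, rng):
        p = ContinuousPotentialParams(q=0.5)
        h = 1e-6
        for _ in range(100):
            r = rng.uniform(0.8, 6.6)
            si, sj = rng.choice([1, 2], size=2)
            fnum = -(pair_potential(r + h, si, sj, p)
                     - pair_potential(r - h, si, sj, p)) / (2 * h)
            fan = pair_force(r, si, sj, p)
            assert fnum == pytest.approx(fan, rel=1e-5, abs=1e-7)

    def test_analytic_wall_force_matches_numeric(self, rng):
        h = 1e-7
        for wall in (WallSpec(), WallSpec(WALL_ATTRACT_SP1),
                     WallSpec(WALL_ATTRACT_BOTH)):
            for _ in range(30):
                z = rng.uniform(0.85, 3.2)
                sp = int(rng.choice([1, 2]))
                fnum = -(wall_potential(z + h, sp, wall, 4.0)
                         - wall_potential(z - h, sp, wall, 4.0)) / (2 * h)
                assert fnum == pytest.approx(wall_force(z, sp, wall, 4.0),
                                             rel=1e-4, abs=1e-6)

    def test_kernel_forces_match_energy_gradient(self):
        from saltmix.md import _compute_forces, _ForceWorkspace

        sys_ = random_system(8, 8, (10.0, 10.0, 4.0), 0.1, seed=2, q=0.5)
        ws = _ForceWorkspace(sys_)
        _compute_forces(sys_, ws)
        F = ws.F.copy()
        h = 1e-6
        for k in range(6):
            i, a = k % sys_.N, k % 3
            p0 = sys_.positions[i, a]
            sys_.positions[i, a] = p0 + h
            ep = potential_energy(sys_)
            sys_.positions[i, a] = p0 - h
            em = potential_energy(sys_)
            sys_.positions[i, a] = p0
            assert -(ep - em) / (2 * h) == pytest.approx(
                F[i, a], rel=1e-4, abs=1e-5)


class TestCellList:
    def test_energy_independent_of_cell_decomposition(self):
        from saltmix.md import _compute_forces, _ForceWorkspace

        sys_ = random_system(30, 30, (25.0, 25.0, 4.0), 0.1, seed=4)
        ws1 = _ForceWorkspace(sys_)
        e1, _, _ = _compute_forces(sys_, ws1)
        ws2 = _ForceWorkspace(sys_)
        ws2.nx = ws2.ny = 1  # force the all-pairs path
        e2, _, _ = _compute_forces(sys_, ws2)
        assert e1 == pytest.approx(e2, rel=1e-12)
        np.testing.assert_allclose(ws1.F, ws2.F, rtol=1e-10, atol=1e-12)


class TestIntegrator:
    def test_distant_resting_pair_feels_only_walls(self):
        pos = np.array([[2.0, 2.0, 2.0], [12.0, 12.0, 2.0]])
        vel = np.zeros((2, 3))
        sys_ = MDSystem(pos, vel, np.array([1, 2], dtype=np.int8),
                        (24.0, 24.0, 4.0))
        step(sys_, 10, thermostat=False)
        # x, y unchanged (no pair force); z symmetric about the slab centre
        np.testing.assert_allclose(sys_.positions[:, :2], pos[:, :2],
                                   atol=1e-12)

    def test_thermostat_holds_target_temperature(self):
        sys_ = random_system(40, 40, (20.0, 20.0, 4.0), 0.15, seed=6)
        integ = MDIntegrator(sys_)
        integ.step(500)
        temps = []
        for _ in range(20):
            integ.step(50)
            temps.append(kinetic_temperature(sys_))
        assert np.mean(temps) == pytest.approx(0.15, rel=0.01)

    def test_xy_momentum_conserved_without_rescaling(self):
        sys_ = random_system(30, 30, (20.0, 20.0, 4.0), 0.1, seed=8)
        step(sys_, 200)  # settle
        p0 = sys_.velocities.sum(axis=0)
        sys_.dt = 0.002
        step(sys_, 500, thermostat=False)
        p1 = sys_.velocities.sum(axis=0)
        np.testing.assert_allclose(p1[:2], p0[:2], atol=1e-9)

    def test_nve_energy_conservation(self):
        """Shifted-energy drift below 1e-4 relative over 1e4 steps."""
        sys_ = random_system(50, 50, (20.0, 20.0, 4.0), 0.1, seed=1)
        step(sys_, 2000)  # thermostatted equilibration
        sys_.dt = 0.0005
        res = run_nve(sys_, 10**4)
        assert res["max_drift"] < 1e-4

    def test_overlap_aborts_with_diagnostic(self):
        pos = np.array([[1.0, 1.0, 2.0], [1.0, 1.45, 2.0]])
        vel = np.zeros((2, 3))
        sys_ = MDSystem(pos, vel, np.array([1, 1], dtype=np.int8),
                        (10.0, 10.0, 4.0), dt=0.05)
        sys_.positions[1, 1] = 1.52  # close pair, large dt: will collapse
        with pytest.raises(RuntimeError, match="unstable"):
            step(sys_, 2000, thermostat=False)


class TestWorkflows:
    def test_slit_run_aggregates(self):
        traj = run_slit(N1=20, N2=20, q=1.0, T=0.1, box=(18.0, 18.0, 4.0),
                        n_steps=20000, seed=3, snapshot_interval=5000)
        assert largest_cluster_fraction(traj.final) > 0.3
        z = traj.final.positions[:, 2]
        assert 0 < z.min() and z.max() < 4.0

    def test_adsorption_neutrality_enforced(self):
        with pytest.raises(ValueError, match="neutrality"):
            run_adsorption_scaled(100, 150, q=0.5, T_final=0.05)

    def test_adsorption_desk_budget_enforced(self):
        with pytest.raises(ValueError, match="2000"):
            run_adsorption_scaled(1500, 3000, q=0.5, T_final=0.05)

    def test_selective_wall_keeps_species2_off_the_substrate(self):
        traj = run_adsorption_scaled(
            25, 50, q=0.5, T_final=0.1, box=(15.0, 15.0, 30.0),
            wall=WallSpec(WALL_ATTRACT_SP1), n_steps=15000, seed=5,
            snapshot_interval=5000,
            zones=[(0.0, 5.0, 0.1), (5.0, np.inf, 0.15)])
        final = traj.final
        near = final.positions[:, 2] < 1.0
        assert np.count_nonzero(near & (final.species == 2)) == 0
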