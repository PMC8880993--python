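import numpy as np
import pytest

from fgdft.potentials import wall_on_grid
from fgdft.solver import (build_workspace, evaluate_rhs, grand_potential,
                          initial_state, picard_step, residual_of, solve,
                          warm_start)
from fgdft.system import (Grid, InteractionTable, ParticleSpecies,
                          PolymerSpecies, SystemSpec)
from conftest import mini_spec


def gas_spec(conc=0.001, d=2.0, tolerance=1e-10, eps=None, chains=1, beads=1):
    """A nearly ideal gas over a minimal polymer (solver needs a polymer)."""
    return SystemSpec(
        grid=Grid(256, 0.117), area=400.0,
        polymer=PolymerSpecies(id="p", bead_diameter=0.76, beads_per_chain=beads,
                               num_chains=chains, bond_length=0.76),
        particles=(ParticleSpecies(id="a", diameter=d, bulk_concentration=conc),),
        interactions=InteractionTable(epsilon=eps or {}),
        tolerance=tolerance, max_iterations=60_000)


class TestBarometricLimit:
    def test_noninteracting_particles_follow_wall_boltzmann(self):
        # dilute + non-cohesive: rho(z) = rho_bulk exp(-Vext) away from the
        # single grafted bead's excluded-volume shadow
        spec = gas_spec()
        res = solve(spec)
        assert res.converged
        v = wall_on_grid(spec.grid, 2.0, 20.0)
        rb = spec.particles[0].bulk_density
        z = spec.grid.midpoints
        err = np.abs(res.profiles["a"] - rb * np.exp(-v)) / rb
        assert err[z > 3.0].max() < 1e-6

    def test_excess_chemical_potential_scales_activity(self):
        # mu_exc = +2 multiplies the dilute profile by e^2
        s0 = gas_spec()
        s2 = SystemSpec(
            grid=s0.grid, area=s0.area, polymer=s0.polymer,
            particles=(ParticleSpecies(id="a", diameter=2.0,
                                       bulk_concentration=0.001,
                                       excess_chem_potential=2.0),),
            interactions=s0.interactions, tolerance=s0.tolerance,
            max_iterations=s0.max_iterations)
        r0, r2 = solve(s0), solve(s2)
        z = s0.grid.midpoints
        m = z > 3.0
        ratio = r2.profiles["a"][m] / r0.profiles["a"][m]
        assert ratio == pytest.approx(np.e ** 2, rel=1e-4)


class TestPicardMechanics:
    def test_fixed_point_is_stationary_and_residual_zero(self, mini_bare):
        spec = mini_bare.spec
        ws = build_workspace(spec)
        state = mini_bare.state
        rhs = evaluate_rhs(ws, state)
        res = residual_of(ws, state, rhs)
        assert res <= spec.tolerance
        stepped = picard_step(ws, state, dt=0.5, rhs=rhs)
        assert np.max(np.abs(stepped.w - state.w)) <= 0.5 * spec.tolerance * 1.01

    def test_dt_one_is_direct_substitution(self):
        spec = gas_spec()
        ws = build_workspace(spec)
        state = initial_state(ws)
        rhs = evaluate_rhs(ws, state)
        stepped = picard_step(ws, state, dt=1.0, rhs=rhs)
        assert np.allclose(stepped.w, rhs.w_target)
        assert np.allclose(stepped.profiles["a"], rhs.rho_targets["a"])

    def test_residual_positive_off_fixed_point(self):
        spec = gas_spec()
        ws = build_workspace(spec)
        state = initial_state(ws)
        state.profiles["a"] = state.profiles["a"] * 2.0
        assert residual_of(ws, state) > 0.1

    def test_residual_matches_recomputation(self, mini_with_ntr):
        ws = build_workspace(mini_with_ntr.spec)
        r1 = residual_of(ws, mini_with_ntr.state)
        r2 = residual_of(ws, mini_with_ntr.state, evaluate_rhs(ws, mini_with_ntr.state))
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestHenryLimit:
    def test_dilute_cohesive_particle_boltzmann_weight(self, mini_bare):
        # an ultradilute cohesive sphere equilibrates to
        # rho_bulk exp(c - att - Vext): solve with the probe present and
        # compare against the weight assembled from the solved fields
        spec = mini_spec(
            particles=[ParticleSpecies(id="probe", diameter=3.0,
                                       bulk_concentration=1e-5)],
            epsilon={("probe", "fg"): 1.5})
        res = solve(spec, init=warm_start(mini_bare.state, spec))
        assert res.converged
        ws = build_workspace(spec)
        v = wall_on_grid(spec.grid, 3.0, 20.0)
        expected = spec.particles[0].bulk_density * np.exp(
            np.minimum(res.c["probe"] - res.attraction["probe"] - v, 30.0))
        mask = v == 0
        assert np.allclose(res.profiles["probe"][mask], expected[mask],
                           rtol=1e-6)


class TestSymmetry:
    def test_identical_species_get_identical_profiles(self):
        spec = mini_spec(
            particles=[ParticleSpecies(id="a", diameter=4.0, bulk_concentration=0.5),
                       ParticleSpecies(id="b", diameter=4.0, bulk_concentration=0.5)],
            epsilon={("a", "fg"): 2.0, ("b", "fg"): 2.0},
            tolerance=1e-9)
        res = solve(spec)
        assert res.converged
        assert np.max(np.abs(res.profiles["a"] - res.profiles["b"])) < 1e-10


class TestSolveProperties:
    def test_initial_condition_independence(self, mini_with_ntr):
        # warm start from a perturbed state reaches the same solution
        spec = mini_with_ntr.spec
        perturbed = mini_with_ntr.state.copy()
        perturbed.w = perturbed.w * 0.9
        perturbed.profiles["ntr"] = perturbed.profiles["ntr"] * 1.5
        res2 = solve(spec, init=perturbed)
        assert res2.converged
        assert np.max(np.abs(res2.profiles["ntr"] - mini_with_ntr.profiles["ntr"])) \
            < 1e-6 * max(1e-12, mini_with_ntr.profiles["ntr"].max())
        assert np.max(np.abs(res2.rho_poly - mini_with_ntr.rho_poly)) \
            < 1e-6 * mini_with_ntr.rho_poly.max()

    def test_unconverged_run_is_flagged(self):
        spec = mini_spec(tolerance=1e-8)
        from dataclasses import replace
        spec = replace(spec, max_iterations=5)
        res = solve(spec)
        assert not res.converged
        assert res.residual > spec.tolerance

    def test_bead_count_conserved_at_solution(self, mini_bare):
        spec = mini_bare.spec
        total = mini_bare.rho_poly.sum() * spec.grid.dz * spec.area
        expected = spec.polymer.beads_per_chain * spec.polymer.num_chains
        assert total == pytest.approx(expected, rel=1e-12)

    def test_isotherm_monotonicity(self, mini_bare):
        # film uptake of a cohesive sphere grows with its reservoir
        # concentration, everything else fixed
        gammas = []
        state = mini_bare.state
        for c in (0.1, 1.0, 10.0):
            spec = mini_spec(
                particles=[ParticleSpecies(id="ntr", diameter=4.0,
                                           bulk_concentration=c)],
                epsilon={("ntr", "fg"): 2.4}, tolerance=1e-7)
            res = solve(spec, init=warm_start(state, spec))
            assert res.converged
            state = res.state
            gammas.append(res.profiles["ntr"][:120].sum())
        assert gammas[0] < gammas[1] < gammas[2]


class TestContactTheorem:
    def test_wall_sum_rule_for_pure_hard_spheres(self):
        # mechanical equilibrium at a repulsive wall: the normal force per
        # area, int rho(z) (-dVext/dz) dz, equals the bulk pressure; for a
        # one-component hard-sphere fluid at eta = 0.2 the bulk pressure is
        # Carnahan-Starling to high accuracy
        d = 2.0
        eta = 0.2
        rho_b = eta / (np.pi / 6 * d ** 3)
        conc = rho_b / 6.02214076e-7         # nm^-3 -> uM
        # at this density the reservoir must carry its own hard-sphere
        # excess chemical potential for rho(far field) to equal rho_b
        mu_cs = (8 * eta - 9 * eta ** 2 + 3 * eta ** 3) / (1 - eta) ** 3
        spec = SystemSpec(
            grid=Grid(512, 0.0585), area=400.0,
            polymer=PolymerSpecies(id="p", bead_diameter=0.76,
                                   beads_per_chain=1, num_chains=1,
                                   bond_length=0.76),
            particles=(ParticleSpecies(id="hs", diameter=d,
                                       bulk_concentration=conc,
                                       excess_chem_potential=mu_cs),),
            interactions=InteractionTable(epsilon={}),
            tolerance=1e-9, max_iterations=60_000)
        res = solve(spec)
        assert res.converged
        z = spec.grid.midpoints
        # the bare integrand rho * (-dV/dz) is steep near the wall; the
        # cavity profile rho * e^{V} is smooth there, so interpolate it and
        # requadrate on a 20x finer grid
        v = wall_on_grid(spec.grid, d, 20.0)
        g = res.profiles["hs"] * np.exp(np.minimum(v, 60.0))
        zf = np.linspace(z[0], z[-1], len(z) * 20)
        gf = np.interp(zf, z, g)
        sigma = 2 ** (-1 / 6) * d
        from fgdft.potentials import wca_wall
        vf = np.minimum(wca_wall(zf, d, 20.0), 60.0)
        with np.errstate(over="ignore"):
            x6 = (sigma / zf) ** 6
            dvdz = np.where((zf > 0) & (zf < d),
                            -4 * 20.0 * (12 * x6 ** 2 - 6 * x6) / zf, 0.0)
        force = np.trapezoid(gf * np.exp(-vf) * (-dvdz), zf)
        p_cs = rho_b * (1 + eta + eta ** 2 - eta ** 3) / (1 - eta) ** 3
        assert force == pytest.approx(p_cs, rel=0.02)


class TestGrandPotential:
    def test_ideal_gas_closed_form(self):
        # mu_exc = 0 ideal gas over a tiny polymer: beta Omega ~
        # -N_accessible = -A rho_bulk int exp(-Vext) dz  (up to the single
        # grafted bead's small footprint)
        spec = gas_spec(conc=0.0005)
        res = solve(spec)
        ws = build_workspace(spec)
        v = wall_on_grid(spec.grid, 2.0, 20.0)
        rb = spec.particles[0].bulk_density
        expected = -spec.area * rb * np.sum(np.exp(-v)) * spec.grid.dz
        # polymer terms contribute O(1); the gas term scales with rb*A*H
        gas_part = res.grand_potential - solve(gas_spec(conc=1e-12)).grand_potential
        assert gas_part == pytest.approx(expected, rel=1e-3)

    def test_grand_potential_decreases_along_trajectory(self):
        # after burn-in the Picard flow descends the grand potential
        spec = mini_spec(tolerance=1e-8)
        ws = build_workspace(spec)
        state = initial_state(ws)
        omegas = []
        for i in range(400):
            rhs = evaluate_rhs(ws, state)
            if i % 25 == 0:
                omegas.append(grand_potential(ws, state, rhs))
            state = picard_step(ws, state, 0.01, rhs)
        tail = omegas[4:]
        assert all(b <= a + 1e-6 for a, b in zip(tail, tail[1:]))
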