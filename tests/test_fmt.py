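import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fgdft import fmt
from fgdft._conv import convolve
from fgdft.system import Grid

GRID = Grid(num_slices=400, dz=0.05)


def uniform_bulk(eta, d, grid=GRID, pid="none"):
    """Weighted densities of a one-component uniform bulk at packing eta."""
    rho = eta / (np.pi / 6 * d ** 3)
    w = fmt.planar_weights(d / 2, grid)
    prof = {"s": np.full(grid.num_slices, rho)}
    n = fmt.weighted_densities(prof, {"s": w}, grid.dz, pid, pads={"s": rho})
    return n, rho, w


class TestPlanarWeights:
    @pytest.mark.parametrize("R", [0.38, 0.5, 2.0, 3.0])
    def test_discrete_quadratures_match_sphere_measures(self, R):
        w = fmt.planar_weights(R, GRID)
        assert w.w3.sum() * GRID.dz == pytest.approx(4 / 3 * np.pi * R ** 3, rel=1e-10)
        assert w.w2.sum() * GRID.dz == pytest.approx(4 * np.pi * R ** 2, rel=1e-10)
        assert w.w1.sum() * GRID.dz == pytest.approx(R, rel=1e-10)
        assert w.w0.sum() * GRID.dz == pytest.approx(1.0, rel=1e-10)
        assert abs(w.wv2.sum() * GRID.dz) < 1e-12
        assert abs(w.wv1.sum() * GRID.dz) < 1e-12

    def test_uniform_profile_reproduces_bulk_values(self):
        n, rho, _ = uniform_bulk(0.3, 1.0)
        mid = GRID.num_slices // 2
        R = 0.5
        assert n.n3[mid] == pytest.approx(4 / 3 * np.pi * R ** 3 * rho, rel=1e-10)
        assert n.n2[mid] == pytest.approx(4 * np.pi * R ** 2 * rho, rel=1e-10)
        assert n.n1[mid] == pytest.approx(R * rho, rel=1e-10)
        assert n.n0[mid] == pytest.approx(rho, rel=1e-10)
        assert abs(n.nv1[mid]) < 1e-12 and abs(n.nv2[mid]) < 1e-12

    def test_unresolvable_radius_rejected(self):
        with pytest.raises(ValueError):
            fmt.planar_weights(0.01, GRID)

    def test_step_profile_matches_brute_force_convolution(self):
        rng = np.random.default_rng(3)
        prof = np.where(np.arange(200) < 100, 0.1, 0.0) * (1 + 0.1 * rng.random(200))
        grid = Grid(200, 0.05)
        w = fmt.planar_weights(0.5, grid)
        n = fmt.weighted_densities({"s": prof}, {"s": w}, grid.dz, "none",
                                   pads={"s": 0.0})
        # O(L^2) direct double loop oracle
        K = len(w.w3) // 2
        direct = np.zeros(200)
        for j in range(200):
            for k in range(200):
                m = j - k
                if abs(m) <= K:
                    direct[j] += prof[k] * w.w3[m + K] * grid.dz
        assert np.allclose(n.n3, direct, atol=1e-12)


class TestWhiteBear:
    def test_zero_density_gives_zero(self):
        n, _, _ = uniform_bulk(0.0, 1.0)
        assert np.allclose(fmt.whitebear_phi(n), 0.0)

    @pytest.mark.parametrize("eta", [0.05, 0.2, 0.3, 0.45])
    def test_bulk_reduces_to_carnahan_starling(self, eta):
        # in a one-component bulk White Bear reduces to the CS excess free
        # energy per particle (4 eta - 3 eta^2)/(1-eta)^2
        n, rho, _ = uniform_bulk(eta, 1.0)
        mid = GRID.num_slices // 2
        phi = fmt.whitebear_phi(n)
        cs = (4 * eta - 3 * eta ** 2) / (1 - eta) ** 2
        assert phi[mid] / rho == pytest.approx(cs, rel=1e-9)

    def test_bulk_pressure_matches_cs_equation_of_state(self):
        # p = -phi + sum_a n_a dphi/dn_a in bulk; compare with CS pressure
        eta, d = 0.45, 1.0
        n, rho, _ = uniform_bulk(eta, d)
        mid = GRID.num_slices // 2
        phi = fmt.whitebear_phi(n)[mid]
        der = fmt.phi_derivatives(n, M=1, R_poly=d / 2)
        p_excess = -phi + sum(der[a][mid] * getattr(n, f"n{a}")[mid]
                              for a in ("0", "1", "2", "3"))
        cs_p = rho * (1 + eta + eta ** 2 - eta ** 3) / (1 - eta) ** 3
        assert rho + p_excess == pytest.approx(cs_p, rel=1e-8)

    def test_small_n3_series_is_smooth(self):
        # the n3->0 limit of the third term is finite (handled by series):
        # values just below and above the series cut must agree
        for eta in (1e-6, 9.9e-4, 1.01e-3, 1e-2):
            n, rho, _ = uniform_bulk(eta, 1.0)
            mid = GRID.num_slices // 2
            phi = fmt.whitebear_phi(n)[mid]
            cs = (4 * eta - 3 * eta ** 2) / (1 - eta) ** 2
            assert phi / rho == pytest.approx(cs, rel=1e-6)

    def test_overpacking_raises(self):
        rho = 1.2 / (np.pi / 6)      # eta = 1.2
        prof = {"s": np.full(GRID.num_slices, rho)}
        w = fmt.planar_weights(0.5, GRID)
        with pytest.raises(fmt.OverpackingError):
            fmt.weighted_densities(prof, {"s": w}, GRID.dz, "none",
                                   pads={"s": rho})


class TestChainFunctional:
    def test_monomer_chain_term_vanishes(self):
        n, _, _ = uniform_bulk(0.3, 0.76)
        assert np.allclose(fmt.chain_phi(n, M=1, R=0.38), 0.0)

    def test_bulk_contact_value(self):
        # one-component bulk at eta=0.2: y = (1 - eta/2)/(1 - eta)^3
        eta, d = 0.2, 0.76
        n, _, _ = uniform_bulk(eta, d)
        from fgdft.fmt import _zeta_and_y
        _, y, _, _, _ = _zeta_and_y(n, d / 2)
        mid = GRID.num_slices // 2
        assert y[mid] == pytest.approx((1 - eta / 2) / (1 - eta) ** 3, rel=1e-9)

    def test_zero_density_gives_zero(self):
        n, _, _ = uniform_bulk(0.0, 0.76)
        assert np.allclose(fmt.chain_phi(n, M=300, R=0.38), 0.0)


def _random_profiles(seed, L=240, dz=0.05):
    rng = np.random.default_rng(seed)
    z = np.linspace(0, 6, L)
    rho_s = 0.25 * (1 + 0.5 * np.sin(z * rng.uniform(0.5, 2)))
    rho_p = 0.35 * (1 + 0.4 * np.cos(z * rng.uniform(0.5, 2)))
    return {"s": rho_s, "p": rho_p}


class TestDirectCorrelations:
    def test_zero_density_gives_zero(self):
        grid = Grid(100, 0.05)
        w = {"s": fmt.planar_weights(0.5, grid)}
        prof = {"s": np.zeros(100)}
        c = fmt.direct_correlations(prof, w, grid.dz, "none", 1, {"s": 0.0})
        assert np.allclose(c["s"], 0.0)

    def test_bulk_equals_minus_excess_chemical_potential(self):
        # uniform system: c is z-independent and equals -mu_exc_hs, checked
        # against a finite-difference derivative of the bulk free energy
        eta, d = 0.2, 1.0
        n, rho, w = uniform_bulk(eta, d)
        prof = {"s": np.full(GRID.num_slices, rho)}
        c = fmt.direct_correlations(prof, {"s": w}, GRID.dz, "none", 1,
                                    {"s": rho})
        mid = slice(150, 250)
        assert np.ptp(c["s"][mid]) < 1e-10
        h = 1e-7

        def f_bulk(r):
            e = np.pi / 6 * d ** 3 * r
            return r * (4 * e - 3 * e ** 2) / (1 - e) ** 2

        mu_fd = (f_bulk(rho + h) - f_bulk(rho - h)) / (2 * h)
        assert -c["s"][200] == pytest.approx(mu_fd, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_difference_functional_derivative(self, seed):
        # c_i(z) = -dF/drho_i(z) at every z, on random smooth two-species
        # profiles including the chain term (M=5)
        profs = _random_profiles(seed)
        L = len(profs["s"])
        grid = Grid(L, 0.05)
        weights = {"s": fmt.planar_weights(0.5, grid),
                   "p": fmt.planar_weights(0.38, grid)}
        pads = {"s": 0.0, "p": 0.0}
        M = 5
        c = fmt.direct_correlations(profs, weights, grid.dz, "p", M, pads)

        def free_energy(p):
            n = fmt.weighted_densities(p, weights, grid.dz, "p", pads)
            return float(np.sum(fmt.whitebear_phi(n)
                                + fmt.chain_phi(n, M, 0.38)) * grid.dz)

        base = free_energy(profs)
        h = 1e-7
        rng = np.random.default_rng(seed + 100)
        for sid in ("s", "p"):
            for k in rng.integers(5, L - 5, size=4):
                bumped = {x: v.copy() for x, v in profs.items()}
                bumped[sid][k] += h
                fd = (free_energy(bumped) - base) / (h * grid.dz)
                assert -fd == pytest.approx(c[sid][k], rel=2e-6, abs=1e-8)

    def test_mirror_symmetry(self):
        # phi terms are even under reflection of the profiles
        profs = _random_profiles(7)
        L = len(profs["s"])
        grid = Grid(L, 0.05)
        weights = {"s": fmt.planar_weights(0.5, grid),
                   "p": fmt.planar_weights(0.38, grid)}
        pads = {"s": 0.0, "p": 0.0}
        n_f = fmt.weighted_densities(profs, weights, grid.dz, "p", pads)
        mirrored = {k: v[::-1].copy() for k, v in profs.items()}
        n_m = fmt.weighted_densities(mirrored, weights, grid.dz, "p", pads)
        phi_f = fmt.whitebear_phi(n_f) + fmt.chain_phi(n_f, 5, 0.38)
        phi_m = fmt.whitebear_phi(n_m) + fmt.chain_phi(n_m, 5, 0.38)
        assert np.allclose(phi_f, phi_m[::-1], atol=1e-12)
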