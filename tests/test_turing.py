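import numpy as np
import pytest

import immunores as ir
from immunores.turing import dispersion_coefficients, growth_rates, max_growth_rate

from conftest import random_valid_params, random_valid_state


def _jac(params, state):
    return ir.reaction_jacobian(state, params)


class TestDispersionCoefficients:
    def test_k0_equals_ode_characteristic_polynomial(self):
        """At k = 0 the dispersion cubic is the characteristic polynomial of
        the kinetics Jacobian, coefficient by coefficient."""
        rng = np.random.default_rng(31)
        for _ in range(30):
            p = random_valid_params(rng)
            J = _jac(p, random_valid_state(rng))
            c = dispersion_coefficients(J, p.delta_u, p.delta_w, 0.0)
            char = np.poly(J)  # leading 1, then a2, a1, a0
            assert c.a2 == pytest.approx(char[1], rel=1e-12, abs=1e-12)
            assert c.a1 == pytest.approx(char[2], rel=1e-12, abs=1e-12)
            assert c.a0 == pytest.approx(char[3], rel=1e-12, abs=1e-12)
            assert c.a0 == pytest.approx(c.D, rel=1e-12, abs=1e-15)

    def test_a0_matches_determinant_oracle(self):
        """a0 = -det(M_k) at any wavenumber (direct determinant check)."""
        rng = np.random.default_rng(37)
        for _ in range(30):
            p = random_valid_params(rng)
            J = _jac(p, random_valid_state(rng))
            k2 = rng.uniform(0.0, 5.0)
            Mk = J - np.diag([p.delta_u, 1.0, p.delta_w]) * k2
            c = dispersion_coefficients(J, p.delta_u, p.delta_w, k2)
            assert c.a0 == pytest.approx(-np.linalg.det(Mk), rel=1e-9)

    def test_equal_diffusivity_specialisation(self, base_params):
        J = _jac(base_params, (0.3, 0.5, 0.01))
        c = dispersion_coefficients(J, 1.0, 1.0, 0.7)
        assert c.A == 1.0
        assert c.B == pytest.approx(-(J[0, 0] + J[1, 1] + J[2, 2]))

    def test_rejects_negative_k2(self, base_params):
        J = _jac(base_params, (0.3, 0.5, 0.01))
        with pytest.raises(ValueError):
            dispersion_coefficients(J, 1.0, 1.0, -1.0)


class TestGrowthRates:
    def test_roots_satisfy_cubic_and_match_matrix(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            p = random_valid_params(rng)
            J = _jac(p, random_valid_state(rng))
            k2 = rng.uniform(0.0, 2.0)
            g = growth_rates(J, p.delta_u, p.delta_w, k2)
            c = dispersion_coefficients(J, p.delta_u, p.delta_w, k2)
            for lam in g.lambdas:
                assert abs(lam**3 + c.a2 * lam**2 + c.a1 * lam + c.a0) < 1e-8 * max(
                    1.0, abs(lam) ** 3)
            Mk = J - np.diag([p.delta_u, 1.0, p.delta_w]) * k2
            ev = np.sort_complex(np.linalg.eigvals(Mk))
            assert np.allclose(np.sort_complex(np.array(g.lambdas)), ev, atol=1e-8)

    def test_diffusive_damping_at_large_k(self, turing_params):
        eq = [e for e in ir.coexistence_equilibria(turing_params) if e.stable][-1]
        J = _jac(turing_params, eq.state)
        g = growth_rates(J, turing_params.delta_u, turing_params.delta_w, 1e6)
        assert g.max_real < -1e5

    def test_ode_stable_at_k0(self, base_params):
        eq = [e for e in ir.coexistence_equilibria(base_params) if e.stable][-1]
        g = growth_rates(_jac(base_params, eq.state), base_params.delta_u,
                         base_params.delta_w, 0.0)
        assert g.max_real < 0


class TestCriticalWavenumber:
    def test_closed_form_example(self):
        assert ir.critical_wavenumber(1.0, 0.0, -3.0) == pytest.approx(1.0)

    def test_matches_interior_minimum_oracle(self):
        """k_c^2 is the positive stationary point of the a0 cubic with
        positive curvature (generic polynomial-root oracle)."""
        rng = np.random.default_rng(43)
        done = 0
        while done < 30:
            A = rng.uniform(0.5, 50.0)
            B = rng.uniform(-20.0, 20.0)
            C = rng.uniform(-20.0, 20.0)
            try:
                kc2 = ir.critical_wavenumber(A, B, C)
            except ValueError:
                continue
            crit = np.roots([3 * A, 2 * B, C])
            minima = [x.real for x in crit
                      if abs(x.imag) < 1e-12 and 6 * A * x.real + 2 * B > 0
                      and x.real > 0]
            assert len(minima) == 1
            assert kc2 == pytest.approx(minima[0], rel=1e-10)
            # and it is a local minimum of a0 on a dense grid
            h = kc2 * 1e-3
            a0 = lambda x: A * x**3 + B * x**2 + C * x
            assert a0(kc2) <= min(a0(kc2 - h), a0(kc2 + h))
            done += 1

    def test_monotone_cubic_has_no_interior_minimum(self):
        with pytest.raises(ValueError):
            ir.critical_wavenumber(1.0, 2.0, 3.0)


class TestTuringTest:
    def test_cancer_free_states_never_turing_unstable(self):
        rng = np.random.default_rng(47)
        done = 0
        while done < 50:
            p = random_valid_params(rng)
            try:
                eq = ir.cancer_free_equilibrium(p)
            except ValueError:
                continue
            assert not ir.turing_test(p, eq).unstable
            done += 1

    def test_reference_band_is_turing_unstable(self, turing_params):
        """Inside the sigma_u band between Turing onset (~0.0165) and the
        Hopf point, the stable coexistence state loses stability to a
        finite-wavenumber perturbation at delta_u = delta_w = 100."""
        eq = [e for e in ir.coexistence_equilibria(turing_params) if e.stable][-1]
        tt = ir.turing_test(turing_params, eq)
        assert tt.unstable and tt.ode_stable
        assert tt.a0_at_kc < 0
        # cross-check: positive growth rate at the critical wavenumber, and
        # the fastest-growing wavenumber lies inside the a0 < 0 band
        J = _jac(turing_params, eq.state)
        assert max_growth_rate(J, turing_params.delta_u, turing_params.delta_w,
                               tt.k_c2) > 0
        k2 = np.linspace(1e-4, 10 * tt.k_c2, 1500)
        g = max_growth_rate(J, turing_params.delta_u, turing_params.delta_w, k2)
        k2_star = k2[np.argmax(g)]
        from immunores.turing import dispersion_coefficients as dc
        assert dc(J, turing_params.delta_u, turing_params.delta_w, k2_star).a0 < 0

    def test_fastest_mode_matches_kc_at_onset(self, base_params):
        """Just inside the instability the growing band is narrow and the
        brute-force argmax of the dispersion relation coincides with the
        critical wavenumber."""
        from scipy.optimize import brentq

        def margin(su):
            p = base_params.replace(sigma_u=float(su))
            eq = [e for e in ir.coexistence_equilibria(p) if e.stable][-1]
            tt = ir.turing_test(p, eq)
            return tt.a0_at_kc if tt.k_c2 is not None else 1.0

        su_onset = brentq(margin, 0.016, 0.018, xtol=1e-12)
        p = base_params.replace(sigma_u=su_onset * (1 + 2e-4))
        eq = [e for e in ir.coexistence_equilibria(p) if e.stable][-1]
        tt = ir.turing_test(p, eq)
        assert tt.unstable
        J = _jac(p, eq.state)
        k2 = np.linspace(1e-4, 4 * tt.k_c2, 3000)
        g = max_growth_rate(J, p.delta_u, p.delta_w, k2)
        assert k2[np.argmax(g)] == pytest.approx(tt.k_c2, abs=3 * (k2[1] - k2[0]))

    def test_equal_diffusion_cannot_destabilise(self, turing_params):
        """With delta_u = delta_w = 1 the same kinetics admit no
        diffusion-driven instability of an ODE-stable state."""
        p = turing_params.replace(delta_u=1.0, delta_w=1.0)
        for eq in ir.coexistence_equilibria(p):
            if not eq.stable:
                continue
            assert not ir.turing_test(p, eq).unstable
            J = _jac(p, eq.state)
            k2 = np.linspace(0.0, 5.0, 400)
            assert np.all(max_growth_rate(J, 1.0, 1.0, k2) < 0)

    def test_kinetically_unstable_state_flagged(self, base_params):
        p = base_params.replace(sigma_w=3.0)
        eqs = ir.coexistence_equilibria(p)
        assert eqs and not any(e.stable for e in eqs)
        tt = ir.turing_test(p, eqs[0])
        assert not tt.unstable and not tt.ode_stable

    def test_no_wave_instabilities_in_reference_regimes(self, base_params):
        """Wherever an ODE-stable state has a growing spatial mode in the
        scanned regimes, the leading growth rate is purely real (stationary
        pattern, not an oscillatory wave instability)."""
        for su in (0.0165, 0.017, 0.018, 0.019):
            p = base_params.replace(sigma_u=su)
            for eq in ir.coexistence_equilibria(p):
                if not eq.stable:
                    continue
                J = _jac(p, eq.state)
                for k2 in np.linspace(1e-3, 1.0, 120):
                    g = growth_rates(J, p.delta_u, p.delta_w, k2)
                    lead = max(g.lambdas, key=lambda l: l.real)
                    if lead.real > 0:
                        assert abs(lead.imag) < 1e-10


def test_scan_turing_plane(base_params):
    """Turing cells border the coexistence-stability boundary and the cell
    census is insensitive to the IL-2 diffusivity."""
    su = np.linspace(0.012, 0.022, 21)
    sw = np.linspace(0.0, 3.0, 13)
    lab = ir.scan_turing_plane(0.07, 100.0, 100.0, su, sw)
    flat = set(lab.ravel())
    assert flat <= {"no_coexistence", "coex_stable_all", "coex_turing_unstable"}
    lab_s = lab.astype(str)
    n_turing = int(np.sum(lab_s == "coex_turing_unstable"))
    assert n_turing > 0
    assert np.any(lab_s == "coex_stable_all")
    # the Turing band is adjacent to the region of stable coexistence
    idx = np.argwhere(lab_s == "coex_turing_unstable")
    touches = False
    for i, j in idx:
        neigh = lab_s[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
        touches = touches or np.any(neigh == "coex_stable_all")
    assert touches
    # varying delta_w leaves the census unchanged at this resolution
    lab2 = ir.scan_turing_plane(0.07, 100.0, 1000.0, su, sw)
    assert int(np.sum(lab2.astype(str) == "coex_turing_unstable")) == n_turing
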