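import numpy as np
import pytest

import immunores as ir
from immunores.domains import nonlinear_diffusion_apply
from immunores.simulate import extinction_time, integrate, integrate_ode, summarise


class TestLaplacians:
    @pytest.mark.parametrize("dom", [
        ir.DomainND.interval(10.0, 33),
        ir.DomainND.square(10.0, 17),
        ir.DomainND.disc(10.0, 21),
    ], ids=["interval", "square", "disc"])
    def test_annihilates_constants(self, dom):
        L = ir.build_laplacian(dom, "neumann")
        assert np.max(np.abs(L @ np.ones(dom.n_nodes))) < 1e-12

    def test_interval_eigenfunction_second_order(self):
        """cos(pi x/L) is an eigenfunction; the discrete eigenvalue converges
        at second order in h."""
        L_len = 10.0
        errs = []
        for m in (41, 81):
            dom = ir.DomainND.interval(L_len, m)
            Lap = ir.build_laplacian(dom)
            f = np.cos(np.pi * dom.x / L_len)
            exact = -(np.pi / L_len) ** 2 * f
            errs.append(np.max(np.abs(Lap @ f - exact)))
        order = np.log2(errs[0] / errs[1])
        assert order == pytest.approx(2.0, abs=0.2)

    def test_nine_point_exact_for_quadratics(self):
        dom = ir.DomainND.square(4.0, 9)
        Lap = ir.build_laplacian(dom)
        X, Y = np.meshgrid(dom.x, dom.x, indexing="ij")
        f = (X**2 + Y**2).ravel()
        out = (Lap @ f).reshape(dom.shape)
        assert np.allclose(out[1:-1, 1:-1], 4.0, atol=1e-11)

    def test_dirichlet_rows_zeroed(self):
        dom = ir.DomainND.square(4.0, 9)
        Lap = ir.build_laplacian(dom, "dirichlet")
        rows = np.flatnonzero(dom.boundary)
        assert np.max(np.abs(Lap[rows, :].toarray())) == 0.0
        interior = np.flatnonzero(~dom.boundary)
        assert Lap[interior, :].nnz > 0

    def test_disc_mask_and_rim(self):
        dom = ir.DomainND.disc(10.0, 41)
        frac = dom.n_nodes / dom.mask.size
        assert frac == pytest.approx(np.pi / 4.0, rel=0.05)
        assert dom.boundary.sum() > 0
        # rim nodes are near the circle
        X, Y = np.meshgrid(dom.x, dom.x, indexing="ij")
        r = np.hypot(X - 5.0, Y - 5.0)[dom.mask]
        assert np.all(r[dom.boundary] > 5.0 - 2.5 * dom.h)


class TestNonlinearDiffusion:
    def test_constant_field_and_mass_conservation(self):
        dom = ir.DomainND.interval(10.0, 51)
        assert np.allclose(nonlinear_diffusion_apply(np.full(51, 0.4), dom), 0.0)
        rng = np.random.default_rng(1)
        v = rng.uniform(0.0, 0.9, dom.n_nodes)
        out = nonlinear_diffusion_apply(v, dom)
        vol = np.ones(dom.n_nodes)
        vol[[0, -1]] = 0.5  # boundary cells are half-width
        assert abs(vol @ out) < 1e-10  # zero-flux conservative form

    def test_reduces_to_linear_for_small_density(self):
        dom = ir.DomainND.interval(10.0, 51)
        Lap = ir.build_laplacian(dom)
        v = 1e-5 * np.cos(np.pi * dom.x / dom.L)
        out = nonlinear_diffusion_apply(v, dom)
        assert np.allclose(out, Lap @ v, rtol=1e-3, atol=1e-10)


class TestIntegration:
    def test_homogeneous_ic_tracks_ode(self, base_params):
        """Spatially constant data under zero-flux conditions stays on the
        well-mixed invariant manifold."""
        proto = ir.make_protocol("linear_ramp", param="sigma_u", start=0.01,
                                 rate=1e-4, sigma_w=0.5, final_time=100.0)
        eq = [e for e in ir.coexistence_equilibria(
            base_params.replace(sigma_u=0.01)) if e.stable][-1]
        dom = ir.DomainND.interval(30.0, 48)
        ic = {k: np.full(48, s) for k, s in zip("uvw", eq.state)}
        traj = integrate(ic, base_params, proto, dom, rtol=1e-11, atol=1e-11,
                         n_save=21)
        ode = integrate_ode(eq.state, base_params, proto, rtol=1e-12, atol=1e-12,
                            n_save=21)
        for name in ("u", "v", "w"):
            pde = getattr(traj, name)
            ref = getattr(ode, name)[:, 0]
            assert np.max(np.abs(pde - ref[:, None])) < 1e-6

    def test_linear_pattern_growth_rate(self, base_params):
        """In the linear regime a seeded unstable mode grows at the rate
        predicted by the dispersion relation (within 10%)."""
        from immunores.continuation import discrete_mode_growth, _critical_mode_fields

        p = base_params.replace(sigma_w=1.4)
        dom = ir.DomainND.interval(30.0, 128)
        eq = [e for e in ir.coexistence_equilibria(p) if e.stable][-1]
        n = 2
        rate = discrete_mode_growth(p, eq.state, dom, n)
        assert rate > 0
        y0, _ = _critical_mode_fields(p, dom, eq.state, n, amplitude=1e-6)
        m = dom.n_nodes
        proto = ir.make_protocol("constant", sigma_u=p.sigma_u, sigma_w=p.sigma_w,
                                 final_time=60.0)
        traj = integrate({"u": y0[:m], "v": y0[m:2 * m], "w": y0[2 * m:]},
                         p, proto, dom, rtol=1e-11, atol=1e-13, n_save=13)
        profile = np.cos(n * np.pi * dom.x / dom.L)
        amp = (traj.v - traj.v.mean(axis=1, keepdims=True)) @ profile
        amp = np.abs(amp) / len(profile)
        sl = slice(2, 11)
        fit = np.polyfit(traj.t[sl], np.log(amp[sl]), 1)[0]
        assert fit == pytest.approx(rate, rel=0.10)

    def test_nonnegativity_with_noisy_ic(self, base_params):
        p = base_params.replace(sigma_w=1.4)
        dom = ir.DomainND.interval(30.0, 64)
        eq = [e for e in ir.coexistence_equilibria(p) if e.stable][-1]
        ic = ir.perturbed_ic(eq, ir.PerturbationSpec(eta=0.1, seed=4), dom)
        proto = ir.make_protocol("constant", sigma_u=p.sigma_u, sigma_w=p.sigma_w,
                                 final_time=50.0)
        traj = integrate(ic, p, proto, dom, rtol=1e-8, atol=1e-10, n_save=11)
        for f in (traj.u, traj.v, traj.w):
            assert f.min() >= 0.0  # floored on output; raw solution > -1e-8

    def test_rejects_negative_treatment(self, base_params):
        dom = ir.DomainND.interval(30.0, 16)
        proto = ir.make_protocol("constant", sigma_u=-0.01, sigma_w=0.0,
                                 final_time=1.0)
        ic = {k: np.zeros(16) for k in "uvw"}
        with pytest.raises(ValueError, match="unphysical"):
            integrate(ic, base_params, proto, dom)

    def test_dirichlet_boundary_dosing_applies(self, base_params):
        """With a boundary IL-2 ramp the rim w values track B_w(t)."""
        dom = ir.DomainND.square(30.0, 12)
        p = base_params.replace(alpha=0.1, sigma_u=0.007, sigma_w=0.0,
                                delta_u=10.0, delta_w=1000.0)
        eq = [e for e in ir.coexistence_equilibria(
            p.replace(sigma_u=0.007)) if e.stable][-1]
        proto = ir.make_protocol("boundary_ramp", rate=0.01, sigma_u=0.007,
                                 sigma_w=0.0, final_time=20.0)
        ic = {k: np.full(dom.n_nodes, s) for k, s in zip("uvw", eq.state)}
        traj = integrate(ic, p, proto, dom, rtol=1e-8, atol=1e-10, n_save=5)
        rim = traj.w[:, dom.boundary]
        for i, t in enumerate(traj.t):
            assert np.allclose(rim[i], 0.01 * t, atol=1e-6)


class TestExtinctionAndSummary:
    def test_interpolated_crossing(self, base_params):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        v = np.array([[1e-3], [1e-4], [1e-8], [1e-12]])
        traj = ir.Trajectory(t, v.copy(), v, v.copy(), None, base_params, None)
        te = extinction_time(traj, threshold=1e-6)
        # linear interpolation between saves at 1e-4 and 1e-8
        assert 1.0 < te < 2.0
        assert te == pytest.approx(1.0 + (1e-4 - 1e-6) / (1e-4 - 1e-8))

    def test_no_crossing_returns_none(self, base_params):
        t = np.linspace(0, 1, 5)
        v = np.full((5, 1), 0.3)
        traj = ir.Trajectory(t, v, v, v, None, base_params, None)
        assert extinction_time(traj) is None

    def test_event_location_preferred(self, base_params):
        proto = ir.make_protocol("constant", sigma_u=0.03, sigma_w=0.5,
                                 final_time=500.0)
        eq = [e for e in ir.coexistence_equilibria(
            base_params.replace(sigma_u=0.014)) if e.stable][-1]
        ode = integrate_ode(eq.state, base_params.replace(sigma_u=0.03), proto,
                            stop_at_extinction=True, rtol=1e-10, atol=1e-12)
        te = extinction_time(ode)
        assert ode.extinction is not None
        assert te == ode.extinction
        assert ode.v[-1].max() <= 1.01e-6

    def test_summarise_constant_and_masked(self, base_params):
        dom = ir.DomainND.disc(10.0, 15)
        n = dom.n_nodes
        t = np.array([0.0, 1.0])
        f = np.full((2, n), 0.7)
        traj = ir.Trajectory(t, f, f, f, dom, base_params, None)
        averages, kymo = summarise(traj)
        assert np.allclose(averages["v"], 0.7)
        assert kymo is None  # kymographs only for 1D runs
        dom1 = ir.DomainND.interval(10.0, 8)
        f1 = np.tile(np.arange(8.0), (2, 1))
        traj1 = ir.Trajectory(t, f1, f1, f1, dom1, base_params, None)
        _, kymo1 = summarise(traj1)
        assert kymo1.shape == (2, 8)
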