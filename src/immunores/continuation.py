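"""Pseudo-arclength continuation of homogeneous and patterned steady states.

Steady states of the 1D reaction-diffusion system (3-point Neumann
Laplacian) are continued in a treatment parameter (sigma_u or sigma_w) with
a secant predictor and a Newton corrector on the arclength-extended system.
Stability comes from the leading eigenvalues of the discretised Jacobian;
folds are tagged at parameter-direction reversals and refined from the
local branch geometry, Hopf points when a complex-conjugate eigenvalue pair
crosses the imaginary axis (refined by bisection on the crossing real
part).  A degenerate domain (homogeneous fields) reduces the machinery to
the well-mixed 3-equation system, which is how the homogeneous Hopf point
is located to high precision.

Negative treatment values are permitted during continuation (they are
needed to round the fold of the primary patterned branch); the simulation
layer rejects them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from .domains import DomainND, build_laplacian
from .equilibria import coexistence_equilibria
from .kinetics import reaction_rates
from .params import NondimParams
from .simulate import _reaction_jac_diagonals

__all__ = [
    "BranchPoint",
    "Branch",
    "steady_residual",
    "steady_jacobian",
    "newton_steady",
    "continue_branch",
    "switch_branch",
    "classify_criticality",
    "hopf_point_ode",
    "primary_patterned_state",
    "fold_sigma_w",
]

#: Eigenvalue stability threshold along branches.
EIG_STABLE_TOL = 1e-8
#: Newton residual tolerance (scaled 2-norm) for accepted branch points.
NEWTON_TOL = 1e-10


@dataclass
class BranchPoint:
    """One converged steady state on a branch."""

    param: float
    fields: np.ndarray  # stacked (u, v, w), length 3 m
    v_l1: float         # trapezoidal domain integral of v
    v_mean: float
    leading_eigenvalues: np.ndarray | None
    stable: bool | None
    tag: str = "regular"

    def species(self, dom: DomainND) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = dom.n_nodes
        return self.fields[:m], self.fields[m:2 * m], self.fields[2 * m:]


@dataclass
class Branch:
    """An ordered set of branch points continued in one parameter."""

    points: list[BranchPoint]
    param_name: str
    provenance: str = "homogeneous"
    special: list[dict] = field(default_factory=list)
    message: str = "ok"

    @property
    def params(self) -> np.ndarray:
        return np.array([p.param for p in self.points])

    @property
    def v_l1(self) -> np.ndarray:
        return np.array([p.v_l1 for p in self.points])

    def folds(self) -> list[dict]:
        return [s for s in self.special if s["tag"] == "fold"]

    def hopfs(self) -> list[dict]:
        return [s for s in self.special if s["tag"] == "hopf"]


def _with_param(p: NondimParams, name: str, value: float) -> NondimParams:
    return p.replace(**{name: float(value)})


def _split(y: np.ndarray, m: int):
    return y[:m], y[m:2 * m], y[2 * m:]


def steady_residual(fields: np.ndarray, params: NondimParams, dom: DomainND) -> np.ndarray:
    """Residual of the steady 1D system: diffusion + reaction terms.

    ``fields`` is the stacked (u, v, w) vector of length 3 m (or shape
    (3, m)); spatially constant kinetic equilibria give exactly zero.
    Treatment inputs may be negative here (continuation range).
    """
    y = np.asarray(fields, dtype=float).ravel()
    m = dom.n_nodes
    if y.size != 3 * m:
        raise ValueError(f"fields have size {y.size}, expected {3 * m}")
    u, v, w = _split(y, m)
    Lap = build_laplacian(dom, "neumann")
    gv, gw = params.gamma_v, params.gamma_w
    fu = params.alpha * v - params.mu_u * u + params.rho_u * u * w / (1.0 + w) + params.sigma_u
    fv = v * (1.0 - v) - u * v / (gv + v)
    fw = params.rho_w * u * v / (gw + v) - params.mu_w * w + params.sigma_w
    out = np.concatenate([
        params.delta_u * (Lap @ u) + fu,
        Lap @ v + fv,
        params.delta_w * (Lap @ w) + fw,
    ])
    return out.reshape(np.shape(fields)) if np.ndim(fields) == 2 else out


class _System:
    """Cached sparse operators for one (domain, params-shape) problem."""

    def __init__(self, dom: DomainND, params: NondimParams):
        self.dom = dom
        self.m = dom.n_nodes
        Lap = build_laplacian(dom, "neumann")
        self.Lu = (params.delta_u * Lap).tocsr()
        self.Lv = Lap
        self.Lw = (params.delta_w * Lap).tocsr()

    def residual(self, y: np.ndarray, params: NondimParams) -> np.ndarray:
        m = self.m
        u, v, w = _split(y, m)
        fu, fv, fw = reaction_rates((u, v, w), params)
        return np.concatenate([self.Lu @ u + fu, self.Lv @ v + fv, self.Lw @ w + fw])

    def jacobian(self, y: np.ndarray, params: NondimParams) -> sp.csc_matrix:
        u, v, w = _split(y, self.m)
        juu, juv, juw, jvu, jvv, jwu, jwv, jww = (
            sp.diags(x) for x in _reaction_jac_diagonals(u, v, w, params))
        return sp.bmat([
            [self.Lu + juu, juv, juw],
            [jvu, self.Lv + jvv, None],
            [jwu, jwv, self.Lw + jww],
        ], format="csc")

    def dparam(self, name: str) -> np.ndarray:
        m = self.m
        d = np.zeros(3 * m)
        if name == "sigma_u":
            d[:m] = 1.0
        elif name == "sigma_w":
            d[2 * m:] = 1.0
        else:
            raise ValueError(f"cannot continue in {name!r}")
        return d


def steady_jacobian(fields: np.ndarray, params: NondimParams, dom: DomainND) -> sp.csc_matrix:
    """Sparse Jacobian of :func:`steady_residual`."""
    return _System(dom, params).jacobian(np.asarray(fields, dtype=float).ravel(), params)


def newton_steady(fields: np.ndarray, params: NondimParams, dom: DomainND,
                  tol: float = NEWTON_TOL, max_iter: int = 30) -> np.ndarray:
    """Newton-correct a steady-state guess at fixed parameters."""
    sysm = _System(dom, params)
    y = np.asarray(fields, dtype=float).ravel().copy()
    scale = np.sqrt(y.size)
    for _ in range(max_iter):
        F = sysm.residual(y, params)
        if np.linalg.norm(F) / scale < tol:
            return y
        y -= spla.spsolve(sysm.jacobian(y, params), F)
    F = sysm.residual(y, params)
    if np.linalg.norm(F) / scale < tol:
        return y
    raise RuntimeError(f"Newton failed to converge (residual {np.linalg.norm(F)/scale:.2e})")


def _leading_eigs(J: sp.spmatrix, n_eig: int = 8) -> np.ndarray:
    n = J.shape[0]
    if n <= 1600:
        ev = np.linalg.eigvals(J.toarray())
    else:
        # largest-real-part eigenvalues via shift-invert about zero plus a
        # mild positive shift to catch slightly unstable modes
        try:
            ev = spla.eigs(J.tocsc(), k=min(n_eig, n - 2), sigma=0.1,
                           return_eigenvectors=False)
        except Exception:
            ev = np.linalg.eigvals(J.toarray())
    ev = ev[np.argsort(-ev.real)]
    return ev[:n_eig]


def _v_norms(y: np.ndarray, dom: DomainND) -> tuple[float, float]:
    m = dom.n_nodes
    v = y[m:2 * m]
    return float(np.trapezoid(v, dx=dom.h)), float(v.mean())


def _corrector(sysm: _System, params0: NondimParams, name: str,
               z_pred: np.ndarray, tangent: np.ndarray,
               tol: float, max_iter: int = 12) -> tuple[np.ndarray, int] | None:
    """Newton on the arclength-extended system; returns (z, n_iter)."""
    z = z_pred.copy()
    nvar = z.size - 1
    dFdp = None
    for it in range(max_iter):
        params = _with_param(params0, name, z[-1])
        F = sysm.residual(z[:nvar], params)
        g = tangent @ (z - z_pred)
        res = np.linalg.norm(F) / np.sqrt(nvar)
        if res < tol and abs(g) < tol:
            return z, it
        J = sysm.jacobian(z[:nvar], params)
        if dFdp is None:
            dFdp = sysm.dparam(name)
        A = sp.bmat([[J, dFdp[:, None]],
                     [tangent[None, :nvar], np.array([[tangent[-1]]])]],
                    format="csc")
        rhs = np.concatenate([F, [g]])
        try:
            z = z - spla.spsolve(A, rhs)
        except Exception:
            return None
    return None


def continue_branch(
    seed_fields: np.ndarray,
    params: NondimParams,
    dom: DomainND,
    param_name: str,
    direction: int = 1,
    *,
    ds0: float = 1e-2,
    ds_min: float = 1e-5,
    ds_max: float = 1e-1,
    max_steps: int = 400,
    param_bounds: tuple[float, float] = (-np.inf, np.inf),
    compute_stability: bool = True,
    n_eig: int = 8,
    newton_tol: float = NEWTON_TOL,
    provenance: str = "homogeneous",
) -> Branch:
    """Trace a steady-state branch in ``param_name`` from a converged seed.

    The seed is first Newton-corrected at the seed parameter value.  The
    branch is traced with secant prediction and pseudo-arclength Newton
    correction until a parameter bound, the point budget, or step-size
    underflow (reported in ``Branch.message`` with the partial branch).
    Fold and Hopf special points are tagged and refined.
    """
    sysm = _System(dom, params)
    m = dom.n_nodes
    y = newton_steady(seed_fields, params, dom, tol=newton_tol)
    p0 = float(getattr(params, param_name))

    def make_point(y, pval, tag="regular"):
        if compute_stability:
            ev = _leading_eigs(sysm.jacobian(y, _with_param(params, param_name, pval)), n_eig)
            stable = bool(ev.real.max() < -EIG_STABLE_TOL)
        else:
            ev, stable = None, None
        l1, mean = _v_norms(y, dom)
        return BranchPoint(float(pval), y.copy(), l1, mean, ev, stable, tag)

    branch = Branch([make_point(y, p0)], param_name, provenance)

    # initial tangent from the bordered system: J y_p = -dF/dp
    J = sysm.jacobian(y, params)
    dFdp = sysm.dparam(param_name)
    try:
        y_p = spla.spsolve(J, -dFdp)
    except Exception:
        raise RuntimeError("non-convergent seed: singular Jacobian at seed point")
    tangent = np.concatenate([y_p, [1.0]])
    tangent /= np.linalg.norm(tangent)
    if tangent[-1] * direction < 0:
        tangent = -tangent

    z = np.concatenate([y, [p0]])
    ds = ds0
    lo, hi = param_bounds
    message = "ok"
    for _ in range(max_steps):
        ok = None
        while ok is None:
            z_pred = z + ds * tangent
            ok = _corrector(sysm, params, param_name, z_pred, tangent, newton_tol)
            if ok is None:
                ds *= 0.5
                if ds < ds_min:
                    break
        if ok is None:
            message = "step-size underflow"
            break
        z_new, n_iter = ok
        new_tangent = (z_new - z) / np.linalg.norm(z_new - z)
        branch.points.append(make_point(z_new[:3 * m], z_new[-1]))
        z, tangent = z_new, new_tangent
        if n_iter <= 3:
            ds = min(ds * 1.5, ds_max)
        if not (lo <= z[-1] <= hi):
            message = "parameter bound reached"
            break
    else:
        message = "point budget exhausted"
    branch.message = message

    _tag_special_points(branch, sysm, params, dom)
    return branch


def _tag_special_points(branch: Branch, sysm: _System, params: NondimParams,
                        dom: DomainND) -> None:
    pts = branch.points
    pv = branch.params
    # folds: reversals of the parameter direction along the branch
    dp = np.diff(pv)
    for i in range(1, len(dp)):
        if dp[i - 1] * dp[i] < 0:
            # quadratic fit of param vs arclength index around the reversal
            s = np.array([-1.0, 0.0, 1.0])
            c = np.polyfit(s, pv[i - 1:i + 2], 2)
            p_fold = float(c[2] - c[1] ** 2 / (4.0 * c[0])) if c[0] != 0 else float(pv[i])
            pts[i].tag = "fold"
            branch.special.append({"tag": "fold", "param": p_fold, "index": i})
    # Hopf: complex-pair real-part sign change between consecutive points
    if pts[0].leading_eigenvalues is None:
        return

    def hopf_fn(pt: BranchPoint) -> float:
        ev = pt.leading_eigenvalues
        cplx = ev[np.abs(ev.imag) > 1e-9]
        return float(cplx.real.max()) if len(cplx) else -np.inf

    h = np.array([hopf_fn(pt) for pt in pts])
    for i in range(1, len(pts)):
        if not (np.isfinite(h[i - 1]) and np.isfinite(h[i])):
            continue
        if h[i - 1] * h[i] < 0 and pts[i].tag == "regular":
            p_hopf = _refine_hopf(sysm, params, branch.param_name, dom,
                                  pts[i - 1], pts[i])
            pts[i].tag = "hopf"
            branch.special.append({"tag": "hopf", "param": p_hopf, "index": i})
    # remaining real-eigenvalue crossings are branch points (Turing modes)
    def real_fn(pt: BranchPoint) -> float:
        ev = pt.leading_eigenvalues
        re = ev[np.abs(ev.imag) <= 1e-9]
        return float(re.real.max()) if len(re) else -np.inf

    r = np.array([real_fn(pt) for pt in pts])
    for i in range(1, len(pts)):
        if not (np.isfinite(r[i - 1]) and np.isfinite(r[i])):
            continue
        if r[i - 1] * r[i] < 0 and pts[i].tag == "regular":
            pts[i].tag = "branch_point"
            branch.special.append({"tag": "branch_point",
                                   "param": float(pts[i].param), "index": i})


def _refine_hopf(sysm: _System, params: NondimParams, name: str, dom: DomainND,
                 a: BranchPoint, b: BranchPoint, xtol: float = 1e-14) -> float:
    """Bisection on the complex-pair real part between two branch points.

    Valid on segments where the branch is a graph over the parameter (away
    from folds): the state is re-converged by Newton at each trial value.
    """
    ya, yb = a.fields, b.fields

    def test(pval: float) -> float:
        t = 0.0 if b.param == a.param else (pval - a.param) / (b.param - a.param)
        guess = (1 - t) * ya + t * yb
        y = newton_steady(guess, _with_param(params, name, pval), dom)
        ev = _leading_eigs(sysm.jacobian(y, _with_param(params, name, pval)), 6)
        cplx = ev[np.abs(ev.imag) > 1e-9]
        return float(cplx.real.max())

    lo, hi = sorted((a.param, b.param))
    return float(brentq(test, lo, hi, xtol=xtol, rtol=8.9e-16))


def _critical_mode_fields(params: NondimParams, dom: DomainND, homogeneous_state,
                          mode: int, amplitude: float) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous state plus amplitude * cos(n pi x/L) along the critical
    eigenvector of the mode-n linearisation; also returns the (unit) mode
    direction used."""
    from .kinetics import reaction_jacobian

    n = abs(int(mode))
    sign = 1.0 if mode >= 0 else -1.0
    k2 = (n * np.pi / dom.L) ** 2
    J = reaction_jacobian(homogeneous_state, params)
    Mk = J - np.diag([params.delta_u, 1.0, params.delta_w]) * k2
    ev, vec = np.linalg.eig(Mk)
    direction = np.real(vec[:, np.argmax(ev.real)])
    direction /= np.max(np.abs(direction))
    profile = sign * np.cos(n * np.pi * dom.x / dom.L)
    phi = np.concatenate([direction[0] * profile,
                          direction[1] * profile,
                          direction[2] * profile])
    phi /= np.linalg.norm(phi)
    y_h = np.concatenate([np.full(dom.n_nodes, s) for s in homogeneous_state])
    return y_h + amplitude * phi, phi


def switch_branch(params: NondimParams, dom: DomainND, homogeneous_state,
                  mode: int, *, amplitude: float = 0.05,
                  param_name: str = "sigma_w",
                  max_iter: int = 40) -> tuple[np.ndarray, float]:
    """Seed the mode-n patterned branch bifurcating from a homogeneous state.

    Perturbs along cos(n pi x / L) in the critical eigenvector and corrects
    with Newton on the bordered system {steady residual = 0, projection of
    the pattern onto the mode = amplitude}, with the continuation parameter
    free.  Pinning the amplitude prevents collapse back onto the homogeneous
    branch, which is a nearby root of the unpinned system.  ``mode`` may be
    negative for the phase-flipped seed.  Returns (fields, parameter value);
    raises RuntimeError with diagnostics on Newton failure.
    """
    sysm = _System(dom, params)
    m = dom.n_nodes
    y0, phi = _critical_mode_fields(params, dom, homogeneous_state, mode, amplitude)
    y_h = np.concatenate([np.full(m, s) for s in homogeneous_state])
    dFdp = sysm.dparam(param_name)
    y = y0.copy()
    pval = float(getattr(params, param_name))
    for it in range(max_iter):
        p = _with_param(params, param_name, pval)
        F = sysm.residual(y, p)
        g = phi @ (y - y_h) - amplitude
        if np.linalg.norm(F) / np.sqrt(y.size) < NEWTON_TOL and abs(g) < NEWTON_TOL:
            return y, pval
        A = sp.bmat([[sysm.jacobian(y, p), dFdp[:, None]],
                     [phi[None, :], None]], format="csc")
        step = spla.spsolve(A, np.concatenate([F, [g]]))
        y -= step[:-1]
        pval -= step[-1]
    raise RuntimeError(
        f"branch switch failed: residual {np.linalg.norm(F):.2e}, "
        f"pinning {g:.2e} after {max_iter} iterations (mode {mode})")


def classify_criticality(branch: Branch, p_star: float, stable_side: int) -> str:
    """Sub/supercriticality of a bifurcating branch from its geometry.

    ``stable_side`` is +1 (-1) when the homogeneous state is linearly
    stable for parameter values above (below) the bifurcation at ``p_star``.
    The branch is subcritical when it initially extends into the stable
    side, i.e. where patterns coexist with the stable homogeneous state.
    """
    pv = branch.params
    if len(pv) < 3:
        raise ValueError("branch too short to determine direction")
    drift = np.sign(np.median(pv[1:4]) - p_star)
    if drift == 0:
        drift = np.sign(pv[-1] - p_star)
    return "subcritical" if drift == stable_side else "supercritical"


# ---------------------------------------------------------------------------
# High-level analyses built on the machinery above


def hopf_point_ode(base: NondimParams, bracket: tuple[float, float] = (0.015, 0.0215),
                   branch: str = "upper") -> float:
    """Hopf bifurcation of the well-mixed coexistence state in sigma_u.

    Tracks the coexistence equilibrium (largest v0 by default) across the
    bracket and bisects the real part of its complex-conjugate eigenvalue
    pair of the 3x3 Jacobian to machine precision.
    """
    idx = -1 if branch == "upper" else 0

    def test(su: float) -> float:
        p = base.replace(sigma_u=float(su))
        eqs = coexistence_equilibria(p, method="quintic")
        if not eqs:
            raise ValueError(f"no coexistence state at sigma_u={su}")
        ev = np.array(eqs[idx].eigenvalues)
        cplx = ev[np.abs(ev.imag) > 1e-12]
        if len(cplx) == 0:
            return -1.0
        return float(cplx.real.max())

    return float(brentq(test, *bracket, xtol=1e-16, rtol=8.9e-16))


def discrete_mode_growth(params: NondimParams, state, dom: DomainND, n: int) -> float:
    """Max Re growth rate of the discrete Neumann mode k = n pi / L."""
    from .kinetics import reaction_jacobian
    from .turing import growth_rates

    J = reaction_jacobian(state, params)
    return growth_rates(J, params.delta_u, params.delta_w,
                        (n * np.pi / dom.L) ** 2).max_real


def primary_patterned_state(params: NondimParams, dom: DomainND, *,
                            mode: int | None = None, relax_time: float = 600.0,
                            rtol: float = 1e-9, atol: float = 1e-9,
                            max_modes: int = 12) -> np.ndarray:
    """A converged steady pattern on the primary Turing branch.

    Perturbs the Turing-unstable coexistence state along its most unstable
    discrete Neumann mode (n pi / L), grows the pattern by stiff time
    integration until it saturates, then Newton-polishes.  Raises when no
    discrete mode is linearly unstable at these parameters.
    """
    from .protocols import Protocol, _constant
    from .simulate import integrate

    from .turing import turing_test

    eqs = [e for e in coexistence_equilibria(params) if e.stable]
    best = None
    for eq in eqs:
        growths = [discrete_mode_growth(params, eq.state, dom, n)
                   for n in range(1, max_modes + 1)]
        # the primary branch carries the mode nearest the continuous k_c;
        # fall back to the fastest-growing discrete mode
        tt = turing_test(params, eq)
        n_best = None
        if tt.k_c2 is not None:
            n_c = max(1, min(max_modes, round(dom.L * np.sqrt(tt.k_c2) / np.pi)))
            if growths[n_c - 1] > 0:
                n_best = n_c
        if n_best is None:
            n_best = int(np.argmax(growths)) + 1
        if best is None or growths[n_best - 1] > best[2]:
            best = (eq, n_best, growths[n_best - 1])
    if best is None or best[2] <= 0:
        raise ValueError("no linearly unstable discrete mode at these parameters")
    eq, n_mode, rate = best
    if mode is not None:
        n_mode = mode
        rate = max(discrete_mode_growth(params, eq.state, dom, n_mode), 1e-3)
    y0, _ = _critical_mode_fields(params, dom, eq.state, n_mode, amplitude=0.05)

    m = dom.n_nodes
    # grow over ~12 e-folds of the linear rate, at least the requested time
    t_relax = max(relax_time, 12.0 / max(rate, 1e-3))
    proto = Protocol(_constant(params.sigma_u), _constant(params.sigma_w), t_relax)
    traj = integrate({"u": y0[:m], "v": np.maximum(y0[m:2 * m], 0.0), "w": y0[2 * m:]},
                     params, proto, dom, rtol=rtol, atol=atol, n_save=3)
    y = newton_steady(np.concatenate([traj.u[-1], traj.v[-1], traj.w[-1]]), params, dom)
    if np.ptp(y[m:2 * m]) < 1e-3:
        raise RuntimeError("pattern relaxation collapsed to a homogeneous state")
    return y


def turing_onset_sigma_w(params: NondimParams, dom: DomainND,
                         scan=(0.0, 4.0), n_scan: int = 81,
                         min_rate: float = 0.01, max_modes: int = 12) -> float:
    """Smallest scanned sigma_w at which some discrete Neumann mode of a
    kinetics-stable coexistence state grows at rate > min_rate."""
    for sw in np.linspace(*scan, n_scan):
        p = params.replace(sigma_w=float(sw))
        for eq in coexistence_equilibria(p, method="quintic"):
            if not eq.stable:
                continue
            if any(discrete_mode_growth(p, eq.state, dom, n) > min_rate
                   for n in range(1, max_modes + 1)):
                return float(sw)
    raise ValueError("no Turing-unstable coexistence state in the scanned range")


def fold_sigma_w(params: NondimParams, dom: DomainND, *,
                 param_bounds: tuple[float, float] = (-2.0, 2.5),
                 ds0: float = 5e-3, max_steps: int = 2000) -> tuple[float, Branch]:
    """Fold of the primary patterned branch continued down in sigma_w.

    Locates the sigma_w window where the coexistence state is
    Turing-unstable, builds the primary patterned state inside it, continues
    toward smaller (including unphysical negative) sigma_w, and returns the
    refined parameter value of the first fold together with the branch.
    """
    sw_seed = turing_onset_sigma_w(params, dom)
    p_seed = params.replace(sigma_w=sw_seed)
    y = primary_patterned_state(p_seed, dom)
    branch = continue_branch(y, p_seed, dom, "sigma_w", direction=-1,
                             ds0=ds0, ds_max=5e-2, max_steps=max_steps,
                             param_bounds=param_bounds, compute_stability=False,
                             provenance="patterned")
    folds = branch.folds()
    if not folds:
        raise RuntimeError(f"no fold found ({branch.message})")
    # the relevant fold is where the branch turns back from its minimum
    p_min = min(f["param"] for f in folds)
    return float(p_min), branch
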