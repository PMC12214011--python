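"""Method-of-lines simulation of the treated tumour-immune system.

The PDE system (dimensionless; tumour diffusivity 1)

    u_t = delta_u lap u + alpha v - mu_u u + rho_u u w/(1+w) + sigma_u(t)
    v_t = lap v          + v(1-v) - u v/(gamma_v+v)
    w_t = delta_w lap w  + rho_w u v/(gamma_w+v) - mu_w w + sigma_w(t)

is discretised on a :class:`~immunores.domains.DomainND` and integrated
with a stiff variable-order implicit method (BDF) using an analytically
assembled sparse Jacobian.  Treatment enters through time-dependent source
inputs sigma_u(t), sigma_w(t) and, optionally, through Dirichlet boundary
dosing of the IL-2 field, w = B_w(t) on the rim (u and v keep zero-flux
conditions).  The tumour transport term can be switched to the
volume-filling nonlinear form div((1-v)^2 grad v).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .domains import DomainND, build_laplacian, nonlinear_diffusion_apply
from .kinetics import reaction_rates
from .params import NondimParams
from .protocols import Protocol

__all__ = ["Trajectory", "integrate", "integrate_ode", "extinction_time", "summarise"]

#: Nondimensional tumour density below which the tumour counts as extinct
#: (roughly one cell at the carrying-capacity scale of 1e6 cells per unit).
EXTINCTION_THRESHOLD = 1e-6


@dataclass
class Trajectory:
    """A space-time solution record.

    ``t`` are the save times; ``u``, ``v``, ``w`` have shape
    (len(t), n_nodes).  ``extinction`` holds the event-located time at which
    max v first crossed the extinction threshold, when the run was asked to
    watch for it.  Saved fields have small solver-tolerance negatives floored
    at zero.
    """

    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    dom: DomainND | None
    params: NondimParams
    protocol: Protocol | None
    stats: dict[str, Any] = field(default_factory=dict)
    extinction: float | None = None

    @property
    def max_v(self) -> np.ndarray:
        return self.v.max(axis=1)


def _reaction_jac_diagonals(u, v, w, p: NondimParams):
    gv, gw = p.gamma_v, p.gamma_w
    return (
        p.rho_u * w / (1.0 + w) - p.mu_u,                      # dfu/du
        np.full_like(u, p.alpha),                              # dfu/dv
        p.rho_u * u / (1.0 + w) ** 2,                          # dfu/dw
        -v / (gv + v),                                         # dfv/du
        u * v / (gv + v) ** 2 - u / (gv + v) - 2.0 * v + 1.0,  # dfv/dv
        p.rho_w * v / (gw + v),                                # dfw/du
        p.rho_w * u * gw / (gw + v) ** 2,                      # dfw/dv
        np.full_like(u, -p.mu_w),                              # dfw/dw
    )


def integrate(
    ic: dict[str, np.ndarray],
    params: NondimParams,
    proto: Protocol,
    dom: DomainND,
    *,
    t_final: float | None = None,
    t_eval=None,
    n_save: int = 201,
    rtol: float = 1e-11,
    atol: float = 1e-11,
    method: str = "BDF",
    nonlinear_v_diffusion: bool = False,
    stop_at_extinction: bool = False,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> Trajectory:
    """Integrate the discretised system and return a :class:`Trajectory`.

    ``ic`` maps "u", "v", "w" to non-negative flat fields over the active
    nodes.  Dirichlet IL-2 dosing is enabled automatically when the protocol
    carries a ``boundary_w`` schedule.  With ``stop_at_extinction`` the run
    terminates (and records the crossing time) when max v falls below the
    threshold.  Default tolerances are the strict reference values 1e-11;
    production 2D runs typically relax them.
    """
    n = dom.n_nodes
    u0, v0, w0 = (np.asarray(ic[k], dtype=float).ravel() for k in ("u", "v", "w"))
    if len(u0) != n or len(v0) != n or len(w0) != n:
        raise ValueError("initial fields do not match the domain size")
    if min(u0.min(), v0.min(), w0.min()) < 0:
        raise ValueError("initial fields must be non-negative")
    if t_final is None:
        t_final = proto.final_time
    for t_chk in (0.0, 0.5 * t_final, t_final):
        if proto.sigma_u_of_t(t_chk) < 0 or proto.sigma_w_of_t(t_chk) < 0:
            raise ValueError("negative treatment input: unphysical in simulation "
                             "(allowed only during continuation)")

    dirichlet_w = proto.boundary_w is not None
    Lap_n = build_laplacian(dom, "neumann")
    Lu = (params.delta_u * Lap_n).tocsr()
    Lv = Lap_n
    if dirichlet_w:
        Lw = (params.delta_w * build_laplacian(dom, "dirichlet")).tocsr()
        bidx = np.flatnonzero(dom.boundary)
        w0 = w0.copy()
        w0[bidx] = proto.boundary_w(0.0)
    else:
        Lw = (params.delta_w * Lap_n).tocsr()
        bidx = None
    y0 = np.concatenate([u0, v0, w0])

    floor = proto.atto_fox_floor
    su_t, sw_t = proto.sigma_u_of_t, proto.sigma_w_of_t

    def rhs(t, y):
        u, v, w = y[:n], y[n:2 * n], y[2 * n:]
        fu, fv, fw = reaction_rates((u, v, w), params,
                                    sigma_u=float(su_t(t)), sigma_w=float(sw_t(t)))
        fu += Lu @ u
        if nonlinear_v_diffusion:
            fv += nonlinear_diffusion_apply(v, dom)
        else:
            fv += Lv @ v
        fw += Lw @ w
        if floor is not None and np.any(v < floor):
            fv += np.where(v < floor, -v, 0.0)
        if dirichlet_w:
            fw[bidx] = proto.boundary_rate(t)
        return np.concatenate([fu, fv, fw])

    if dirichlet_w:
        zb = np.ones(n)
        zb[bidx] = 0.0
        Zb = sp.diags(zb)
    jac_kw: dict[str, Any] = {}
    if method in ("BDF", "Radau", "LSODA") and not nonlinear_v_diffusion:
        def jac(t, y):
            u, v, w = y[:n], y[n:2 * n], y[2 * n:]
            d = _reaction_jac_diagonals(u, v, w, params)
            juu, juv, juw, jvu, jvv, jwu, jwv, jww = (sp.diags(x) for x in d)
            if floor is not None and np.any(v < floor):
                jvv = jvv + sp.diags(np.where(v < floor, -1.0, 0.0))
            if dirichlet_w:
                jwu, jwv, jww = Zb @ jwu, Zb @ jwv, Zb @ jww
            return sp.bmat([
                [Lu + juu, juv, juw],
                [jvu, Lv + jvv, None],
                [jwu, jwv, Lw + jww],
            ], format="csc")
        jac_kw["jac"] = jac
    elif method in ("BDF", "Radau"):
        eye = sp.identity(n, format="csr")
        patt = sp.bmat([
            [Lu + eye, eye, eye],
            [eye, Lv + Lap_n + eye, None],
            [eye, eye, Lw + eye],
        ], format="csc")
        jac_kw["jac_sparsity"] = patt

    events = None
    if stop_at_extinction:
        def hit(t, y):
            return y[n:2 * n].max() - extinction_threshold
        hit.terminal = True
        hit.direction = -1
        events = [hit]

    if t_eval is None:
        t_eval = np.linspace(0.0, t_final, n_save)
    sol = solve_ivp(rhs, (0.0, float(t_final)), y0, method=method,
                    rtol=rtol, atol=atol, t_eval=t_eval, events=events, **jac_kw)
    if sol.status < 0:
        raise RuntimeError(f"integrator failed: {sol.message}")

    Y = sol.y.T
    t_out = sol.t
    ext = None
    if stop_at_extinction and len(sol.t_events[0]):
        ext = float(sol.t_events[0][0])
        Y = np.vstack([Y, sol.y_events[0]])
        t_out = np.append(t_out, ext)
    U = np.maximum(Y[:, :n], 0.0)
    V = np.maximum(Y[:, n:2 * n], 0.0)
    W = np.maximum(Y[:, 2 * n:], 0.0)
    stats = {"nfev": sol.nfev, "njev": sol.njev, "nlu": sol.nlu,
             "status": sol.status, "message": sol.message,
             "rtol": rtol, "atol": atol, "method": method}
    return Trajectory(t_out, U, V, W, dom, params, proto, stats, ext)


def integrate_ode(
    state0,
    params: NondimParams,
    proto: Protocol,
    *,
    t_final: float | None = None,
    rtol: float = 1e-11,
    atol: float = 1e-11,
    method: str = "LSODA",
    n_save: int = 401,
    stop_at_extinction: bool = False,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> Trajectory:
    """Integrate the well-mixed (spatially homogeneous) system.

    The spatial model with homogeneous initial data and zero-flux boundaries
    stays on this invariant manifold, so this is also the eta = 0 limit of
    any Neumann simulation.
    """
    if t_final is None:
        t_final = proto.final_time
    floor = proto.atto_fox_floor

    def rhs(t, y):
        du, dv, dw = reaction_rates(y, params, sigma_u=float(proto.sigma_u_of_t(t)),
                                    sigma_w=float(proto.sigma_w_of_t(t)))
        if floor is not None and y[1] < floor:
            dv = dv - y[1]
        return [du, dv, dw]

    events = None
    if stop_at_extinction:
        def hit(t, y):
            return y[1] - extinction_threshold
        hit.terminal = True
        hit.direction = -1
        events = [hit]
    sol = solve_ivp(rhs, (0.0, float(t_final)), np.asarray(state0, dtype=float),
                    method=method, rtol=rtol, atol=atol,
                    t_eval=np.linspace(0.0, t_final, n_save), events=events)
    if sol.status < 0:
        raise RuntimeError(f"integrator failed: {sol.message}")
    Y = sol.y.T
    t_out = sol.t
    ext = None
    if stop_at_extinction and len(sol.t_events[0]):
        ext = float(sol.t_events[0][0])
        Y = np.vstack([Y, sol.y_events[0]])
        t_out = np.append(t_out, ext)
    U, V, W = (np.maximum(Y[:, [i]], 0.0) for i in range(3))
    stats = {"nfev": sol.nfev, "status": sol.status, "method": method}
    return Trajectory(t_out, U, V, W, None, params, proto, stats, ext)


def extinction_time(traj: Trajectory, threshold: float = EXTINCTION_THRESHOLD) -> float | None:
    """First time the spatial maximum of v drops below the threshold.

    Uses the event-located crossing when the run recorded one at this
    threshold; otherwise linearly interpolates the saved max-v series.
    Returns None when the trajectory never crosses.
    """
    if traj.extinction is not None and threshold == EXTINCTION_THRESHOLD:
        return traj.extinction
    mv = traj.max_v
    below = np.flatnonzero(mv < threshold)
    if len(below) == 0:
        return None
    i = below[0]
    if i == 0:
        return float(traj.t[0])
    t0, t1 = traj.t[i - 1], traj.t[i]
    f0, f1 = mv[i - 1], mv[i]
    return float(t0 + (f0 - threshold) / (f0 - f1) * (t1 - t0))


def summarise(traj: Trajectory):
    """Spatial-average series and (for 1D) the kymograph array.

    Returns ``(averages, kymograph)`` where ``averages`` is a dict of
    per-species means over the domain's active nodes at each save time and
    ``kymograph`` is the (time x space) tumour-density array for interval
    domains (None otherwise).
    """
    averages = {"t": traj.t,
                "u": traj.u.mean(axis=1),
                "v": traj.v.mean(axis=1),
                "w": traj.w.mean(axis=1)}
    kymo = traj.v if (traj.dom is not None and traj.dom.geometry == "interval") else None
    return averages, kymo
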