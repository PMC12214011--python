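"""Homogeneous steady states of the well-mixed model and their stability.

The cancer-free state (v0 = 0) has a closed form; coexistence states
(0 < v0 < 1) satisfy a scalar residual in v0 obtained by back-substituting

    u0 = (gamma_v + v0)(1 - v0)
    w0 = (sigma_w + rho_w u0 v0 / (gamma_w + v0)) / mu_w

into the steady effector equation.  Clearing denominators turns that
residual into a quintic polynomial in v0; both root-finding routes are
implemented and are required to agree (dual-oracle property).  The sign
scan + bracketing route is the default for single parameter sets, the
quintic companion-matrix route is used by the plane scans for speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.optimize import brentq

from .kinetics import reaction_jacobian, reaction_rates
from .params import NondimParams

__all__ = [
    "Equilibrium",
    "RegionLabel",
    "STABILITY_MARGIN",
    "cancer_free_equilibrium",
    "cancer_free_eigenvalues",
    "coexistence_quintic",
    "coexistence_equilibria",
    "transcritical_sigma_u",
    "classify_homogeneous",
    "scan_stability_plane",
    "bistability_alpha_bound",
]

#: Eigenvalue real parts below -STABILITY_MARGIN count as stable; within
#: +/- STABILITY_MARGIN the state is flagged marginal and excluded from
#: stable counts (deterministic classification near boundaries).
STABILITY_MARGIN = 1e-10

#: Coexistence roots closer than this in v0 are merged (fold points
#: produce near-double roots).
ROOT_MERGE_TOL = 1e-8


class RegionLabel(str, Enum):
    """Classification of the set of linearly stable homogeneous states."""

    CF_only = "CF_only"
    one_coex = "one_coex"
    two_coex = "two_coex"
    CF_and_coex = "CF_and_coex"
    none_stable = "none_stable"


@dataclass(frozen=True)
class Equilibrium:
    """A homogeneous steady state with its linear stability record."""

    state: tuple[float, float, float]
    kind: str  # "cancer_free" | "coexistence"
    eigenvalues: tuple[complex, complex, complex]
    stable: bool
    marginal: bool = False

    @property
    def u0(self) -> float:
        return self.state[0]

    @property
    def v0(self) -> float:
        return self.state[1]

    @property
    def w0(self) -> float:
        return self.state[2]


def _classify_state(state, kind, p: NondimParams) -> Equilibrium:
    ev = np.linalg.eigvals(reaction_jacobian(state, p))
    ev = ev[np.argsort(-ev.real)]
    stable = bool(np.all(ev.real < -STABILITY_MARGIN))
    marginal = bool(np.any(np.abs(ev.real) <= STABILITY_MARGIN))
    return Equilibrium(tuple(float(x) for x in state), kind, tuple(ev), stable, marginal)


def cancer_free_equilibrium(p: NondimParams) -> Equilibrium:
    """The unique v0 = 0 steady state.

    u0 = sigma_u (mu_w + sigma_w) / (mu_u (mu_w + sigma_w) - rho_u sigma_w),
    w0 = sigma_w / mu_w.  Feasible iff the denominator of u0 is positive.
    """
    denom = p.mu_u * (p.mu_w + p.sigma_w) - p.rho_u * p.sigma_w
    if denom <= 0:
        raise ValueError("cancer-free state infeasible: "
                         "mu_u (mu_w + sigma_w) <= rho_u sigma_w")
    u0 = p.sigma_u * (p.mu_w + p.sigma_w) / denom
    return _classify_state((u0, 0.0, p.sigma_w / p.mu_w), "cancer_free", p)


def cancer_free_eigenvalues(p: NondimParams) -> tuple[float, float, float]:
    """Closed-form Jacobian eigenvalues at the cancer-free state.

    lambda_1 = 1 - u0/gamma_v governs tumour invasion, lambda_2 the effector
    balance, lambda_3 = -mu_w the IL-2 decay.
    """
    denom = p.mu_u * (p.mu_w + p.sigma_w) - p.rho_u * p.sigma_w
    if denom <= 0:
        raise ValueError("cancer-free state infeasible")
    lam1 = 1.0 - p.sigma_u * (p.mu_w + p.sigma_w) / (p.gamma_v * denom)
    lam2 = (p.rho_u * p.sigma_w - p.mu_u * (p.mu_w + p.sigma_w)) / (p.mu_w + p.sigma_w)
    lam3 = -p.mu_w
    return lam1, lam2, lam3


def coexistence_quintic(p: NondimParams) -> np.ndarray:
    """Coefficients (low order first) of the quintic in v0 for coexistence.

    Obtained by polynomial elimination: substitute u0(v0) and w0(v0) into
    the steady effector equation and clear the denominators
    (1 + w0) (gamma_w + v0) mu_w.  The constant term is
    gamma_w (gamma_v rho_u sigma_w + (mu_w + sigma_w)(sigma_u - gamma_v mu_u)),
    whose zero set is the transcritical curve where a coexistence root
    crosses v0 = 0.
    """
    gv, gw = p.gamma_v, p.gamma_w
    u = P.polymul([gv, 1.0], [1.0, -1.0])  # u0(v) = (gv + v)(1 - v)
    # Q(v) = mu_w (1 + w0(v)) (gw + v) = (mu_w + sigma_w)(gw + v) + rho_w u v
    Q = P.polyadd([(p.mu_w + p.sigma_w) * gw, p.mu_w + p.sigma_w],
                  P.polymul(p.rho_w * u, [0.0, 1.0]))
    # (alpha v - mu_u u0 + sigma_u) Q + rho_u u0 (sigma_w (gw + v) + rho_w u0 v)
    lin = P.polyadd(P.polyadd([0.0, p.alpha], -p.mu_u * u), [p.sigma_u])
    t1 = P.polymul(lin, Q)
    t2 = P.polymul(p.rho_u * u,
                   P.polyadd([p.sigma_w * gw, p.sigma_w], P.polymul(p.rho_w * u, [0.0, 1.0])))
    c = P.polyadd(t1, t2)
    out = np.zeros(6)
    out[: len(c)] = c
    return out


def _complete_state(v0: float, p: NondimParams) -> tuple[float, float, float]:
    u0 = (p.gamma_v + v0) * (1.0 - v0)
    w0 = (p.sigma_w + p.rho_w * u0 * v0 / (p.gamma_w + v0)) / p.mu_w
    return u0, v0, w0


def _scalar_residual(v0, p: NondimParams):
    """Steady effector equation with u0, w0 eliminated; roots in (0,1) are
    coexistence states.  Written with positive denominators so the sign
    scan is reliable."""
    v0 = np.asarray(v0, dtype=float)
    u0 = (p.gamma_v + v0) * (1.0 - v0)
    num_w = p.sigma_w * (p.gamma_w + v0) + p.rho_w * u0 * v0
    Q = (p.mu_w + p.sigma_w) * (p.gamma_w + v0) + p.rho_w * u0 * v0
    return (p.alpha * v0 - p.mu_u * u0 + p.sigma_u) + p.rho_u * u0 * num_w / Q


def _roots_residual(p: NondimParams, n_scan: int = 2000) -> list[float]:
    grid = np.linspace(0.0, 1.0, n_scan + 1)
    f = _scalar_residual(grid, p)
    roots = []
    for i in np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0):
        roots.append(brentq(lambda x: float(_scalar_residual(x, p)),
                            grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16))
    for i in np.flatnonzero(f == 0.0):
        if 0.0 < grid[i] < 1.0:
            roots.append(float(grid[i]))
    return sorted(roots)


def _roots_quintic(p: NondimParams) -> list[float]:
    c = coexistence_quintic(p)
    c = np.trim_zeros(c, "b")
    if len(c) < 2:
        return []
    dc = P.polyder(c)
    out = []
    for r in np.roots(c[::-1]):
        if abs(r.imag) > 1e-7:
            continue
        v0 = float(r.real)
        if not (1e-12 < v0 < 1.0 - 1e-12):
            continue
        for _ in range(100):  # Newton polish to machine precision
            fv = P.polyval(v0, c)
            dfv = P.polyval(v0, dc)
            if dfv == 0:
                break
            step = fv / dfv
            v0 -= step
            if abs(step) < 1e-16:
                break
        if 1e-12 < v0 < 1.0 - 1e-12:
            out.append(v0)
    return sorted(out)


def _merge_roots(roots: list[float]) -> list[float]:
    merged: list[float] = []
    for r in roots:
        if merged and abs(r - merged[-1]) < ROOT_MERGE_TOL:
            merged[-1] = 0.5 * (merged[-1] + r)
        else:
            merged.append(r)
    return merged


def coexistence_equilibria(p: NondimParams, method: str = "residual") -> list[Equilibrium]:
    """All coexistence steady states (0 < v0 < 1), sorted by v0.

    ``method`` selects the root finder: ``"residual"`` (dense sign scan and
    bracketing of the scalar residual, the default) or ``"quintic"``
    (companion-matrix roots of the eliminated polynomial, faster in scans).
    Returns an empty list when no coexistence state exists.
    """
    if method == "residual":
        roots = _roots_residual(p)
    elif method == "quintic":
        roots = _roots_quintic(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return [_classify_state(_complete_state(v0, p), "coexistence", p)
            for v0 in _merge_roots(roots)]


def transcritical_sigma_u(p: NondimParams) -> float:
    """The sigma_u on the transcritical curve (quintic constant term = 0).

    sigma_u* = gamma_v mu_u - gamma_v rho_u sigma_w / (mu_w + sigma_w); at
    this value the tumour-invasion eigenvalue of the cancer-free state
    vanishes and a coexistence root crosses v0 = 0.
    """
    if p.mu_w + p.sigma_w <= 0:
        raise ValueError("mu_w + sigma_w must be positive")
    return p.gamma_v * p.mu_u - p.gamma_v * p.rho_u * p.sigma_w / (p.mu_w + p.sigma_w)


def classify_homogeneous(p: NondimParams, method: str = "residual") -> RegionLabel:
    """Label the parameter point by its set of stable homogeneous states."""
    try:
        cf_stable = cancer_free_equilibrium(p).stable
    except ValueError:  # infeasible cancer-free state
        cf_stable = False
    n_coex = sum(e.stable for e in coexistence_equilibria(p, method=method))
    if cf_stable and n_coex >= 1:
        return RegionLabel.CF_and_coex
    if cf_stable:
        return RegionLabel.CF_only
    if n_coex >= 2:
        return RegionLabel.two_coex
    if n_coex == 1:
        return RegionLabel.one_coex
    return RegionLabel.none_stable


def scan_stability_plane(alpha: float, sigma_u_grid, sigma_w_grid,
                         base: NondimParams | None = None) -> np.ndarray:
    """Stability-region labels over a (sigma_u, sigma_w) grid at fixed alpha.

    Returns an object array of :class:`RegionLabel`, shape
    (len(sigma_u_grid), len(sigma_w_grid)).  Deterministic for fixed grids.
    """
    from .params import table1_nondim

    sigma_u_grid = np.asarray(sigma_u_grid, dtype=float)
    sigma_w_grid = np.asarray(sigma_w_grid, dtype=float)
    for g in (sigma_u_grid, sigma_w_grid):
        if g.ndim != 1 or not np.all(np.isfinite(g)) or np.any(np.diff(g) <= 0):
            raise ValueError("grids must be 1-D, finite and ascending")
    if base is None:
        base = table1_nondim(alpha=alpha)
    out = np.empty((len(sigma_u_grid), len(sigma_w_grid)), dtype=object)
    for i, su in enumerate(sigma_u_grid):
        for j, sw in enumerate(sigma_w_grid):
            p = base.replace(alpha=alpha, sigma_u=float(su), sigma_w=float(sw))
            out[i, j] = classify_homogeneous(p, method="quintic")
    return out


def _has_dual_bistability(alpha: float, sigma_u_grid, sigma_w_grid, base) -> bool:
    labels = scan_stability_plane(alpha, sigma_u_grid, sigma_w_grid, base=base)
    present = {lab for lab in labels.ravel()}
    return RegionLabel.CF_and_coex in present and RegionLabel.two_coex in present


def bistability_alpha_bound(
    sigma_u_grid=None, sigma_w_grid=None,
    alpha_lo: float = 0.05, alpha_hi: float = 0.12, tol: float = 1e-3,
    base: NondimParams | None = None,
) -> float:
    """Largest alpha at which both bistability region types coexist.

    Both a (cancer-free + coexistence) cell and a two-coexistence cell must
    be present in the scanned (sigma_u, sigma_w) window.  Located by
    bisection on the scan outcome; the default window sigma_u in [0, 0.05],
    sigma_w in [0, 20] on 201x201 grids covers all reported features.
    """
    if sigma_u_grid is None:
        sigma_u_grid = np.linspace(0.0, 0.05, 201)
    if sigma_w_grid is None:
        sigma_w_grid = np.linspace(0.0, 20.0, 201)
    if not _has_dual_bistability(alpha_lo, sigma_u_grid, sigma_w_grid, base):
        raise ValueError("alpha_lo does not exhibit dual bistability")
    if _has_dual_bistability(alpha_hi, sigma_u_grid, sigma_w_grid, base):
        raise ValueError("alpha_hi still exhibits dual bistability")
    lo, hi = alpha_lo, alpha_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _has_dual_bistability(mid, sigma_u_grid, sigma_w_grid, base):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
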