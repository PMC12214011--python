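"""Reaction terms and Jacobian of the effector / tumour / IL-2 kinetics.

The diffusion-free system in dimensionless variables (u effector cells,
v tumour cells scaled to carrying capacity, w IL-2 concentration):

    du/dt = alpha v - mu_u u + rho_u u w / (1 + w) + sigma_u
    dv/dt = v (1 - v) - u v / (gamma_v + v)
    dw/dt = rho_w u v / (gamma_w + v) - mu_w w + sigma_w

All functions are vectorised: u, v, w may be scalars or same-shaped arrays.
The instantaneous treatment inputs may be overridden per call so that
time-dependent protocols and equilibrium analysis share one code path.
"""

from __future__ import annotations

import numpy as np

from .params import NondimParams

__all__ = ["reaction_rates", "reaction_jacobian", "cancer_free_subsystem_jacobian"]


def _check_denominators(v, w, p: NondimParams) -> None:
    if np.any(1.0 + np.asarray(w) <= 0):
        raise ValueError("denominator 1 + w must be positive")
    if np.any(p.gamma_v + np.asarray(v) <= 0):
        raise ValueError("denominator gamma_v + v must be positive")
    if np.any(p.gamma_w + np.asarray(v) <= 0):
        raise ValueError("denominator gamma_w + v must be positive")


def reaction_rates(state, p: NondimParams, sigma_u: float | None = None,
                   sigma_w: float | None = None):
    """Kinetic rates (du/dt, dv/dt, dw/dt) of the well-mixed system.

    ``state`` is an (u, v, w) triple of scalars or arrays.  ``sigma_u`` /
    ``sigma_w`` override the treatment inputs stored in ``p`` (used by the
    time-dependent protocol layer).
    """
    u, v, w = state
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v)) and np.all(np.isfinite(w))):
        raise ValueError("state components must be finite")
    _check_denominators(v, w, p)
    su = p.sigma_u if sigma_u is None else sigma_u
    sw = p.sigma_w if sigma_w is None else sigma_w
    du = p.alpha * v - p.mu_u * u + p.rho_u * u * w / (1.0 + w) + su
    dv = v * (1.0 - v) - u * v / (p.gamma_v + v)
    dw = p.rho_w * u * v / (p.gamma_w + v) - p.mu_w * w + sw
    return du, dv, dw


def reaction_jacobian(state, p: NondimParams) -> np.ndarray:
    """3x3 Jacobian of :func:`reaction_rates` with respect to (u, v, w).

    For array-valued states the result has shape (3, 3) + state.shape.
    The (2, 3) entry is identically zero: the tumour equation does not
    involve the IL-2 concentration.
    """
    u, v, w = (np.asarray(x, dtype=float) for x in state)
    _check_denominators(v, w, p)
    gv, gw = p.gamma_v, p.gamma_w
    z = np.zeros(np.broadcast(u, v, w).shape)
    J = np.array([
        [p.rho_u * w / (w + 1.0) - p.mu_u + z,
         p.alpha + z,
         p.rho_u * u / (w + 1.0) - p.rho_u * u * w / (w + 1.0) ** 2],
        [-v / (gv + v) + z,
         u * v / (gv + v) ** 2 - u / (gv + v) - 2.0 * v + 1.0,
         z],
        [p.rho_w * v / (gw + v) + z,
         p.rho_w * u / (gw + v) - p.rho_w * u * v / (gw + v) ** 2,
         -p.mu_w + z],
    ])
    return J


def cancer_free_subsystem_jacobian(state, p: NondimParams) -> np.ndarray:
    """Jacobian of the (u, w) subsystem on the invariant plane v = 0.

    Spatial perturbations of v away from a cancer-free state would be
    negative, so pattern formation there is governed by this reduced 2x2
    matrix.  It is upper triangular (the w-equation loses its u dependence
    at v = 0), which rules out diffusion-driven instability of a stable
    cancer-free state.
    """
    u, _, w = state
    return np.array([
        [p.rho_u * w / (w + 1.0) - p.mu_u,
         p.rho_u * u / (w + 1.0) - p.rho_u * u * w / (w + 1.0) ** 2],
        [0.0, -p.mu_w],
    ])
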