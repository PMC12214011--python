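"""Reference study configurations of the resilience analysis.

Each function reproduces one headline quantity of the pipeline from
scratch: the homogeneous Hopf dose, the dual-bistability bound in the
immune-response strength, quasi-static extinction times of the well-mixed
model under ramped dosing, the patterned-branch fold, and the 2D
boundary-dosing extinction times.  These are the entry points used by the
acceptance script; problem sizes default to the values documented in the
methods note.
"""

from __future__ import annotations

import numpy as np

from .continuation import fold_sigma_w, hopf_point_ode
from .domains import DomainND
from .equilibria import bistability_alpha_bound, coexistence_equilibria
from .params import NondimParams, table1_nondim
from .protocols import PerturbationSpec, make_protocol, perturbed_ic
from .simulate import extinction_time, integrate, integrate_ode

__all__ = [
    "reference_hopf_sigma_u",
    "reference_bistability_bound",
    "effector_ramp_extinction_ode",
    "il2_boost_ramp_extinction_ode",
    "patterned_fold_sigma_w",
    "boundary_dosing_extinction",
]


def reference_hopf_sigma_u(alpha: float = 0.07, sigma_w: float = 0.5) -> float:
    """Hopf dose of the homogeneous coexistence branch in sigma_u."""
    return hopf_point_ode(table1_nondim(alpha=alpha, sigma_u=0.014,
                                        sigma_w=sigma_w))


def reference_bistability_bound(tol: float = 1e-3) -> float:
    """Largest immune-response strength alpha with both bistability types."""
    return bistability_alpha_bound(tol=tol)


def _stable_coexistence(p: NondimParams):
    eqs = [e for e in coexistence_equilibria(p) if e.stable]
    if not eqs:
        raise ValueError("no stable coexistence state at the start of the run")
    return eqs[-1]


def effector_ramp_extinction_ode(final_time: float = 1e5,
                                 threshold: float = 1e-6) -> float:
    """Extinction time of the well-mixed model under the slow effector ramp
    sigma_u = 0.01 + 0.03 t/T (sigma_w = 0.5, alpha = 0.07), started from
    the stable coexistence state.

    The collapse happens once the ramp carries the dose past the subcritical
    Hopf point (~0.0196), i.e. around t/T ~ 0.35 for this quasi-static ramp.
    """
    p = table1_nondim(alpha=0.07, sigma_u=0.01, sigma_w=0.5)
    proto = make_protocol("linear_ramp", param="sigma_u", start=0.01, stop=0.04,
                          final_time=final_time, sigma_w=0.5)
    eq = _stable_coexistence(p)
    traj = integrate_ode(eq.state, p, proto, stop_at_extinction=True,
                         extinction_threshold=threshold, rtol=1e-11, atol=1e-11)
    te = extinction_time(traj, threshold)
    if te is None:
        raise RuntimeError("tumour did not go extinct within the protocol")
    return te


def il2_boost_ramp_extinction_ode(threshold: float = 1e-6,
                                  final_time: float = 1e3) -> float:
    """Extinction time of the homogeneous (zero-perturbation) limit of the
    2D effector ramp sigma_u = 0.015 + 5e-5 t at sigma_w = 0.5, alpha = 0.07.

    With eta = 0 the square-domain run stays spatially uniform, so this is
    exactly the well-mixed system.
    """
    p = table1_nondim(alpha=0.07, sigma_u=0.015, sigma_w=0.5)
    proto = make_protocol("linear_ramp", param="sigma_u", start=0.015,
                          rate=5e-5, final_time=final_time, sigma_w=0.5)
    eq = _stable_coexistence(p)
    traj = integrate_ode(eq.state, p, proto, stop_at_extinction=True,
                         extinction_threshold=threshold, rtol=1e-11, atol=1e-11)
    te = extinction_time(traj, threshold)
    if te is None:
        raise RuntimeError("tumour did not go extinct within the protocol")
    return te


def patterned_fold_sigma_w(m: int = 256, L: float = 30.0) -> float:
    """Fold of the primary patterned branch in sigma_w (1D, sigma_u = 0.014,
    alpha = 0.07, delta_u = delta_w = 100), continued to negative dosing."""
    p = table1_nondim(alpha=0.07, sigma_u=0.014, sigma_w=0.5)
    dom = DomainND.interval(L, m)
    fold, _ = fold_sigma_w(p, dom)
    return fold


def boundary_dosing_extinction(delta_u: float, m: int = 100, seed: int = 1,
                               *, L: float = 300.0, eta: float = 0.1,
                               rtol: float = 1e-6, atol: float = 1e-6,
                               t_max: float = 4000.0,
                               threshold: float = 1e-6) -> float:
    """Extinction time under Dirichlet IL-2 boundary dosing B_w = 0.01 t.

    Square domain of side L, sigma_u = 0.007, sigma_w = 0, alpha = 0.1,
    delta_w = 1000; the effector diffusivity delta_u controls how far into
    the Turing regime the interior sits, and thereby the resilience of the
    interior tumour to the boundary-driven treatment.
    """
    p = table1_nondim(alpha=0.1, sigma_u=0.007, sigma_w=0.0,
                      delta_u=delta_u, delta_w=1000.0)
    dom = DomainND.square(L, m)
    proto = make_protocol("boundary_ramp", rate=0.01, sigma_u=p.sigma_u,
                          sigma_w=0.0, final_time=t_max)
    eq = _stable_coexistence(p)
    ic = perturbed_ic(eq, PerturbationSpec(eta=eta, seed=seed), dom)
    traj = integrate(ic, p, proto, dom, rtol=rtol, atol=atol, n_save=9,
                     stop_at_extinction=True, extinction_threshold=threshold)
    te = extinction_time(traj, threshold)
    if te is None:
        raise RuntimeError("tumour did not go extinct within t_max")
    return te
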