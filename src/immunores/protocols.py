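"""Treatment protocols and seeded random initial conditions.

Every pipeline stage is testable without external data: the inputs are
parameter sets, the treatment schedules below, and random multiplicative
perturbations of a homogeneous equilibrium,

    field = equilibrium value * (1 + eta * xi(x)),   xi ~ iid N(0, 1),

with eta = 0.1 by default and an independent noise field per species
(the published description illustrates only the effector field; per-species
independence is the documented choice here and can be switched off).
Negative values after perturbation are floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .equilibria import Equilibrium

__all__ = [
    "Protocol",
    "PerturbationSpec",
    "make_protocol",
    "perturbed_ic",
    "atto_fox_term",
    "heaviside",
    "ATTO_FOX_FLOOR",
]

#: Default density floor for the extinction sink term (~one cell at the
#: densities represented by the nondimensional scales).
ATTO_FOX_FLOOR = 1e-15


def heaviside(x):
    """Heaviside step with H(0) = 1/2 (the ramp formulas are continuous at
    their switch points, so the convention there is immaterial)."""
    return np.heaviside(x, 0.5)


@dataclass(frozen=True)
class Protocol:
    """Time-dependent treatment specification on [0, final_time].

    ``sigma_u_of_t`` / ``sigma_w_of_t`` give the instantaneous source
    inputs; ``boundary_w`` (optional) the Dirichlet IL-2 dose B_w(t) applied
    on domain boundaries, with ``boundary_w_rate`` its time derivative
    (finite-differenced when not supplied).  ``atto_fox_floor`` enables the
    extinction sink term when not None.
    """

    sigma_u_of_t: Callable[[float], float]
    sigma_w_of_t: Callable[[float], float]
    final_time: float
    boundary_w: Callable[[float], float] | None = None
    boundary_w_rate: Callable[[float], float] | None = None
    atto_fox_floor: float | None = None
    kind: str = "custom"
    args: dict = field(default_factory=dict)

    def boundary_rate(self, t: float) -> float:
        if self.boundary_w is None:
            raise ValueError("protocol has no boundary dosing")
        if self.boundary_w_rate is not None:
            return self.boundary_w_rate(t)
        dt = max(1e-6 * max(self.final_time, 1.0), 1e-9)
        return (self.boundary_w(t + dt) - self.boundary_w(max(t - dt, 0.0))) / (
            dt + min(t, dt))

    def with_atto_fox(self, floor: float = ATTO_FOX_FLOOR) -> "Protocol":
        from dataclasses import replace
        return replace(self, atto_fox_floor=floor)


def _constant(value):
    return lambda t: value + 0.0 * np.asarray(t)


def make_protocol(kind: str, **args) -> Protocol:
    """Build one of the named treatment schedules.

    constant
        ``sigma_u``, ``sigma_w``, ``final_time``.
    linear_ramp
        ``param`` ("sigma_u" or "sigma_w") ramped as start + rate * t, with
        ``rate`` given directly or derived from ``stop`` at ``final_time``;
        the other input held at its ``sigma_u`` / ``sigma_w`` value.
        E.g. effector dosing 0.01 + 0.03 t/T, or IL-2 dosing 10 t/T.
    triangular_ramp
        ``param`` ramped linearly 0 -> ``peak`` over [0, T/2] and back to 0
        over [T/2, T] with T = ``period`` (default ``final_time``); switched
        off entirely after ``off_after`` when given.
    boundary_ramp
        Dirichlet IL-2 boundary dose B_w(t) = ``rate`` * t (default 0.01),
        with constant ``sigma_u``, ``sigma_w`` source inputs.
    """
    T = float(args.get("final_time", 1e5))
    su0 = float(args.get("sigma_u", 0.0))
    sw0 = float(args.get("sigma_w", 0.0))

    if kind == "constant":
        return Protocol(_constant(su0), _constant(sw0), T, kind=kind, args=args)

    if kind == "linear_ramp":
        param = args.get("param", "sigma_u")
        start = float(args["start"])
        rate = float(args["rate"]) if "rate" in args else (float(args["stop"]) - start) / T
        ramp = lambda t: start + rate * np.asarray(t)
        if param == "sigma_u":
            return Protocol(ramp, _constant(sw0), T, kind=kind, args=args)
        if param == "sigma_w":
            return Protocol(_constant(su0), ramp, T, kind=kind, args=args)
        raise ValueError(f"unknown ramp parameter {param!r}")

    if kind == "triangular_ramp":
        param = args.get("param", "sigma_w")
        peak = float(args["peak"])
        period = float(args.get("period", T))

        def tri(t):
            s = np.asarray(t) / period
            val = 2.0 * peak * (s * heaviside(0.5 - s) + (1.0 - s) * heaviside(s - 0.5))
            if args.get("off_after") is not None:
                val = val * heaviside(float(args["off_after"]) - np.asarray(t))
            return np.maximum(val, 0.0)

        if param == "sigma_w":
            return Protocol(_constant(su0), tri, T, kind=kind, args=args)
        return Protocol(tri, _constant(sw0), T, kind=kind, args=args)

    if kind == "boundary_ramp":
        rate = float(args.get("rate", 0.01))
        return Protocol(_constant(su0), _constant(sw0), T,
                        boundary_w=lambda t: rate * np.asarray(t),
                        boundary_w_rate=_constant(rate), kind=kind, args=args)

    raise ValueError(f"unknown protocol kind {kind!r}")


@dataclass(frozen=True)
class PerturbationSpec:
    """Multiplicative normal perturbation of a homogeneous equilibrium."""

    eta: float = 0.1
    seed: int = 0
    per_species_independent: bool = True

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


def perturbed_ic(eq: Equilibrium, spec: PerturbationSpec, dom) -> dict[str, np.ndarray]:
    """Seeded random initial fields around a homogeneous equilibrium.

    Returns ``{"u": ..., "v": ..., "w": ...}`` flat arrays over the domain's
    active nodes.  Identical spec and domain give bit-identical fields.
    """
    n = dom.n_nodes
    rng = np.random.default_rng(spec.seed)
    out = {}
    if spec.per_species_independent:
        noises = [rng.standard_normal(n) for _ in range(3)]
    else:
        noises = [rng.standard_normal(n)] * 3
    for name, value, xi in zip(("u", "v", "w"), eq.state, noises):
        out[name] = np.maximum(value * (1.0 + spec.eta * xi), 0.0)
    return out


def atto_fox_term(v, floor: float = ATTO_FOX_FLOOR):
    """Extinction sink -H(floor - v) v: removes biologically meaningless
    sub-cellular densities so that they cannot later regrow."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    v = np.asarray(v, dtype=float)
    out = np.where(v < floor, -v, 0.0)
    return out if out.ndim else float(out)
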