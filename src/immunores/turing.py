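"""Dispersion relation and Turing-instability classification.

Linearising the reaction-diffusion system about a homogeneous steady state
with perturbations ~ exp(lambda_k t + i k x) gives growth rates lambda_k
that are eigenvalues of M_k = J - diag(delta_u, 1, delta_w) k^2, i.e. roots
of the cubic

    lambda_k^3 + a2 lambda_k^2 + a1 lambda_k + a0 = 0,

with a0 = A k^6 + B k^4 + C k^2 + D a cubic in k^2.  A kinetics-stable
state is Turing (stationary, finite-wavelength) unstable iff a0 < 0 at the
interior minimum k_c^2 of that cubic.  k^2 is treated as continuous here
(infinite-domain idealisation); finite-domain mode quantisation k = n pi / L
is applied by the continuation and simulation layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import Equilibrium, coexistence_equilibria
from .kinetics import reaction_jacobian
from .params import NondimParams

__all__ = [
    "DispersionCoefficients",
    "GrowthRates",
    "TuringResult",
    "dispersion_coefficients",
    "growth_rates",
    "max_growth_rate",
    "critical_wavenumber",
    "turing_test",
    "scan_turing_plane",
]


@dataclass(frozen=True)
class DispersionCoefficients:
    """Cubic characteristic coefficients at one wavenumber-squared.

    (a2, a1, a0) are the lambda_k-cubic coefficients at the given k2;
    (A, B, C, D) the coefficients of a0 as a cubic in k^2.
    """

    a2: float
    a1: float
    a0: float
    A: float
    B: float
    C: float
    D: float
    k2: float


@dataclass(frozen=True)
class GrowthRates:
    """The three roots lambda_k of the dispersion cubic at one k^2."""

    k2: float
    lambdas: tuple[complex, complex, complex]

    @property
    def max_real(self) -> float:
        return max(l.real for l in self.lambdas)


@dataclass(frozen=True)
class TuringResult:
    """Outcome of the Turing test at one equilibrium.

    ``unstable`` is True only for a kinetics-stable state with a0(k_c^2) < 0.
    ``ode_stable`` records whether the base state was stable without
    diffusion (the test is vacuous otherwise).
    """

    unstable: bool
    ode_stable: bool
    k_c2: float | None = None
    a0_at_kc: float | None = None


def dispersion_coefficients(J: np.ndarray, delta_u: float, delta_w: float,
                            k2: float) -> DispersionCoefficients:
    """Characteristic-cubic coefficients of M_k at wavenumber-squared k2.

    The tumour species' diffusivity is 1 after nondimensionalisation, so
    the trace coefficient is a2 = (delta_u + 1 + delta_w) k^2 - tr J.
    """
    if k2 < 0:
        raise ValueError("k2 must be >= 0")
    J = np.asarray(J, dtype=float)
    J11, J12, J13 = J[0]
    J21, J22, J23 = J[1]
    J31, J32, J33 = J[2]
    du, dw = delta_u, delta_w
    a2 = (du + 1.0 + dw) * k2 - (J11 + J22 + J33)
    a1 = ((du + du * dw + dw) * k2**2
          - (du * (J22 + J33) + (J11 + J33) + dw * (J11 + J22)) * k2
          + J11 * J22 + J11 * J33 + J22 * J33
          - J12 * J21 - J13 * J31 - J23 * J32)
    A = du * dw
    B = -(du * J33 + du * dw * J22 + dw * J11)
    C = (du * J22 * J33 + J11 * J33 + dw * J11 * J22
         - du * J23 * J32 - J13 * J31 - dw * J12 * J21)
    D = (-J11 * J22 * J33 + J11 * J23 * J32 + J12 * J21 * J33
         - J12 * J23 * J31 - J13 * J21 * J32 + J13 * J22 * J31)
    a0 = A * k2**3 + B * k2**2 + C * k2 + D
    return DispersionCoefficients(a2, a1, a0, A, B, C, D, k2)


def growth_rates(J: np.ndarray, delta_u: float, delta_w: float, k2: float) -> GrowthRates:
    """The three growth rates lambda_k at wavenumber-squared k2."""
    c = dispersion_coefficients(J, delta_u, delta_w, k2)
    lam = np.roots([1.0, c.a2, c.a1, c.a0])
    lam = lam[np.argsort(-lam.real)]
    return GrowthRates(k2, tuple(lam))


def max_growth_rate(J: np.ndarray, delta_u: float, delta_w: float, k2) -> np.ndarray:
    """max Re lambda_k over the dispersion cubic, vectorised over k2."""
    k2 = np.atleast_1d(np.asarray(k2, dtype=float))
    out = np.array([growth_rates(J, delta_u, delta_w, float(x)).max_real for x in k2])
    return out if out.size > 1 else out[0]


def critical_wavenumber(A: float, B: float, C: float) -> float:
    """Location k_c^2 of the interior minimum of a0(k^2).

    k_c^2 = (-2B + sqrt(4B^2 - 12AC)) / (6A).  Raises if A <= 0 or the
    discriminant is negative (a0 has no interior extremum for k^2 > 0).
    """
    if A <= 0:
        raise ValueError("A must be positive")
    disc = 4.0 * B**2 - 12.0 * A * C
    if disc < 0:
        raise ValueError("negative discriminant: no interior extremum of a0")
    kc2 = (-2.0 * B + np.sqrt(disc)) / (6.0 * A)
    if kc2 <= 0:
        raise ValueError("no positive stationary point of a0")
    return float(kc2)


def turing_test(p: NondimParams, eq: Equilibrium) -> TuringResult:
    """Test one equilibrium for diffusion-driven (Turing) instability.

    Cancer-free states always return unstable=False: their (u, w)
    perturbation subsystem is triangular and v-perturbations are not
    admissible at v0 = 0.  A kinetics-unstable base state is flagged
    not-Turing with ode_stable=False.
    """
    if not eq.stable:
        return TuringResult(False, ode_stable=False)
    if eq.kind == "cancer_free":
        return TuringResult(False, ode_stable=True)
    J = reaction_jacobian(eq.state, p)
    c0 = dispersion_coefficients(J, p.delta_u, p.delta_w, 0.0)
    try:
        kc2 = critical_wavenumber(c0.A, c0.B, c0.C)
    except ValueError:
        return TuringResult(False, ode_stable=True)
    a0_kc = c0.A * kc2**3 + c0.B * kc2**2 + c0.C * kc2 + c0.D
    return TuringResult(bool(a0_kc < 0), True, k_c2=kc2, a0_at_kc=float(a0_kc))


def scan_turing_plane(alpha: float, delta_u: float, delta_w: float,
                      sigma_u_grid, sigma_w_grid,
                      base: NondimParams | None = None) -> np.ndarray:
    """Three-way Turing classification over a (sigma_u, sigma_w) grid.

    Each cell is labelled ``"no_coexistence"``, ``"coex_stable_all"`` or
    ``"coex_turing_unstable"``; where several kinetics-stable coexistence
    states exist the cell reports Turing-unstable if any of them is
    (multistability is collapsed, as in the reference classification).
    """
    from .params import table1_nondim

    sigma_u_grid = np.asarray(sigma_u_grid, dtype=float)
    sigma_w_grid = np.asarray(sigma_w_grid, dtype=float)
    if base is None:
        base = table1_nondim(alpha=alpha, delta_u=delta_u, delta_w=delta_w)
    out = np.empty((len(sigma_u_grid), len(sigma_w_grid)), dtype=object)
    for i, su in enumerate(sigma_u_grid):
        for j, sw in enumerate(sigma_w_grid):
            p = base.replace(alpha=alpha, delta_u=delta_u, delta_w=delta_w,
                             sigma_u=float(su), sigma_w=float(sw))
            eqs = coexistence_equilibria(p, method="quintic")
            if not eqs:
                out[i, j] = "no_coexistence"
                continue
            results = [turing_test(p, e) for e in eqs if e.stable]
            if any(r.unstable for r in results):
                out[i, j] = "coex_turing_unstable"
            else:
                out[i, j] = "coex_stable_all"
    return out
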