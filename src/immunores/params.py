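"""Parameter sets for the effector-cell / tumour / IL-2 reaction-diffusion model.

Two parameterisations are used:

* :class:`DimensionalParams` — rates in days^-1, densities in cells cm^-1,
  diffusivities in cm^2 day^-1.  These exist for provenance (the published
  literature estimates) and for the two physical diffusivity estimators.
* :class:`NondimParams` — the eleven dimensionless groups obtained by scaling
  time by the tumour growth rate, tumour density by the carrying capacity,
  and space by the tumour diffusion length.  All analysis in this package
  operates on :class:`NondimParams`; the tumour species' own diffusivity is
  identically 1 after the rescaling and is therefore not a field.

The canonical nondimensional values (``table1_nondim``) are the rounded
published ones (mu_u = 0.167, rho_u = 0.692, mu_w = 55.56, ...), which is
the parameter set all quantitative reference results were produced with.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

try:  # Python >= 3.11
    import tomllib
except ImportError:  # pragma: no cover
    tomllib = None

__all__ = [
    "DimensionalParams",
    "ScalingSet",
    "NondimParams",
    "PhysicalEstimateInput",
    "nondimensionalise",
    "redimensionalise",
    "stokes_einstein_diffusivity",
    "tumour_diffusivity",
    "table1_dimensional",
    "table1_nondim",
    "load_params",
    "dump_params",
]

#: CODATA Boltzmann constant, J K^-1.
K_BOLTZMANN = 1.380649e-23

#: Unit conversion: m^2 s^-1 -> cm^2 day^-1.
M2_PER_S_TO_CM2_PER_DAY = 1.0e4 * 86400.0


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional model parameters.

    Rates (c, m_E, m_IL, p_E, p_T, p_IL, r_T) are in day^-1, half-saturation
    densities (g_E, g_T, g_IL) in cells cm^-1, diffusivities in cm^2 day^-1,
    b (inverse carrying capacity) in cm cells^-1 and the treatment sources
    s_E (cells cm^-1 day^-1) and s_IL (IL-2 units cm^-1 day^-1).
    """

    d_E: float
    d_T: float
    d_IL: float
    c: float
    m_E: float
    m_IL: float
    p_E: float
    p_T: float
    p_IL: float
    g_E: float
    g_T: float
    g_IL: float
    s_E: float
    s_IL: float
    r_T: float
    b: float

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val):
                raise ValueError(f"{f.name} must be finite, got {val!r}")
            if f.name in ("s_E", "s_IL", "c"):
                if val < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {val}")
            elif val <= 0:
                raise ValueError(f"{f.name} must be > 0, got {val}")

    def replace(self, **kw) -> "DimensionalParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ScalingSet:
    """Characteristic scales used in the nondimensionalisation.

    t_s = 1/r_T (tumour growth time), T0 = 1/b (carrying capacity),
    IL0 = g_E (effector half-saturation of IL-2), E0 = r_T/(b p_T) and
    X = sqrt(d_T / r_T) (tumour diffusion length).
    """

    E0: float
    T0: float
    IL0: float
    t_s: float
    X: float


@dataclass(frozen=True)
class NondimParams:
    """The eleven dimensionless parameters of the rescaled model.

    delta_u, delta_w are effector and IL-2 diffusivities relative to the
    tumour's; alpha the tumour-induced immune response; mu_u, mu_w decay
    rates; rho_u, rho_w stimulated production rates; sigma_u, sigma_w the
    effector-cell and IL-2 treatment inputs; gamma_v, gamma_w
    half-saturation densities relative to the carrying capacity.

    The treatment inputs sigma_u, sigma_w may be negative: steady-state
    branches are continued to unphysical values to resolve fold points.
    The simulation layer rejects negative treatment.
    """

    alpha: float
    mu_u: float
    rho_u: float
    sigma_u: float
    gamma_v: float
    delta_u: float
    mu_w: float
    rho_w: float
    sigma_w: float
    gamma_w: float
    delta_w: float

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val):
                raise ValueError(f"{f.name} must be finite, got {val!r}")
            if val < 0 and f.name not in ("sigma_u", "sigma_w"):
                raise ValueError(f"{f.name} must be >= 0, got {val!r}")

    def replace(self, **kw) -> "NondimParams":
        return replace(self, **kw)

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PhysicalEstimateInput:
    """Inputs for the physical diffusivity estimates.

    temperature in K, cell_radius in m, viscosity in kg m^-1 s^-1,
    cell_diameter in cm, duplication_rate in day^-1.
    """

    temperature: float = 310.0
    cell_radius: float = 4.0e-6
    viscosity: float = 6.922e-4
    cell_diameter: float = 1.1e-3
    duplication_rate: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


def stokes_einstein_diffusivity(inp: PhysicalEstimateInput) -> float:
    """Stokes-Einstein diffusivity k_B T / (6 pi R eta) in cm^2 day^-1.

    For a sphere of radius R moving through a fluid of viscosity eta at
    low Reynolds number.  With T = 310 K, R = 4 um and the viscosity of
    water this gives ~7e-5 cm^2/day, the effector-cell motility estimate.
    """
    if inp.cell_radius <= 0 or inp.viscosity <= 0:
        raise ValueError("cell_radius and viscosity must be positive")
    d_m2_s = K_BOLTZMANN * inp.temperature / (6.0 * math.pi * inp.cell_radius * inp.viscosity)
    return d_m2_s * M2_PER_S_TO_CM2_PER_DAY


def tumour_diffusivity(inp: PhysicalEstimateInput) -> float:
    """Tumour-cell motility estimate D^2 lambda (cm^2 day^-1).

    D is the cell diameter in cm and lambda the duplication rate per day:
    a cell effectively takes a step of its own size each division.
    """
    return inp.cell_diameter**2 * inp.duplication_rate


def nondimensionalise(dim: DimensionalParams) -> tuple[NondimParams, ScalingSet]:
    """Map dimensional parameters to the dimensionless groups and scales."""
    for name in ("r_T", "b", "p_T", "g_E", "d_T"):
        if getattr(dim, name) <= 0:
            raise ValueError(f"{name} must be positive to nondimensionalise")
    scales = ScalingSet(
        E0=dim.r_T / (dim.b * dim.p_T),
        T0=1.0 / dim.b,
        IL0=dim.g_E,
        t_s=1.0 / dim.r_T,
        X=math.sqrt(dim.d_T / dim.r_T),
    )
    nd = NondimParams(
        alpha=dim.p_T * dim.c / dim.r_T**2,
        mu_u=dim.m_E / dim.r_T,
        rho_u=dim.p_E / dim.r_T,
        sigma_u=dim.b * dim.p_T * dim.s_E / dim.r_T**2,
        gamma_v=dim.g_T * dim.b,
        delta_u=dim.d_E / dim.d_T,
        mu_w=dim.m_IL / dim.r_T,
        rho_w=dim.p_IL / (dim.b * dim.p_T * dim.g_E),
        sigma_w=dim.s_IL / (dim.g_E * dim.r_T),
        gamma_w=dim.g_IL * dim.b,
        delta_w=dim.d_IL / dim.d_T,
    )
    return nd, scales


def redimensionalise(nd: NondimParams, scales: ScalingSet) -> DimensionalParams:
    """Invert :func:`nondimensionalise` given the scaling set."""
    r_T = 1.0 / scales.t_s
    b = 1.0 / scales.T0
    p_T = r_T / (b * scales.E0)
    g_E = scales.IL0
    d_T = scales.X**2 * r_T
    return DimensionalParams(
        d_E=nd.delta_u * d_T,
        d_T=d_T,
        d_IL=nd.delta_w * d_T,
        c=nd.alpha * r_T**2 / p_T,
        m_E=nd.mu_u * r_T,
        m_IL=nd.mu_w * r_T,
        p_E=nd.rho_u * r_T,
        p_T=p_T,
        p_IL=nd.rho_w * b * p_T * g_E,
        g_E=g_E,
        g_T=nd.gamma_v / b,
        g_IL=nd.gamma_w / b,
        s_E=nd.sigma_u * r_T**2 / (b * p_T),
        s_IL=nd.sigma_w * g_E * r_T,
        r_T=r_T,
        b=b,
    )


_DATA_DIR = Path(__file__).parent / "data"


def table1_dimensional(
    c: float = 0.0126, s_E: float = 0.0, s_IL: float = 0.0,
    d_E: float = 1.21e-4, d_IL: float = 1.21e-4, d_T: float = 1.21e-6,
) -> DimensionalParams:
    """Published dimensional parameter set.

    The free choices (immune response c, treatment sources, diffusivities
    within their published ranges) default to values whose dimensionless
    images are alpha = 0.07, sigma_u = sigma_w = 0, delta_u = delta_w = 100.
    """
    with open(_DATA_DIR / "table1.toml", "rb") as fh:
        fixed = tomllib.load(fh)["dimensional"]
    return DimensionalParams(d_E=d_E, d_T=d_T, d_IL=d_IL, c=c, s_E=s_E, s_IL=s_IL, **fixed)


def table1_nondim(
    alpha: float = 0.07,
    sigma_u: float = 0.0,
    sigma_w: float = 0.0,
    delta_u: float = 100.0,
    delta_w: float = 100.0,
) -> NondimParams:
    """Canonical (published, rounded) nondimensional kinetic parameters.

    mu_u = 0.167, rho_u = 0.692, gamma_v = 0.1, mu_w = 55.56, rho_w = 2.5,
    gamma_w = 1e-3; the bifurcation parameters alpha, sigma_u, sigma_w,
    delta_u, delta_w are free arguments.
    """
    with open(_DATA_DIR / "table1.toml", "rb") as fh:
        fixed = tomllib.load(fh)["nondimensional"]
    return NondimParams(
        alpha=alpha, sigma_u=sigma_u, sigma_w=sigma_w,
        delta_u=delta_u, delta_w=delta_w, **fixed,
    )


def load_params(path: str | Path) -> NondimParams | DimensionalParams:
    """Read a parameter set from a TOML or JSON key-value file.

    The file must contain exactly one of the tables ``[nondimensional]``
    (all 11 fields) or ``[dimensional]`` (all 16 fields).
    """
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            doc = json.load(fh)
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    has_nd = "nondimensional" in doc
    has_dim = "dimensional" in doc
    if has_nd == has_dim:
        raise ValueError("parameter file must contain exactly one of "
                         "[nondimensional] or [dimensional]")
    if has_nd:
        return NondimParams(**doc["nondimensional"])
    return DimensionalParams(**doc["dimensional"])


def dump_params(params: NondimParams | DimensionalParams, path: str | Path) -> None:
    """Write a parameter set as JSON (key-value, round-trips with load_params)."""
    key = "nondimensional" if isinstance(params, NondimParams) else "dimensional"
    with open(path, "w") as fh:
        json.dump({key: asdict(params)}, fh, indent=1)
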