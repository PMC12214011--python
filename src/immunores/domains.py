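"""Spatial domains and discrete Laplacians.

1D intervals use the centred 3-point stencil; 2D squares the compact
9-point stencil (weights 4 and 1 for edge and corner neighbours over 6 h^2,
exact for quadratics); discs a masked Cartesian grid with a stair-step rim.
Homogeneous Neumann conditions are imposed by ghost-node reflection.  For
Dirichlet dosing of the IL-2 field the rim rows of the operator are zeroed
and the rim values are prescribed by the protocol instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["Domain1D", "DomainND", "build_laplacian", "nonlinear_diffusion_apply"]


def _lap1d(m: int, h: float) -> sp.csr_matrix:
    """3-point Neumann Laplacian on m equispaced nodes (vertex-centred)."""
    e = np.ones(m)
    D = sp.diags([e[:-1], -2.0 * e, e[:-1]], [-1, 0, 1], format="lil")
    D[0, 1] = 2.0  # ghost reflection at both ends
    D[-1, -2] = 2.0
    return (D / h**2).tocsr()


@dataclass(frozen=True)
class DomainND:
    """A discretised interval, square, or disc.

    ``geometry`` is one of "interval", "square", "disc" (diameter L).
    ``mask`` marks active nodes of the bounding grid (all nodes except for
    the disc), ``boundary`` the domain-boundary nodes among the active ones
    (flattened indexing over active nodes).
    """

    geometry: str
    L: float
    shape: tuple[int, ...]
    h: float
    mask: np.ndarray = field(repr=False)
    boundary: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return int(self.mask.sum())

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def to_grid(self, f: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a flat active-node field back onto the bounding grid."""
        g = np.full(self.shape, fill, dtype=float)
        g[self.mask] = f
        return g

    @staticmethod
    def interval(L: float, m: int) -> "DomainND":
        if m < 3:
            raise ValueError("need at least 3 nodes")
        h = L / (m - 1)
        mask = np.ones(m, dtype=bool)
        boundary = np.zeros(m, dtype=bool)
        boundary[[0, -1]] = True
        return DomainND("interval", L, (m,), h, mask, boundary, np.linspace(0.0, L, m))

    @staticmethod
    def square(L: float, m: int) -> "DomainND":
        if m < 3:
            raise ValueError("need at least 3 nodes per side")
        h = L / (m - 1)
        mask = np.ones((m, m), dtype=bool)
        b = np.zeros((m, m), dtype=bool)
        b[0, :] = b[-1, :] = b[:, 0] = b[:, -1] = True
        return DomainND("square", L, (m, m), h, mask, b.ravel(), np.linspace(0.0, L, m))

    @staticmethod
    def disc(L: float, m: int) -> "DomainND":
        """Disc of diameter L on an m x m bounding grid.

        Active nodes are those whose centres lie inside the circle; the
        boundary is the stair-step rim (active nodes with a missing
        4-neighbour).
        """
        if m < 3:
            raise ValueError("need at least 3 nodes per side")
        h = L / (m - 1)
        x = np.linspace(0.0, L, m)
        X, Y = np.meshgrid(x, x, indexing="ij")
        r = L / 2.0
        mask = (X - r) ** 2 + (Y - r) ** 2 < r**2 + 1e-12
        inside = mask.astype(int)
        nb = np.zeros_like(inside)
        nb[1:, :] += inside[:-1, :]
        nb[:-1, :] += inside[1:, :]
        nb[:, 1:] += inside[:, :-1]
        nb[:, :-1] += inside[:, 1:]
        rim = mask & (nb < 4)
        return DomainND("disc", L, (m, m), h, mask, rim[mask], x)


def build_laplacian(dom: DomainND, bc: str = "neumann") -> sp.csr_matrix:
    """Discrete Laplacian over the domain's active nodes.

    ``bc="neumann"``: zero-flux closure by ghost reflection everywhere.
    ``bc="dirichlet"``: rows at domain-boundary nodes are zeroed — the
    caller prescribes those values (used for IL-2 boundary dosing); interior
    rows still couple to the boundary columns.
    """
    if bc not in ("neumann", "dirichlet"):
        raise ValueError(f"unknown bc {bc!r}")
    if dom.geometry == "interval":
        Lap = _lap1d(dom.shape[0], dom.h)
    elif dom.geometry == "square":
        m = dom.shape[0]
        D = _lap1d(m, dom.h)
        I = sp.identity(m, format="csr")
        # 9-point compact stencil: Dxx + Dyy + h^2/6 Dxx Dyy
        Lap = (sp.kron(D, I) + sp.kron(I, D) + (dom.h**2 / 6.0) * sp.kron(D, D)).tocsr()
    else:  # disc: masked 5-point, zero-flux across the stair-step rim
        m = dom.shape[0]
        idx_grid = -np.ones(dom.shape, dtype=int)
        idx_grid[dom.mask] = np.arange(dom.n_nodes)
        rows, cols, vals = [], [], []
        ii, jj = np.nonzero(dom.mask)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = ii + di, jj + dj
            ok = (ni >= 0) & (ni < m) & (nj >= 0) & (nj < m)
            ok[ok] &= dom.mask[ni[ok], nj[ok]]
            a = idx_grid[ii[ok], jj[ok]]
            b = idx_grid[ni[ok], nj[ok]]
            rows.extend([a, a])
            cols.extend([b, a])
            vals.extend([np.ones(len(a)), -np.ones(len(a))])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals) / dom.h**2
        Lap = sp.csr_matrix((vals, (rows, cols)), shape=(dom.n_nodes, dom.n_nodes))
    if bc == "dirichlet":
        Lap = Lap.tolil()
        Lap[np.flatnonzero(dom.boundary), :] = 0.0
        Lap = Lap.tocsr()
    Lap.eliminate_zeros()
    return Lap


class Domain1D:
    """Convenience alias: a 1D interval domain (used by continuation)."""

    def __new__(cls, L: float, m: int) -> DomainND:
        return DomainND.interval(L, m)


def _face_pairs(dom: DomainND):
    """Faces between adjacent active nodes with ghost-reflection weights.

    Returns (a, b, w_a, w_b) per face: node indices and the accumulation
    weight for each side.  A node with a single neighbour along an axis has
    its face contribution doubled along that axis (mirror ghost), matching
    the Neumann closure of the linear 3-point operator.  Cached per domain.
    """
    cache = getattr(dom, "_faces", None)
    if cache is not None:
        return cache
    if dom.geometry == "interval":
        m = dom.shape[0]
        a = np.arange(m - 1)
        axes = [(a, a + 1)]
        n_nodes = m
    else:
        m = dom.shape[0]
        idx_grid = -np.ones(dom.shape, dtype=int)
        idx_grid[dom.mask] = np.arange(dom.n_nodes)
        ii, jj = np.nonzero(dom.mask)
        axes = []
        for di, dj in ((1, 0), (0, 1)):
            ni, nj = ii + di, jj + dj
            ok = (ni < m) & (nj < m)
            ok[ok] &= dom.mask[ni[ok], nj[ok]]
            axes.append((idx_grid[ii[ok], jj[ok]], idx_grid[ni[ok], nj[ok]]))
        n_nodes = dom.n_nodes
    A, B, WA, WB = [], [], [], []
    for a, b in axes:
        deg = np.zeros(n_nodes)
        np.add.at(deg, a, 1.0)
        np.add.at(deg, b, 1.0)
        A.append(a)
        B.append(b)
        WA.append(np.where(deg[a] == 1.0, 2.0, 1.0))
        WB.append(np.where(deg[b] == 1.0, 2.0, 1.0))
    pairs = tuple(np.concatenate(x) for x in (A, B, WA, WB))
    object.__setattr__(dom, "_faces", pairs)
    return pairs


def nonlinear_diffusion_apply(v: np.ndarray, dom: DomainND) -> np.ndarray:
    """Volume-filling tumour transport div((1 - v)^2 grad v).

    Conservative finite-volume form: the face diffusivity is the average of
    (1 - v)^2 at the two adjacent nodes, times the face-normal difference;
    zero-flux (Neumann) closure by ghost reflection at all domain
    boundaries.  Uses the 5-point face set in 2D.
    """
    a, b, wa, wb = _face_pairs(dom)
    Dv = (1.0 - v) ** 2
    flux = 0.5 * (Dv[a] + Dv[b]) * (v[b] - v[a]) / dom.h**2
    out = np.zeros_like(v)
    np.add.at(out, a, wa * flux)
    np.add.at(out, b, -wb * flux)
    return out
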