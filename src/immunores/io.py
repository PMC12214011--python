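"""Output writers: trajectories to HDF5, tables to CSV, run manifests.

Every output carries the SHA-256 hash of the canonicalised run
configuration so that reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .continuation import Branch
from .simulate import Trajectory, summarise

__all__ = [
    "config_hash",
    "write_manifest",
    "trajectory_to_hdf5",
    "export_kymograph",
    "read_kymograph",
    "averages_to_csv",
    "branch_to_csv",
    "labels_to_csv",
]


def config_hash(cfg: dict) -> str:
    """SHA-256 of the canonical (sorted-key) JSON form of a configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path: str | Path, cfg: dict, outputs: dict[str, str],
                   seed: int | None = None) -> dict:
    """Write a JSON run manifest (config, hash, outputs) and return it."""
    import immunores

    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "version": immunores.__version__,
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def trajectory_to_hdf5(traj: Trajectory, path: str | Path, cfg: dict | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("t", data=traj.t)
        for name in ("u", "v", "w"):
            fh.create_dataset(name, data=getattr(traj, name))
        if traj.dom is not None:
            g = fh.create_group("domain")
            g.attrs["geometry"] = traj.dom.geometry
            g.attrs["L"] = traj.dom.L
            g.attrs["shape"] = traj.dom.shape
            g.create_dataset("mask", data=traj.dom.mask)
        fh.attrs["params"] = json.dumps(traj.params.asdict())
        if cfg is not None:
            fh.attrs["config_hash"] = config_hash(cfg)
        if traj.extinction is not None:
            fh.attrs["extinction"] = traj.extinction


def export_kymograph(traj: Trajectory, path: str | Path, png: bool = False) -> np.ndarray:
    """Write the (time x space) tumour-density array of a 1D run as CSV.

    Rows are save times, columns grid nodes; the first column holds the
    time stamps.  Optionally renders a PNG alongside.
    """
    _, kymo = summarise(traj)
    if kymo is None:
        raise ValueError("kymographs require a 1D (interval) trajectory")
    df = pd.DataFrame(kymo, index=pd.Index(traj.t, name="t"))
    df.to_csv(path)
    if png:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(kymo.T, aspect="auto", origin="lower",
                  extent=(traj.t[0], traj.t[-1], 0.0, traj.dom.L))
        ax.set_xlabel("t")
        ax.set_ylabel("x")
        fig.savefig(Path(path).with_suffix(".png"), dpi=120)
        plt.close(fig)
    return kymo


def read_kymograph(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Round-trip reader for :func:`export_kymograph` output."""
    df = pd.read_csv(path, index_col=0)
    return df.index.to_numpy(dtype=float), df.to_numpy(dtype=float)


def averages_to_csv(traj: Trajectory, path: str | Path) -> None:
    averages, _ = summarise(traj)
    pd.DataFrame(averages).to_csv(path, index=False)


def branch_to_hdf5(branch: Branch, path: str | Path) -> None:
    """Full branch record: per-point fields, parameter values, norms, tags."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["param_name"] = branch.param_name
        fh.attrs["provenance"] = branch.provenance
        fh.attrs["message"] = branch.message
        fh.create_dataset("param", data=np.array([p.param for p in branch.points]))
        fh.create_dataset("fields", data=np.array([p.fields for p in branch.points]))
        fh.create_dataset("v_l1", data=np.array([p.v_l1 for p in branch.points]))
        fh.create_dataset("tag", data=np.array([p.tag for p in branch.points],
                                               dtype=h5py.string_dtype()))
        stab = np.array([-1 if p.stable is None else int(p.stable)
                         for p in branch.points])
        fh.create_dataset("stable", data=stab)


def branch_to_csv(branch: Branch, path: str | Path) -> None:
    """Branch summary: parameter, L1 norm of v, stability, tag per point."""
    rows = [{"param": pt.param, "v_l1": pt.v_l1, "v_mean": pt.v_mean,
             "stable": pt.stable, "tag": pt.tag} for pt in branch.points]
    pd.DataFrame(rows).to_csv(path, index=False)


def labels_to_csv(labels: np.ndarray, sigma_u_grid, sigma_w_grid, path: str | Path) -> None:
    """Long-format (sigma_u, sigma_w, label) export of a plane scan."""
    su, sw = np.meshgrid(sigma_u_grid, sigma_w_grid, indexing="ij")
    lab = np.array([str(getattr(x, "value", x)) for x in labels.ravel()])
    pd.DataFrame({"sigma_u": su.ravel(), "sigma_w": sw.ravel(),
                  "label": lab}).to_csv(path, index=False)


def labels_to_png(labels: np.ndarray, sigma_u_grid, sigma_w_grid,
                  path: str | Path) -> None:
    """Render a plane-scan label matrix as a categorical map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = sorted({str(getattr(x, "value", x)) for x in labels.ravel()})
    index = {n: i for i, n in enumerate(names)}
    img = np.array([[index[str(getattr(x, "value", x))] for x in row]
                    for row in labels])
    fig, ax = plt.subplots(figsize=(6, 5))
    pc = ax.imshow(img.T, origin="lower", aspect="auto",
                   extent=(sigma_u_grid[0], sigma_u_grid[-1],
                           sigma_w_grid[0], sigma_w_grid[-1]),
                   cmap="viridis", vmin=-0.5, vmax=len(names) - 0.5)
    cbar = fig.colorbar(pc, ticks=range(len(names)))
    cbar.ax.set_yticklabels(names)
    ax.set_xlabel(r"$\sigma_u$")
    ax.set_ylabel(r"$\sigma_w$")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def branch_to_png(branches, path: str | Path, param_label: str = "parameter") -> None:
    """Bifurcation diagram: ||v||_L1 against the parameter, solid where
    stable, dotted where unstable or of unknown stability."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(branches, Branch):
        branches = [branches]
    fig, ax = plt.subplots(figsize=(6, 4))
    for bi, br in enumerate(branches):
        pv = br.params
        l1 = br.v_l1
        stable = np.array([bool(p.stable) for p in br.points])
        colour = f"C{bi}"
        ax.plot(np.where(stable, pv, np.nan), np.where(stable, l1, np.nan),
                "-", lw=2, color=colour, label=br.provenance)
        ax.plot(np.where(~stable, pv, np.nan), np.where(~stable, l1, np.nan),
                ":", lw=1, color=colour)
    ax.set_xlabel(param_label)
    ax.set_ylabel(r"$\|v\|_{L^1}$")
    ax.legend(loc="best", fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
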