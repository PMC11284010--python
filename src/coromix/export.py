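"""Field and report serialization: legacy-VTK, HDF5 bundles, CSV samples.

The VTK writer emits minimal legacy ASCII ``STRUCTURED_GRID`` files (one
per stored time step) that load in ParaView; the HDF5 bundle keeps the
whole simulation (temperatures, times, grid, mask, provenance attributes)
in one file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__

__all__ = ["write_vtk", "export_vtk_series", "write_hdf5", "write_samples_csv"]


def _grid_points(field):
    """Cell-centre points of the wrapped cylindrical lattice, (n, 3) mm."""
    g = field.grid
    theta = np.append(g.theta_centers, g.theta_centers[0])  # close the ring
    r, th, z = np.meshgrid(g.r_centers, theta, g.z_centers, indexing="ij")
    pts = np.column_stack(
        [(r * np.cos(th)).ravel(order="F"), (r * np.sin(th)).ravel(order="F"), z.ravel(order="F")]
    )
    return pts, (g.nr, theta.size, g.nz)


def write_vtk(field, path, time_index: int) -> Path:
    """One stored snapshot as a legacy ASCII VTK structured grid."""
    path = Path(path)
    pts, dims = _grid_points(field)
    temp = field.temperature[time_index]  # (nz, nr, ntheta)
    wrapped = np.concatenate([temp, temp[:, :, :1]], axis=2)  # close the ring
    scal = np.transpose(wrapped, (1, 2, 0)).ravel(order="F")
    mask = np.concatenate([field.mask, field.mask[:, :, :1]], axis=2)
    mask_s = np.transpose(mask, (1, 2, 0)).ravel(order="F")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(
            f"coromix t={field.times[time_index]:.6f}s {field.protocol.label}\n"
        )
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        fh.write(f"POINTS {len(pts)} float\n")
        np.savetxt(fh, pts, fmt="%.6g")
        fh.write(f"POINT_DATA {len(pts)}\n")
        fh.write("SCALARS temperature_C float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, np.nan_to_num(scal, nan=-1.0), fmt="%.6g")
        fh.write("SCALARS domain_label int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mask_s, fmt="%d")
    return path


def export_vtk_series(field, outdir, prefix: str | None = None) -> list[Path]:
    """All stored snapshots, one VTK file per time step."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or field.protocol.label
    return [
        write_vtk(field, outdir / f"{prefix}_{i:03d}.vtk", i)
        for i in range(field.times.size)
    ]


def write_hdf5(field, path, extra_attrs: dict | None = None) -> Path:
    """Whole simulation as one HDF5 bundle with provenance attributes."""
    path = Path(path)
    g = field.grid
    with h5py.File(path, "w") as h5:
        h5.create_dataset("temperature_C", data=field.temperature, compression="gzip")
        h5["times_s"] = field.times
        h5["mask"] = field.mask
        grp = h5.create_group("grid")
        grp["z_centers_mm"] = g.z_centers
        grp["r_centers_mm"] = g.r_centers
        grp["theta_centers_rad"] = g.theta_centers
        h5.attrs["software_version"] = __version__
        h5.attrs["protocol"] = json.dumps(_asdict(field.protocol))
        h5.attrs["geometry"] = json.dumps(_asdict(field.geometry))
        h5.attrs["mixing_model"] = json.dumps(_asdict(field.mixing))
        h5.attrs["pulsatility"] = field.pulsatility
        h5.attrs["z_injection_mm"] = field.z_injection
        for k, v in (extra_attrs or {}).items():
            h5.attrs[k] = v
    return path


def _asdict(obj):
    d = dataclasses.asdict(obj)
    return {k: (v.value if hasattr(v, "value") else v) for k, v in d.items()}


def write_samples_csv(field, sample, t_mk, path, header_meta: str = "") -> Path:
    """Per-point time-averaged cross-section temperatures as CSV."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "r_mm": sample.r,
            "theta_rad": sample.theta,
            "wire_masked": sample.wire_mask,
            "temperature_C": t_mk,
        }
    )
    with open(path, "w") as fh:
        if header_meta:
            fh.write(f"# {header_meta}\n")
        df.to_csv(fh, index=False)
    return path
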