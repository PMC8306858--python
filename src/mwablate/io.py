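"""Field output: legacy-ASCII VTK rectilinear grids, HDF5 and CSV traces."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .geometry import AxisymGrid

__all__ = ["write_vtk", "write_hdf5", "read_hdf5"]


def write_vtk(path, grid: AxisymGrid, cell_data=None, point_data=None, title="mwablate fields"):
    """Write the (r, z) plane as a VTK legacy rectilinear grid.

    The radial axis maps to VTK x, the axial axis to y.  ``cell_data`` and
    ``point_data`` are name -> 2D array mappings; complex arrays are split
    into magnitude and phase.
    """
    path = Path(path)
    nr, nz = grid.shape

    def expand(data):
        out = {}
        for name, arr in (data or {}).items():
            arr = np.asarray(arr)
            if np.iscomplexobj(arr):
                out[f"{name}_mag"] = np.abs(arr)
                out[f"{name}_phase"] = np.angle(arr)
            else:
                out[name] = arr
        return out

    cdata, pdata = expand(cell_data), expand(point_data)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\n")
        f.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        f.write(f"DIMENSIONS {nr} {nz} 1\n")
        for axis, coords in (
            ("X", grid.r_coords),
            ("Y", grid.z_coords),
            ("Z", np.array([0.0])),
        ):
            f.write(f"{axis}_COORDINATES {len(coords)} double\n")
            f.write(" ".join(f"{c:.12g}" for c in coords) + "\n")

        def dump(section, n, data):
            if not data:
                return
            f.write(f"{section} {n}\n")
            for name, arr in data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                flat = np.nan_to_num(np.asarray(arr, float)).ravel(order="F")
                f.write("\n".join(f"{v:.9g}" for v in flat) + "\n")

        dump("CELL_DATA", (nr - 1) * (nz - 1), cdata)
        dump("POINT_DATA", nr * nz, pdata)
    return path


def write_hdf5(path, grid: AxisymGrid, datasets=None, attrs=None):
    """Store the grid plus named arrays in an HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        g.create_dataset("r_coords", data=grid.r_coords)
        g.create_dataset("z_coords", data=grid.z_coords)
        g.create_dataset("labels", data=grid.labels)
        d = f.create_group("fields")
        for name, arr in (datasets or {}).items():
            d.create_dataset(name, data=np.asarray(arr))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
    return path


def read_hdf5(path):
    """Load a file written by :func:`write_hdf5`; returns (grid, fields, attrs)."""
    with h5py.File(path, "r") as f:
        grid = AxisymGrid(
            f["grid/r_coords"][()],
            f["grid/z_coords"][()],
            f["grid/labels"][()],
        )
        fields = {k: f["fields"][k][()] for k in f["fields"]}
        attrs = dict(f.attrs)
    return grid, fields, attrs
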