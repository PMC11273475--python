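"""Artifact writers: legacy-ASCII VTK structured grids, HDF5 phantoms, CSVs."""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk_structured_points", "phantom_to_hdf5"]


def write_vtk_structured_points(path, origin, spacing, cell_data: dict) -> None:
    """Write voxel-grid cell data as a legacy-ASCII VTK STRUCTURED_POINTS file.

    ``origin`` is the corner of the first cell (m), ``spacing`` the isotropic
    voxel size (m); each entry of ``cell_data`` is an (nx, ny, nz) array.
    """
    arrays = {name: np.asarray(a) for name, a in cell_data.items()}
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError("all cell-data arrays must share one shape")
    nx, ny, nz = shapes.pop()
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("mihsim voxel grid\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        f.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        f.write(f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}\n")
        f.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, a in arrays.items():
            kind = "int" if np.issubdtype(a.dtype, np.integer) else "float"
            f.write(f"SCALARS {name.replace(' ', '_')} {kind} 1\n")
            f.write("LOOKUP_TABLE default\n")
            flat = a.ravel(order="F")  # x varies fastest in legacy VTK
            np.savetxt(f, flat.reshape(-1, 1), fmt="%.9g")


def phantom_to_hdf5(phantom, path) -> None:
    """Store labels plus grid metadata (voxel size, origin, tissue names)."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("labels", data=phantom.labels, compression="gzip")
        d.attrs["voxel_size_m"] = phantom.voxel_size
        d.attrs["origin_m"] = phantom.origin
        d.attrs["tissue_names"] = [n.encode() for n in phantom.tissue_names]
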