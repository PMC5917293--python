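"""Minimal VTK XML ImageData (.vti) writer for field snapshots.

Writes ASCII-encoded .vti files readable by ParaView/VisIt/pyvista, with
point data on the voxel-center grid.  Scalar arrays have shape
(nx, ny, nz); vector arrays (3, nx, ny, nz).
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vti"]


def _fmt(arr: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in arr.ravel())


def write_vti(
    path,
    dims: tuple[int, int, int],
    spacing: float,
    origin,
    arrays: dict[str, np.ndarray],
) -> None:
    """Write named point-data arrays on a regular grid to a .vti file."""
    nx, ny, nz = dims
    origin = np.asarray(origin, dtype=float)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">',
        f'  <ImageData WholeExtent="0 {nx - 1} 0 {ny - 1} 0 {nz - 1}"'
        f' Origin="{origin[0]} {origin[1]} {origin[2]}"'
        f' Spacing="{spacing} {spacing} {spacing}">',
        f'    <Piece Extent="0 {nx - 1} 0 {ny - 1} 0 {nz - 1}">',
        "      <PointData>",
    ]
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        if arr.ndim == 4 and arr.shape[0] == 3:
            # VTK expects x-fastest point order with interleaved components
            flat = np.moveaxis(arr, 0, -1).transpose(2, 1, 0, 3)
            lines.append(
                f'        <DataArray type="Float64" Name="{name}"'
                ' NumberOfComponents="3" format="ascii">'
            )
        elif arr.ndim == 3:
            flat = arr.transpose(2, 1, 0)
            lines.append(
                f'        <DataArray type="Float64" Name="{name}" format="ascii">'
            )
        else:
            raise ValueError(f"array {name!r} must be (nx,ny,nz) or (3,nx,ny,nz)")
        lines.append("          " + _fmt(flat))
        lines.append("        </DataArray>")
    lines += [
        "      </PointData>",
        "    </Piece>",
        "  </ImageData>",
        "</VTKFile>",
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
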