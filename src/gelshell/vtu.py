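"""Minimal VTU (XML unstructured grid) writer plus a .pvd time-series index.

ASCII output only — the files are plain text and readable by any standard
VTK/ParaView installation.  Only triangle cells are emitted (VTK type 5).
"""

from __future__ import annotations

import os
from xml.sax.saxutils import escape

import numpy as np

from .errors import DimensionError

_VTK_TRIANGLE = 5


def _format_array(name: str, data: np.ndarray, indent: str) -> str:
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 1:
        ncomp = 1
        flat = data
    elif data.ndim == 2:
        ncomp = data.shape[1]
        flat = data.ravel()
    else:
        raise DimensionError(f"field {name!r} must be 1D or 2D")
    body = " ".join(f"{x:.16g}" for x in flat)
    return (
        f'{indent}<DataArray type="Float64" Name="{escape(name)}" '
        f'NumberOfComponents="{ncomp}" format="ascii">\n'
        f"{indent}  {body}\n"
        f"{indent}</DataArray>\n"
    )


def write_vtu(mesh, path, point_fields=None, cell_fields=None):
    """Write a triangle mesh plus named vertex/element arrays to a VTU file.

    ``mesh`` needs ``vertices`` (n, 3) and ``triangles`` (m, 3) attributes.
    Field arrays may be scalars (length n or m) or vectors ((n, 3)/(m, 3)).
    """
    point_fields = point_fields or {}
    cell_fields = cell_fields or {}
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    tris = np.asarray(mesh.triangles, dtype=np.int64)
    n, m = len(verts), len(tris)
    for name, arr in point_fields.items():
        if len(np.asarray(arr)) != n:
            raise DimensionError(
                f"point field {name!r} has length {len(np.asarray(arr))}, "
                f"expected {n}"
            )
    for name, arr in cell_fields.items():
        if len(np.asarray(arr)) != m:
            raise DimensionError(
                f"cell field {name!r} has length {len(np.asarray(arr))}, "
                f"expected {m}"
            )

    parts = []
    parts.append(
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">\n'
        "  <UnstructuredGrid>\n"
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n'
    )
    parts.append("      <Points>\n")
    parts.append(
        '        <DataArray type="Float64" NumberOfComponents="3" '
        'format="ascii">\n          '
        + " ".join(f"{x:.16g}" for x in verts.ravel())
        + "\n        </DataArray>\n"
    )
    parts.append("      </Points>\n      <Cells>\n")
    parts.append(
        '        <DataArray type="Int64" Name="connectivity" format="ascii">\n'
        "          " + " ".join(str(i) for i in tris.ravel()) + "\n"
        "        </DataArray>\n"
    )
    parts.append(
        '        <DataArray type="Int64" Name="offsets" format="ascii">\n'
        "          " + " ".join(str(3 * (i + 1)) for i in range(m)) + "\n"
        "        </DataArray>\n"
    )
    parts.append(
        '        <DataArray type="UInt8" Name="types" format="ascii">\n'
        "          " + " ".join(str(_VTK_TRIANGLE) for _ in range(m)) + "\n"
        "        </DataArray>\n      </Cells>\n"
    )
    if point_fields:
        parts.append("      <PointData>\n")
        for name, arr in point_fields.items():
            parts.append(_format_array(name, np.asarray(arr), "        "))
        parts.append("      </PointData>\n")
    if cell_fields:
        parts.append("      <CellData>\n")
        for name, arr in cell_fields.items():
            parts.append(_format_array(name, np.asarray(arr), "        "))
        parts.append("      </CellData>\n")
    parts.append("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))


class VtuSeries:
    """Maintains a ParaView collection (.pvd) index across time steps."""

    def __init__(self, directory, basename="step"):
        self.directory = str(directory)
        self.basename = basename
        self.entries = []  # (timestep value, relative filename)
        os.makedirs(self.directory, exist_ok=True)

    @property
    def index_path(self):
        return os.path.join(self.directory, f"{self.basename}.pvd")

    def write_step(self, mesh, step, time, point_fields=None, cell_fields=None):
        fname = f"{self.basename}_{step:05d}.vtu"
        write_vtu(
            mesh,
            os.path.join(self.directory, fname),
            point_fields=point_fields,
            cell_fields=cell_fields,
        )
        self.entries.append((float(time), fname))
        self._write_index()
        return fname

    def _write_index(self):
        lines = [
            '<?xml version="1.0"?>',
            '<VTKFile type="Collection" version="0.1" '
            'byte_order="LittleEndian">',
            "  <Collection>",
        ]
        for t, fname in self.entries:
            lines.append(
                f'    <DataSet timestep="{t:.16g}" group="" part="0" '
                f'file="{fname}"/>'
            )
        lines += ["  </Collection>", "</VTKFile>", ""]
        with open(self.index_path, "w") as fh:
            fh.write("\n".join(lines))
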