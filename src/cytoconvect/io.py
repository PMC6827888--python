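"""Minimal readers/writers for the interchange formats the package emits.

VTU (VTK XML unstructured grid, ASCII) carries solution fields for
standard viewers; Gmsh ``.msh`` v2.2 ASCII carries meshes with physical
boundary tags.  Both writers cover exactly the subset the package
produces, and the readers round-trip those files.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np

from .errors import InvalidInputError
from .meshing import Mesh

__all__ = ["write_vtu", "read_vtu", "write_msh", "read_msh"]

_VTK_TRIANGLE = 5
_VTK_TETRA = 10


def write_vtu(path, mesh: Mesh, point_data: dict | None = None) -> None:
    """Write mesh + named nodal arrays as an ASCII .vtu file.

    Vector arrays may have 2 or 3 components (2-D vectors are padded with a
    zero third component so slice/glyph filters behave in viewers).
    """
    point_data = point_data or {}
    pts = np.asarray(mesh.points, dtype=float)
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    cells = mesh.cells
    ctype = _VTK_TRIANGLE if mesh.dim == 2 else _VTK_TETRA
    nv = mesh.dim + 1

    def fmt(arr, per_line):
        arr = np.asarray(arr)
        flat = arr.ravel()
        lines = []
        for i in range(0, len(flat), per_line):
            lines.append(" ".join(repr(float(v)) if arr.dtype.kind == "f"
                                  else str(int(v)) for v in flat[i : i + per_line]))
        return "\n".join(lines)

    parts = []
    parts.append('<?xml version="1.0"?>')
    parts.append('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    parts.append("<UnstructuredGrid>")
    parts.append(f'<Piece NumberOfPoints="{len(pts)}" NumberOfCells="{len(cells)}">')
    parts.append("<Points>")
    parts.append('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    parts.append(fmt(pts, 3))
    parts.append("</DataArray></Points>")
    parts.append("<Cells>")
    parts.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    parts.append(fmt(cells, nv))
    parts.append("</DataArray>")
    parts.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    parts.append(fmt(np.arange(1, len(cells) + 1) * nv, 12))
    parts.append("</DataArray>")
    parts.append('<DataArray type="UInt8" Name="types" format="ascii">')
    parts.append(fmt(np.full(len(cells), ctype, dtype=int), 24))
    parts.append("</DataArray></Cells>")
    parts.append("<PointData>")
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            ncomp = 1
        else:
            if arr.shape[1] == 2:
                arr = np.column_stack([arr, np.zeros(len(arr))])
            ncomp = arr.shape[1]
        parts.append(
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">'
        )
        parts.append(fmt(arr, max(ncomp, 6)))
        parts.append("</DataArray>")
    parts.append("</PointData>")
    parts.append("</Piece></UnstructuredGrid></VTKFile>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")


def read_vtu(path):
    """Read back a .vtu written by :func:`write_vtu`.

    Returns ``(points, cells, point_data)`` with 2-D points restored when
    the third coordinate is identically zero.
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = np.fromstring(
        piece.find("Points/DataArray").text.replace("\n", " "), sep=" "
    ).reshape(-1, 3)
    arrays = {a.get("Name"): a for a in piece.find("Cells")}
    conn = np.fromstring(arrays["connectivity"].text.replace("\n", " "),
                         sep=" ", dtype=int)
    offs = np.fromstring(arrays["offsets"].text.replace("\n", " "),
                         sep=" ", dtype=int)
    nv = offs[0]
    cells = conn.reshape(-1, nv)
    point_data = {}
    pd = piece.find("PointData")
    if pd is not None:
        for a in pd:
            ncomp = int(a.get("NumberOfComponents", "1"))
            data = np.fromstring(a.text.replace("\n", " "), sep=" ")
            if ncomp > 1:
                data = data.reshape(-1, ncomp)
                if ncomp == 3 and np.all(data[:, 2] == 0) and pts.shape[0] and np.all(pts[:, 2] == 0) and nv == 3:
                    data = data[:, :2]
            point_data[a.get("Name")] = data
    if np.all(pts[:, 2] == 0) and nv == 3:
        pts = pts[:, :2]
    return pts, cells, point_data


_MSH_TYPE = {1: 2, 2: 3, 4: 4}  # gmsh element type -> node count
_FACET_TYPE = {2: 1, 3: 2}      # mesh dim -> gmsh boundary element type
_CELL_TYPE = {2: 2, 3: 4}       # mesh dim -> gmsh cell element type


def write_msh(path, mesh: Mesh) -> None:
    """Write the mesh in Gmsh 2.2 ASCII format with physical boundary tags."""
    dim = mesh.dim
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(mesh.tag_names) + 1)]
    for tid, name in sorted(mesh.tag_names.items()):
        lines.append(f'{dim - 1} {tid} "{name}"')
    fluid_tag = max(mesh.tag_names) + 1
    lines.append(f'{dim} {fluid_tag} "fluid"')
    lines.append("$EndPhysicalNames")
    lines += ["$Nodes", str(mesh.n_nodes)]
    for i, p in enumerate(mesh.points, start=1):
        coords = list(p) + [0.0] * (3 - dim)
        lines.append(f"{i} {coords[0]:.16g} {coords[1]:.16g} {coords[2]:.16g}")
    lines.append("$EndNodes")
    n_elem = len(mesh.boundary_facets) + len(mesh.cells)
    lines += ["$Elements", str(n_elem)]
    eid = 1
    ft = _FACET_TYPE[dim]
    for facet, tag in zip(mesh.boundary_facets, mesh.facet_tags):
        nodes = " ".join(str(v + 1) for v in facet)
        lines.append(f"{eid} {ft} 2 {tag} {tag} {nodes}")
        eid += 1
    ct = _CELL_TYPE[dim]
    regions = (
        mesh.element_region
        if mesh.element_region is not None
        else np.zeros(len(mesh.cells), dtype=int)
    )
    for cell, reg in zip(mesh.cells, regions):
        nodes = " ".join(str(v + 1) for v in cell)
        lines.append(f"{eid} {ct} 2 {fluid_tag} {int(reg) + 1} {nodes}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path) -> Mesh:
    """Read a Gmsh 2.2 ASCII mesh (as written by :func:`write_msh`)."""
    with open(path) as fh:
        text = fh.read()

    def section(name):
        start = text.index(f"${name}") + len(name) + 2
        end = text.index(f"$End{name}")
        return text[start:end].strip().splitlines()

    names = {}
    fluid_tag = None
    for line in section("PhysicalNames")[1:]:
        parts = line.split(" ", 2)
        tid = int(parts[1])
        name = parts[2].strip('"')
        if name == "fluid":
            fluid_tag = tid
        else:
            names[tid] = name
    node_lines = section("Nodes")[1:]
    pts3 = np.array([[float(v) for v in ln.split()[1:4]] for ln in node_lines])
    elem_lines = section("Elements")[1:]
    facets, tags, cells, regions = [], [], [], []
    for ln in elem_lines:
        parts = [int(v) for v in ln.split()]
        etype, ntags = parts[1], parts[2]
        phys = parts[3]
        elementary = parts[4] if ntags >= 2 else phys
        nodes = [v - 1 for v in parts[3 + ntags :]]
        if etype in (1, 2) and phys != fluid_tag and phys in names:
            facets.append(nodes)
            tags.append(phys)
        elif phys == fluid_tag:
            cells.append(nodes)
            regions.append(elementary - 1)
    cells = np.asarray(cells, dtype=int)
    dim = cells.shape[1] - 1
    if dim not in (2, 3):
        raise InvalidInputError(f"unsupported element arity in {path}")
    pts = pts3[:, :dim] if dim == 2 and np.all(pts3[:, 2] == 0) else pts3[:, :dim]
    regions = np.asarray(regions, dtype=int)
    return Mesh(
        points=pts,
        cells=cells,
        boundary_facets=np.asarray(facets, dtype=int),
        facet_tags=np.asarray(tags, dtype=int),
        tag_names=names,
        element_region=regions if len(np.unique(regions)) > 1 else None,
    )
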