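"""Simplicial mesh generation for cell domains.

Two mesh families cover every domain in the package:

* 2-D: structured "star" triangulations of the annular region between the
  nucleus wall and the membrane.  Rays are cast from the nucleus center
  (both walls are star-shaped with respect to it), giving a boundary-
  conforming quad grid split into triangles.
* 3-D: the fluid shell between an eccentric spherical nucleus and the
  spherical membrane, built by radially extruding a subdivided-icosahedron
  triangulation of the unit sphere and splitting each prism into three
  tetrahedra with index-based diagonal selection so neighbouring prisms
  always conform.

Boundary facets carry exactly one tag: ``w1`` (membrane), ``w2`` (nucleus
wall) or a named heat patch.  Multi-cell sheets suffix tags with the cell
index (``w1:3``); lookups by base name match all cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidInputError, MeshingError
from .geometry import CellGeometry, HeatPatch, Membrane, Nucleus

__all__ = [
    "Mesh",
    "build_spherical_cell",
    "build_star_cell",
    "build_columnar_sheet",
    "merge_meshes",
    "icosphere",
]


# ----------------------------------------------------------------------------
# mesh container
# ----------------------------------------------------------------------------


@dataclass
class Mesh:
    """Simplicial mesh (triangles or tetrahedra) with tagged boundary facets.

    Coordinates are micrometres.  ``facet_tags`` indexes into ``tag_names``;
    ``element_region`` identifies the (disconnected) fluid region of each
    element in multi-cell domains.  ``geometry`` optionally keeps the analytic
    descriptor of a single-region domain for particle-wall reflection.
    """

    points: np.ndarray            # (n_nodes, dim), μm
    cells: np.ndarray             # (n_elems, dim+1) int
    boundary_facets: np.ndarray   # (n_facets, dim) int
    facet_tags: np.ndarray        # (n_facets,) int
    tag_names: dict               # int -> str
    element_region: np.ndarray | None = None
    geometry: CellGeometry | None = None

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    def element_volumes(self) -> np.ndarray:
        """Signed element areas (2-D) / volumes (3-D) in μm^dim."""
        p = self.points[self.cells]
        e = p[:, 1:, :] - p[:, :1, :]
        if self.dim == 2:
            return 0.5 * np.linalg.det(e)
        return np.linalg.det(e) / 6.0

    def volume(self) -> float:
        """Total meshed fluid area/volume (μm^dim)."""
        return float(np.sum(self.element_volumes()))

    def tag_id(self, name: str) -> int:
        for k, v in self.tag_names.items():
            if v == name:
                return k
        raise KeyError(name)

    def tags_matching(self, base: str) -> list:
        """Tag ids whose name equals ``base`` or starts with ``base + ':'``."""
        return [
            k
            for k, v in self.tag_names.items()
            if v == base or v.startswith(base + ":")
        ]

    def facets_with_tag(self, base: str) -> np.ndarray:
        ids = self.tags_matching(base)
        if not ids:
            raise KeyError(f"no boundary tag matching {base!r}")
        mask = np.isin(self.facet_tags, ids)
        return self.boundary_facets[mask]

    def nodes_with_tag(self, base: str) -> np.ndarray:
        """Sorted unique node indices lying on facets matching ``base``."""
        return np.unique(self.facets_with_tag(base))

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_facets)

    def element_sizes(self) -> np.ndarray:
        """Longest edge per element (μm)."""
        p = self.points[self.cells]
        nv = p.shape[1]
        h = np.zeros(len(self.cells))
        for i in range(nv):
            for j in range(i + 1, nv):
                h = np.maximum(h, np.linalg.norm(p[:, i] - p[:, j], axis=1))
        return h

    def validate(self) -> None:
        """Raise :class:`MeshingError` on inverted elements, untagged or
        multiply-tagged facets, or a disconnected single-region fluid."""
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise MeshingError(
                f"{int(np.sum(vols <= 0))} inverted/zero-volume elements"
            )
        # every boundary facet appears once and has exactly one tag
        key = np.sort(self.boundary_facets, axis=1)
        uniq = np.unique(key, axis=0)
        if len(uniq) != len(key):
            raise MeshingError("duplicate boundary facets (multiple tags)")
        # boundary facets must match the topological boundary of the cells
        topo = _boundary_facets_of(self.cells, self.dim)
        if len(topo) != len(key):
            raise MeshingError(
                f"tagged facets ({len(key)}) != topological boundary ({len(topo)})"
            )
        # connectivity per region
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        n = self.n_nodes
        i = np.repeat(np.arange(len(self.cells)), self.cells.shape[1])
        j = self.cells.ravel()
        incidence = coo_matrix(
            (np.ones_like(j), (i, j)), shape=(len(self.cells), n)
        ).tocsr()
        adj = incidence @ incidence.T
        ncomp, labels = connected_components(adj > 0, directed=False)
        if self.element_region is None:
            if ncomp != 1:
                raise MeshingError(f"fluid region is disconnected ({ncomp} parts)")
        else:
            nreg = len(np.unique(self.element_region))
            if ncomp != nreg:
                raise MeshingError(
                    f"{ncomp} connected components for {nreg} declared regions"
                )

    def refined(self) -> "Mesh":
        """Uniform red refinement (each simplex split into 2^dim children)."""
        return _refine_uniform(self)


def _boundary_facets_of(cells: np.ndarray, dim: int) -> np.ndarray:
    """Facets belonging to exactly one element."""
    if dim == 2:
        local = [(0, 1), (1, 2), (2, 0)]
    else:
        local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    facets = np.concatenate([cells[:, idx] for idx in local], axis=0)
    key = np.sort(facets, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    return uniq[counts == 1]


def _refine_uniform(mesh: Mesh) -> Mesh:
    pts, cells = mesh.points, mesh.cells
    nv = cells.shape[1]
    # build edge midpoints
    edges = []
    for i in range(nv):
        for j in range(i + 1, nv):
            edges.append(np.sort(cells[:, [i, j]], axis=1))
    edges = np.concatenate(edges, axis=0)
    uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
    mid = 0.5 * (pts[uniq[:, 0]] + pts[uniq[:, 1]])
    new_pts = np.vstack([pts, mid])
    edge_id = {}
    for k, (a, b) in enumerate(uniq):
        edge_id[(int(a), int(b))] = len(pts) + k

    def m(a, b):
        a, b = int(a), int(b)
        return edge_id[(min(a, b), max(a, b))]

    new_cells = []
    new_region = []
    regions = (
        mesh.element_region
        if mesh.element_region is not None
        else np.zeros(len(cells), dtype=int)
    )
    for c, reg in zip(cells, regions):
        if nv == 3:
            a, b, cc = c
            ab, bc, ca = m(a, b), m(b, cc), m(cc, a)
            sub = [(a, ab, ca), (ab, b, bc), (ca, bc, cc), (ab, bc, ca)]
        else:
            a, b, cc, d = c
            ab, ac, ad = m(a, b), m(a, cc), m(a, d)
            bc, bd, cd = m(b, cc), m(b, d), m(cc, d)
            sub = [
                (a, ab, ac, ad),
                (ab, b, bc, bd),
                (ac, bc, cc, cd),
                (ad, bd, cd, d),
                (ab, ac, ad, bd),
                (ab, ac, bd, bc),
                (ac, ad, bd, cd),
                (ac, bc, bd, cd),
            ]
        new_cells.extend(sub)
        new_region.extend([reg] * len(sub))
    new_cells = np.asarray(new_cells, dtype=int)
    # fix inverted children
    p = new_pts[new_cells]
    e = p[:, 1:, :] - p[:, :1, :]
    det = np.linalg.det(e) if mesh.dim == 3 else np.linalg.det(e)
    flip = det < 0
    if np.any(flip):
        new_cells[flip][:, [0, 1]] = new_cells[flip][:, [1, 0]]
        tmp = new_cells[flip].copy()
        tmp[:, [0, 1]] = tmp[:, [1, 0]]
        new_cells[flip] = tmp
    # refine boundary facets, inheriting tags
    new_facets, new_tags = [], []
    for f, t in zip(mesh.boundary_facets, mesh.facet_tags):
        if mesh.dim == 2:
            a, b = f
            ab = m(a, b)
            new_facets += [(a, ab), (ab, b)]
            new_tags += [t, t]
        else:
            a, b, cc = f
            ab, bc, ca = m(a, b), m(b, cc), m(cc, a)
            new_facets += [(a, ab, ca), (ab, b, bc), (ca, bc, cc), (ab, bc, ca)]
            new_tags += [t, t, t, t]
    return Mesh(
        points=new_pts,
        cells=new_cells,
        boundary_facets=np.asarray(new_facets, dtype=int),
        facet_tags=np.asarray(new_tags, dtype=int),
        tag_names=dict(mesh.tag_names),
        element_region=np.asarray(new_region, dtype=int),
        geometry=mesh.geometry,
    )


# ----------------------------------------------------------------------------
# 2-D star-domain mesher
# ----------------------------------------------------------------------------


def _patch_tag_for_angle(theta: float, patches, tag_of: dict) -> int | None:
    for p in patches:
        if p.theta_end - p.theta_start >= 2 * math.pi - 1e-12:
            return tag_of[p.name]  # patch covers the whole wall
        lo, hi = p.theta_start % (2 * math.pi), p.theta_end % (2 * math.pi)
        t = theta % (2 * math.pi)
        inside = lo <= t <= hi if lo <= hi else (t >= lo or t <= hi)
        if inside:
            return tag_of[p.name]
    return None


def build_star_cell(
    geom: CellGeometry,
    target_edge_length: float = 0.75,
    n_theta: int | None = None,
    n_radial: int | None = None,
    tag_suffix: str = "",
) -> Mesh:
    """Mesh a 2-D fluid region between nucleus wall and membrane.

    Both walls must be star-shaped about the nucleus center (true for discs,
    rectangles and convex polygons with an interior nucleus).  The grid is
    structured: ``n_theta`` rays from the nucleus center times ``n_radial``
    layers, each quad split into two triangles.
    """
    if geom.dimension != 2:
        raise InvalidInputError("build_star_cell is 2-D only")
    if target_edge_length <= 0 or not math.isfinite(target_edge_length):
        raise MeshingError(f"degenerate target edge length {target_edge_length!r}")
    c = np.asarray(geom.nucleus.center)
    probe = np.linspace(0, 2 * math.pi, 256, endpoint=False)
    e_probe = np.column_stack([np.cos(probe), np.sin(probe)])
    r_in_p = geom.nucleus.support_radius(e_probe)
    r_out_p = geom.membrane_ray_distance(c, e_probe)
    mean_gap = float(np.mean(r_out_p - r_in_p))
    mean_circ = float(np.mean(2 * math.pi * 0.5 * (r_in_p + r_out_p)))
    if n_theta is None:
        n_theta = max(48, int(round(mean_circ / target_edge_length)))
    if n_radial is None:
        n_radial = max(6, int(round(mean_gap / target_edge_length)))
    th = np.linspace(0, 2 * math.pi, n_theta, endpoint=False)
    e = np.column_stack([np.cos(th), np.sin(th)])
    r_in = geom.nucleus.support_radius(e)
    r_out = geom.membrane_ray_distance(c, e)
    s = np.linspace(0.0, 1.0, n_radial + 1)
    rad = r_in[:, None] + s[None, :] * (r_out - r_in)[:, None]  # (n_theta, n_radial+1)
    pts = c[None, None, :] + rad[:, :, None] * e[:, None, :]
    points = pts.reshape(-1, 2)

    def node(i, j):
        return (i % n_theta) * (n_radial + 1) + j

    tris = []
    for i in range(n_theta):
        for j in range(n_radial):
            a, b = node(i, j), node(i + 1, j)
            d, cpt = node(i, j + 1), node(i + 1, j + 1)
            if (i + j) % 2 == 0:
                tris += [(a, b, cpt), (a, cpt, d)]
            else:
                tris += [(a, b, d), (b, cpt, d)]
    cells = np.asarray(tris, dtype=int)
    # orientation fix
    p = points[cells]
    e1, e2 = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    swap = det < 0
    cells[swap] = cells[swap][:, [0, 2, 1]]

    tag_names = {1: "w1" + tag_suffix, 2: "w2" + tag_suffix}
    tag_of_patch = {}
    for k, patch in enumerate(geom.heat_patches):
        tag_of_patch[patch.name] = 3 + k
        tag_names[3 + k] = patch.name + tag_suffix
    facets, tags = [], []
    dth = 2 * math.pi / n_theta
    for i in range(n_theta):
        facets.append((node(i, 0), node(i + 1, 0)))
        mid = (th[i] + 0.5 * dth)
        t = _patch_tag_for_angle(mid, geom.heat_patches, tag_of_patch)
        tags.append(t if t is not None else 2)
        facets.append((node(i, n_radial), node(i + 1, n_radial)))
        tags.append(1)
    mesh = Mesh(
        points=points,
        cells=cells,
        boundary_facets=np.asarray(facets, dtype=int),
        facet_tags=np.asarray(tags, dtype=int),
        tag_names=tag_names,
        geometry=geom,
    )
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------------
# icosphere and 3-D shell mesher
# ----------------------------------------------------------------------------


def icosphere(subdivisions: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-uniform triangulation of the unit sphere.

    Returns (vertices, faces); 20·4^s faces, 10·4^s + 2 vertices.
    """
    phi = (1 + math.sqrt(5)) / 2
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=int,
    )
    for _ in range(subdivisions):
        edge_mid = {}
        new_faces = []
        verts_list = [v for v in verts]

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in edge_mid:
                m = verts_list[a] + verts_list[b]
                m /= np.linalg.norm(m)
                verts_list.append(m)
                edge_mid[key] = len(verts_list) - 1
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces, dtype=int)
    # orient faces outward
    n = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                 verts[faces[:, 2]] - verts[faces[:, 0]])
    centroid = verts[faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", n, centroid) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return verts, faces


_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1),
    (4, 3, 5, 1, 0, 2),
    (5, 4, 3, 2, 1, 0),
]


def _split_prism(vids: np.ndarray) -> list:
    """Split prism (bottom v0 v1 v2, top v3 v4 v5) into three tetrahedra.

    Diagonals on quad faces pass through the globally smallest vertex index,
    which makes the choice consistent between neighbouring prisms.
    """
    imin = int(np.argmin(vids))
    rot = _PRISM_ROTATIONS[imin]
    v = [vids[r] for r in rot]
    if min(v[1], v[5]) < min(v[2], v[4]):
        tets = [(v[0], v[1], v[2], v[5]), (v[0], v[1], v[5], v[4]),
                (v[0], v[4], v[5], v[3])]
    else:
        tets = [(v[0], v[1], v[2], v[4]), (v[0], v[4], v[2], v[5]),
                (v[0], v[4], v[5], v[3])]
    return tets


def build_spherical_shell_3d(
    geom: CellGeometry,
    subdivisions: int = 3,
    n_radial: int = 8,
    tag_suffix: str = "",
) -> Mesh:
    """Tetrahedral mesh of the fluid between an eccentric spherical nucleus
    and the spherical membrane (both star-shaped about the nucleus center)."""
    if geom.dimension != 3:
        raise InvalidInputError("build_spherical_shell_3d is 3-D only")
    if len(set(geom.nucleus.radii)) != 1:
        raise MeshingError("3-D nucleus must be spherical for shell meshing")
    sverts, sfaces = icosphere(subdivisions)
    c = np.asarray(geom.nucleus.center)
    r_in = geom.nucleus.support_radius(sverts)
    r_out = geom.membrane_ray_distance(c, sverts)
    n_sphere = len(sverts)
    s = np.linspace(0.0, 1.0, n_radial + 1)
    rad = r_in[:, None] + s[None, :] * (r_out - r_in)[:, None]
    pts = c[None, None, :] + rad[:, :, None] * sverts[:, None, :]
    # node index: layer-major — node(v, j) = j * n_sphere + v
    points = pts.transpose(1, 0, 2).reshape(-1, 3)

    def node(v, j):
        return j * n_sphere + v

    tets = []
    for j in range(n_radial):
        base = j * n_sphere
        top = (j + 1) * n_sphere
        for a, b, cc in sfaces:
            prism = np.array([base + a, base + b, base + cc,
                              top + a, top + b, top + cc])
            tets.extend(_split_prism(prism))
    cells = np.asarray(tets, dtype=int)
    p = points[cells]
    det = np.linalg.det(p[:, 1:, :] - p[:, :1, :])
    cells[det < 0] = cells[det < 0][:, [0, 2, 1, 3]]

    tag_names = {1: "w1" + tag_suffix, 2: "w2" + tag_suffix}
    patch_tag = {}
    for k, patch in enumerate(geom.heat_patches):
        patch_tag[patch.name] = 3 + k
        tag_names[3 + k] = patch.name + tag_suffix
    facets, tags = [], []
    centroids = sverts[sfaces].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    for (a, b, cc), ctr in zip(sfaces, centroids):
        tag = 2
        for patch in geom.heat_patches:
            axis = np.array(
                [math.cos(patch.theta_start), 0.0, math.sin(patch.theta_start)]
            )
            if np.arccos(np.clip(ctr @ axis, -1, 1)) <= patch.theta_end:
                tag = patch_tag[patch.name]
                break
        facets.append((a, b, cc))
        tags.append(tag)
        facets.append((node(a, n_radial), node(b, n_radial), node(cc, n_radial)))
        tags.append(1)
    mesh = Mesh(
        points=points,
        cells=cells,
        boundary_facets=np.asarray(facets, dtype=int),
        facet_tags=np.asarray(tags, dtype=int),
        tag_names=tag_names,
        geometry=geom,
    )
    mesh.validate()
    return mesh


def build_spherical_cell(
    geom: CellGeometry,
    target_edge_length: float | None = None,
    subdivisions: int = 3,
    n_radial: int = 8,
) -> Mesh:
    """Mesh the spherical-cell fluid region in the geometry's dimension.

    In 2-D ``target_edge_length`` (μm, default 0.6) controls the structured
    grid; in 3-D resolution is set by icosphere ``subdivisions`` and
    ``n_radial`` layers (defaults ≈ 5 800 nodes for the 10 μm cell).
    """
    if geom.dimension == 2:
        return build_star_cell(geom, target_edge_length or 0.6)
    if target_edge_length is not None:
        # translate an edge-length request into subdivision/layer counts
        R = geom.membrane.radius
        edge0 = 1.05146 * R  # icosahedron edge at unit radius, scaled
        subdivisions = max(1, int(round(math.log2(edge0 / target_edge_length))))
        probe = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        gap = R - max(geom.nucleus.radii) - np.linalg.norm(geom.nucleus.center)
        n_radial = max(4, int(round(abs(gap) * 1.6 / target_edge_length)))
    return build_spherical_shell_3d(geom, subdivisions, n_radial)


# ----------------------------------------------------------------------------
# columnar sheets and mesh merging
# ----------------------------------------------------------------------------


def merge_meshes(meshes: list, regions: list | None = None) -> Mesh:
    """Concatenate independent meshes into one (disconnected) mesh.

    Tag ids are renumbered; tag names must already be unique (use suffixes).
    """
    if not meshes:
        raise InvalidInputError("no meshes to merge")
    offset = 0
    pts, cells, facets, tags = [], [], [], []
    tag_names = {}
    region_arr = []
    next_tag = 1
    for k, m in enumerate(meshes):
        remap = {}
        for tid, name in m.tag_names.items():
            if name in tag_names.values():
                raise InvalidInputError(f"duplicate tag name {name!r} in merge")
            remap[tid] = next_tag
            tag_names[next_tag] = name
            next_tag += 1
        pts.append(m.points)
        cells.append(m.cells + offset)
        facets.append(m.boundary_facets + offset)
        tags.append(np.array([remap[t] for t in m.facet_tags], dtype=int))
        reg = regions[k] if regions is not None else k
        region_arr.append(np.full(len(m.cells), reg, dtype=int))
        offset += m.n_nodes
    merged = Mesh(
        points=np.vstack(pts),
        cells=np.vstack(cells),
        boundary_facets=np.vstack(facets),
        facet_tags=np.concatenate(tags),
        tag_names=tag_names,
        element_region=np.concatenate(region_arr),
    )
    merged.validate()
    return merged


def build_columnar_sheet(
    n_cells: int,
    cell_width: float = 10.0,
    cell_height: float = 25.0,
    nucleus_specs: list | None = None,
    target_edge_length: float = 0.8,
    heat_patches_per_cell: list | None = None,
    gravity_direction: tuple = (0.0, -1.0),
) -> Mesh:
    """Mesh a row of ``n_cells`` columnar epithelial cells (2-D).

    Each cell is an independent fluid region (no inter-cell flow): a
    ``cell_width`` × ``cell_height`` rectangle with its own interior nucleus,
    tagged ``w1:k`` / ``w2:k``.  ``nucleus_specs`` is a list of
    :class:`~cytoconvect.geometry.Nucleus` (coordinates local to each cell,
    origin at the cell's lower-left corner); by default nuclei are circles of
    8 % area fraction centered at mid-width, 30 % height.
    """
    if n_cells < 1:
        raise InvalidInputError("n_cells must be >= 1")
    if nucleus_specs is None:
        r = math.sqrt(0.08 * cell_width * cell_height / math.pi)
        nucleus_specs = [
            Nucleus(center=(cell_width / 2, 0.3 * cell_height), radii=(r,))
            for _ in range(n_cells)
        ]
    if len(nucleus_specs) != n_cells:
        raise InvalidInputError("one nucleus spec per cell required")
    meshes = []
    for k in range(n_cells):
        x0 = k * cell_width
        nuc = nucleus_specs[k]
        center = (nuc.center[0] + x0, nuc.center[1])
        nuc_k = Nucleus(center=center, radii=nuc.radii, angle=nuc.angle)
        verts = (
            (x0, 0.0),
            (x0 + cell_width, 0.0),
            (x0 + cell_width, cell_height),
            (x0, cell_height),
        )
        patches = ()
        if heat_patches_per_cell is not None:
            patches = tuple(heat_patches_per_cell[k])
        geom = CellGeometry(
            dimension=2,
            membrane=Membrane(kind="polygon", vertices=verts, center=(0, 0)),
            nucleus=nuc_k,
            heat_patches=patches,
            gravity_direction=gravity_direction,
        )
        meshes.append(build_star_cell(geom, target_edge_length, tag_suffix=f":{k}"))
    if n_cells == 1:
        single = meshes[0]
        single.element_region = np.zeros(len(single.cells), dtype=int)
        return single
    return merge_meshes(meshes)
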