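"""Embryo geometry: ellipsoid surface tiling, open-prism cell meshes, fluid domain.

The cellularization-stage embryo is modelled as an ellipsoid of revolution
(long axis = x) whose surface is tiled with a disordered hexagonal network of
cell outlines.  Each cell is an open prism: the apical polygon (facing the
vitelline membrane) and the lateral walls are triangulated spring networks,
while the basal face is left open -- only the basal polygonal rim carries
springs, reflecting the basally-open cells of cellularization.

Units throughout: lengths in um, viscosities in nN s/um^2 (1000 cP =
1e-3 nN s/um^2), forces in nN, time in s.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay, SphericalVoronoi

#: compartment codes used on spring and face arrays
APICAL, LATERAL, BASAL = 0, 1, 2
COMPARTMENT_NAMES = ("apical", "lateral", "basal")


@dataclass(frozen=True)
class EmbryoGeometrySpec:
    """Geometric and material parameters of the model embryo.

    Defaults follow measured embryo geometry: a 511 x 184 um ellipsoid,
    cell heights grading from 20 um at mid-embryo to 10 um at the poles,
    a 3 um perivitelline gap filled with ~1 cP fluid, and 1000 cP
    cytoplasm/yolk in the interior.
    """

    long_axis: float = 511.0
    short_axis: float = 184.0
    n_cells: int = 200
    height_mid: float = 20.0
    height_pole: float = 10.0
    perivitelline_gap: float = 3.0
    mu_interior: float = 1e-3
    mu_perivitelline: float = 1e-6
    seed: int = 0
    lloyd_iterations: int = 40

    def __post_init__(self) -> None:
        if not (self.long_axis > self.short_axis > 0):
            raise ValueError("require long_axis > short_axis > 0")
        if not (0 < self.height_pole <= self.height_mid < self.short_axis / 2):
            raise ValueError(
                "require 0 < height_pole <= height_mid < short_axis/2"
            )
        if self.mu_interior <= 0 or self.mu_perivitelline <= 0:
            raise ValueError("viscosities must be strictly positive")
        if self.perivitelline_gap < 0:
            raise ValueError("perivitelline_gap must be >= 0")

    # outer (vitelline) semi-axes
    @property
    def a(self) -> float:
        return self.long_axis / 2.0

    @property
    def b(self) -> float:
        return self.short_axis / 2.0

    # semi-axes of the apical (cell-layer) surface, offset by the gap
    @property
    def a_surface(self) -> float:
        return self.a - self.perivitelline_gap

    @property
    def b_surface(self) -> float:
        return self.b - self.perivitelline_gap

    def with_(self, **kw) -> "EmbryoGeometrySpec":
        return replace(self, **kw)


@dataclass
class CellTiling:
    """Closed polygonal partition of the apical ellipsoid surface.

    ``vertices`` lie exactly on the ellipsoid with semi-axes
    ``(a_surface, b_surface, b_surface)``; ``cells`` are ordered vertex
    loops (predominantly hexagons); ``adjacency`` maps an unordered cell
    pair to the shared edge (vertex index pair).
    """

    vertices: np.ndarray  # (V, 3)
    cells: list  # list of int arrays, ordered loops
    adjacency: dict  # frozenset({ci, cj}) -> (v1, v2)
    semi_axes: tuple  # (a_surface, b_surface)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def edge_map(self) -> dict:
        """Map (min_v, max_v) -> list of incident cell ids."""
        edges: dict = {}
        for ci, loop in enumerate(self.cells):
            for k in range(len(loop)):
                v, w = int(loop[k]), int(loop[(k + 1) % len(loop)])
                edges.setdefault((min(v, w), max(v, w)), []).append(ci)
        return edges

    def cell_areas(self) -> np.ndarray:
        areas = np.empty(self.n_cells)
        for ci, loop in enumerate(self.cells):
            p = self.vertices[loop]
            c = p.mean(axis=0)
            v1 = p - c
            v2 = np.roll(p, -1, axis=0) - c
            areas[ci] = 0.5 * np.linalg.norm(np.cross(v1, v2), axis=1).sum()
        return areas

    def cell_centroids(self) -> np.ndarray:
        return np.array([self.vertices[loop].mean(axis=0) for loop in self.cells])


def _polygon_centroid_on_sphere(pts: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a spherical polygon, projected to the sphere."""
    c = pts.mean(axis=0)
    v1 = pts - c
    v2 = np.roll(pts, -1, axis=0) - c
    w = np.linalg.norm(np.cross(v1, v2), axis=1)
    tri_c = (pts + np.roll(pts, -1, axis=0) + c) / 3.0
    if w.sum() <= 0:
        out = c
    else:
        out = (tri_c * w[:, None]).sum(axis=0) / w.sum()
    return out / np.linalg.norm(out)


def make_ellipsoid_tiling(spec: EmbryoGeometrySpec) -> CellTiling:
    """Tile the apical ellipsoid surface with a disordered hexagonal network.

    Seeded points on the unit sphere are relaxed by a fixed number of Lloyd
    iterations of the spherical Voronoi diagram (a seeded centroidal Voronoi
    tessellation); the resulting vertices are mapped affinely onto the
    ellipsoid.  Re-running with the same spec is bit-identical.
    """
    if spec.n_cells < 12:
        raise ValueError(f"n_cells={spec.n_cells} too small to tile an ellipsoid (need >= 12)")
    rng = np.random.default_rng(spec.seed)
    pts = rng.normal(size=(spec.n_cells, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)

    sv = None
    for _ in range(max(spec.lloyd_iterations, 0)):
        sv = SphericalVoronoi(pts, radius=1.0)
        sv.sort_vertices_of_regions()
        new_pts = np.array(
            [_polygon_centroid_on_sphere(sv.vertices[region]) for region in sv.regions]
        )
        pts = new_pts
    sv = SphericalVoronoi(pts, radius=1.0)
    sv.sort_vertices_of_regions()

    scale = np.array([spec.a_surface, spec.b_surface, spec.b_surface])
    vertices = sv.vertices * scale
    cells = [np.asarray(region, dtype=int) for region in sv.regions]

    tiling = CellTiling(
        vertices=vertices,
        cells=cells,
        adjacency={},
        semi_axes=(spec.a_surface, spec.b_surface),
    )
    # closure check + adjacency construction
    adjacency: dict = {}
    for edge, incident in tiling.edge_map().items():
        if len(incident) != 2:
            raise RuntimeError(
                f"tiling is not closed: edge {edge} shared by {len(incident)} cells"
            )
        adjacency[frozenset(incident)] = edge
    tiling.adjacency = adjacency
    return tiling


def height_profile(axial_position, spec: EmbryoGeometrySpec):
    """Cell height (um) as a smooth symmetric gradient along the long axis.

    Cosine interpolation from ``height_mid`` at the equator to
    ``height_pole`` at the poles of the cell layer.
    """
    x = np.asarray(axial_position, dtype=float)
    if np.any(np.abs(x) > spec.long_axis / 2 + 1e-9):
        raise ValueError("axial position outside the embryo")
    t = np.minimum(np.abs(x) / spec.a_surface, 1.0)
    h = spec.height_pole + (spec.height_mid - spec.height_pole) * 0.5 * (
        1.0 + np.cos(np.pi * t)
    )
    return h if h.ndim else float(h)


@dataclass
class EmbryoMesh:
    """Spring-network mesh of the whole cell layer.

    ``nodes`` holds apical tiling vertices, apical cell centroids and basal
    vertices (in that order).  Springs carry a compartment code
    (APICAL/LATERAL/BASAL) and rest lengths equal to their construction
    lengths, so the mesh is stress-free as built.  ``faces`` are the
    triangles of the apical and lateral surfaces (no basal faces exist).
    """

    nodes: np.ndarray  # (N, 3)
    edges: np.ndarray  # (S, 2) int
    rest_lengths: np.ndarray  # (S,)
    compartment: np.ndarray  # (S,) int8
    faces: np.ndarray  # (F, 3) int
    face_compartment: np.ndarray  # (F,) int8
    pull_edge: tuple  # (apical node, basal node) of the cantilever-contacted edge
    n_cells: int
    spec: EmbryoGeometrySpec
    spring_cells: list = field(default_factory=list)  # owning cell ids per spring
    apical_vertex_count: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_springs(self) -> int:
        return len(self.edges)

    def compartment_mask(self, name: str) -> np.ndarray:
        return self.compartment == COMPARTMENT_NAMES.index(name)

    def copy(self) -> "EmbryoMesh":
        return EmbryoMesh(
            nodes=self.nodes.copy(),
            edges=self.edges,
            rest_lengths=self.rest_lengths,
            compartment=self.compartment,
            faces=self.faces,
            face_compartment=self.face_compartment,
            pull_edge=self.pull_edge,
            n_cells=self.n_cells,
            spec=self.spec,
            spring_cells=self.spring_cells,
            apical_vertex_count=self.apical_vertex_count,
        )


def _inward_normals(vertices: np.ndarray, a: float, b: float) -> np.ndarray:
    grad = np.column_stack(
        [vertices[:, 0] / a**2, vertices[:, 1] / b**2, vertices[:, 2] / b**2]
    )
    n = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    return -n


def build_embryo_mesh(tiling: CellTiling, spec: EmbryoGeometrySpec) -> EmbryoMesh:
    """Extrude the tiling into open prisms and assemble the spring network.

    Apical faces are fan-triangulated about the cell centroid; lateral walls
    are quads split along the shorter diagonal (ties broken toward the lower
    node index); the basal face is left open, represented only by its rim of
    basal springs.  Every tiling vertex is extruded along its inward
    ellipsoid normal by the local height, so adjacent cells share walls.
    """
    a_s, b_s = tiling.semi_axes
    verts = tiling.vertices
    V = len(verts)
    C = tiling.n_cells

    normals_in = _inward_normals(verts, a_s, b_s)
    heights = height_profile(verts[:, 0], spec)
    basal = verts + normals_in * np.asarray(heights)[:, None]

    centroids = np.array(
        [verts[loop].mean(axis=0) for loop in tiling.cells]
    )
    # project centroids onto the apical ellipsoid
    g = np.sqrt(
        (centroids[:, 0] / a_s) ** 2
        + (centroids[:, 1] / b_s) ** 2
        + (centroids[:, 2] / b_s) ** 2
    )
    centroids = centroids / g[:, None]

    nodes = np.vstack([verts, centroids, basal])

    def centroid_idx(ci: int) -> int:
        return V + ci

    def basal_idx(v: int) -> int:
        return V + C + v

    # self-intersection check: basal rim loops must keep apical orientation
    for ci, loop in enumerate(tiling.cells):
        ap = verts[loop]
        ba = basal[loop]
        c_ap, c_ba = ap.mean(axis=0), ba.mean(axis=0)
        n_ap = np.cross(ap - c_ap, np.roll(ap, -1, axis=0) - c_ap).sum(axis=0)
        n_ba = np.cross(ba - c_ba, np.roll(ba, -1, axis=0) - c_ba).sum(axis=0)
        if float(n_ap @ n_ba) <= 0:
            raise ValueError(
                f"extrusion self-intersects at cell {ci}: height exceeds the "
                "local radius of curvature"
            )

    springs: dict = {}  # (i, j) sorted -> compartment
    spring_owner: dict = {}

    def add_spring(i: int, j: int, comp: int, cell: int) -> None:
        key = (i, j) if i < j else (j, i)
        if key not in springs:
            springs[key] = comp
            spring_owner[key] = []
        spring_owner[key].append(cell)

    faces = []
    face_comp = []

    for ci, loop in enumerate(tiling.cells):
        cidx = centroid_idx(ci)
        m = len(loop)
        for k in range(m):
            v, w = int(loop[k]), int(loop[(k + 1) % m])
            # apical polygon edge + fan spokes
            add_spring(v, w, APICAL, ci)
            add_spring(cidx, v, APICAL, ci)
            faces.append((cidx, v, w))
            face_comp.append(APICAL)
            # basal rim
            add_spring(basal_idx(v), basal_idx(w), BASAL, ci)
            # lateral verticals
            add_spring(v, basal_idx(v), LATERAL, ci)

    # lateral walls: one quad per unique tiling edge, split on the shorter diagonal
    done_edges = set()
    for ci, loop in enumerate(tiling.cells):
        m = len(loop)
        for k in range(m):
            v, w = int(loop[k]), int(loop[(k + 1) % m])
            key = (min(v, w), max(v, w))
            if key in done_edges:
                continue
            done_edges.add(key)
            v, w = key
            bv, bw = basal_idx(v), basal_idx(w)
            d1 = np.linalg.norm(nodes[v] - nodes[bw])  # diagonal v-bw
            d2 = np.linalg.norm(nodes[w] - nodes[bv])  # diagonal w-bv
            if d1 < d2 or (d1 == d2 and v < w):
                add_spring(v, bw, LATERAL, ci)
                faces.append((v, w, bw))
                faces.append((v, bw, bv))
            else:
                add_spring(w, bv, LATERAL, ci)
                faces.append((v, w, bv))
                faces.append((w, bw, bv))
            face_comp.append(LATERAL)
            face_comp.append(LATERAL)

    edge_arr = np.array(sorted(springs.keys()), dtype=int)
    comp_arr = np.array([springs[tuple(e)] for e in edge_arr], dtype=np.int8)
    owners = [spring_owner[tuple(e)] for e in edge_arr]
    d = nodes[edge_arr[:, 1]] - nodes[edge_arr[:, 0]]
    rest = np.linalg.norm(d, axis=1)
    if np.any(rest <= 0):
        raise RuntimeError("degenerate spring of zero length in constructed mesh")

    # cantilever contact: vertical lateral edge of the vertex nearest the
    # dorsal mid-embryo point (0, 0, b_surface)
    target = np.array([0.0, 0.0, b_s])
    pull_v = int(np.argmin(np.linalg.norm(verts - target, axis=1)))
    pull_edge = (pull_v, basal_idx(pull_v))

    return EmbryoMesh(
        nodes=nodes,
        edges=edge_arr,
        rest_lengths=rest,
        compartment=comp_arr,
        faces=np.array(faces, dtype=int),
        face_compartment=np.array(face_comp, dtype=np.int8),
        pull_edge=pull_edge,
        n_cells=C,
        spec=spec,
        spring_cells=owners,
        apical_vertex_count=V,
    )


@dataclass
class FluidDomain:
    """Tetrahedral discretization of the fluid inside the vitelline shell.

    The viscosity field takes exactly the two configured values, partitioned
    by the perivitelline gap surface; shell nodes carry the no-slip
    condition of the rigid vitelline membrane.
    """

    nodes: np.ndarray  # (N, 3)
    tets: np.ndarray  # (T, 4) int
    viscosity: np.ndarray  # (N,)
    shell_mask: np.ndarray  # (N,) bool
    node_volumes: np.ndarray  # (N,)
    resolution: float
    semi_axes: tuple  # outer (a, b)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def interior_mask(self) -> np.ndarray:
        return ~self.shell_mask


def _fibonacci_ellipsoid(n: int, a: float, b: float) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    sph = np.column_stack([z, r * np.cos(phi), r * np.sin(phi)])
    return sph * np.array([a, b, b])


def build_fluid_domain(
    spec: EmbryoGeometrySpec,
    resolution: float,
    collapse_gap: bool = False,
    n_shell: int | None = None,
) -> FluidDomain:
    """Mesh the fluid interior of the vitelline shell with tetrahedra.

    Interior nodes are a Cartesian grid at the given spacing; shell nodes
    sample the vitelline ellipsoid; the node count scales as
    (size/resolution)^3.  The gap region gets ``mu_perivitelline`` and the
    interior ``mu_interior``.  If the resolution cannot resolve the gap the
    call fails unless ``collapse_gap`` explicitly merges the thin layer into
    the shell (lubrication treatment).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if not collapse_gap and resolution > spec.perivitelline_gap:
        raise ValueError(
            f"resolution {resolution} um cannot resolve the "
            f"{spec.perivitelline_gap} um perivitelline gap; pass "
            "collapse_gap=True to merge it into the shell"
        )
    a, b = spec.a, spec.b
    ax = np.arange(-a, a + resolution / 2, resolution)
    bx = np.arange(-b, b + resolution / 2, resolution)
    X, Y, Z = np.meshgrid(ax, bx, bx, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    g = np.sqrt((pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / b) ** 2)
    # keep points at least half a spacing inside the shell
    interior = pts[g <= 1.0 - 0.5 * resolution / b]

    if n_shell is None:
        # aim for shell spacing comparable to the volume resolution
        area = 4 * np.pi * ((a * b + a * b + b * b) / 3.0)  # rough ellipsoid area
        n_shell = max(64, int(area / resolution**2))
    shell = _fibonacci_ellipsoid(n_shell, a, b)

    nodes = np.vstack([interior, shell])
    shell_mask = np.zeros(len(nodes), dtype=bool)
    shell_mask[len(interior):] = True

    tri = Delaunay(nodes)
    tets = tri.simplices

    p = nodes[tets]
    vol = np.abs(
        np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
    ) / 6.0
    node_volumes = np.zeros(len(nodes))
    np.add.at(node_volumes, tets.ravel(), np.repeat(vol / 4.0, 4))

    if collapse_gap:
        visc = np.full(len(nodes), spec.mu_interior)
        visc[shell_mask] = spec.mu_interior
    else:
        a_i, b_i = a - spec.perivitelline_gap, b - spec.perivitelline_gap
        gi = np.sqrt(
            (nodes[:, 0] / a_i) ** 2
            + (nodes[:, 1] / b_i) ** 2
            + (nodes[:, 2] / b_i) ** 2
        )
        visc = np.where(gi > 1.0, spec.mu_perivitelline, spec.mu_interior)

    return FluidDomain(
        nodes=nodes,
        tets=tets,
        viscosity=visc,
        shell_mask=shell_mask,
        node_volumes=node_volumes,
        resolution=resolution,
        semi_axes=(a, b),
    )
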