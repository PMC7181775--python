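"""Cortical source space: triangle meshes, edge (gradient) operators, geodesic patches.

The source space is a triangulated cortical surface with one current dipole per
vertex (cortical current density convention, orientation normal to the surface).
Everything downstream — the discrete gradient operator ``V`` whose L1 norm is
the edge-sparsity penalty, geodesic region growing for simulated focal patches,
and area-weighted overlap metrics — lives on this mesh.

Coordinates are millimetres, faces are 0-based vertex triples, and vertex areas
are the usual barycentric lumping (one third of each incident triangle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "CorticalMesh",
    "GradientOperator",
    "SourcePatch",
    "build_gradient_operator",
    "grow_patch",
    "icosphere",
    "fibonacci_sphere",
    "flat_grid",
    "read_off",
    "read_obj",
]


@dataclass
class CorticalMesh:
    """Triangulated cortical surface holding the N-source grid.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in mm.
    faces : (F, 3) int array
        0-based vertex index triples.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_areas: np.ndarray = field(init=False)
    adjacency: list = field(init=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (F, 3) array")
        n = len(self.vertices)
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= n:
            raise ValueError("face indices out of range")
        referenced = np.zeros(n, dtype=bool)
        referenced[self.faces.ravel()] = True
        if not referenced.all():
            isolated = np.flatnonzero(~referenced)
            raise ValueError(
                f"mesh has isolated vertices not referenced by any face: {isolated.tolist()}"
            )
        self.vertex_areas = self._lumped_vertex_areas()
        self.adjacency = self._vertex_adjacency()

    def _face_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def _lumped_vertex_areas(self) -> np.ndarray:
        fa = self._face_areas()
        areas = np.zeros(len(self.vertices))
        for k in range(3):
            np.add.at(areas, self.faces[:, k], fa / 3.0)
        return areas

    def _vertex_adjacency(self) -> list:
        nbrs = [set() for _ in range(len(self.vertices))]
        for i, j, k in self.faces:
            nbrs[i].update((j, k))
            nbrs[j].update((i, k))
            nbrs[k].update((i, j))
        return [np.array(sorted(s), dtype=int) for s in nbrs]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def total_area(self) -> float:
        return float(self.vertex_areas.sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (M, 2) array, low index first, lexsorted."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_graph(self) -> sp.csr_matrix:
        """Sparse symmetric graph weighted by Euclidean edge length (mm)."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        g = sp.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
        return (g + g.T).tocsr()

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        a, b, c = (self.vertices[self.faces[:, k]] for k in range(3))
        fn = np.cross(b - a, c - a)  # magnitude = 2 * face area
        normals = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(normals, self.faces[:, k], fn)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return normals / norm


@dataclass
class GradientOperator:
    """Signed incidence matrix over unique mesh edges.

    Row m of ``V @ j`` is ``j[b] - j[a]`` for the m-th undirected edge ``(a, b)``
    with ``a < b`` — the discrete spatial gradient whose L1 norm is the
    edge-sparsity (total-variation) penalty.
    """

    V: sp.csr_matrix
    edge_list: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.V.shape[0]


@dataclass
class SourcePatch:
    """A geodesically connected set of vertices: a focally extended source."""

    vertex_ids: np.ndarray
    seed: int
    area: float

    def __post_init__(self):
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=int)

    def __len__(self) -> int:
        return len(self.vertex_ids)

    def indicator(self, n_vertices: int) -> np.ndarray:
        x = np.zeros(n_vertices)
        x[self.vertex_ids] = 1.0
        return x


def build_gradient_operator(mesh: CorticalMesh) -> GradientOperator:
    """Build the discrete gradient operator V on unique undirected edges.

    Sign convention: each edge is oriented low-index -> high-index, so row m
    carries -1 at vertex a and +1 at vertex b (a < b).  Any consistent
    orientation leaves the L1 edge penalty unchanged.
    """
    edges = mesh.edges()
    m = len(edges)
    rows = np.repeat(np.arange(m), 2)
    cols = edges.ravel()
    data = np.tile([-1.0, 1.0], m)
    V = sp.csr_matrix((data, (rows, cols)), shape=(m, mesh.n_vertices))
    return GradientOperator(V=V, edge_list=edges)


def grow_patch(mesh: CorticalMesh, seed: int, target_area: float) -> SourcePatch:
    """Grow a geodesic patch around ``seed`` until its area reaches ``target_area``.

    Vertices are added in order of increasing geodesic (graph) distance to the
    seed, so the patch is a geodesic disc on the mesh; the returned area
    overshoots the target by at most one vertex's area.
    """
    if not (0 <= seed < mesh.n_vertices):
        raise ValueError(f"seed vertex {seed} out of range [0, {mesh.n_vertices})")
    if target_area > mesh.total_area:
        raise ValueError(
            f"target_area {target_area:.1f} exceeds total mesh area {mesh.total_area:.1f}"
        )
    dist = dijkstra(mesh.edge_graph(), directed=False, indices=seed)
    order = np.argsort(dist, kind="stable")
    cum = np.cumsum(mesh.vertex_areas[order])
    # smallest prefix whose area meets the target
    stop = int(np.searchsorted(cum, target_area)) + 1
    stop = min(stop, mesh.n_vertices)
    members = np.sort(order[:stop])
    return SourcePatch(vertex_ids=members, seed=seed, area=float(cum[stop - 1]))


# ---------------------------------------------------------------------------
# mesh constructors and readers


def icosphere(subdivisions: int = 3, radius: float = 70.0) -> CorticalMesh:
    """Triangulated sphere from iterative icosahedron subdivision.

    ``subdivisions=3`` gives 642 vertices, ``4`` gives 2562.  Used as the
    spherical stand-in cortex for simulations (radius in mm, default well
    inside an 80 mm inner skull shell).
    """
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    for _ in range(subdivisions):
        midpoint: dict = {}
        verts_list = list(verts)

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                verts_list.append((verts_list[a] + verts_list[b]) / 2.0)
                midpoint[key] = len(verts_list) - 1
            return midpoint[key]

        new_faces = []
        for i, j, k in faces:
            ij, jk, ki = mid(i, j), mid(j, k), mid(k, i)
            new_faces += [[i, ij, ki], [j, jk, ij], [k, ki, jk], [ij, jk, ki]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=int)
    verts = radius * verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return CorticalMesh(vertices=verts, faces=faces)


def fibonacci_sphere(n_vertices: int = 1000, radius: float = 70.0) -> CorticalMesh:
    """Near-uniform spherical mesh with an arbitrary vertex count.

    Vertices follow the Fibonacci lattice; faces come from the convex hull
    (oriented outward).  Complements :func:`icosphere`, whose vertex counts
    jump in powers of four.
    """
    from scipy.spatial import ConvexHull

    i = np.arange(n_vertices)
    ga = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n_vertices
    r = np.sqrt(1.0 - z ** 2)
    theta = ga * i
    verts = radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    hull = ConvexHull(verts)
    faces = hull.simplices.copy()
    # orient all faces outward
    a, b, c = (verts[faces[:, k]] for k in range(3))
    centroid = (a + b + c) / 3.0
    flip = np.einsum("ij,ij->i", np.cross(b - a, c - a), centroid) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return CorticalMesh(vertices=verts, faces=faces)


def flat_grid(nx: int, ny: int, spacing: float = 5.0) -> CorticalMesh:
    """Flat regular triangulated grid in the z=0 plane (test geometry)."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    faces = []
    for r in range(ny - 1):
        for c in range(nx - 1):
            v0 = r * nx + c
            faces.append([v0, v0 + 1, v0 + nx])
            faces.append([v0 + 1, v0 + nx + 1, v0 + nx])
    return CorticalMesh(vertices=verts, faces=np.array(faces, dtype=int))


def read_off(path) -> CorticalMesh:
    """Read an OFF surface file (vertices and triangular faces only)."""
    with open(path) as fh:
        tokens = iter(fh.read().split())
    header = next(tokens)
    if header != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(next(tokens)), int(next(tokens))
    next(tokens)  # edge count, ignored
    verts = np.array([float(next(tokens)) for _ in range(3 * nv)]).reshape(nv, 3)
    faces = []
    for _ in range(nf):
        k = int(next(tokens))
        idx = [int(next(tokens)) for _ in range(k)]
        if k != 3:
            raise ValueError("only triangular faces supported")
        faces.append(idx)
    return CorticalMesh(vertices=verts, faces=np.array(faces, dtype=int))


def read_obj(path) -> CorticalMesh:
    """Read a Wavefront OBJ surface (v/f records only; 1-based indices)."""
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) != 3:
                    raise ValueError("only triangular faces supported")
                faces.append(idx)
    return CorticalMesh(vertices=np.array(verts), faces=np.array(faces, dtype=int))
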